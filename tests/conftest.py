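"""Shared fixtures: small handmade blocks plus the heavy seeded runs that
several suites reuse (the five-seed fusion experiment sweep and the
full-size LC pretreatment)."""

from __future__ import annotations

import numpy as np
import pytest

from chemfuse import (FusionExperiment, RunConfig,
                      default_design, generate_block, generate_dataset,
                      pretreat_lc)

SWEEP_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def experiment_sweep():
    """Five seeded runs of the full protocol on the reference design.

    Desk-scale problem sizes: 721-point chromatograms, 433-point spectra,
    12 samples per origin class, and the quick forest settings.
    """
    out = {}
    for seed in SWEEP_SEEDS:
        data = generate_dataset(default_design(n_per_class=12, seed=seed))
        out[seed] = FusionExperiment(
            data["lc"][0], data["ftir"][0], RunConfig.quick(seed=seed)).fit()
    return out


@pytest.fixture(scope="session")
def lc_full_scale_pretreated():
    """Full LC chain on an instrument-size (7201-point) chromatogram block."""
    cfg = default_design(n_per_class=2, lc_points=7201, ftir_points=1737,
                         seed=3)
    block, _ = generate_block(cfg, "lc")
    small = block.take_rows(np.arange(3))  # alignment cost scales with rows
    return small, pretreat_lc(small)
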