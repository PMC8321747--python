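"""Flat run configuration with the pipeline's standard defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Every tunable of a full traceability run.

    Defaults follow the pipeline's standard protocol: 1-in-3 grid
    reduction, 15-point second-order SG window, 2:1 Kennard-Stone split,
    7-fold cross-validation, 2000 initial trees, 30 permutation
    iterations, and FTIR band deletion at 1750-2670 and 3700-4000 cm**-1.
    """

    # pretreatment
    segment_length: int = 50
    slack: int = 15
    downsample_k: int = 3
    sg_window: int = 15
    sg_polyorder: int = 2
    ftir_bands: tuple = ((1750.0, 2670.0), (3700.0, 4000.0))
    # split
    split_ratio: tuple = (2, 1)
    # feature extraction
    boruta_alpha: float = 0.05
    boruta_max_iter: int = 100
    boruta_trees: int = 500
    max_components: int = 15
    # classifiers
    max_lv: int = 10
    folds: int = 7
    ntree_init: int = 2000
    mtry_window: int = 10
    # evaluation
    permutation_iter: int = 30
    # fusion
    operators: tuple = ("maximum", "minimum", "average", "product")
    # bookkeeping
    seed: int = 0
    output_dir: str = "chemfuse_out"

    @classmethod
    def quick(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Desk-scale protocol: fewer trees and Boruta iterations.

        Paired with the reduced-grid synthetic design, this keeps a full
        multi-seed experiment in the minutes range while leaving every
        methodological choice (split, folds, windows, operators) intact.
        """
        base = dict(ntree_init=300, boruta_trees=150, boruta_max_iter=40,
                    seed=seed)
        base.update(overrides)
        return cls(**base)


def load_config(path: str | Path) -> RunConfig:
    """Read a flat YAML mapping; unknown keys are errors (typo guard)."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    for key in ("ftir_bands", "split_ratio", "operators"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(tuple(v) if isinstance(v, list) else v
                             for v in raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = {}
    for f in fields(RunConfig):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            v = [list(x) if isinstance(x, tuple) else x for x in v]
        data[f.name] = v
    with Path(path).open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
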