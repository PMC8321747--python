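"""Core in-memory containers for fingerprint data.

A *fingerprint* is an instrument-response vector characterising one sample:
a liquid chromatogram (intensity vs retention time in minutes) or an
ATR-FTIR spectrum (absorbance vs wavenumber in cm**-1).  A block stacks the
fingerprints of m samples measured on a common axis into an m x n matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

AXIS_KINDS = ("retention_time", "wavenumber")


@dataclass
class FingerprintBlock:
    """Sample-by-variable fingerprint matrix with its measurement axis.

    Parameters
    ----------
    values : (m, n) ndarray
        One row per sample, one column per axis position.
    axis : (n,) ndarray
        Retention times (minutes, ascending) or wavenumbers (cm**-1);
        must be strictly monotone.
    axis_kind : {"retention_time", "wavenumber"}
    sample_ids : sequence of m str
    labels : sequence of m class identifiers, optional
    """

    values: np.ndarray
    axis: np.ndarray
    axis_kind: str
    sample_ids: Sequence[str]
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        if self.axis.shape != (n,):
            raise ValueError(
                f"axis length {self.axis.shape} does not match {n} columns"
            )
        d = np.diff(self.axis)
        if n > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"axis_kind must be one of {AXIS_KINDS}")
        self.sample_ids = list(self.sample_ids)
        if len(self.sample_ids) != m:
            raise ValueError("sample_ids length must equal row count")
        if len(set(self.sample_ids)) != m:
            raise ValueError("duplicate sample IDs")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != m:
                raise ValueError("labels length must equal row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, axis: np.ndarray | None = None
                    ) -> "FingerprintBlock":
        """Copy of the block with new values (and optionally a new axis)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            axis=self.axis if axis is None else np.asarray(axis, dtype=float),
        )

    def take_columns(self, idx: np.ndarray) -> "FingerprintBlock":
        idx = np.asarray(idx)
        return self.with_values(self.values[:, idx], self.axis[idx])

    def take_rows(self, idx: np.ndarray) -> "FingerprintBlock":
        idx = np.asarray(idx)
        labels = None if self.labels is None else [self.labels[i] for i in idx]
        return FingerprintBlock(
            self.values[idx], self.axis, self.axis_kind,
            [self.sample_ids[i] for i in idx], labels,
        )


def autoscale(X: np.ndarray, mean: np.ndarray | None = None,
              std: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise mean-centre and unit-variance scale.

    Zero-variance columns are scaled by 1 instead of 0 to stay finite.
    Returns (scaled, mean, std) so validation data can reuse calibration
    statistics.
    """
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
    if std is None:
        std = X.std(axis=0, ddof=1)
    std = np.where(std > 0, std, 1.0)
    return (X - mean) / std, mean, std
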