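"""CSV formats tying the pipeline stages together.

Fingerprint CSV layout
----------------------
Header row: ``sample_id[,label],<axis 1>,<axis 2>,...`` where the axis cells
are the numeric retention times / wavenumbers.  Each following row is one
sample: its ID, optionally its class label, then the intensities.  Values
round-trip losslessly to 12 significant digits.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .blocks import FingerprintBlock


class FingerprintFormatError(ValueError):
    """Malformed fingerprint CSV; message names the offending line."""


def write_fingerprint_csv(block: FingerprintBlock, path: str | Path) -> None:
    path = Path(path)
    has_labels = block.labels is not None
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        head = ["sample_id"] + (["label"] if has_labels else [])
        w.writerow(head + [f"{v:.12g}" for v in block.axis])
        for i, sid in enumerate(block.sample_ids):
            row = [sid] + ([str(block.labels[i])] if has_labels else [])
            w.writerow(row + [f"{v:.12g}" for v in block.values[i]])


def read_fingerprint_csv(path: str | Path,
                         axis_kind: str | None = None) -> FingerprintBlock:
    """Read a fingerprint block, validating structure line by line.

    ``axis_kind`` defaults to ``wavenumber`` for descending axes and
    ``retention_time`` for ascending ones when not given.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FingerprintFormatError(f"{path}: empty file")
    header = rows[0]
    if not header or header[0] != "sample_id":
        raise FingerprintFormatError(f"{path}: line 1: header must start with 'sample_id'")
    has_labels = len(header) > 1 and header[1] == "label"
    skip = 2 if has_labels else 1
    try:
        axis = np.array([float(v) for v in header[skip:]])
    except ValueError as e:
        raise FingerprintFormatError(f"{path}: line 1: non-numeric axis value ({e})") from None
    n = axis.size
    ids, labels, data = [], [], []
    for ln, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != n + skip:
            raise FingerprintFormatError(
                f"{path}: line {ln}: expected {n + skip} fields, got {len(row)} (ragged row)")
        ids.append(row[0])
        if has_labels:
            labels.append(row[1])
        try:
            data.append([float(v) for v in row[skip:]])
        except ValueError as e:
            raise FingerprintFormatError(f"{path}: line {ln}: non-numeric value ({e})") from None
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise FingerprintFormatError(f"{path}: duplicate sample IDs {dupes}")
    if axis_kind is None:
        axis_kind = "wavenumber" if (n > 1 and axis[1] < axis[0]) else "retention_time"
    try:
        return FingerprintBlock(np.array(data), axis, axis_kind, ids,
                                labels if has_labels else None)
    except ValueError as e:
        raise FingerprintFormatError(f"{path}: {e}") from None


def write_split_csv(sample_ids, calibration, validation, path: str | Path) -> None:
    """Two-column CSV (sample_id, set) recording a calibration/validation split."""
    assignment = {}
    for i in calibration:
        assignment[i] = "cal"
    for i in validation:
        assignment[i] = "val"
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "set"])
        for i, sid in enumerate(sample_ids):
            w.writerow([sid, assignment[i]])


def write_ground_truth_csv(truth, path: str | Path) -> None:
    """Serialize generator ground truth (variable index, block, informative flag)."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["variable_index", "block", "informative"])
        for block, idx_set in (("lc", truth.informative_lc),
                               ("ftir", truth.informative_ftir)):
            for j in sorted(idx_set):
                w.writerow([j, block, 1])


def write_feature_decision_csv(decision, axis, path: str | Path) -> None:
    """Serialize a Boruta verdict (variable index, axis value, status, hits)."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["variable_index", "axis_value", "status", "hits"])
        for j, status in enumerate(decision.status):
            w.writerow([j, f"{axis[j]:.12g}", status, decision.hits[j]])
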