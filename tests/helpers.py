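"""Tiny construction helpers shared by the test modules."""

import numpy as np

from chemfuse import FingerprintBlock


def make_block(values, axis=None, kind="retention_time", labels=None):
    values = np.asarray(values, dtype=float)
    if axis is None:
        axis = np.arange(values.shape[1], dtype=float)
    ids = [f"S{i:02d}" for i in range(values.shape[0])]
    return FingerprintBlock(values, axis, kind, ids, labels)
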