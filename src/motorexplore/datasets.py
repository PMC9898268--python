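"""Published reference values bundled for replication checks.

These are the per-participant learning-rate fits and the cluster-selection
BIC curve reported by a published longitudinal study of breaststroke
learning (7 novice swimmers, 16 sessions over two months, each practicing
at a low and a high speed condition).  They let the statistical machinery
be exercised against in-print numbers without access to the study's raw
recordings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["learning_rate_table", "coordination_bic_curve"]

_PARTICIPANTS = [1, 2, 4, 5, 6, 7, 8]

_LOW = {
    "b": [0.0006178, 0.1777, 0.1394, 0.1796, 0.2285, 0.1286, 0.2407],
    "r2": [0.9374, 0.8805, 0.8935, 0.897, 0.8342, 0.9576, 0.95],
    "rmse": [0.0233, 0.0404, 0.0317, 0.0427, 0.045, 0.0261, 0.0247],
}
_HIGH = {
    "b": [0.02319, 0.3423, 0.005785, 0.2656, 0.1559, 0.3524, 0.4648],
    "r2": [0.7468, 0.8571, 0.8777, 0.9159, 0.7573, 0.693, 0.6866],
    "rmse": [0.0484, 0.0467, 0.0402, 0.0442, 0.0642, 0.0338, 0.0484],
}

# BIC (larger is better) for candidate cluster counts K = 2..16
_BIC_K = list(range(2, 17))
_BIC = [-12266770, -12054679, -11835712, -11758107, -11478308, -11414261,
        -11299105, -11096673, -10771125, -10382736, -10477354, -10527102,
        -10513261, -10358955, -10398427]


def learning_rate_table() -> pd.DataFrame:
    """Exponential learning-curve fits per participant and speed condition.

    Long format with columns ``participant``, ``speed`` ("low"/"high"),
    ``b`` (learning rate, 1/session), ``r2`` and ``rmse`` (Hz).
    """
    rows = []
    for speed, block in (("low", _LOW), ("high", _HIGH)):
        for i, p in enumerate(_PARTICIPANTS):
            rows.append({"participant": p, "speed": speed,
                         "b": block["b"][i], "r2": block["r2"][i],
                         "rmse": block["rmse"][i]})
    return pd.DataFrame(rows)


def coordination_bic_curve() -> dict[int, float]:
    """Clustering BIC by candidate cluster count K = 2..16 (larger is
    better), as reported for the pooled cycle set."""
    return {k: float(v) for k, v in zip(_BIC_K, _BIC)}
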