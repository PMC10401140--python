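"""External clustering validation: NMI and ARI.

NMI is the mutual information normalized by the arithmetic mean of the two
partition entropies, 2 I(T,P) / (H(T) + H(P)), so identical partitions
score 1 and independent ones 0. ARI is the chance-corrected Rand index
computed from the pair-count contingency table, in [-1, 1].
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = ["nmi", "ari", "contingency"]


def _validate(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if truth.size == 0:
        raise ValueError("empty label vectors")
    if truth.size != pred.size:
        raise ValueError(f"length mismatch: {truth.size} vs {pred.size}")
    return truth, pred


def contingency(truth, pred) -> np.ndarray:
    """r x c contingency table of the two labelings."""
    truth, pred = _validate(truth, pred)
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=int)
    np.add.at(table, (ti, pi), 1)
    return table


def nmi(truth, pred) -> float:
    """Normalized mutual information in [0, 1]."""
    truth, pred = _validate(truth, pred)
    k_t = np.unique(truth).size
    k_p = np.unique(pred).size
    if k_t == 1 and k_p == 1:
        return 1.0  # both trivially identical single-cluster partitions
    if k_t == 1 or k_p == 1:
        return 0.0  # zero entropy on one side, zero information
    return float(normalized_mutual_info_score(truth, pred, average_method="arithmetic"))


def ari(truth, pred) -> float:
    """Adjusted Rand index in [-1, 1]; 1 for identical partitions."""
    truth, pred = _validate(truth, pred)
    return float(adjusted_rand_score(truth, pred))
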