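"""Independent brute-force oracles used by the acceptance script.

Deliberately naive implementations, kept separate from the package: greedy
farthest-point selection recomputed from scratch at every step, a plain
distance filter for the ball query, and exhaustive Mann-Whitney pair
counting (ties worth one half) for the AUC.
"""

from __future__ import annotations

import numpy as np


def brute_fps(pts: np.ndarray, k: int, start: int) -> np.ndarray:
    sel = [start]
    n = len(pts)
    for _ in range(k - 1):
        dmin = np.full(n, np.inf)
        for j in sel:
            dmin = np.minimum(dmin, np.linalg.norm(pts - pts[j], axis=1))
        dmin[sel] = -1.0
        sel.append(int(np.argmax(dmin)))
    return np.asarray(sel)


def brute_ball(pts: np.ndarray, centroid: int, radius: float) -> np.ndarray:
    d = np.linalg.norm(pts - pts[centroid], axis=1)
    return np.where(d <= radius)[0]


def pair_auc(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return float(wins / (len(pos) * len(neg)))
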