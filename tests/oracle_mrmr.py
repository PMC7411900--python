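"""Naive greedy mRMR oracle: recomputes every MI term from scratch at each
step using an independent dict-of-counts MI estimator."""

from __future__ import annotations

import math

import numpy as np


def oracle_mi(a, b) -> float:
    a, b = list(a), list(b)
    n = len(a)
    joint: dict[tuple, int] = {}
    pa: dict[object, int] = {}
    pb: dict[object, int] = {}
    for x, y in zip(a, b):
        joint[(x, y)] = joint.get((x, y), 0) + 1
        pa[x] = pa.get(x, 0) + 1
        pb[y] = pb.get(y, 0) + 1
    mi = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        mi += pxy * math.log(pxy / (pa[x] / n * pb[y] / n))
    return mi


def oracle_greedy_mid(columns: dict[str, np.ndarray], y: np.ndarray,
                      k: int) -> list[str]:
    """Greedy MID selection, all MI terms recomputed naively at each step.

    Ties break lexicographically by feature name.
    """
    selected: list[str] = []
    remaining = sorted(columns)
    while len(selected) < k and remaining:
        best_name, best_score = None, None
        for name in remaining:
            rel = oracle_mi(columns[name], y)
            if selected:
                red = sum(oracle_mi(columns[name], columns[s])
                          for s in selected) / len(selected)
            else:
                red = 0.0
            score = rel - red
            if best_score is None or score > best_score + 1e-12:
                best_name, best_score = name, score
        selected.append(best_name)
        remaining.remove(best_name)
    return selected
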