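"""Independent brute-force feature oracle.

Direct textbook formulas with explicit loops and an O(n^2) DFT — written
before and kept independent of the vectorized implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_axis_features(x, sample_rate=30.0) -> dict[str, float]:
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    if sd > 0:
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        skew = m3 / sd ** 3
        kurt = m4 / sd ** 4 - 3.0
    else:
        skew = kurt = 0.0

    def percentile(q):
        s = sorted(x)
        h = (n - 1) * q / 100.0
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    centered = [v - mean for v in x]
    signs = [1 if v > 0 else (-1 if v < 0 else 0) for v in centered]
    signs = [s for s in signs if s != 0]
    zc = sum(1 for a, b in zip(signs, signs[1:]) if a != b)

    # O(n^2) DFT, non-DC bins 1..n//2, magnitudes scaled by 2/n.
    nbins = n // 2
    mags = []
    for k in range(1, nbins + 1):
        re = sum(centered[j] * math.cos(2 * math.pi * j * k / n)
                 for j in range(n))
        im = -sum(centered[j] * math.sin(2 * math.pi * j * k / n)
                  for j in range(n))
        mags.append(2.0 / n * math.hypot(re, im))
    power = [m * m for m in mags]
    total = sum(power)
    energy = total / nbins
    if sd > 0 and total > 0:
        best = max(range(nbins), key=lambda k: (mags[k], -k))
        # first maximum = lowest frequency on ties
        best = next(k for k in range(nbins) if mags[k] == mags[best])
        domfreq = (best + 1) * sample_rate / n
        dommag = mags[best]
        probs = [p / total for p in power]
        entropy = -sum(p * math.log(p) for p in probs if p > 0) / math.log(nbins)
    else:
        domfreq = dommag = entropy = 0.0

    return {
        "min": min(x), "max": max(x), "mean": mean, "var": var, "sd": sd,
        "skew": skew, "kurt": kurt, "p25": percentile(25),
        "p50": percentile(50), "p75": percentile(75), "zerocross": float(zc),
        "energy": energy, "domfreq": domfreq, "dommag": dommag,
        "entropy": entropy,
    }


def oracle_pearson(a, b) -> float:
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    sa = math.sqrt(sum((x - ma) ** 2 for x in a) / n)
    sb = math.sqrt(sum((y - mb) ** 2 for y in b) / n)
    if sa == 0 or sb == 0:
        return 0.0
    return cov / (sa * sb)


def oracle_window_features(samples, placement, sample_rate=30.0) -> dict[str, float]:
    samples = np.asarray(samples, dtype=float)
    out = {}
    for ai, ax in enumerate(("x", "y", "z")):
        for name, val in oracle_axis_features(samples[:, ai],
                                              sample_rate).items():
            out[f"{placement}_{ax}_{name}"] = val
    out[f"{placement}_corr_xy"] = oracle_pearson(samples[:, 0], samples[:, 1])
    out[f"{placement}_corr_xz"] = oracle_pearson(samples[:, 0], samples[:, 2])
    out[f"{placement}_corr_yz"] = oracle_pearson(samples[:, 1], samples[:, 2])
    out[f"{placement}_vm_mean"] = float(
        np.mean([math.sqrt(x * x + y * y + z * z) for x, y, z in samples]))
    return out
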