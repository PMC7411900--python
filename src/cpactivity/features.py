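"""Window feature extraction: 49 features per placement.

Per axis (x, y, z), 15 features: min, max, mean, variance, standard deviation,
skewness, kurtosis, 25th/50th/75th percentiles, zero-crossings, energy,
dominant frequency, dominant magnitude, entropy.  Plus the three Pearson
cross-axis correlations and the mean vector magnitude: 15 x 3 + 3 + 1 = 49.

Conventions (fixed so results are reproducible; pinned by oracle tests):

* moments: population (biased) estimators; kurtosis is excess kurtosis;
* percentiles: linear interpolation;
* zero-crossings: sign changes of the mean-centered signal, exact zeros
  ignored;
* spectrum: DFT of the mean-centered, untapered window; only non-DC bins
  (0.1 Hz resolution for a 300-sample window at 30 Hz, up to the 15 Hz
  Nyquist); magnitudes scaled by 2/n so a pure sine of amplitude A yields a
  dominant magnitude of A;
* energy: mean squared scaled magnitude over non-DC bins;
* entropy: Shannon entropy of the non-DC normalized power spectrum divided by
  log(#bins), lying in [0, 1];
* degenerate (zero-variance) axes: skewness = kurtosis = entropy = 0,
  dominant frequency/magnitude = 0, and correlations with a constant axis = 0,
  keeping tables free of missing values.

No band-pass filtering is applied; raw g values are used.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .signal_io import Window

logger = logging.getLogger(__name__)

AXES = ("x", "y", "z")
AXIS_FEATURES = ("min", "max", "mean", "var", "sd", "skew", "kurt",
                 "p25", "p50", "p75", "zerocross", "energy",
                 "domfreq", "dommag", "entropy")
CROSS_FEATURES = ("corr_xy", "corr_xz", "corr_yz")
VM_FEATURE = "vm_mean"
METADATA_COLUMNS = ("subject_id", "gmfcs_level", "trial_id", "window_index",
                    "label")

PLACEMENT_SETS = ("W", "H", "A", "W+H", "W+A", "H+A", "W+H+A")
_LETTER = {"W": "wrist", "H": "hip", "A": "ankle"}


def parse_placement_set(placement_set: str) -> tuple[str, ...]:
    """Map a placement-set code like ``"H+A"`` to placement names."""
    try:
        return tuple(_LETTER[part] for part in placement_set.split("+"))
    except KeyError:
        raise ValueError(f"unknown placement set {placement_set!r}") from None


def feature_names(placement: str) -> list[str]:
    """The 49 fixed, ordered feature-column names for one placement."""
    names = [f"{placement}_{ax}_{f}" for ax in AXES for f in AXIS_FEATURES]
    names += [f"{placement}_{c}" for c in CROSS_FEATURES]
    names.append(f"{placement}_{VM_FEATURE}")
    return names


def placement_set_feature_names(placement_set: str) -> list[str]:
    out: list[str] = []
    for p in parse_placement_set(placement_set):
        out.extend(feature_names(p))
    return out


# ---------------------------------------------------------------------------
# Per-axis features (vectorized over windows)
# ---------------------------------------------------------------------------

def _zero_crossings(centered: np.ndarray) -> np.ndarray:
    """Count sign changes per row, ignoring exact zeros."""
    out = np.empty(centered.shape[0], dtype=float)
    for i, row in enumerate(centered):
        s = np.sign(row)
        s = s[s != 0]
        out[i] = 0.0 if s.size < 2 else float(np.count_nonzero(s[1:] != s[:-1]))
    return out


def _axis_feature_matrix(x: np.ndarray, sample_rate: float) -> np.ndarray:
    """Features for a batch of axis signals, shape (m, n) -> (m, 15)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    mn, mx = x.min(axis=1), x.max(axis=1)
    degenerate = mn == mx                # exactly constant window
    mean = np.where(degenerate, mn, x.mean(axis=1))
    var = np.where(degenerate, 0.0, x.var(axis=1))   # population variance
    sd = np.sqrt(var)

    # scipy warns about near-constant data; degenerate rows are overridden
    # by convention below, so the warning is moot.
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = _stats.skew(x, axis=1, bias=True)
        kurt = _stats.kurtosis(x, axis=1, fisher=True, bias=True)
    skew = np.where(degenerate, 0.0, np.nan_to_num(skew))
    kurt = np.where(degenerate, 0.0, np.nan_to_num(kurt))

    p25, p50, p75 = np.percentile(x, [25, 50, 75], axis=1)

    centered = np.where(degenerate[:, None], 0.0, x - mean[:, None])
    zc = _zero_crossings(centered)

    spec = np.fft.rfft(centered, axis=1)
    mag = np.abs(spec)[:, 1:] * (2.0 / n)        # non-DC bins
    nbins = mag.shape[1]
    freqs = np.arange(1, nbins + 1) * sample_rate / n
    dom_idx = np.argmax(mag, axis=1)             # ties -> lowest frequency
    dommag = mag[np.arange(m), dom_idx]
    domfreq = np.where(degenerate, 0.0, freqs[dom_idx])
    dommag = np.where(degenerate, 0.0, dommag)

    power = mag ** 2
    energy = power.mean(axis=1)
    total = power.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = power / total[:, None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        entropy = -plogp.sum(axis=1) / np.log(nbins)
    entropy = np.where(total > 0, entropy, 0.0)

    return np.column_stack([
        mn, mx, mean, var, sd, skew, kurt,
        p25, p50, p75, zc, energy, domfreq, dommag, entropy,
    ])


def extract_axis_features(samples: Sequence[float] | np.ndarray,
                          sample_rate: float = 30.0) -> dict[str, float]:
    """The 15 named per-axis features for one window-length axis signal."""
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("expected a 1-D axis signal of >= 2 samples")
    if not np.all(np.isfinite(arr)):
        raise ValueError("axis signal contains non-finite values")
    row = _axis_feature_matrix(arr, sample_rate)[0]
    return dict(zip(AXIS_FEATURES, (float(v) for v in row)))


def _correlations(samples: np.ndarray) -> np.ndarray:
    """Pearson correlations (xy, xz, yz) per window; constant axis -> 0."""
    mean = samples.mean(axis=1, keepdims=True)
    c = samples - mean
    sd = c.std(axis=1)
    constant = samples.min(axis=1) == samples.max(axis=1)
    cov = np.einsum("nia,nib->nab", c, c) / samples.shape[1]
    out = np.empty((samples.shape[0], 3))
    pairs = ((0, 1), (0, 2), (1, 2))
    for k, (i, j) in enumerate(pairs):
        denom = sd[:, i] * sd[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov[:, i, j] / denom
        valid = (denom > 0) & ~constant[:, i] & ~constant[:, j]
        out[:, k] = np.where(valid, r, 0.0)
    return np.clip(out, -1.0, 1.0)


def features_from_array(samples: np.ndarray,
                        sample_rate: float = 30.0) -> np.ndarray:
    """49 features for a batch of windows, shape (nwin, n, 3) -> (nwin, 49)."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 2:
        samples = samples[None, ...]
    if not np.all(np.isfinite(samples)):
        raise ValueError("window contains non-finite values")
    per_axis = [_axis_feature_matrix(samples[:, :, a], sample_rate)
                for a in range(3)]
    corr = _correlations(samples)
    vm = np.sqrt((samples ** 2).sum(axis=2)).mean(axis=1)
    return np.column_stack(per_axis + [corr, vm[:, None]])


def extract_window_features(window: Window,
                            sample_rate: float = 30.0) -> dict[str, float]:
    """FeatureVector for one window, keyed ``<placement>_<axis>_<feature>``."""
    vals = features_from_array(window.samples, sample_rate)[0]
    return dict(zip(feature_names(window.placement), (float(v) for v in vals)))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def _per_placement_frame(windows: Sequence[Window], placement: str,
                         sample_rate: float) -> pd.DataFrame:
    labeled = [w for w in windows if w.label is not None]
    if not labeled:
        return pd.DataFrame(columns=list(METADATA_COLUMNS)
                            + feature_names(placement))
    arr = np.stack([w.samples for w in labeled])
    feats = features_from_array(arr, sample_rate)
    df = pd.DataFrame(feats, columns=feature_names(placement))
    df.insert(0, "label", [w.label for w in labeled])
    df.insert(0, "window_index", [w.window_index for w in labeled])
    df.insert(0, "trial_id", [w.trial_id for w in labeled])
    df.insert(0, "gmfcs_level", [w.gmfcs_level for w in labeled])
    df.insert(0, "subject_id", [w.subject_id for w in labeled])
    return df


def build_feature_table(
    windows_by_placement: Mapping[str, Sequence[Window]],
    placement_set: str,
    sample_rate: float = 30.0,
) -> pd.DataFrame:
    """Assemble one row per (subject, trial, window) for a placement set.

    For multi-placement sets the per-placement 49-vectors of the same
    (subject, trial, window_index) are concatenated; the placements of one
    subject must be index-aligned (same timeline), otherwise a validation
    error names the offending subjects.
    """
    placements = parse_placement_set(placement_set)
    frames = []
    for p in placements:
        if p not in windows_by_placement:
            raise ValueError(f"missing windows for placement {p!r}")
        frames.append(_per_placement_frame(windows_by_placement[p], p,
                                           sample_rate))
    key = ["subject_id", "gmfcs_level", "trial_id", "window_index", "label"]
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.merge(f, on=key, how="inner")

    # Misalignment check: every placement must contribute the same windows
    # per subject.
    bad: list[str] = []
    for f in frames:
        counts = f.groupby("subject_id").size()
        mcounts = merged.groupby("subject_id").size()
        for sid in set(counts.index) | set(mcounts.index):
            if counts.get(sid, 0) != mcounts.get(sid, 0):
                bad.append(str(sid))
    if bad:
        raise ValueError(
            "misaligned window timelines across placements for subjects: "
            + ", ".join(sorted(set(bad))))

    feat_cols = placement_set_feature_names(placement_set)
    merged = merged[key + feat_cols].reset_index(drop=True)
    if merged[feat_cols].isna().any().any():
        raise ValueError("feature table contains missing values")
    return merged


def feature_columns(table: pd.DataFrame) -> list[str]:
    """All non-metadata columns of a feature table, in table order."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
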