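"""Raw-CSV / label-file I/O, label-to-sample alignment, and fixed windowing.

Windows are 10 s, non-overlapping, and consecutive (300 samples at 30 Hz).
Under the default ``"drop"`` transition policy only homogeneous windows are
labeled, so evaluation rests on unambiguous windows; the ``"majority"``
policy instead labels a mixed window with its majority class when that class
covers at least half of the samples.  Trailing samples that do not fill a
window are dropped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import CLASSES, CohortError, LabelTrack, RawRecording

logger = logging.getLogger(__name__)

UNLABELED = -1
CLASS_TO_INT = {c: i for i, c in enumerate(CLASSES)}


class ParseError(ValueError):
    """Malformed raw or label file; message names the offending line."""


@dataclass(frozen=True)
class Window:
    """One 10 s window of one recording, with its majority label (or None)."""

    subject_id: str
    placement: str
    window_index: int
    samples: np.ndarray          # (300, 3) in g
    label: str | None
    gmfcs_level: str | None = None
    trial_id: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise CohortError("window samples must have shape (n, 3)")
        object.__setattr__(self, "samples", arr)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_raw_csv(path: str | Path) -> RawRecording:
    """Parse an ActiGraph-style raw CSV written by :func:`cohort.write_raw_csv`.

    Raises :class:`ParseError` naming the offending line on malformed headers
    or non-numeric sample rows.
    """
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[float, float, float]] = []
    with path.open("r", newline="") as fh:
        saw_columns = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line.lstrip("# ").partition(":")
                    header[key.strip()] = value.strip()
                continue
            if not saw_columns:
                if [c.strip().upper() for c in line.split(",")] != ["X", "Y", "Z"]:
                    raise ParseError(
                        f"{path}: line {lineno}: expected column header X,Y,Z, "
                        f"got {line!r}")
                saw_columns = True
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 comma-separated values")
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric acceleration value "
                    f"({exc})") from None
    if "sample_rate_hz" not in header:
        raise ParseError(f"{path}: header does not declare sample_rate_hz")
    try:
        rate = float(header["sample_rate_hz"])
    except ValueError:
        raise ParseError(f"{path}: malformed sample_rate_hz "
                         f"{header['sample_rate_hz']!r}") from None
    if rate <= 0:
        raise ParseError(f"{path}: sample_rate_hz must be positive")
    return RawRecording(
        subject_id=header.get("subject_id", path.stem),
        placement=header.get("placement", "wrist"),
        sample_rate=rate,
        start_time=header.get("start_time", "1970-01-01T00:00:00"),
        samples=np.asarray(rows, dtype=float),
    )


def read_label_csv(path: str | Path) -> dict[str, LabelTrack]:
    """Read label intervals; returns one LabelTrack per subject_id."""
    path = Path(path)
    per_subject: dict[str, list[tuple[float, float, str]]] = {}
    with path.open("r", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "start_s", "end_s", "class"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: label file must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                start, end = float(row["start_s"]), float(row["end_s"])
            except (TypeError, ValueError):
                raise ParseError(f"{path}: line {lineno}: non-numeric interval "
                                 "bounds") from None
            cls = (row["class"] or "").strip()
            if cls not in CLASSES:
                raise ParseError(f"{path}: line {lineno}: unknown class {cls!r}")
            per_subject.setdefault(row["subject_id"], []).append((start, end, cls))
    return {sid: LabelTrack(tuple(sorted(iv))) for sid, iv in per_subject.items()}


# ---------------------------------------------------------------------------
# Label alignment and windowing
# ---------------------------------------------------------------------------

def attach_labels(recording: RawRecording, track: LabelTrack) -> np.ndarray:
    """Map each sample to a class index or UNLABELED (-1).

    Half-open convention: a sample at time t belongs to [start, end) iff
    start <= t < end, so adjoining bouts partition time with no
    double-assignment.  Intervals may extend at most one sample period past
    the recording span.
    """
    n = recording.n_samples
    fs = recording.sample_rate
    tol = 1.0 / fs
    span = n / fs
    mask = np.full(n, UNLABELED, dtype=np.int64)
    t = np.arange(n) / fs
    for start, end, cls in track.intervals:
        if start < -tol or end > span + tol:
            raise CohortError(
                f"interval [{start}, {end}) lies outside recording span "
                f"[0, {span:.3f}]")
        sel = (t >= start) & (t < end)
        if not sel.any():
            logger.warning("interval [%s, %s) covers no sample", start, end)
            continue
        if (mask[sel] != UNLABELED).any():
            raise CohortError("overlapping label intervals")
        mask[sel] = CLASS_TO_INT[cls]
    return mask


def window_signal(
    recording: RawRecording,
    labels: np.ndarray | None = None,
    window_s: float = 10.0,
    policy: str = "drop",
    gmfcs_level: str | None = None,
    trial_id: str | None = None,
) -> list[Window]:
    """Cut a recording into consecutive non-overlapping fixed-length windows.

    ``policy="drop"`` (default): label only homogeneous windows, leaving
    bout-transition windows unlabeled.  ``policy="majority"``: window label =
    majority class when it covers >= 50% of samples, else unlabeled.
    Trailing samples not filling a window are dropped.
    """
    if policy not in ("majority", "drop"):
        raise ValueError(f"unknown transition policy {policy!r}")
    wlen = int(round(window_s * recording.sample_rate))
    if wlen <= 0:
        raise ValueError("window_s must be positive")
    n = recording.n_samples
    nwin = n // wlen
    if nwin == 0:
        logger.warning("recording shorter than one %.0f s window; no windows",
                       window_s)
        return []
    if labels is None:
        labels = np.full(n, UNLABELED, dtype=np.int64)
    windows: list[Window] = []
    for i in range(nwin):
        sl = slice(i * wlen, (i + 1) * wlen)
        lab = _window_label(labels[sl], policy)
        windows.append(Window(
            subject_id=recording.subject_id,
            placement=recording.placement,
            window_index=i,
            samples=recording.samples[sl],
            label=lab,
            gmfcs_level=gmfcs_level,
            trial_id=trial_id,
        ))
    return windows


def _window_label(lab: np.ndarray, policy: str) -> str | None:
    labeled = lab[lab != UNLABELED]
    if labeled.size == 0:
        return None
    counts = np.bincount(labeled, minlength=len(CLASSES))
    if policy == "drop":
        if labeled.size != lab.size or np.count_nonzero(counts) != 1:
            return None
        return CLASSES[int(np.argmax(counts))]
    best = int(np.argmax(counts))
    if counts[best] * 2 >= lab.size:   # majority covers >= 50% of all samples
        return CLASSES[best]
    return None


def count_unlabeled(windows: Sequence[Window]) -> int:
    """QC count of windows excluded for lacking a majority label."""
    return sum(1 for w in windows if w.label is None)
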