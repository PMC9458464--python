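"""Nuclear-envelope rupture kinetics from reporter-intensity traces.

A nuclear export-reporter trace (NLS-GFP mean nuclear intensity) is
background-subtracted and normalized to the mean of the frames preceding
the first rupture. Ruptures appear as abrupt intensity losses: an event
opens when the series drops below the rolling pre-event baseline by the
drop threshold and closes when it recovers to 95% of that baseline. The
event magnitude is the baseline-relative fractional loss at the nadir;
events with magnitude > 0.30 are *major* ruptures, the rest *minor*.

Re-rupture statistics follow major events: the time to the next event of
any class is binned to 15-minute intervals with a >90 min overflow bin,
counting only events that could be observed for at least ``min_follow_up``
frames afterwards. Conditions are compared with a two-sided Fisher exact
test on the (>90 min vs ≤90 min) × condition contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import regionprops

__all__ = [
    "IntensityTrace",
    "RuptureEvent",
    "ReRuptureHistogram",
    "track_nuclei",
    "preprocess_trace",
    "detect_ruptures",
    "align_recovery",
    "rerupture_intervals",
    "build_rerupture_table",
    "fisher_exact_2x2",
    "MAJOR_THRESHOLD",
    "RERUPTURE_BIN_MIN",
    "RERUPTURE_OVERFLOW_MIN",
]

#: Fractional intensity loss above which a rupture is classified major.
MAJOR_THRESHOLD = 0.30
#: Width of a re-rupture histogram bin, minutes.
RERUPTURE_BIN_MIN = 15.0
#: Lower edge of the overflow bin, minutes.
RERUPTURE_OVERFLOW_MIN = 90.0


@dataclass
class IntensityTrace:
    """One per-nucleus reporter trace with its normalization."""

    nucleus_id: object
    frame_interval_min: float
    raw: np.ndarray
    background: np.ndarray
    normalized: np.ndarray | None = None
    reference_frames: tuple[int, int] | None = None
    usable: bool = True
    note: str = ""


@dataclass
class RuptureEvent:
    """One detected loss-of-compartmentalization event."""

    onset_frame: int
    nadir_frame: int
    magnitude: float
    classification: str  # "major" | "minor"
    recovered_frame: int | None
    baseline: float

    @property
    def is_major(self) -> bool:
        return self.classification == "major"


@dataclass
class ReRuptureHistogram:
    """15-min binned re-rupture intervals with a >90 min overflow bin."""

    bin_edges_min: np.ndarray
    counts: np.ndarray
    overflow: int

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.overflow


# ---------------------------------------------------------------------------
# Tracking


def track_nuclei(
    label_maps: Sequence[np.ndarray],
    images: Sequence[np.ndarray] | None = None,
    max_displacement: float = 10.0,
) -> pd.DataFrame:
    """Link nuclei frame-to-frame by nearest centroids.

    A track continues to the unique candidate centroid within
    ``max_displacement`` pixels of its last position; tracks with zero or
    multiple candidates in the gate, and pairs of tracks contesting the
    same candidate, are terminated (ambiguity is logged in the output
    rather than guessed through). Returns one row per (track, frame) with
    the frame's label, centroid and — when ``images`` is given — the mean
    intensity over the labelled object.
    """
    if len(label_maps) < 2:
        raise ValueError("need at least 2 frames to track")

    def centroids(lbl):
        return {p.label: np.array(p.centroid) for p in regionprops(lbl)}

    rows = []
    prev = centroids(label_maps[0])
    track_of_label = {lab: i + 1 for i, lab in enumerate(sorted(prev))}
    active = dict(track_of_label)  # label in previous frame -> track id
    next_track = len(active) + 1

    def emit(track_id, frame, lab, cen):
        row = {
            "track_id": track_id, "frame": frame, "label": int(lab),
            "y": float(cen[0]), "x": float(cen[1]),
        }
        if images is not None:
            m = label_maps[frame] == lab
            row["mean_intensity"] = float(np.asarray(images[frame])[m].mean())
        rows.append(row)

    for lab, cen in prev.items():
        emit(active[lab], 0, lab, cen)

    for f in range(1, len(label_maps)):
        cur = centroids(label_maps[f])
        claims: dict[int, list] = {}
        for lab, tid in active.items():
            cen = prev[lab]
            cands = [
                (np.linalg.norm(cur[nl] - cen), nl) for nl in cur
                if np.linalg.norm(cur[nl] - cen) <= max_displacement
            ]
            if len(cands) == 1:
                claims.setdefault(cands[0][1], []).append(tid)
            # 0 or >=2 candidates: track ends here
        new_active = {}
        for new_lab, tids in claims.items():
            if len(tids) == 1:  # contested assignments terminate both tracks
                new_active[new_lab] = tids[0]
                emit(tids[0], f, new_lab, cur[new_lab])
        for new_lab in cur:
            if new_lab not in new_active:
                new_active[new_lab] = next_track
                emit(next_track, f, new_lab, cur[new_lab])
                next_track += 1
        active, prev = new_active, cur
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trace preprocessing and event detection


def preprocess_trace(
    raw: np.ndarray,
    background: np.ndarray | float = 0.0,
    frame_interval_min: float = 3.0,
    reference_window: int = 5,
    rupture_onset: int | None = None,
    nucleus_id: object = None,
) -> IntensityTrace:
    """Background-subtract and normalize a reporter trace.

    The normalizer is the mean of the ``reference_window`` frames
    immediately before ``rupture_onset`` (all available pre-rupture frames
    when fewer exist); without a known onset, the first
    ``reference_window`` frames are used. A non-positive reference mean
    marks the trace unusable. Negative normalized values are permitted —
    background may exceed signal at individual frames.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size <= reference_window:
        raise ValueError("trace must be longer than the reference window")
    bg = np.broadcast_to(np.asarray(background, dtype=float), raw.shape)
    corrected = raw - bg

    if rupture_onset is None:
        ref = slice(0, reference_window)
    else:
        start = max(0, rupture_onset - reference_window)
        if start == rupture_onset:
            ref = slice(0, reference_window)  # no pre-rupture frames at all
        else:
            ref = slice(start, rupture_onset)
    ref_mean = float(corrected[ref].mean())
    trace = IntensityTrace(
        nucleus_id=nucleus_id,
        frame_interval_min=frame_interval_min,
        raw=raw,
        background=np.asarray(bg).copy(),
        reference_frames=(ref.start, ref.stop),
    )
    if ref_mean <= 0:
        trace.usable = False
        trace.note = "non-positive reference mean"
        return trace
    trace.normalized = corrected / ref_mean
    return trace


def detect_ruptures(
    normalized: np.ndarray,
    drop_threshold: float = 0.05,
    baseline_window: int = 5,
    recovery_fraction: float = 0.95,
    min_duration: int = 3,
    major_threshold: float = MAJOR_THRESHOLD,
) -> list[RuptureEvent]:
    """Detect rupture events on a normalized trace.

    The rolling baseline is the median of the last ``baseline_window``
    non-event frames. An event opens when the series falls at least
    ``drop_threshold`` below the baseline and closes at the first frame
    back at ``recovery_fraction`` of it; the magnitude is the
    baseline-relative loss at the nadir, 1 − min/baseline, and events with
    magnitude > ``major_threshold`` are major. Candidates recovering in
    fewer than ``min_duration`` frames are rejected as single-frame noise
    excursions — a real leak/recovery cycle spans many frames even at
    3-min sampling.
    """
    x = np.asarray(normalized, dtype=float)
    events: list[RuptureEvent] = []
    history: list[float] = []
    i = 0
    n = len(x)
    while i < n:
        baseline = float(np.median(history[-baseline_window:])) if history else None
        if baseline is not None and x[i] < baseline - drop_threshold:
            onset = i
            nadir, nadir_val = i, x[i]
            recovered = None
            j = i
            while j < n:
                if x[j] < nadir_val:
                    nadir, nadir_val = j, x[j]
                if x[j] >= recovery_fraction * baseline:
                    recovered = j
                    break
                j += 1
            duration = (recovered if recovered is not None else n) - onset
            if duration < min_duration:
                # transient noise spike, not a rupture
                history.append(x[i])
                i += 1
                continue
            magnitude = float(np.clip(1.0 - nadir_val / baseline, 0.0, 1.0))
            events.append(
                RuptureEvent(
                    onset_frame=onset,
                    nadir_frame=nadir,
                    magnitude=magnitude,
                    classification="major" if magnitude > major_threshold else "minor",
                    recovered_frame=recovered,
                    baseline=baseline,
                )
            )
            if recovered is None:
                break
            i = recovered
            history = [x[recovered]]
        else:
            history.append(x[i])
            i += 1
    return events


def align_recovery(
    traces: Sequence[np.ndarray],
    events: Sequence[RuptureEvent],
    window: int = 40,
) -> pd.DataFrame:
    """Mean ± SD recovery curve of major events aligned at onset (t = 0).

    Each event contributes its trace from onset to onset + ``window``
    frames; shorter tails are padded with NaN and averaged over the
    available events. SD is NaN wherever only one event contributes.
    Returns columns frame_offset, mean, sd, n.
    """
    majors = [(tr, ev) for tr, ev in zip(traces, events) if ev.is_major]
    if not majors:
        raise ValueError("no major events to align")
    mat = np.full((len(majors), window + 1), np.nan)
    for row, (tr, ev) in enumerate(majors):
        seg = np.asarray(tr, dtype=float)[ev.onset_frame : ev.onset_frame + window + 1]
        mat[row, : len(seg)] = seg
    n = np.sum(np.isfinite(mat), axis=0)
    mean = np.nanmean(mat, axis=0)
    sd = np.full(mat.shape[1], np.nan)
    multi = n > 1
    if multi.any():
        sd[multi] = np.nanstd(mat[:, multi], axis=0, ddof=1)
    return pd.DataFrame(
        {"frame_offset": np.arange(window + 1), "mean": mean, "sd": sd, "n": n}
    )


def rerupture_intervals(
    events_per_trace: Sequence[Sequence[RuptureEvent]],
    trace_lengths: Sequence[int],
    frame_interval_min: float = 3.0,
    min_follow_up: int = 30,
) -> tuple[list[float], ReRuptureHistogram]:
    """Intervals from each major rupture to the next rupture of any class.

    A major event qualifies only when its trace continues for at least
    ``min_follow_up`` frames after the onset, so that an absent next event
    can be placed in the overflow bin rather than censored. Intervals are
    onset-to-onset in minutes, binned half-open to [0,15), [15,30), …,
    [75,90), plus [90, ∞); a qualifying major with no later event also
    lands in the overflow bin. Returns the finite intervals observed and
    the histogram (``np.inf`` encodes an unobserved next event).
    """
    edges = np.arange(0.0, RERUPTURE_OVERFLOW_MIN + RERUPTURE_BIN_MIN, RERUPTURE_BIN_MIN)
    counts = np.zeros(len(edges) - 1, dtype=int)
    overflow = 0
    intervals: list[float] = []
    for events, length in zip(events_per_trace, trace_lengths):
        events = sorted(events, key=lambda e: e.onset_frame)
        for k, ev in enumerate(events):
            if not ev.is_major:
                continue
            if (length - 1 - ev.onset_frame) < min_follow_up:
                continue
            nxt = next((e for e in events[k + 1 :]), None)
            if nxt is None:
                overflow += 1
                intervals.append(np.inf)
                continue
            dt = (nxt.onset_frame - ev.onset_frame) * frame_interval_min
            intervals.append(dt)
            if dt >= RERUPTURE_OVERFLOW_MIN:
                overflow += 1
            else:
                counts[int(dt // RERUPTURE_BIN_MIN)] += 1
    return intervals, ReRuptureHistogram(
        bin_edges_min=edges, counts=counts, overflow=overflow
    )


def build_rerupture_table(
    intervals_control: Sequence[float], intervals_case: Sequence[float]
) -> np.ndarray:
    """2×2 table of (>90 min vs ≤90 min) re-rupture intervals by condition."""
    def split(vals):
        v = np.asarray(list(vals), dtype=float)
        late = int(np.sum(v >= RERUPTURE_OVERFLOW_MIN))
        return late, len(v) - late

    return np.array([split(intervals_control), split(intervals_case)], dtype=int)


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value of a 2×2 contingency table.

    The two-sided p is the sum of hypergeometric probabilities of every
    table with the same margins whose probability does not exceed the
    observed table's. A zero margin makes the test degenerate; p = 1 by
    convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)
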