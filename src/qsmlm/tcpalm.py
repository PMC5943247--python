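"""Time-correlated analysis of localization streams (tcPALM).

The temporal history of localizations inside an ROI distinguishes two
kinds of protein cluster:

* **stable** — a steady stream of detections from the very start of the
  acquisition (the cluster pre-existed), gradually plateauing as the
  pool of photoconvertible fluorophores is depleted;
* **transient** — essentially no detections at first, then a delayed,
  abrupt burst that ceases abruptly: the cluster assembled and
  disassembled during the acquisition.

This module builds per-ROI time traces, detects bursts as epochs of
elevated localization rate, classifies them, and computes the summary
statistics (lifetime histogram, transient fraction, burst sizes).

Burst detection thresholds the centred moving-average localization rate
against the background rate — the median windowed rate over the whole
trace (robust to the burst itself) — plus a multiple of its Poisson
standard error. On a clean ROI
the median can be exactly zero, which would make any detection a burst;
the background is therefore floored at one detection per window.
Conversely, a trace that is active throughout never stands out against
its own median and is treated as a single burst from t = 0 (the stable
signature). Runs closer than ``min_gap`` merge; runs carrying fewer
than ``min_burst`` localizations are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .table import LocalizationTable, crop_roi

STABLE = "stable"
TRANSIENT = "transient"


@dataclass
class TimeTrace:
    """Detections per frame inside an ROI, over the full acquisition."""

    counts: np.ndarray            # per frame, frame 1 first
    frame_time: float             # s
    record_frames: Optional[np.ndarray] = None   # frame of each ROI record
    record_indices: Optional[np.ndarray] = None  # row index in source table

    @property
    def n_frames(self) -> int:
        return len(self.counts)

    @property
    def duration(self) -> float:
        """Acquisition duration, s."""
        return self.n_frames * self.frame_time

    @property
    def times(self) -> np.ndarray:
        """Start time of each frame, s."""
        return np.arange(self.n_frames) * self.frame_time

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.counts)

    def smoothed(self, width: int) -> np.ndarray:
        """Boxcar moving average of the per-frame counts, for display.

        Rescaled so the total count is conserved exactly (plain ``same``
        convolution loses kernel mass at the trace edges).
        """
        if width <= 1:
            return self.counts.astype(float)
        kernel = np.ones(width) / width
        sm = np.convolve(self.counts.astype(float), kernel, mode="same")
        total = self.counts.sum()
        if sm.sum() > 0:
            sm *= total / sm.sum()
        return sm


@dataclass
class TemporalCluster:
    """A detected burst of localizations."""

    onset: float          # s, start of the first burst frame
    end: float            # s, end of the last burst frame
    burst_size: int       # localizations within [onset, end]
    classification: Optional[str] = None
    member_indices: Optional[np.ndarray] = None
    onset_frame: int = 0  # 1-based
    end_frame: int = 0

    @property
    def lifetime(self) -> float:
        return self.end - self.onset


@dataclass
class BurstDetectionParams:
    """Tunable burst-detection and classification parameters.

    window
        Moving-average width, frames (50 frames = 3 s at 60 ms/frame).
    rate_threshold_factor
        A frame belongs to a burst when its windowed rate exceeds the
        background rate by this many standard errors of the windowed
        mean (z-score against Poisson background).
    min_gap
        Bursts separated by less than this (s) are merged.
    min_burst
        Minimum localizations for a burst to be kept.
    onset_delay_threshold
        A cluster is transient only if its burst starts later than this (s).
    plateau_fraction
        ... and its lifetime is shorter than this fraction of the
        acquisition.
    """

    window: int = 50
    rate_threshold_factor: float = 3.0
    min_gap: float = 1.0
    min_burst: int = 10
    onset_delay_threshold: float = 5.0
    plateau_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.window, self.rate_threshold_factor, self.min_gap,
               self.min_burst, self.onset_delay_threshold,
               self.plateau_fraction) <= 0:
            raise ValueError("all burst-detection parameters must be positive")


def time_trace(
    table: LocalizationTable, roi=None, n_frames: Optional[int] = None
) -> TimeTrace:
    """Per-frame detection counts for an ROI.

    The trace spans the full acquisition: frames 1 through ``n_frames``
    (default: the last frame present in the *uncropped* table, so an
    empty ROI still yields an all-zero trace of the right length).
    """
    if len(table) == 0:
        raise ValueError("time_trace requires a nonempty table")
    if n_frames is None:
        n_frames = int(table.frame.max())
    sub = crop_roi(table, roi) if roi is not None else table
    counts = np.bincount(sub.frame, minlength=n_frames + 1)[1:].astype(np.int64)
    return TimeTrace(
        counts=counts,
        frame_time=table.frame_time,
        record_frames=sub.frame.copy(),
        record_indices=sub.data.index.to_numpy() if roi is None else
        np.flatnonzero(roi.contains(table.x, table.y)),
    )


def _windowed_rate(counts: np.ndarray, window: int) -> np.ndarray:
    """Centred moving-average rate (detections/frame), edge-corrected."""
    kernel = np.ones(window)
    s = np.convolve(counts, kernel, mode="same")
    norm = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return s / norm


def detect_bursts(
    trace: TimeTrace, params: Optional[BurstDetectionParams] = None
) -> List[TemporalCluster]:
    """Detect bursts as runs of elevated windowed localization rate.

    Returns non-overlapping, time-ordered bursts, each with at least
    ``min_burst`` localizations.
    """
    params = params or BurstDetectionParams()
    counts = trace.counts
    if counts.sum() == 0:
        return []
    rate = _windowed_rate(counts, params.window)
    floor = 1.0 / params.window  # one detection per window
    background = max(float(np.median(rate)), floor)
    if background > params.rate_threshold_factor * floor:
        # dense regime: the trace is active for most of the acquisition,
        # so the median measures the activity itself, not a quiet
        # background (on merged 0/1 traces it can saturate near 1, where
        # no frame can stand out against it). Bursts are then the runs
        # above the absolute detectability floor.
        threshold = params.rate_threshold_factor * floor
    else:
        # sparse regime: Poisson-aware threshold — a burst frame must sit
        # rate_threshold_factor standard errors of the windowed mean
        # above the background level.
        threshold = background + params.rate_threshold_factor * np.sqrt(
            background / params.window)

    above = rate >= threshold
    if not above.any():
        return []
    # maximal runs of above-threshold frames
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)
    runs = list(zip(starts, ends))

    # merge runs separated by less than min_gap
    gap_frames = params.min_gap / trace.frame_time
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe < gap_frames:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))

    bursts = []
    ft = trace.frame_time
    for s, e in merged:
        size = int(counts[s:e + 1].sum())
        if size < params.min_burst:
            continue
        members = None
        if trace.record_frames is not None:
            in_burst = (trace.record_frames >= s + 1) & (trace.record_frames <= e + 1)
            if trace.record_indices is not None:
                members = trace.record_indices[in_burst]
        bursts.append(TemporalCluster(
            onset=s * ft, end=(e + 1) * ft, burst_size=size,
            member_indices=members, onset_frame=s + 1, end_frame=e + 1,
        ))
    return bursts


def classify_cluster(
    trace: TimeTrace, burst: TemporalCluster,
    params: Optional[BurstDetectionParams] = None,
) -> str:
    """Label a burst transient or stable.

    Transient requires *both* a delayed onset (the cluster was absent at
    the start) and a bounded lifetime (it disassembled before the end);
    anything else — a stream present from t = 0 or lasting most of the
    acquisition — is stable. Pure function of (onset, lifetime,
    acquisition duration, params).
    """
    params = params or BurstDetectionParams()
    transient = (
        burst.onset > params.onset_delay_threshold
        and burst.lifetime < params.plateau_fraction * trace.duration
    )
    return TRANSIENT if transient else STABLE


class BurstDetector(BaseEstimator):
    """Estimator wrapper: detect and classify bursts on a time trace.

    Parameters mirror :class:`BurstDetectionParams`. After ``fit``:
    ``bursts_`` (classified, time-ordered) and ``primary_burst_`` (the
    largest, or None) are available.
    """

    def __init__(self, window: int = 50, rate_threshold_factor: float = 3.0,
                 min_gap: float = 1.0, min_burst: int = 10,
                 onset_delay_threshold: float = 5.0, plateau_fraction: float = 0.5):
        self.window = window
        self.rate_threshold_factor = rate_threshold_factor
        self.min_gap = min_gap
        self.min_burst = min_burst
        self.onset_delay_threshold = onset_delay_threshold
        self.plateau_fraction = plateau_fraction

    def _params(self) -> BurstDetectionParams:
        return BurstDetectionParams(
            window=self.window,
            rate_threshold_factor=self.rate_threshold_factor,
            min_gap=self.min_gap, min_burst=self.min_burst,
            onset_delay_threshold=self.onset_delay_threshold,
            plateau_fraction=self.plateau_fraction)

    def fit(self, trace: TimeTrace, y=None):
        params = self._params()
        bursts = detect_bursts(trace, params)
        for b in bursts:
            b.classification = classify_cluster(trace, b, params)
        self.bursts_ = bursts
        self.largest_burst_ = max(bursts, key=lambda b: b.burst_size, default=None)
        # the earliest sustained burst decides the cluster's class: what
        # separates stable from transient is whether activity was already
        # present at acquisition start, and a stable cluster's decaying
        # stream can fragment into several late runs
        self.primary_burst_ = bursts[0] if bursts else None
        return self


def lifetime_histogram(
    bursts: Sequence[TemporalCluster], bin_width: float = 2.0
) -> Tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Histogram of transient-burst lifetimes.

    Returns (bin_centers, counts, mean, sem, degenerate) where
    ``degenerate`` flags a single-burst input whose SEM is reported as 0.
    """
    lifetimes = np.array([b.lifetime for b in bursts
                          if b.classification == TRANSIENT], dtype=float)
    if len(lifetimes) == 0:
        raise ValueError("no transient bursts to histogram")
    edges = np.arange(0.0, lifetimes.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    counts, edges = np.histogram(lifetimes, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = float(lifetimes.mean())
    degenerate = len(lifetimes) < 2
    sem = 0.0 if degenerate else float(lifetimes.std(ddof=1) / np.sqrt(len(lifetimes)))
    return centers, counts, mean, sem, degenerate


def transient_fraction(
    bursts: Sequence[TemporalCluster],
) -> Tuple[float, float, int]:
    """(fraction_transient, fraction_stable, n); fractions sum to 1."""
    classes = [b.classification for b in bursts]
    if not classes:
        raise ValueError("no classified bursts")
    if any(c not in (STABLE, TRANSIENT) for c in classes):
        raise ValueError("all bursts must be classified first")
    n = len(classes)
    ft = classes.count(TRANSIENT) / n
    return ft, 1.0 - ft, n


def cluster_dynamics(
    table: LocalizationTable,
    labels: np.ndarray,
    params: Optional[BurstDetectionParams] = None,
    roi_pad: float = 100.0,
) -> List[dict]:
    """Per-spatial-cluster tcPALM: trace, primary burst, classification.

    For every non-noise spatial cluster, an ROI is taken as the
    cluster's bounding box padded by ``roi_pad`` nm, its time trace is
    extracted from the full table, and the largest detected burst is
    classified. Returns one dict per cluster with keys ``cluster_id``,
    ``burst`` (may be None), ``classification``, ``trace``.
    """
    from .roi import RectangleROI

    params = params or BurstDetectionParams()
    labels = np.asarray(labels)
    results = []
    for cid in np.unique(labels[labels >= 0]):
        pts = table.xy[labels == cid]
        roi = RectangleROI(pts[:, 0].min() - roi_pad,
                           pts[:, 0].max() + roi_pad,
                           pts[:, 1].min() - roi_pad,
                           pts[:, 1].max() + roi_pad)
        trace = time_trace(table, roi)
        det = BurstDetector(**vars(params)).fit(trace)
        burst = det.primary_burst_
        results.append({
            "cluster_id": int(cid),
            "trace": trace,
            "burst": burst,
            "classification": burst.classification if burst else None,
        })
    return results
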