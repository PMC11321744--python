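"""The two 3D smooth-pursuit selection algorithms.

Both detectors operate on a moving window (default 40 samples, ~0.67 s at
60 Hz) of time-aligned gaze and object positions expressed in spherical
coordinates ``(r, theta, phi)`` relative to the HMD centre.  No decision is
emitted before the window is full.

Correlation-based detector
    For every candidate object, the Pearson product-moment correlation between
    the gaze and object series is computed per dimension and the three
    coefficients are averaged.  The object with the highest score is selected
    once that score exceeds the threshold.  A dimension with (numerically)
    zero variance in either series has an undefined Pearson coefficient; it
    contributes 0 to the average, which deliberately keeps the score scale
    comparable across objects at the cost of capping the score for
    degenerate-symmetry trajectories (see docs/methods.md).

Difference-based detector
    The window is split in half by timestamp; each half is averaged and the
    older mean subtracted from the newer, yielding a movement vector per
    stream.  Gaze and object movement vectors are compared per dimension by
    the difference coefficient

        c(dg, do) = |dg - do| / (2 |dg + do|),

    which is 0 for a perfect fit, 0.5 for a stationary gaze (and in the limit
    of very fast gaze in the object's direction), > 0.5 when gaze moves
    opposite to the object, and symmetric in log10(dg/do).  At ``dg = -do``
    the coefficient is undefined (division by zero) and that dimension-frame
    is skipped.  The per-dimension coefficients are averaged over the frames
    of the moving window and combined (mean by default) into a single score;
    the object with the smallest score below the threshold is selected.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .trial import TrialLog

__all__ = [
    "WINDOW_SIZE",
    "DetectorDecision",
    "SampleWindow",
    "pearson",
    "correlation_score",
    "correlation_detect",
    "movement_vector",
    "difference_coefficient",
    "difference_score",
    "difference_detect",
    "ScoreTrace",
    "correlation_trace",
    "difference_trace",
    "score_trace",
    "CorrelationDetector",
    "DifferenceDetector",
]

WINDOW_SIZE = 40          # samples; ~0.67 s at 60 Hz
ZERO_VAR_RTOL = 1e-12     # relative tolerance declaring a series constant
COEFF_ZERO_TOL = 1e-12    # |dg + do| below this (relative) is a division by zero

Combine = Literal["mean", "sum"]


@dataclass
class DetectorDecision:
    """Outcome of a detector at one frame (or for a whole trial)."""

    selected_object: Optional[str]
    score_per_object: dict[str, float]
    threshold: float
    frame_index: Optional[int] = None   # samples since movement onset
    time: Optional[float] = None        # s since movement onset
    tied: bool = False


class SampleWindow:
    """Fixed-capacity moving window of time-aligned gaze and object samples.

    All streams share the (strictly increasing) timestamps; the oldest sample
    is evicted jointly from every stream when a push exceeds the capacity.
    """

    def __init__(self, capacity: int = WINDOW_SIZE, object_ids: Sequence[str] = ()):
        if capacity < 2:
            raise ValueError("capacity must be at least 2")
        self.capacity = capacity
        self.object_ids = tuple(object_ids)
        self._t: deque[float] = deque(maxlen=capacity)
        self._gaze: deque[tuple] = deque(maxlen=capacity)
        self._objects: dict[str, deque] = {k: deque(maxlen=capacity) for k in self.object_ids}

    def __len__(self) -> int:
        return len(self._t)

    @property
    def full(self) -> bool:
        return len(self._t) == self.capacity

    def push(self, gaze, objects: Mapping[str, tuple], t: float) -> "SampleWindow":
        """Append one aligned sample; evicts the oldest sample when full."""
        if self._t and t <= self._t[-1]:
            raise ValueError(f"non-monotone timestamp {t} after {self._t[-1]}")
        if not self.object_ids:
            self.object_ids = tuple(objects)
            self._objects = {k: deque(maxlen=self.capacity) for k in self.object_ids}
        if set(objects) != set(self.object_ids):
            raise ValueError("object-id set differs from the window's streams")
        self._t.append(float(t))
        self._gaze.append(tuple(gaze))
        for k in self.object_ids:
            self._objects[k].append(tuple(objects[k]))
        return self

    def timestamps(self) -> np.ndarray:
        return np.array(self._t)

    def gaze_array(self) -> np.ndarray:
        return np.array(self._gaze, dtype=float)

    def object_array(self, object_id: str) -> np.ndarray:
        return np.array(self._objects[object_id], dtype=float)


# ---------------------------------------------------------------------------
# Correlation-based algorithm
# ---------------------------------------------------------------------------

def pearson(x: np.ndarray, y: np.ndarray, zero_var_rtol: float = ZERO_VAR_RTOL) -> float:
    """Pearson product-moment correlation; 0.0 when either series is constant.

    Constancy is judged against ``zero_var_rtol`` relative to the series
    magnitude, so pure floating-point jitter on an analytically constant
    coordinate does not masquerade as signal.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm = x - x.mean()
    ym = y - y.mean()
    sx = math.sqrt(float(xm @ xm))
    sy = math.sqrt(float(ym @ ym))
    n = len(x)
    tol_x = zero_var_rtol * max(1.0, float(np.abs(x).max(initial=0.0))) * math.sqrt(n)
    tol_y = zero_var_rtol * max(1.0, float(np.abs(y).max(initial=0.0))) * math.sqrt(n)
    if sx <= tol_x or sy <= tol_y:
        return 0.0
    return float(np.clip((xm @ ym) / (sx * sy), -1.0, 1.0))


def correlation_score(w: SampleWindow, object_id: str) -> Optional[float]:
    """Mean of the three per-dimension Pearson correlations, or None in warm-up."""
    if not w.full:
        return None
    g = w.gaze_array()
    o = w.object_array(object_id)
    return float(np.mean([pearson(g[:, d], o[:, d]) for d in range(3)]))


def correlation_detect(w: SampleWindow, threshold: float) -> Optional[DetectorDecision]:
    """Select the highest-scoring object if its score surpasses the threshold."""
    if not w.full:
        return None
    scores = {k: correlation_score(w, k) for k in w.object_ids}
    return _decide(scores, threshold, direction="max")


# ---------------------------------------------------------------------------
# Difference-based algorithm
# ---------------------------------------------------------------------------

def movement_vector(series: np.ndarray) -> np.ndarray:
    """Half-window movement vector of an ordered ``(n, k)`` series.

    The series is split in half (the older half takes the extra sample when n
    is odd); the component-wise mean of the older half is subtracted from the
    mean of the newer half.
    """
    s = np.asarray(series, float)
    n = len(s)
    if n < 2:
        raise ValueError("series must contain at least two samples")
    split = n - n // 2    # older half gets the extra sample
    return s[split:].mean(axis=0) - s[:split].mean(axis=0)


def difference_coefficient(delta_gaze: float, delta_obj: float,
                           zero_tol: float = COEFF_ZERO_TOL) -> float:
    """Per-dimension difference coefficient ``|dg - do| / (2 |dg + do|)``.

    The coefficient is 0 iff the two deltas are equal (including the case of
    no movement in either stream).  It is NaN (undefined) when ``dg + do``
    vanishes with non-equal deltas -- the division-by-zero case at exactly
    opposite movement; callers skip such dimension-frames.
    """
    dg = float(delta_gaze)
    do = float(delta_obj)
    s = dg + do
    tol = zero_tol * max(1.0, abs(dg), abs(do))
    if abs(s) <= tol:
        return 0.0 if abs(dg - do) <= tol else math.nan
    return abs(dg - do) / (2.0 * abs(s))


def _coefficients(delta_gaze: np.ndarray, delta_obj: np.ndarray,
                  zero_tol: float = COEFF_ZERO_TOL) -> np.ndarray:
    """Vectorised difference coefficients with NaN at undefined entries."""
    dg = np.asarray(delta_gaze, float)
    do = np.asarray(delta_obj, float)
    s = dg + do
    tol = zero_tol * np.maximum(1.0, np.maximum(np.abs(dg), np.abs(do)))
    small_sum = np.abs(s) <= tol
    equal = np.abs(dg - do) <= tol
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(dg - do) / (2.0 * np.abs(s))
    c = np.where(small_sum & equal, 0.0, c)
    return np.where(small_sum & ~equal, np.nan, c)


def _combine_dims(coeffs: np.ndarray, combine: Combine) -> float:
    """Combine per-dimension coefficients, skipping undefined ones."""
    ok = ~np.isnan(coeffs)
    if not ok.any():
        return math.nan
    if combine == "mean":
        return float(np.mean(coeffs[ok]))
    return float(np.sum(coeffs[ok]))


def difference_score(w: SampleWindow, object_id: str, combine: Combine = "mean") -> Optional[float]:
    """Window-level combined difference score for one object (None in warm-up)."""
    if not w.full:
        return None
    dg = movement_vector(w.gaze_array())
    do = movement_vector(w.object_array(object_id))
    return _combine_dims(_coefficients(dg, do), combine)


def difference_detect(w: SampleWindow, threshold: float, combine: Combine = "mean") -> Optional[DetectorDecision]:
    """Select the lowest-scoring object if its score falls below the threshold."""
    if not w.full:
        return None
    scores = {k: difference_score(w, k, combine) for k in w.object_ids}
    return _decide(scores, threshold, direction="min")


def _decide(scores: Mapping[str, Optional[float]], threshold: float,
            direction: Literal["max", "min"]) -> DetectorDecision:
    finite = {k: v for k, v in scores.items() if v is not None and not math.isnan(v)}
    selected = None
    tied = False
    if finite:
        best = max(finite.values()) if direction == "max" else min(finite.values())
        hits = sorted(k for k, v in finite.items() if v == best)
        crossed = best > threshold if direction == "max" else best < threshold
        if crossed:
            selected = hits[0]          # deterministic tie-break: lowest id
            tied = len(hits) > 1
    return DetectorDecision(selected_object=selected,
                            score_per_object={k: (math.nan if v is None else v) for k, v in scores.items()},
                            threshold=threshold, tied=tied)


# ---------------------------------------------------------------------------
# Whole-trial score traces (vectorised)
# ---------------------------------------------------------------------------

@dataclass
class ScoreTrace:
    """Per-frame detector scores over a trial, threshold-free.

    ``scores`` has shape ``(n_objects, n_scored_frames)``; frame ``j``
    corresponds to sample count ``frame_index[j]`` since movement onset
    (the first scored frame is the one that fills the window).  Caching the
    trace lets a threshold sweep re-threshold without re-running detectors.
    """

    algorithm: str                      # "correlation" | "difference"
    object_ids: tuple[str, ...]
    scores: np.ndarray
    frame_index: np.ndarray             # (n_scored_frames,)
    time: np.ndarray                    # (n_scored_frames,) s since movement onset
    direction: Literal["max", "min"]

    def decide(self, threshold: float) -> DetectorDecision:
        """First-crossing decision for a trial at the given threshold."""
        if self.scores.size == 0:
            return DetectorDecision(None, {}, threshold)
        with np.errstate(invalid="ignore"):
            if self.direction == "max":
                best = np.nanmax(self.scores, axis=0, initial=-np.inf)
                crossed = best > threshold
            else:
                best = np.nanmin(self.scores, axis=0, initial=np.inf)
                crossed = best < threshold
        idx = np.flatnonzero(crossed)
        if idx.size == 0:
            last = self.scores[:, -1]
            return DetectorDecision(None, dict(zip(self.object_ids, last.tolist())), threshold)
        j = int(idx[0])
        col = self.scores[:, j]
        hits = [self.object_ids[i] for i in np.flatnonzero(col == best[j])]
        hits.sort()
        return DetectorDecision(
            selected_object=hits[0],
            score_per_object=dict(zip(self.object_ids, col.tolist())),
            threshold=threshold,
            frame_index=int(self.frame_index[j]),
            time=float(self.time[j]),
            tied=len(hits) > 1,
        )


def _window_view(a: np.ndarray, window: int) -> np.ndarray:
    """(N, k) -> (N - window + 1, window, k) sliding windows along time."""
    return sliding_window_view(a, window, axis=0).transpose(0, 2, 1)


def _windowed_pearson(g: np.ndarray, o: np.ndarray, window: int) -> np.ndarray:
    """Per-window, per-dimension Pearson r with the zero-variance -> 0 rule."""
    gw = _window_view(g, window)      # (F, W, 3)
    ow = _window_view(o, window)
    gm = gw - gw.mean(axis=1, keepdims=True)
    om = ow - ow.mean(axis=1, keepdims=True)
    sg = np.sqrt(np.sum(gm * gm, axis=1))
    so = np.sqrt(np.sum(om * om, axis=1))
    cov = np.sum(gm * om, axis=1)
    root_w = math.sqrt(window)
    tol_g = ZERO_VAR_RTOL * np.maximum(1.0, np.abs(gw).max(axis=1)) * root_w
    tol_o = ZERO_VAR_RTOL * np.maximum(1.0, np.abs(ow).max(axis=1)) * root_w
    ok = (sg > tol_g) & (so > tol_o)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / (sg * so)
    return np.where(ok, np.clip(r, -1.0, 1.0), 0.0)


def correlation_trace(t: np.ndarray, gaze_sph: np.ndarray,
                      objects_sph: Mapping[str, np.ndarray],
                      window: int = WINDOW_SIZE) -> ScoreTrace:
    """Moving-window correlation scores for every object over a trial."""
    ids = tuple(objects_sph)
    n = len(t)
    if n < window:
        return ScoreTrace("correlation", ids, np.empty((len(ids), 0)),
                          np.empty(0, int), np.empty(0), "max")
    scores = np.stack([_windowed_pearson(gaze_sph, objects_sph[k], window).mean(axis=1)
                       for k in ids])
    frames = np.arange(window, n + 1)
    return ScoreTrace("correlation", ids, scores, frames, t[window - 1:] - t[0], "max")


def _half_means_delta(a: np.ndarray, window: int) -> np.ndarray:
    """Per-window movement vectors: mean(newer half) - mean(older half)."""
    n = len(a)
    old_len = window - window // 2
    new_len = window // 2
    c = np.vstack([np.zeros((1, a.shape[1])), np.cumsum(a, axis=0)])
    starts = np.arange(0, n - window + 1)
    old_mean = (c[starts + old_len] - c[starts]) / old_len
    new_mean = (c[starts + window] - c[starts + old_len]) / new_len
    return new_mean - old_mean


def _rolling_nanmean(c: np.ndarray, window: int) -> np.ndarray:
    """Trailing mean over up to ``window`` rows, ignoring NaN entries."""
    vals = np.where(np.isnan(c), 0.0, c)
    cnt = (~np.isnan(c)).astype(float)
    cv = np.vstack([np.zeros((1, c.shape[1])), np.cumsum(vals, axis=0)])
    cc = np.vstack([np.zeros((1, c.shape[1])), np.cumsum(cnt, axis=0)])
    n = len(c)
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window, 0)
    s = cv[idx] - cv[lo]
    k = cc[idx] - cc[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = s / k
    return np.where(k > 0, out, np.nan)


def difference_trace(t: np.ndarray, gaze_sph: np.ndarray,
                     objects_sph: Mapping[str, np.ndarray],
                     window: int = WINDOW_SIZE, combine: Combine = "mean",
                     smooth: bool = True) -> ScoreTrace:
    """Moving-window difference scores for every object over a trial.

    With ``smooth=True`` (default) the per-dimension coefficients are averaged
    over their recomputations at the frames spanned by the moving window
    before being combined across dimensions.
    """
    ids = tuple(objects_sph)
    n = len(t)
    if n < window:
        return ScoreTrace("difference", ids, np.empty((len(ids), 0)),
                          np.empty(0, int), np.empty(0), "min")
    dg = _half_means_delta(gaze_sph, window)            # (F, 3)
    rows = []
    for k in ids:
        do = _half_means_delta(objects_sph[k], window)
        c = _coefficients(dg, do)                       # (F, 3), NaN = undefined
        if smooth:
            c = _rolling_nanmean(c, window)
        ok = ~np.isnan(c)
        cnt = ok.sum(axis=1)
        total = np.where(ok, c, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            combined = total / cnt if combine == "mean" else total
        rows.append(np.where(cnt > 0, combined, np.nan))
    scores = np.stack(rows)
    frames = np.arange(window, n + 1)
    return ScoreTrace("difference", ids, scores, frames, t[window - 1:] - t[0], "min")


def score_trace(log: TrialLog, algorithm: str, window: int = WINDOW_SIZE,
                objects: str | Sequence[str] = "all", combine: Combine = "mean",
                smooth: bool = True) -> ScoreTrace:
    """Score a trial log with one of the detectors.

    ``objects`` selects the candidate set: ``"all"`` scores every logged
    object (hidden ones included), ``"visible"`` restricts to the rendered
    set, or pass an explicit sequence of labels.
    """
    if objects == "all":
        ids = None
    elif objects == "visible":
        ids = log.meta.visible
    else:
        ids = tuple(objects)
    t, gaze, objs = log.analysis_series(ids)
    if algorithm == "correlation":
        trace = correlation_trace(t, gaze, objs, window)
    elif algorithm == "difference":
        trace = difference_trace(t, gaze, objs, window, combine=combine, smooth=smooth)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    # Duration-until-selection convention: sample count / frame rate.
    trace.time = trace.frame_index / log.meta.frame_rate
    return trace


# ---------------------------------------------------------------------------
# Streaming (online-style) detectors
# ---------------------------------------------------------------------------

class CorrelationDetector:
    """Frame-by-frame correlation detector over a :class:`SampleWindow`."""

    algorithm = "correlation"

    def __init__(self, threshold: float, window_size: int = WINDOW_SIZE):
        self.threshold = threshold
        self.window = SampleWindow(window_size)
        self.frames_seen = 0

    def update(self, gaze, objects, t) -> Optional[DetectorDecision]:
        self.window.push(gaze, objects, t)
        self.frames_seen += 1
        decision = correlation_detect(self.window, self.threshold)
        if decision is not None:
            decision.frame_index = self.frames_seen
        return decision


class DifferenceDetector:
    """Frame-by-frame difference detector with in-window coefficient smoothing."""

    algorithm = "difference"

    def __init__(self, threshold: float, window_size: int = WINDOW_SIZE,
                 combine: Combine = "mean", smooth: bool = True):
        self.threshold = threshold
        self.combine: Combine = combine
        self.smooth = smooth
        self.window = SampleWindow(window_size)
        self.frames_seen = 0
        self._history: dict[str, deque] = {}

    def update(self, gaze, objects, t) -> Optional[DetectorDecision]:
        self.window.push(gaze, objects, t)
        self.frames_seen += 1
        if not self.window.full:
            return None
        dg = movement_vector(self.window.gaze_array())
        scores: dict[str, float] = {}
        for k in self.window.object_ids:
            do = movement_vector(self.window.object_array(k))
            c = _coefficients(dg, do)
            if self.smooth:
                hist = self._history.setdefault(k, deque(maxlen=self.window.capacity))
                hist.append(c)
                stack = np.array(hist)
                with np.errstate(invalid="ignore"):
                    c = np.nanmean(stack, axis=0)
            scores[k] = _combine_dims(c, self.combine)
        decision = _decide(scores, self.threshold, direction="min")
        decision.frame_index = self.frames_seen
        return decision
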