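"""Trial classification, rate metrics, threshold sweeps and algorithm comparison.

A trial outcome is one of

* TP -- the detector selected the true target,
* FP -- it selected any other object,
* ND -- no object crossed the threshold.

The detection rate DR = #TP / n, the false-positive rate FPR = #FP / n and
the non-detection rate NDR = #ND / n partition unity; efficiency
= #TP / (#TP + #FP) is the precision of emitted selections.

Threshold sweeps re-threshold cached score traces over the published grids
(correlation: 0 to .95 in steps of .05; difference: .20 down to .01 in steps
of .01) and score each grid point with two composite criteria built on the
"effectiveness" e = DR / (DR + FPR):

* ``efficiency_1 = e * (1 - e * NDR)`` favours operating points whose misses
  are non-detections rather than false selections (a non-detection can simply
  be repeated, a false selection needs correcting);
* ``efficiency_2`` is the discrete rate of change of effectiveness + NDR
  between adjacent thresholds; a pronounced maximum marks the knee where
  false positives collapse while the detection rate still holds up.

The recommended threshold codifies the hybrid rule: take the candidate from
efficiency_2 (correlation) or efficiency_1 (difference), then move to the
nearest grid point that keeps DR >= 95 % of its curve maximum while
NDR >= FPR, if such a point exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detectors import Combine, DetectorDecision, ScoreTrace, WINDOW_SIZE, score_trace
from .geometry import SPAWN_LABELS
from .trial import TrialLog

__all__ = [
    "CORRELATION_GRID",
    "DIFFERENCE_GRID",
    "DetectionOutcome",
    "RateSummary",
    "ThresholdCurve",
    "classify",
    "summarize",
    "evaluate_trials",
    "compute_traces",
    "threshold_sweep",
    "efficiency_1",
    "efficiency_2",
    "recommend_threshold",
    "directional_dr",
    "sign_test_compare",
    "SignTestResult",
]

#: Published threshold grids (20 points each).
CORRELATION_GRID: np.ndarray = np.round(np.arange(0.0, 0.96, 0.05), 2)
DIFFERENCE_GRID: np.ndarray = np.round(np.arange(0.20, 0.009, -0.01), 2)


@dataclass
class DetectionOutcome:
    """Per-trial classification of a detector decision."""

    trial_id: str
    algorithm: str
    outcome: Literal["TP", "FP", "ND"]
    target: str
    selected: Optional[str] = None
    selection_frame: Optional[int] = None
    selection_time: Optional[float] = None

    @property
    def correct(self) -> bool:
        return self.outcome == "TP"


@dataclass
class RateSummary:
    """DR/FPR/NDR and efficiency over a set of trials."""

    dr: float
    fpr: float
    ndr: float
    efficiency: float
    n_trials: int
    no_selections: bool = False   # efficiency undefined, reported as 1


def classify(decision: DetectorDecision, true_target: str, trial_id: str = "",
             algorithm: str = "") -> DetectionOutcome:
    """Map a detector decision to TP / FP / ND against the ground truth."""
    sel = decision.selected_object
    if sel is None:
        outcome = "ND"
    elif sel == true_target:
        outcome = "TP"
    else:
        outcome = "FP"
    return DetectionOutcome(trial_id=trial_id, algorithm=algorithm, outcome=outcome,
                            target=true_target, selected=sel,
                            selection_frame=decision.frame_index,
                            selection_time=decision.time)


def summarize(outcomes: Sequence[DetectionOutcome]) -> RateSummary:
    """Rates over all trials; DR + FPR + NDR = 1 by construction."""
    n = len(outcomes)
    if n == 0:
        raise ValueError("cannot summarize an empty outcome list")
    tp = sum(o.outcome == "TP" for o in outcomes)
    fp = sum(o.outcome == "FP" for o in outcomes)
    nd = n - tp - fp
    no_sel = (tp + fp) == 0
    eff = 1.0 if no_sel else tp / (tp + fp)
    return RateSummary(dr=tp / n, fpr=fp / n, ndr=nd / n, efficiency=eff,
                       n_trials=n, no_selections=no_sel)


def compute_traces(logs: Iterable[TrialLog], algorithm: str, window: int = WINDOW_SIZE,
                   objects: str | Sequence[str] = "all", combine: Combine = "mean",
                   smooth: bool = True) -> list[tuple[TrialLog, ScoreTrace]]:
    """Score every trial once; sweeps re-threshold these cached traces."""
    return [(log, score_trace(log, algorithm, window=window, objects=objects,
                              combine=combine, smooth=smooth)) for log in logs]


def evaluate_trials(logs: Iterable[TrialLog], algorithm: str, threshold: float,
                    window: int = WINDOW_SIZE, objects: str | Sequence[str] = "all",
                    combine: Combine = "mean", smooth: bool = True) -> list[DetectionOutcome]:
    """Run one detector at one threshold over a set of trials."""
    out = []
    for log, trace in compute_traces(logs, algorithm, window, objects, combine, smooth):
        out.append(classify(trace.decide(threshold), log.meta.target,
                            trial_id=log.meta.trial_id, algorithm=algorithm))
    return out


# ---------------------------------------------------------------------------
# Composite threshold criteria
# ---------------------------------------------------------------------------

def efficiency_1(dr: float, fpr: float, ndr: float) -> float:
    """Composite score ``e * (1 - e * NDR)`` with e = DR/(DR+FPR).

    NaN (undefined) when no selections occurred (DR + FPR = 0).  For equal
    DR the score favours operating points whose residual mass sits in
    non-detections rather than false positives.
    """
    denom = dr + fpr
    if denom <= 0:
        return math.nan
    e = dr / denom
    return e * (1.0 - e * ndr)


def efficiency_2(effectiveness: np.ndarray, ndr: np.ndarray) -> np.ndarray:
    """Signed slope score between adjacent grid points.

    Entry ``i`` is the change of effectiveness + NDR from grid point ``i-1``
    to ``i``; the leading entry is NaN.  Reversing the grid order negates the
    slopes.
    """
    e = np.asarray(effectiveness, float)
    n = np.asarray(ndr, float)
    if len(e) < 2:
        raise ValueError("efficiency_2 needs at least two grid points")
    out = np.full(len(e), np.nan)
    out[1:] = np.diff(e) + np.diff(n)
    return out


@dataclass
class ThresholdCurve:
    """Rates and composite criteria as functions of the threshold grid."""

    algorithm: str
    thresholds: np.ndarray
    summaries: list[RateSummary] = field(repr=False)
    efficiency_1: np.ndarray = field(repr=False)
    efficiency_2: np.ndarray = field(repr=False)
    recommended_threshold: Optional[float] = None
    rationale: dict = field(default_factory=dict)

    @property
    def dr(self) -> np.ndarray:
        return np.array([s.dr for s in self.summaries])

    @property
    def fpr(self) -> np.ndarray:
        return np.array([s.fpr for s in self.summaries])

    @property
    def ndr(self) -> np.ndarray:
        return np.array([s.ndr for s in self.summaries])

    @property
    def efficiency(self) -> np.ndarray:
        return np.array([s.efficiency for s in self.summaries])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "dr": self.dr,
            "fpr": self.fpr,
            "ndr": self.ndr,
            "efficiency": self.efficiency,
            "efficiency_1": self.efficiency_1,
            "efficiency_2": self.efficiency_2,
        })


def threshold_sweep(logs: Sequence[TrialLog], algorithm: str,
                    grid: Optional[np.ndarray] = None, window: int = WINDOW_SIZE,
                    objects: str | Sequence[str] = "all", combine: Combine = "mean",
                    smooth: bool = True,
                    traces: Optional[Sequence[tuple[TrialLog, ScoreTrace]]] = None) -> ThresholdCurve:
    """Evaluate a detector over its full threshold grid."""
    if grid is None:
        grid = CORRELATION_GRID if algorithm == "correlation" else DIFFERENCE_GRID
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if traces is None:
        traces = compute_traces(logs, algorithm, window, objects, combine, smooth)
    summaries = []
    for thr in grid:
        outcomes = [classify(trace.decide(float(thr)), log.meta.target,
                             trial_id=log.meta.trial_id, algorithm=algorithm)
                    for log, trace in traces]
        summaries.append(summarize(outcomes))
    eff1 = np.array([efficiency_1(s.dr, s.fpr, s.ndr) for s in summaries])
    with np.errstate(invalid="ignore"):
        effectiveness = np.array([math.nan if (s.dr + s.fpr) == 0 else s.dr / (s.dr + s.fpr)
                                  for s in summaries])
    eff2 = efficiency_2(effectiveness, np.array([s.ndr for s in summaries]))
    curve = ThresholdCurve(algorithm=algorithm, thresholds=grid, summaries=summaries,
                           efficiency_1=eff1, efficiency_2=eff2)
    thr, rationale = recommend_threshold(curve, algorithm)
    curve.recommended_threshold = thr
    curve.rationale = rationale
    return curve


def recommend_threshold(curve: ThresholdCurve, algorithm: Optional[str] = None) -> tuple[float, dict]:
    """Deterministic codification of the hybrid threshold choice.

    Candidate = argmax of efficiency_2 (correlation) or efficiency_1
    (difference); adjusted to the nearest grid point keeping DR >= 95 % of
    the curve maximum, preferring points with NDR >= FPR when attainable.
    """
    algorithm = algorithm or curve.algorithm
    criterion = "efficiency_2" if algorithm == "correlation" else "efficiency_1"
    score = curve.efficiency_2 if criterion == "efficiency_2" else curve.efficiency_1
    defined = ~np.isnan(score)
    if not defined.any() or np.nanmax(score) == np.nanmin(score):
        cand = 0                      # flat criterion: no informative maximum
    else:
        cand = int(np.nanargmax(score))
    dr = curve.dr
    fpr = curve.fpr
    ndr = curve.ndr
    dr_ok = dr >= 0.95 * dr.max() - 1e-12
    preferred = dr_ok & (ndr >= fpr)
    pool = preferred if preferred.any() else dr_ok
    idxs = np.flatnonzero(pool)
    chosen = int(idxs[np.argmin(np.abs(idxs - cand))])
    rationale = {
        "criterion": criterion,
        "candidate_threshold": float(curve.thresholds[cand]),
        "chosen_threshold": float(curve.thresholds[chosen]),
        "dr_floor": float(0.95 * dr.max()),
        "ndr_ge_fpr_attainable": bool(preferred.any()),
    }
    return float(curve.thresholds[chosen]), rationale


# ---------------------------------------------------------------------------
# Directional analysis and algorithm comparison
# ---------------------------------------------------------------------------

BASE_DIRECTIONS = ("l", "r", "t", "b", "n", "f")


def directional_dr(outcomes: Sequence[DetectionOutcome]) -> dict[str, float]:
    """Mean DR per base movement direction (left/right/up/down/nearing/far).

    Each direction averages the per-object DRs of the nine labels containing
    that direction letter; directions with no observed labels are omitted.
    """
    by_label: dict[str, list[DetectionOutcome]] = {}
    for o in outcomes:
        by_label.setdefault(o.target, []).append(o)
    label_dr = {lab: np.mean([o.outcome == "TP" for o in objs])
                for lab, objs in by_label.items()}
    result: dict[str, float] = {}
    for d in BASE_DIRECTIONS:
        members = [lab for lab in SPAWN_LABELS if d in lab]
        present = [label_dr[lab] for lab in members if lab in label_dr]
        if present:
            result[d] = float(np.mean(present))
    return result


class SignTestResult(NamedTuple):
    n_plus_a: int          # informative trials where algorithm A was the correct one
    n_informative: int     # trials with diverging correctness
    p_value: Optional[float]


def sign_test_compare(outcomes_a: Sequence[DetectionOutcome],
                      outcomes_b: Sequence[DetectionOutcome]) -> SignTestResult:
    """Paired sign test of two algorithms on the same trials.

    Trials where both algorithms were equally (in)correct are dropped; for
    the rest a '+' goes to the correct algorithm and the '+' count for A is
    tested against an exact Binomial(n, 0.5), two-sided by doubling the
    smaller tail (capped at 1).  Returns ``p_value=None`` when no informative
    trials remain.
    """
    b_by_id = {o.trial_id: o for o in outcomes_b}
    k = 0
    n = 0
    for oa in outcomes_a:
        ob = b_by_id.get(oa.trial_id)
        if ob is None:
            continue
        if oa.correct == ob.correct:
            continue
        n += 1
        if oa.correct:
            k += 1
    if n == 0:
        return SignTestResult(0, 0, None)
    p = binomial_two_sided(k, n)
    return SignTestResult(k, n, p)


def binomial_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial p-value by doubling the smaller tail."""
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return float(min(1.0, 2.0 * min(lower, upper)))
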