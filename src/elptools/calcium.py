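"""Ratiometric (Fura-2, F340/380) calcium trace normalization and peak calling.

Traces are sampled every 2 s.  A 0-200 s baseline precedes a 20 s capsaicin
pulse (200-220 s) and, after washout, a 45 s high-K+ (KCl) pulse at
780-825 s.  Response calls follow run-length rules on the baseline-normalized
fold series:

* capsaicin: first run of at least 5 consecutive samples strictly greater
  than 10% above baseline, starting in [200, 780) s;
* KCl: same run rule at strictly greater than 20% above baseline, starting
  strictly after 780 s.

The reported peak is the maximum of the contiguous supra-baseline excursion
containing the qualifying run; the AUC is the trapezoidal integral of
(fold - 1) over that excursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalciumTrace",
    "StimulusWindows",
    "PeakCall",
    "normalize_to_baseline",
    "find_threshold_run",
    "call_capsaicin_peak",
    "call_kcl_peak",
    "call_trace",
    "calls_to_frame",
    "summarize_population",
]


@dataclass
class CalciumTrace:
    """One neuron's F340/380 ratio series on a uniform time grid."""

    times: np.ndarray
    ratios: np.ndarray
    neuron_id: str = ""
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.times.shape != self.ratios.shape:
            raise ValueError("times and ratios must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class StimulusWindows:
    """Stimulus timing of the standard perfusion protocol, in seconds."""

    baseline: tuple[float, float] = (0.0, 200.0)
    capsaicin: tuple[float, float] = (200.0, 220.0)
    caps_search: tuple[float, float] = (200.0, 780.0)
    kcl: tuple[float, float] = (780.0, 825.0)
    kcl_search_start: float = 780.0  # KCl run must start strictly after this

    def __post_init__(self) -> None:
        if self.baseline[1] > self.capsaicin[0]:
            raise ValueError("baseline window must end before the capsaicin pulse")
        if self.capsaicin[1] > self.kcl[0]:
            raise ValueError("capsaicin and KCl windows overlap")


@dataclass
class PeakCall:
    """Outcome of one run-length response rule on one trace."""

    detected: bool
    rule: str
    threshold: float
    peak_fold: float = float("nan")
    time_to_peak: float = float("nan")
    auc: float = float("nan")


def normalize_to_baseline(
    trace: CalciumTrace, baseline: tuple[float, float] = (0.0, 200.0)
) -> np.ndarray:
    """Fold-change series: ratio(t) / mean ratio over the baseline window."""
    mask = (trace.times >= baseline[0]) & (trace.times < baseline[1])
    if mask.sum() < 10:
        raise ValueError("need at least 10 samples in the baseline window")
    base = float(np.mean(trace.ratios[mask]))
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    return trace.ratios / base


def find_threshold_run(
    fold: np.ndarray,
    times: np.ndarray,
    threshold: float,
    min_run: int,
    window: tuple[float, float],
    left_open: bool = False,
) -> tuple[int, int] | None:
    """Earliest run of >= ``min_run`` consecutive samples with fold strictly
    above ``threshold`` whose start time lies in the search window.

    Returns ``(start_index, run_length)`` of the maximal qualifying run, or
    ``None``.  ``left_open`` makes the window's left edge strict (the KCl
    "time to peak > 780 s" convention).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    lo, hi = window
    if not lo < hi:
        raise ValueError("empty search window")
    fold = np.asarray(fold, dtype=float)
    times = np.asarray(times, dtype=float)
    above = fold > threshold
    if not above.any():
        return None
    # maximal runs of consecutive supra-threshold samples
    padded = np.r_[False, above, False].astype(np.int8)
    edges = np.diff(padded)
    run_starts = np.flatnonzero(edges == 1)
    run_ends = np.flatnonzero(edges == -1)  # exclusive
    for s, e in zip(run_starts, run_ends):
        if e - s < min_run:
            continue
        t0 = times[s]
        in_window = (t0 > lo if left_open else t0 >= lo) and t0 < hi
        if in_window:
            return int(s), int(e - s)
    return None


def _excursion_call(
    fold: np.ndarray, times: np.ndarray, run_start: int, rule: str, threshold: float
) -> PeakCall:
    """Build a PeakCall from the supra-baseline excursion containing a run.

    The excursion is the contiguous stretch with fold > 1 around the run;
    the integration interval is extended by one sample on each side (clipped
    at 0 below baseline) so the trapezoid captures the baseline crossings.
    """
    n = fold.size
    lo = run_start
    while lo > 0 and fold[lo - 1] > 1.0:
        lo -= 1
    hi = run_start
    while hi < n - 1 and fold[hi + 1] > 1.0:
        hi += 1
    peak_idx = lo + int(np.argmax(fold[lo : hi + 1]))
    a = max(lo - 1, 0)
    b = min(hi + 1, n - 1)
    auc = float(np.trapezoid(np.clip(fold[a : b + 1] - 1.0, 0.0, None), times[a : b + 1]))
    return PeakCall(
        detected=True,
        rule=rule,
        threshold=threshold,
        peak_fold=float(fold[peak_idx]),
        time_to_peak=float(times[peak_idx]),
        auc=auc,
    )


def call_capsaicin_peak(
    fold: np.ndarray,
    times: np.ndarray,
    windows: StimulusWindows | None = None,
    threshold: float = 1.10,
    min_run: int = 5,
) -> PeakCall:
    """Capsaicin response call: 5-sample run strictly above 10% over baseline.

    The search window ends where the KCl window begins so depolarization
    responses are never attributed to capsaicin.
    """
    windows = windows or StimulusWindows()
    run = find_threshold_run(fold, times, threshold, min_run, windows.caps_search)
    if run is None:
        return PeakCall(detected=False, rule="capsaicin", threshold=threshold)
    return _excursion_call(fold, times, run[0], "capsaicin", threshold)


def call_kcl_peak(
    fold: np.ndarray,
    times: np.ndarray,
    windows: StimulusWindows | None = None,
    threshold: float = 1.20,
    min_run: int = 5,
) -> PeakCall:
    """High-K+ response call: 5-sample run strictly above 20% over baseline,
    starting strictly after 780 s."""
    windows = windows or StimulusWindows()
    t_end = float(times[-1]) + 1.0
    run = find_threshold_run(
        fold,
        times,
        threshold,
        min_run,
        (windows.kcl_search_start, t_end),
        left_open=True,
    )
    if run is None:
        return PeakCall(detected=False, rule="kcl", threshold=threshold)
    return _excursion_call(fold, times, run[0], "kcl", threshold)


def call_trace(
    trace: CalciumTrace, windows: StimulusWindows | None = None
) -> tuple[PeakCall, PeakCall]:
    """Normalize one trace and apply both stimulus rules."""
    windows = windows or StimulusWindows()
    fold = normalize_to_baseline(trace, windows.baseline)
    return (
        call_capsaicin_peak(fold, trace.times, windows),
        call_kcl_peak(fold, trace.times, windows),
    )


def calls_to_frame(
    traces: list[CalciumTrace], windows: StimulusWindows | None = None
) -> pd.DataFrame:
    """Tidy per-neuron per-rule call table for a trace collection."""
    rows = []
    for tr in traces:
        for call in call_trace(tr, windows):
            rows.append(
                {
                    "neuron_id": tr.neuron_id,
                    "animal_id": tr.animal_id,
                    "group": tr.group,
                    "rule": call.rule,
                    "detected": call.detected,
                    "peak_fold": call.peak_fold,
                    "time_to_peak_s": call.time_to_peak,
                    "auc": call.auc,
                }
            )
    return pd.DataFrame(rows)


def summarize_population(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-rule responder fractions and response distributions.

    Input is the tidy frame from :func:`calls_to_frame`.  Detected-only means
    are reported for peak_fold / time-to-peak / AUC; the responder fraction
    uses all neurons of the group.
    """
    if calls.empty:
        raise ValueError("empty call table")
    out = []
    for (group, rule), sub in calls.groupby(["group", "rule"], sort=True):
        det = sub[sub["detected"]]
        out.append(
            {
                "group": group,
                "rule": rule,
                "n_neurons": len(sub),
                "n_responders": len(det),
                "responder_fraction": len(det) / len(sub),
                "mean_peak_fold": det["peak_fold"].mean(),
                "mean_time_to_peak_s": det["time_to_peak_s"].mean(),
                "mean_auc": det["auc"].mean(),
            }
        )
    return pd.DataFrame(out)
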