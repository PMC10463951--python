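"""IntelliCage event-stream phenotyping.

Turns corner-visit event tables (animal, corner, start, end, nosepoke and
lick counts) plus a task schedule into the behavioral readouts of a
sequential home-cage experiment: 12-h binned activity time courses,
nosepokes per visit, correct-corner fractions in learning tasks, lick
metrics, rapid same-corner re-entries (inter-visit interval < 60 s), a
shuffle-null repetitiveness log-ratio, and a per-animal x per-task feature
matrix.

Visit table schema (CSV, one row per visit)
-------------------------------------------
``animal_id, group, corner, start_s, end_s, task, np_count,
np_correct_count, door_opened, lick_count, lick_duration_s``

with ``corner`` in 1..4 and times in seconds from experiment start (t = 0 is
lights-on of day 0 unless the schedule says otherwise).  ``group`` and
``task`` may be left empty; ``task`` is filled from the schedule on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TASKS",
    "OPPOSITE_CORNER",
    "TaskSchedule",
    "VisitValidationError",
    "load_visits",
    "load_schedule",
    "assign_bins",
    "bin_timecourse",
    "np_per_visit",
    "correct_visit_fraction",
    "fast_reentries",
    "repetitiveness",
    "lick_metrics",
    "task_feature_matrix",
    "FEATURE_PARAMETERS",
]

#: Task sequence: free adaptation, nosepoke adaptation (3 correct corners),
#: place preference learning, and its reversal.
TASKS = ("FA", "NP3c", "PPL", "PPLrev")

#: Diagonally opposite corner of the 4-corner cage; the PPL-reversal corner
#: is the corner opposite the PPL corner.
OPPOSITE_CORNER = {1: 3, 2: 4, 3: 1, 4: 2}

SECONDS_PER_DAY = 86_400.0
SECONDS_PER_HOUR = 3_600.0


class VisitValidationError(ValueError):
    """Raised on schema violations in a visit table, naming the row."""


@dataclass
class TaskSchedule:
    """Ordered task segments plus per-animal corner assignments.

    ``segments`` has columns (task, start_s, end_s), contiguous and
    non-overlapping.  ``ppl_corner`` maps animal_id to its rewarded PPL
    corner; the PPLrev corner is derived as the opposite corner, and the
    NP3c correct set is every corner except the (future) PPLrev corner.
    """

    segments: pd.DataFrame
    ppl_corner: dict[str, int] = field(default_factory=dict)
    lights_on_s: float = 0.0
    day_length_h: float = 12.0

    def __post_init__(self) -> None:
        seg = self.segments.reset_index(drop=True)
        if seg.empty:
            raise ValueError("task schedule must have at least one segment")
        if list(seg.columns[:3]) != ["task", "start_s", "end_s"]:
            seg = seg[["task", "start_s", "end_s"]]
        if (seg["end_s"] <= seg["start_s"]).any():
            raise ValueError("schedule segments must have positive duration")
        if (seg["start_s"].values[1:] != seg["end_s"].values[:-1]).any():
            raise ValueError("schedule segments must be contiguous")
        self.segments = seg

    @property
    def start_s(self) -> float:
        return float(self.segments["start_s"].iloc[0])

    @property
    def end_s(self) -> float:
        return float(self.segments["end_s"].iloc[-1])

    def task_at(self, t: float) -> str | None:
        seg = self.segments
        hit = seg[(seg["start_s"] <= t) & (t < seg["end_s"])]
        if hit.empty:
            return None
        return str(hit["task"].iloc[0])

    def tasks_present(self) -> list[str]:
        return list(dict.fromkeys(self.segments["task"]))

    def correct_corners(self, animal_id: str, task: str) -> set[int]:
        """Correct corner set for an animal in a task (empty set for FA)."""
        if task == "FA" or animal_id not in self.ppl_corner:
            return set()
        ppl = self.ppl_corner[animal_id]
        rev = OPPOSITE_CORNER[ppl]
        if task == "PPL":
            return {ppl}
        if task == "PPLrev":
            return {rev}
        if task == "NP3c":
            return {1, 2, 3, 4} - {rev}
        return set()

    def is_day(self, t: float | np.ndarray) -> np.ndarray:
        """Light phase membership for times in seconds from experiment start."""
        hours = (np.asarray(t, dtype=float) - self.lights_on_s) / SECONDS_PER_HOUR
        return (hours % 24.0) < self.day_length_h


_VISIT_COLUMNS = [
    "animal_id",
    "group",
    "corner",
    "start_s",
    "end_s",
    "task",
    "np_count",
    "np_correct_count",
    "door_opened",
    "lick_count",
    "lick_duration_s",
]


def _validate_visits(visits: pd.DataFrame) -> pd.DataFrame:
    """Schema and ordering checks; raises VisitValidationError with row numbers."""
    required = {"animal_id", "corner", "start_s", "end_s"}
    missing = required - set(visits.columns)
    if missing:
        raise VisitValidationError(f"missing required columns: {sorted(missing)}")
    for col, default in [
        ("group", ""),
        ("task", ""),
        ("np_count", 0),
        ("np_correct_count", 0),
        ("door_opened", True),
        ("lick_count", 0),
        ("lick_duration_s", 0.0),
    ]:
        if col not in visits.columns:
            visits[col] = default
    bad = visits.index[visits["end_s"] <= visits["start_s"]]
    if len(bad):
        raise VisitValidationError(f"end_s <= start_s in row {bad[0]}")
    bad = visits.index[~visits["corner"].isin([1, 2, 3, 4])]
    if len(bad):
        raise VisitValidationError(
            f"unknown corner {visits.loc[bad[0], 'corner']!r} in row {bad[0]}"
        )
    visits = visits.sort_values(["animal_id", "start_s"], kind="stable").reset_index(
        drop=True
    )
    for animal, sub in visits.groupby("animal_id", sort=False):
        overlap = sub["start_s"].values[1:] < sub["end_s"].values[:-1]
        if overlap.any():
            row = sub.index[1:][overlap][0]
            raise VisitValidationError(
                f"overlapping visits for animal {animal!r} at row {row}"
            )
    return visits[_VISIT_COLUMNS]


def load_visits(path, schedule: TaskSchedule | None = None) -> pd.DataFrame:
    """Read and validate a visit CSV; fills the task column from the schedule.

    Empty files yield an empty (but well-formed) visit table.
    """
    try:
        visits = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        visits = pd.DataFrame(columns=_VISIT_COLUMNS)
    if visits.empty:
        return pd.DataFrame(columns=_VISIT_COLUMNS)
    visits = _validate_visits(visits)
    if schedule is not None:
        visits["task"] = [schedule.task_at(t) for t in visits["start_s"]]
    return visits


def load_schedule(segments_path, assignments_path=None, lights_on_s: float = 0.0) -> TaskSchedule:
    """Read the task-segment CSV (task, start_s, end_s) and an optional
    corner-assignment CSV (animal_id, ppl_corner)."""
    segments = pd.read_csv(segments_path)
    ppl: dict[str, int] = {}
    if assignments_path is not None:
        assign = pd.read_csv(assignments_path)
        ppl = dict(zip(assign["animal_id"].astype(str), assign["ppl_corner"].astype(int)))
    return TaskSchedule(segments=segments, ppl_corner=ppl, lights_on_s=lights_on_s)


def assign_bins(
    visits: pd.DataFrame, bin_width_h: float = 12.0, anchor_s: float = 0.0
) -> pd.DataFrame:
    """Add a ``bin`` column: half-open [t, t+width) bins aligned to lights-on.

    A visit belongs to the bin containing its start; a start exactly on a bin
    edge goes to the later bin.
    """
    if bin_width_h <= 0:
        raise ValueError("bin_width_h must be positive")
    visits = visits.copy()
    width_s = bin_width_h * SECONDS_PER_HOUR
    visits["bin"] = np.floor((visits["start_s"].values - anchor_s) / width_s).astype(int)
    return visits


def bin_timecourse(
    visits: pd.DataFrame,
    bin_width_h: float = 12.0,
    anchor_s: float = 0.0,
    total_duration_s: float | None = None,
) -> pd.DataFrame:
    """Per-animal per-bin rates: visits/h, NP/h, licks/h, lick duration/h.

    Bins with no visits within the observation span are reported as zero
    rates, so circadian time courses have a complete grid.
    """
    if visits.empty:
        raise ValueError("empty visit stream")
    visits = assign_bins(visits, bin_width_h, anchor_s)
    if total_duration_s is None:
        total_duration_s = float(visits["end_s"].max())
    n_bins = int(np.ceil((total_duration_s - anchor_s) / (bin_width_h * SECONDS_PER_HOUR)))
    agg = (
        visits.groupby(["animal_id", "bin"])
        .agg(
            n_visits=("corner", "size"),
            n_np=("np_count", "sum"),
            n_licks=("lick_count", "sum"),
            lick_duration_s=("lick_duration_s", "sum"),
        )
        .reset_index()
    )
    animals = sorted(visits["animal_id"].unique())
    grid = pd.MultiIndex.from_product(
        [animals, range(n_bins)], names=["animal_id", "bin"]
    )
    agg = agg.set_index(["animal_id", "bin"]).reindex(grid, fill_value=0).reset_index()
    agg["visits_per_h"] = agg["n_visits"] / bin_width_h
    agg["np_per_h"] = agg["n_np"] / bin_width_h
    agg["licks_per_h"] = agg["n_licks"] / bin_width_h
    agg["lick_duration_per_h"] = agg["lick_duration_s"] / bin_width_h
    agg["bin_start_s"] = anchor_s + agg["bin"] * bin_width_h * SECONDS_PER_HOUR
    return agg


def np_per_visit(visits: pd.DataFrame, by: list[str] | tuple[str, ...] = ("animal_id",)) -> pd.Series:
    """Total nosepokes / total visits per grouping unit; 0-visit units are NaN.

    To get per-bin ratios, first add a ``bin`` column with :func:`assign_bins`
    and group by ``("animal_id", "bin")``.
    """
    by = list(by)
    if not by:
        raise ValueError("grouping must be non-empty")
    g = visits.groupby(by)
    counts = g.size()
    nps = g["np_count"].sum()
    ratio = nps / counts
    return ratio.where(counts > 0)


def correct_visit_fraction(
    visits: pd.DataFrame, schedule: TaskSchedule
) -> pd.DataFrame:
    """Fraction of visits to the animal's correct corner(s) per animal per day.

    Only learning tasks (NP3c, PPL, PPLrev) contribute; FA visits are
    excluded since no corner is "correct" during free adaptation.
    """
    learning = visits[visits["task"].isin(["NP3c", "PPL", "PPLrev"])].copy()
    if learning.empty:
        return pd.DataFrame(columns=["animal_id", "day", "task", "n_visits", "correct_fraction"])
    learning["day"] = (learning["start_s"] // SECONDS_PER_DAY).astype(int)
    rows = []
    for (animal, day, task), sub in learning.groupby(["animal_id", "day", "task"]):
        correct = schedule.correct_corners(str(animal), str(task))
        frac = float(sub["corner"].isin(correct).mean()) if correct else np.nan
        rows.append(
            {
                "animal_id": animal,
                "day": day,
                "task": task,
                "n_visits": len(sub),
                "correct_fraction": frac,
            }
        )
    return pd.DataFrame(rows)


def _reentry_pairs(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(same_corner, ivi) arrays over consecutive visit pairs of one animal.

    The inter-visit interval is measured end-to-start (the gap between
    visits), matching the "re-entry" semantics.
    """
    corners = sub["corner"].to_numpy()
    ivi = sub["start_s"].to_numpy()[1:] - sub["end_s"].to_numpy()[:-1]
    same = corners[1:] == corners[:-1]
    return same, ivi


def fast_reentries(
    visits: pd.DataFrame, ivi_threshold: float = 60.0
) -> pd.DataFrame:
    """Per-animal count and hourly rate of same-corner re-entries with
    IVI strictly below the threshold (default 60 s)."""
    rows = []
    for animal, sub in visits.sort_values("start_s").groupby("animal_id"):
        same, ivi = _reentry_pairs(sub)
        n_fast = int(np.sum(same & (ivi < ivi_threshold)))
        span_h = (sub["end_s"].max() - sub["start_s"].min()) / SECONDS_PER_HOUR
        rows.append(
            {
                "animal_id": animal,
                "n_visits": len(sub),
                "n_fast_reentries": n_fast,
                "fast_reentries_per_h": n_fast / span_h if span_h > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _repetitiveness_unit(
    corners: np.ndarray,
    ivi: np.ndarray,
    ivi_threshold: float,
    n_shuffles: int,
    rng: np.random.Generator,
) -> tuple[int, float, float, bool]:
    """(observed, expected, log2-ratio, pseudo_count_used) for one unit.

    Expected counts come from permuting the corner-label sequence while the
    visit timestamps (hence the IVI structure and the per-corner visit
    counts) stay fixed.
    """
    fast = ivi < ivi_threshold
    observed = int(np.sum((corners[1:] == corners[:-1]) & fast))
    tiled = np.broadcast_to(corners.astype(np.int8), (n_shuffles, corners.size)).copy()
    shuffled = rng.permuted(tiled, axis=1)
    counts = np.sum((shuffled[:, 1:] == shuffled[:, :-1]) & fast, axis=1)
    expected = float(counts.mean())
    if observed == 0 or expected == 0:
        value = float(np.log2((observed + 0.5) / (expected + 0.5)))
        return observed, expected, value, True
    return observed, expected, float(np.log2(observed / expected)), False


def repetitiveness(
    visits: pd.DataFrame,
    ivi_threshold: float = 60.0,
    n_shuffles: int = 1000,
    seed: int = 0,
    by_task: bool = True,
    min_visits: int = 10,
) -> pd.DataFrame:
    """Log2 ratio of observed vs shuffle-expected rapid same-corner returns.

    One row per animal per task plus an "overall" row spanning the whole
    stream.  Units with fewer than 2 visits are NaN; units below
    ``min_visits`` are flagged ``low_n``.  The shuffle null permutes corner
    labels over the fixed visit timestamps (1000 shuffles by default),
    preserving unequal corner preferences and the empirical IVI
    distribution.
    """
    rng = np.random.default_rng(seed)
    units: list[tuple[str, str, pd.DataFrame]] = []
    for animal, sub in visits.sort_values("start_s").groupby("animal_id"):
        if by_task:
            for task in dict.fromkeys(sub["task"]):
                units.append((str(animal), str(task), sub[sub["task"] == task]))
        units.append((str(animal), "overall", sub))
    rows = []
    for animal, task, sub in units:
        if len(sub) < 2:
            rows.append(
                {
                    "animal_id": animal,
                    "task": task,
                    "n_visits": len(sub),
                    "observed": np.nan,
                    "expected": np.nan,
                    "value": np.nan,
                    "pseudo_count": False,
                    "low_n": True,
                }
            )
            continue
        same, ivi = _reentry_pairs(sub)
        obs, exp, value, pseudo = _repetitiveness_unit(
            sub["corner"].to_numpy(), ivi, ivi_threshold, n_shuffles, rng
        )
        rows.append(
            {
                "animal_id": animal,
                "task": task,
                "n_visits": len(sub),
                "observed": obs,
                "expected": exp,
                "value": value,
                "pseudo_count": pseudo,
                "low_n": len(sub) < min_visits,
            }
        )
    return pd.DataFrame(rows)


def lick_metrics(
    visits: pd.DataFrame,
    by: list[str] | tuple[str, ...] = ("animal_id",),
    unit_duration_h: float | None = None,
) -> pd.DataFrame:
    """licks/h, lick duration/h and licks/visit per grouping unit.

    ``unit_duration_h`` normalizes the hourly rates; when None, the time
    span of each unit's visits is used.  For day/night splits, add a
    ``daytime`` column (see :meth:`TaskSchedule.is_day`) and group by it
    with ``unit_duration_h`` set to the phase duration.
    """
    by = list(by)
    if not by:
        raise ValueError("grouping must be non-empty")
    rows = []
    for key, sub in visits.groupby(by):
        key = key if isinstance(key, tuple) else (key,)
        if unit_duration_h is None:
            span_h = (sub["end_s"].max() - sub["start_s"].min()) / SECONDS_PER_HOUR
        else:
            span_h = unit_duration_h
        licks = sub["lick_count"].sum()
        dur = sub["lick_duration_s"].sum()
        rows.append(
            dict(zip(by, key))
            | {
                "n_visits": len(sub),
                "licks_per_h": licks / span_h if span_h > 0 else np.nan,
                "lick_duration_per_h": dur / span_h if span_h > 0 else np.nan,
                "licks_per_visit": licks / len(sub),
            }
        )
    return pd.DataFrame(rows)


#: Parameters computed per day and averaged per task in the feature matrix.
FEATURE_PARAMETERS = (
    "visits_per_h",
    "visits_per_h_day",
    "visits_per_h_night",
    "np_per_visit",
    "np_per_h",
    "licks_per_h",
    "lick_duration_per_h",
    "licks_per_visit",
    "frac_visits_with_np",
    "mean_visit_duration_s",
    "mean_ivi_s",
    "fast_reentries_per_h",
    "correct_fraction",
    "repetitiveness",
)


def _daily_parameters(
    visits: pd.DataFrame, schedule: TaskSchedule, ivi_threshold: float
) -> pd.DataFrame:
    """Per-animal per-day behavioral parameters (everything but repetitiveness)."""
    v = visits.copy()
    v["day"] = (v["start_s"] // SECONDS_PER_DAY).astype(int)
    v["daytime"] = schedule.is_day(v["start_s"].to_numpy())
    day_h = schedule.day_length_h
    night_h = 24.0 - day_h
    rows = []
    for (animal, day), sub in v.sort_values("start_s").groupby(["animal_id", "day"]):
        task = schedule.task_at(day * SECONDS_PER_DAY + 1.0)
        same, ivi = _reentry_pairs(sub)
        n_fast = int(np.sum(same & (ivi < ivi_threshold)))
        correct = schedule.correct_corners(str(animal), str(task)) if task else set()
        rows.append(
            {
                "animal_id": animal,
                "day": day,
                "task": task,
                "visits_per_h": len(sub) / 24.0,
                "visits_per_h_day": sub["daytime"].sum() / day_h,
                "visits_per_h_night": (~sub["daytime"]).sum() / night_h,
                "np_per_visit": sub["np_count"].sum() / len(sub),
                "np_per_h": sub["np_count"].sum() / 24.0,
                "licks_per_h": sub["lick_count"].sum() / 24.0,
                "lick_duration_per_h": sub["lick_duration_s"].sum() / 24.0,
                "licks_per_visit": sub["lick_count"].sum() / len(sub),
                "frac_visits_with_np": float((sub["np_count"] > 0).mean()),
                "mean_visit_duration_s": float((sub["end_s"] - sub["start_s"]).mean()),
                "mean_ivi_s": float(ivi.mean()) if ivi.size else np.nan,
                "fast_reentries_per_h": n_fast / 24.0,
                "correct_fraction": float(sub["corner"].isin(correct).mean())
                if correct
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def task_feature_matrix(
    visits: pd.DataFrame,
    schedule: TaskSchedule,
    ivi_threshold: float = 60.0,
    n_shuffles: int = 200,
    seed: int = 0,
    parameters: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-animal feature matrix: parameters averaged per task plus overall.

    Per-day parameter values are averaged over each task's duration and over
    the whole observation ("overall"), so every animal contributes exactly
    five values per parameter — one per task (FA, NP3c, PPL, PPLrev) and the
    overall mean.  Repetitiveness is computed on each task's whole event
    stream (per-day fast-return counts are too sparse for a stable
    log-ratio).  Columns form a (parameter, task) MultiIndex.
    """
    parameters = parameters or FEATURE_PARAMETERS
    unknown = set(parameters) - set(FEATURE_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    tasks = schedule.tasks_present()
    daily = _daily_parameters(visits, schedule, ivi_threshold)
    day_params = [p for p in parameters if p != "repetitiveness"]
    frames = {}
    if day_params:
        per_task = daily.groupby(["animal_id", "task"])[day_params].mean()
        overall = daily.groupby("animal_id")[day_params].mean()
        overall["task"] = "overall"
        overall = overall.set_index("task", append=True)
        frames["daily"] = pd.concat([per_task, overall])
    if "repetitiveness" in parameters:
        rep = repetitiveness(
            visits, ivi_threshold, n_shuffles=n_shuffles, seed=seed, by_task=True
        )
        frames["rep"] = rep.set_index(["animal_id", "task"])[["value"]].rename(
            columns={"value": "repetitiveness"}
        )
    combined = pd.concat(frames.values(), axis=1)
    wide = combined.unstack("task")
    ordered_tasks = [t for t in list(tasks) + ["overall"] if t in wide.columns.levels[1]]
    wide = wide.reindex(columns=pd.MultiIndex.from_product([list(parameters), ordered_tasks]))
    wide.columns.names = ["parameter", "task"]
    return wide
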