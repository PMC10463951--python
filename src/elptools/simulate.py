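"""Synthetic data generators with exhaustive ground truth.

Every modality the analysis modules consume can be generated here with known
truth, so the whole pipeline is testable without animal data:

* MEA voltage traces — Gaussian noise plus biphasic extracellular spike
  waveforms inserted at Poisson times (the 60-electrode, 50 kHz, 5-minute
  slice-recording regime);
* Fura-2 ratio traces — baseline plus smooth rise/decay transients at the
  capsaicin (200-220 s) and KCl (780-825 s) windows, sampled every 2 s;
* IntelliCage visit streams — a Markov corner chain with circadian
  day/night visit rates, negative-binomial nosepokes, Poisson licks and the
  FA → NP3c → PPL → PPLrev task schedule;
* lipid feature tables — log-normal intensities with a planted group shift
  in a subset of species.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .calcium import CalciumTrace
from .icage import OPPOSITE_CORNER, SECONDS_PER_DAY, SECONDS_PER_HOUR, TaskSchedule
from .mea import MEARecording

__all__ = [
    "ConfigError",
    "MEASimConfig",
    "CaSimConfig",
    "GroupBehavior",
    "ICSimConfig",
    "LipidSimConfig",
    "spike_kernel",
    "simulate_mea_recording",
    "simulate_calcium_traces",
    "simulate_intellicage",
    "simulate_lipid_table",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# MEA


@dataclass
class MEASimConfig:
    """Multichannel extracellular recording simulation.

    Defaults emulate the slice-recording regime: 60 electrodes, 5-minute
    traces at 50 kHz.  ``spike_rate`` may be a scalar (all channels) or a
    per-channel array of Poisson rates in Hz; ``spike_amplitude`` is the
    waveform peak in multiples of ``noise_sd``.
    """

    n_channels: int = 60
    duration: float = 300.0
    sampling_rate: float = 50_000.0
    noise_sd: float = 1.0
    spike_rate: float | np.ndarray = 1.0
    spike_amplitude: float = 8.0
    spike_waveform_width_ms: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if np.any(np.asarray(self.spike_rate) < 0):
            raise ConfigError("spike rates must be non-negative")
        width = int(round(self.spike_waveform_width_ms * 1e-3 * self.sampling_rate))
        if width < 8:
            raise ConfigError("sampling rate too low to resolve the spike waveform")


def spike_kernel(width_samples: int) -> np.ndarray:
    """Biphasic (negative-then-positive) 1 ms-scale waveform, peak |k| = 1.

    A Hann-windowed sine period matching extracellular spike morphology.
    """
    u = np.arange(width_samples) / width_samples
    k = -np.sin(2 * np.pi * u) * np.hanning(width_samples)
    return k / np.max(np.abs(k))


def simulate_mea_recording(
    config: MEASimConfig,
) -> tuple[MEARecording, list[np.ndarray]]:
    """Gaussian-noise channels with inserted spikes at Poisson times.

    Returns the recording and the exhaustive per-channel ground-truth spike
    times (the time of each inserted waveform's negative peak).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_samples = int(round(config.duration * fs))
    rates = np.broadcast_to(
        np.asarray(config.spike_rate, dtype=float), (config.n_channels,)
    )
    width = int(round(config.spike_waveform_width_ms * 1e-3 * fs))
    kernel = spike_kernel(width)
    peak_offset = int(np.argmin(kernel))
    voltages = rng.normal(0.0, config.noise_sd, size=(config.n_channels, n_samples))
    amplitude = config.spike_amplitude * config.noise_sd
    truth: list[np.ndarray] = []
    for ci in range(config.n_channels):
        n_spikes = rng.poisson(rates[ci] * config.duration)
        if n_spikes == 0 or n_samples <= width:
            truth.append(np.empty(0))
            continue
        starts = np.sort(rng.integers(0, n_samples - width, size=n_spikes))
        for s in starts:
            voltages[ci, s : s + width] += amplitude * kernel
        truth.append((starts + peak_offset) / fs)
    rec = MEARecording(voltages=voltages, sampling_rate=fs, slice_id="sim")
    return rec, truth


# ---------------------------------------------------------------------------
# Calcium


@dataclass
class CaSimConfig:
    """Fura-2 ratio trace simulation for one group of neurons.

    Responder transients rise linearly over the stimulus window to a peak of
    ``amplitude`` x baseline and decay exponentially.  With ``noise_sd`` and
    ``amp_cv`` zero, the trace maximum equals the configured fold exactly.
    ``kcl_responder_fraction`` defaults to the control-side viability level.
    """

    n_neurons: int = 100
    duration: float = 1000.0
    sample_interval: float = 2.0
    baseline_level: float = 0.8
    noise_sd: float = 0.01
    caps_onset: float = 200.0
    caps_window: float = 20.0
    caps_amplitude: float = 1.5
    caps_decay_tau: float = 60.0
    kcl_onset: float = 780.0
    kcl_window: float = 45.0
    kcl_amplitude: float = 2.0
    kcl_decay_tau: float = 40.0
    responder_fraction: float = 0.45
    kcl_responder_fraction: float = 0.902
    amp_cv: float = 0.0
    group: str = ""
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 1:
            raise ConfigError("n_neurons must be >= 1")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise ConfigError("duration and sample_interval must be positive")
        if self.baseline_level <= 0:
            raise ConfigError("baseline_level must be positive")
        if not self.caps_onset < self.kcl_onset:
            raise ConfigError("capsaicin onset must precede KCl onset")
        if self.caps_onset + self.caps_window > self.kcl_onset:
            raise ConfigError("stimulus windows overlap")
        for frac in (self.responder_fraction, self.kcl_responder_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("responder fractions must lie in [0, 1]")


def _transient(times: np.ndarray, onset: float, window: float, tau: float) -> np.ndarray:
    """Rise-decay kernel: linear rise to 1 over the stimulus window, then
    exponential decay with time constant tau."""
    g = np.zeros_like(times)
    rising = (times >= onset) & (times <= onset + window)
    g[rising] = (times[rising] - onset) / window
    after = times > onset + window
    g[after] = np.exp(-(times[after] - onset - window) / tau)
    return g


def simulate_calcium_traces(
    config: CaSimConfig,
) -> tuple[list[CalciumTrace], pd.DataFrame]:
    """Baseline + noise traces with responder transients; truth returned.

    Truth lists, per neuron, the responder flags and the realized amplitude
    folds for both stimuli.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.duration + 1e-9, config.sample_interval)
    g_caps = _transient(times, config.caps_onset, config.caps_window, config.caps_decay_tau)
    g_kcl = _transient(times, config.kcl_onset, config.kcl_window, config.kcl_decay_tau)
    caps_resp = rng.random(config.n_neurons) < config.responder_fraction
    kcl_resp = rng.random(config.n_neurons) < config.kcl_responder_fraction
    traces: list[CalciumTrace] = []
    rows = []
    for i in range(config.n_neurons):
        caps_amp = config.caps_amplitude
        kcl_amp = config.kcl_amplitude
        if config.amp_cv > 0:
            caps_amp = 1.0 + (caps_amp - 1.0) * rng.lognormal(0.0, config.amp_cv)
            kcl_amp = 1.0 + (kcl_amp - 1.0) * rng.lognormal(0.0, config.amp_cv)
        fold = np.ones_like(times)
        if caps_resp[i]:
            fold = fold + (caps_amp - 1.0) * g_caps
        if kcl_resp[i]:
            fold = fold + (kcl_amp - 1.0) * g_kcl
        ratios = config.baseline_level * fold
        if config.noise_sd > 0:
            ratios = ratios + rng.normal(0.0, config.noise_sd, size=times.size)
        nid = f"{config.group or 'n'}_{i:04d}"
        traces.append(
            CalciumTrace(times=times.copy(), ratios=ratios, neuron_id=nid, group=config.group)
        )
        rows.append(
            {
                "neuron_id": nid,
                "group": config.group,
                "caps_responder": bool(caps_resp[i]),
                "caps_amplitude": caps_amp if caps_resp[i] else np.nan,
                "kcl_responder": bool(kcl_resp[i]),
                "kcl_amplitude": kcl_amp if kcl_resp[i] else np.nan,
            }
        )
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IntelliCage


@dataclass
class GroupBehavior:
    """Per-genotype behavioral parameters of the visit-stream generator."""

    stay_probability: float = 0.25
    np_per_visit_mean: float = 2.0
    np_dispersion: float = 4.0
    licks_per_visit_mean: float = 25.0
    lick_duration_s: float = 0.12  # duration of a single lick

    def validate(self) -> None:
        if not 0.0 <= self.stay_probability <= 1.0:
            raise ConfigError("stay_probability must lie in [0, 1]")
        for v in (self.np_per_visit_mean, self.licks_per_visit_mean, self.lick_duration_s):
            if v < 0:
                raise ConfigError("behavioral rates must be non-negative")
        if self.np_dispersion <= 0:
            raise ConfigError("np_dispersion must be positive")


def _default_groups() -> dict[str, GroupBehavior]:
    # control ~ ChR2-flfl, elp ~ Avil-ChR2: higher NP/visit, doubled licking,
    # elevated corner-return tendency.
    return {
        "control": GroupBehavior(),
        "elp": GroupBehavior(
            stay_probability=0.40, np_per_visit_mean=3.0, licks_per_visit_mean=50.0
        ),
    }


@dataclass
class ICSimConfig:
    """IntelliCage experiment simulation.

    Corner choice follows a Markov chain with P(same corner) =
    ``stay_probability`` and a uniform split over the other three corners;
    visit starts form an inhomogeneous Poisson process with piecewise
    day/night rates; nosepoke counts are negative-binomial (over-dispersed)
    and licks Poisson, gated by the task's door rule.  The default schedule
    is the study sequence: 2 weeks FA, 2 weeks NP3c, 10 days PPL, 10 days
    PPLrev, with 15 control and 16 ELP females.
    """

    n_animals_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 15, "elp": 16}
    )
    groups: dict[str, GroupBehavior] = field(default_factory=_default_groups)
    visit_rate_day: float = 2.0  # visits/h in the light phase
    visit_rate_night: float = 6.0
    mean_visit_duration_s: float = 25.0
    learning_enabled: bool = True
    learning_max: float = 0.8
    learning_midpoint_days: float = 3.0
    learning_rate_days: float = 1.0
    task_schedule: tuple[tuple[str, int], ...] = (
        ("FA", 14),
        ("NP3c", 14),
        ("PPL", 10),
        ("PPLrev", 10),
    )
    lights_on_hour: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.task_schedule:
            raise ConfigError("task_schedule must not be empty")
        for task, days in self.task_schedule:
            if days <= 0:
                raise ConfigError(f"task {task!r} has non-positive duration")
        if self.visit_rate_day < 0 or self.visit_rate_night < 0:
            raise ConfigError("visit rates must be non-negative")
        if self.mean_visit_duration_s <= 0:
            raise ConfigError("mean_visit_duration_s must be positive")
        if not self.n_animals_per_group:
            raise ConfigError("need at least one group")
        for name in self.n_animals_per_group:
            if name not in self.groups:
                raise ConfigError(f"no GroupBehavior for group {name!r}")
        for g in self.groups.values():
            g.validate()


def _build_schedule(config: ICSimConfig, animal_ids: list[str]) -> TaskSchedule:
    rows = []
    t = 0.0
    for task, days in config.task_schedule:
        rows.append({"task": task, "start_s": t, "end_s": t + days * SECONDS_PER_DAY})
        t += days * SECONDS_PER_DAY
    # each chunk of 4 mice shares a PPL corner
    ppl = {aid: (i // 4) % 4 + 1 for i, aid in enumerate(animal_ids)}
    return TaskSchedule(
        segments=pd.DataFrame(rows),
        ppl_corner=ppl,
        lights_on_s=config.lights_on_hour * SECONDS_PER_HOUR,
    )


def _visit_starts(
    rng: np.random.Generator, config: ICSimConfig, total_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Thinned inhomogeneous Poisson visit starts plus non-overlapping ends."""
    rate_day = config.visit_rate_day / SECONDS_PER_HOUR
    rate_night = config.visit_rate_night / SECONDS_PER_HOUR
    rmax = max(rate_day, rate_night)
    if rmax == 0:
        return np.empty(0), np.empty(0)
    n_cand = rng.poisson(rmax * total_s)
    cand = np.sort(rng.uniform(0.0, total_s, size=n_cand))
    hours = (cand / SECONDS_PER_HOUR - config.lights_on_hour) % 24.0
    rate = np.where(hours < 12.0, rate_day, rate_night)
    keep = rng.random(n_cand) < rate / rmax
    cand = cand[keep]
    durations = np.maximum(rng.exponential(config.mean_visit_duration_s, cand.size), 1.0)
    starts, ends = [], []
    prev_end = -np.inf
    for s, d in zip(cand, durations):
        if s < prev_end:
            continue  # corner still occupied by the previous visit
        e = min(s + d, total_s)
        if e <= s:
            continue
        starts.append(s)
        ends.append(e)
        prev_end = e
    return np.asarray(starts), np.asarray(ends)


def _corner_sequence(
    rng: np.random.Generator,
    n: int,
    stay_probability: float,
    learn_p: np.ndarray,
    correct_sets: list[tuple[int, ...]],
) -> np.ndarray:
    """Markov corner chain with an optional learned-correct-corner override.

    With probability ``learn_p[i]`` visit i goes to a uniformly drawn member
    of ``correct_sets[i]``; otherwise the Markov step applies (stay with the
    configured probability, else uniform over the other three corners).
    """
    u_stay = rng.random(n)
    moves = rng.integers(1, 4, size=n)  # offset among the other 3 corners
    u_learn = rng.random(n)
    pick = rng.random(n)
    corners = np.empty(n, dtype=np.int64)
    prev = int(rng.integers(1, 5))
    for i in range(n):
        cs = correct_sets[i]
        if cs and u_learn[i] < learn_p[i]:
            corners[i] = cs[int(pick[i] * len(cs))]
        elif u_stay[i] < stay_probability:
            corners[i] = prev
        else:
            corners[i] = (prev - 1 + moves[i]) % 4 + 1
        prev = int(corners[i])
    return corners


def simulate_intellicage(
    config: ICSimConfig,
) -> tuple[pd.DataFrame, TaskSchedule, dict]:
    """Generate the visit stream, the task schedule and the ground truth.

    Truth records the generating per-group behavioral parameters and each
    animal's PPL corner assignment.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    animal_ids = [
        f"{gname}_{i:02d}"
        for gname, n in config.n_animals_per_group.items()
        for i in range(n)
    ]
    schedule = _build_schedule(config, animal_ids)
    total_s = schedule.end_s
    seg_starts = schedule.segments["start_s"].to_numpy()
    seg_tasks = list(schedule.segments["task"])
    frames = []
    for aid in animal_ids:
        gname = aid.rsplit("_", 1)[0]
        beh = config.groups[gname]
        starts, ends = _visit_starts(rng, config, total_s)
        n = starts.size
        if n == 0:
            continue
        seg_idx = np.clip(np.searchsorted(seg_starts, starts, side="right") - 1, 0, len(seg_tasks) - 1)
        tasks = [seg_tasks[k] for k in seg_idx]
        correct_sets = [tuple(sorted(schedule.correct_corners(aid, t))) for t in tasks]
        if config.learning_enabled:
            day_in_task = (starts - seg_starts[seg_idx]) / SECONDS_PER_DAY
            learn_p = config.learning_max / (
                1.0
                + np.exp(
                    -(day_in_task - config.learning_midpoint_days)
                    / config.learning_rate_days
                )
            )
            learn_p = np.where([bool(cs) for cs in correct_sets], learn_p, 0.0)
        else:
            learn_p = np.zeros(n)
        corners = _corner_sequence(rng, n, beh.stay_probability, learn_p, correct_sets)
        m = beh.np_per_visit_mean
        k = beh.np_dispersion
        if m > 0:
            np_counts = rng.negative_binomial(k, k / (k + m), size=n)
        else:
            np_counts = np.zeros(n, dtype=np.int64)
        in_correct = np.array(
            [c in cs if cs else True for c, cs in zip(corners, correct_sets)]
        )
        task_arr = np.asarray(tasks)
        door = np.where(
            task_arr == "FA",
            True,
            np.where(
                task_arr == "NP3c",
                np_counts >= 1,
                (np_counts >= 1) & in_correct,
            ),
        )
        licks = np.where(door, rng.poisson(beh.licks_per_visit_mean, size=n), 0)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": aid,
                    "group": gname,
                    "corner": corners,
                    "start_s": starts,
                    "end_s": ends,
                    "task": tasks,
                    "np_count": np_counts,
                    "np_correct_count": np.where(in_correct, np_counts, 0),
                    "door_opened": door,
                    "lick_count": licks,
                    "lick_duration_s": licks * beh.lick_duration_s,
                }
            )
        )
    visits = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
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
        )
    )
    truth = {
        "groups": {name: asdict(g) for name, g in config.groups.items()},
        "ppl_corner": dict(schedule.ppl_corner),
        "visit_rate_day": config.visit_rate_day,
        "visit_rate_night": config.visit_rate_night,
    }
    return visits, schedule, truth


# ---------------------------------------------------------------------------
# Lipids


_LIPID_CLASSES = ("SM", "PC", "PE", "LPC", "Cer", "PS", "PI")


def _species_names(n: int) -> list[str]:
    names = []
    i = 0
    carbons = range(32, 46, 2)
    bonds = range(0, 5)
    combos = [(c, d) for c in carbons for d in bonds]
    while len(names) < n:
        cls = _LIPID_CLASSES[i % len(_LIPID_CLASSES)]
        c, d = combos[(i // len(_LIPID_CLASSES)) % len(combos)]
        names.append(f"{cls}({c}:{d})")
        i += 1
    return names


@dataclass
class LipidSimConfig:
    """Two-group lipid feature table (AUC/IS-style area ratios).

    Log-normal intensities; ``affected_species`` (column indices) receive a
    ``log2_effect`` shift in the second (test) group.  ``cv`` is the
    coefficient of variation of the multiplicative noise.  By default a
    third of the panel carries the effect, emulating the broad co-regulation
    of a lipid class (many sphingomyelin species moving together) rather
    than an isolated marker.
    """

    n_samples_per_group: tuple[int, int] = (15, 16)
    n_species: int = 60
    affected_species: tuple[int, ...] = tuple(range(20))
    log2_effect: float = -1.0
    cv: float = 0.1
    group_labels: tuple[str, str] = ("control", "elp")
    seed: int = 0

    def validate(self) -> None:
        n = (
            self.n_samples_per_group
            if isinstance(self.n_samples_per_group, (tuple, list))
            else (self.n_samples_per_group, self.n_samples_per_group)
        )
        if min(n) < 2:
            raise ConfigError("need >= 2 samples per group for a t-test")
        if self.cv <= 0:
            raise ConfigError("cv must be positive")
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if any(not 0 <= i < self.n_species for i in self.affected_species):
            raise ConfigError("affected_species indices out of range")


def simulate_lipid_table(
    config: LipidSimConfig,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Return (intensity table, group labels, truth).

    The table is samples x species with strictly positive intensities; truth
    names the affected species and the planted log2 effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = (
        tuple(config.n_samples_per_group)
        if isinstance(config.n_samples_per_group, (tuple, list))
        else (config.n_samples_per_group, config.n_samples_per_group)
    )
    species = _species_names(config.n_species)
    base_log2 = rng.uniform(10.0, 20.0, size=config.n_species)
    sigma_log2 = math.sqrt(math.log(1.0 + config.cv**2)) / math.log(2.0)
    labels = [config.group_labels[0]] * n[0] + [config.group_labels[1]] * n[1]
    sample_ids = [
        f"{config.group_labels[0]}_{i:02d}" for i in range(n[0])
    ] + [f"{config.group_labels[1]}_{i:02d}" for i in range(n[1])]
    log2_vals = base_log2[None, :] + rng.normal(
        0.0, sigma_log2, size=(n[0] + n[1], config.n_species)
    )
    affected = np.zeros(config.n_species, dtype=bool)
    affected[list(config.affected_species)] = True
    log2_vals[n[0] :, affected] += config.log2_effect
    table = pd.DataFrame(2.0**log2_vals, index=sample_ids, columns=species)
    groups = pd.Series(labels, index=sample_ids, name="group")
    truth = {
        "affected_species": [species[i] for i in config.affected_species],
        "log2_effect": config.log2_effect,
    }
    return table, groups, truth
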