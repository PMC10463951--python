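"""Multi-unit activity (MUA) detection on multichannel extracellular recordings.

The detection chain mirrors standard online acquisition software for cortical
slice MEA chips: a causal second-order Butterworth highpass at 200 Hz, a
per-channel noise estimate, threshold crossing at a multiple (default 5x) of
the noise SD, and an activity criterion of at least 100 spikes per 5-minute
trace.  No spike sorting is attempted; every supra-threshold event counts as
multi-unit activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "MEARecording",
    "SpikeTrain",
    "ChannelSummary",
    "SliceSummary",
    "DegenerateThresholdError",
    "highpass_filter",
    "estimate_noise_sd",
    "detect_spikes",
    "classify_channel_activity",
    "mua_frequency",
    "summarize_slice",
    "rows_to_channels",
    "match_spike_trains",
]

#: MAD -> SD conversion for Gaussian noise (Phi^-1(0.75)).
MAD_SCALE = 0.6745


class DegenerateThresholdError(ValueError):
    """Raised when the noise estimate is zero and a threshold cannot be formed."""


@dataclass
class MEARecording:
    """Multichannel voltage matrix with acquisition metadata.

    ``voltages`` has shape (n_channels, n_samples); units are whatever the
    acquisition system delivered (volts-equivalent) — the pipeline is scale
    invariant because thresholds are multiples of the per-channel noise SD.
    """

    voltages: np.ndarray
    sampling_rate: float
    channel_ids: list[str] = field(default_factory=list)
    slice_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.voltages = np.atleast_2d(np.asarray(self.voltages))
        if self.voltages.shape[0] < 1:
            raise ValueError("recording needs at least one channel")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_ids) != self.n_channels:
            raise ValueError("channel_ids length must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class SpikeTrain:
    """Detected event times for one channel."""

    channel_id: str
    spike_times: np.ndarray
    threshold_used: float
    noise_sd: float

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class ChannelSummary:
    channel_id: str
    spike_count: int
    active: bool
    mua_hz: float
    noise_sd: float


@dataclass
class SliceSummary:
    slice_id: str
    group: str
    channels: list[ChannelSummary]

    @property
    def active_count(self) -> int:
        return sum(c.active for c in self.channels)

    @property
    def active_mua_hz(self) -> np.ndarray:
        """MUA frequencies of active channels only (the Fig.-style readout)."""
        return np.array([c.mua_hz for c in self.channels if c.active])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": [c.channel_id for c in self.channels],
                "spike_count": [c.spike_count for c in self.channels],
                "active": [c.active for c in self.channels],
                "mua_hz": [c.mua_hz for c in self.channels],
                "noise_sd": [c.noise_sd for c in self.channels],
            }
        )


def highpass_filter(
    trace: np.ndarray,
    sampling_rate: float,
    cutoff: float = 200.0,
    order: int = 2,
    zero_phase: bool = False,
) -> np.ndarray:
    """Butterworth highpass, causal by default (matching online acquisition).

    Parameters
    ----------
    trace : 1-d sample series.
    cutoff : -3 dB corner frequency in Hz; must be below Nyquist.
    zero_phase : apply forward-backward (filtfilt) filtering instead of the
        causal single pass.
    """
    trace = np.asarray(trace, dtype=float)
    nyquist = sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyquist} Hz), got {cutoff}")
    sos = signal.butter(order, cutoff, btype="highpass", fs=sampling_rate, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, trace)
    return signal.sosfilt(sos, trace)


def estimate_noise_sd(filtered: np.ndarray) -> float:
    """Robust noise SD via the median absolute deviation, MAD/0.6745.

    The median is essentially unaffected by the sparse large-amplitude spike
    samples that inflate the plain standard deviation, so thresholds track
    the noise floor rather than the firing rate.
    """
    filtered = np.asarray(filtered)
    return float(np.median(np.abs(filtered)) / MAD_SCALE)


def detect_spikes(
    filtered: np.ndarray,
    sampling_rate: float,
    threshold_multiple: float = 5.0,
    dead_time: float = 0.001,
    noise_sd: float | None = None,
    channel_id: str = "",
) -> SpikeTrain:
    """Both-polarity threshold crossing with a refractory dead time.

    An event is registered wherever ``|x| > threshold_multiple * noise_sd``;
    crossings closer than ``dead_time`` are merged (multiphasic waveforms
    count once) and the event time is the local extremum of the excursion.
    """
    if threshold_multiple <= 0:
        raise ValueError("threshold_multiple must be positive")
    filtered = np.asarray(filtered, dtype=float)
    if noise_sd is None:
        noise_sd = estimate_noise_sd(filtered)
    if noise_sd <= 0:
        raise DegenerateThresholdError(
            "noise SD estimate is zero; threshold would be degenerate"
        )
    threshold = threshold_multiple * noise_sd
    absx = np.abs(filtered)
    idx = np.flatnonzero(absx > threshold)
    if idx.size == 0:
        return SpikeTrain(channel_id, np.empty(0), threshold, noise_sd)
    dead_samples = max(int(round(dead_time * sampling_rate)), 1)
    breaks = np.flatnonzero(np.diff(idx) > dead_samples)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, idx.size - 1]
    peaks = np.empty(starts.size, dtype=np.int64)
    for k, (s, e) in enumerate(zip(starts, ends)):
        seg = idx[s] + np.argmax(absx[idx[s] : idx[e] + 1])
        peaks[k] = seg
    times = peaks / sampling_rate
    return SpikeTrain(channel_id, times, threshold, noise_sd)


def classify_channel_activity(
    spike_count: int,
    duration: float,
    min_spikes: int = 100,
    reference_duration: float = 300.0,
) -> bool:
    """Active iff the count reaches 100 spikes per 5 min (pro-rated).

    The boundary follows the "less than 100 is inactive" rule: exactly 100
    spikes in 300 s is active.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if spike_count < 0:
        raise ValueError("spike_count must be non-negative")
    return spike_count >= min_spikes * (duration / reference_duration)


def mua_frequency(spike_train: SpikeTrain | int, duration: float) -> float:
    """Event count divided by trace duration, in Hz."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    count = spike_train.n_spikes if isinstance(spike_train, SpikeTrain) else int(spike_train)
    return count / duration


def rows_to_channels(layout: tuple[int, int], rows: list[int]) -> list[int]:
    """Channel indices for electrode rows of a row-major grid layout.

    ``layout`` is (n_rows, n_cols); ``rows`` are 1-based row numbers, so the
    somatosensory-layer selection "rows 2 and 3" of a 6x10 chip maps to
    channel indices 10..29.
    """
    n_rows, n_cols = layout
    out: list[int] = []
    for r in rows:
        if not 1 <= r <= n_rows:
            raise ValueError(f"row {r} outside layout with {n_rows} rows")
        out.extend(range((r - 1) * n_cols, r * n_cols))
    return out


def summarize_slice(
    recording: MEARecording,
    threshold_multiple: float = 5.0,
    cutoff: float = 200.0,
    order: int = 2,
    dead_time: float = 0.001,
    min_spikes: int = 100,
    reference_duration: float = 300.0,
    channels: list[int] | None = None,
    zero_phase: bool = False,
) -> SliceSummary:
    """Full per-slice chain: filter -> noise -> detect -> classify per channel.

    ``channels`` optionally restricts analysis to a subset of channel indices
    (e.g. the electrode rows facing the cortical layers of interest).
    """
    if channels is None:
        channels = list(range(recording.n_channels))
    duration = recording.duration
    summaries: list[ChannelSummary] = []
    for ci in channels:
        filtered = highpass_filter(
            recording.voltages[ci], recording.sampling_rate, cutoff, order, zero_phase
        )
        noise = estimate_noise_sd(filtered)
        if noise <= 0:
            # Degenerate channel (flat trace): report as silent, flagged by noise 0.
            summaries.append(
                ChannelSummary(recording.channel_ids[ci], 0, False, 0.0, 0.0)
            )
            continue
        train = detect_spikes(
            filtered,
            recording.sampling_rate,
            threshold_multiple,
            dead_time,
            noise_sd=noise,
            channel_id=recording.channel_ids[ci],
        )
        active = classify_channel_activity(
            train.n_spikes, duration, min_spikes, reference_duration
        )
        summaries.append(
            ChannelSummary(
                recording.channel_ids[ci],
                train.n_spikes,
                active,
                mua_frequency(train, duration),
                noise,
            )
        )
    return SliceSummary(recording.slice_id, recording.group, summaries)


def match_spike_trains(
    true_times: np.ndarray,
    detected_times: np.ndarray,
    tolerance: float = 0.0015,
) -> tuple[int, float, float]:
    """Greedy one-to-one matching of detected to ground-truth events.

    Returns (n_matched, recall, precision).  Used to score detection against
    simulator truth; each true event can absorb at most one detection within
    ``tolerance`` seconds.
    """
    true_times = np.sort(np.asarray(true_times, dtype=float))
    detected_times = np.sort(np.asarray(detected_times, dtype=float))
    i = j = matched = 0
    while i < true_times.size and j < detected_times.size:
        dt = detected_times[j] - true_times[i]
        if abs(dt) <= tolerance:
            matched += 1
            i += 1
            j += 1
        elif dt < 0:
            j += 1
        else:
            i += 1
    recall = matched / true_times.size if true_times.size else 1.0
    precision = matched / detected_times.size if detected_times.size else 1.0
    return matched, recall, precision
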