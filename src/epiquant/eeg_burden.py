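"""Seizure-burden evaluation for single-channel rodent EEG.

The detection rules implemented here are the ones used for chronic
kainic-acid temporal-lobe-epilepsy monitoring:

* the raw trace is high-pass filtered at 0.5 Hz;
* a 10-min seizure-free stretch provides the baseline amplitude level;
* a seizure is a stretch whose amplitude exceeds twice the baseline for
  more than 15 s;
* a spike is a transient of 200-5000 uV lasting 5-70 ms;
* a spike train is a run of three or more spikes with inter-onset
  intervals of 50 ms to 1 s spanning less than 5 s in total.

"Amplitude" is operationalised as a centred 1-s max-|x| envelope and the
baseline level as the median of per-second peak amplitudes; both choices
are robust to isolated artifacts and are configurable via
:class:`DetectorParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import maximum_filter1d

__all__ = [
    "EegRecording",
    "DetectorParams",
    "BaselineEstimate",
    "SpikeEvent",
    "SpikeTrain",
    "SeizureEvent",
    "BurdenSummary",
    "EventSet",
    "highpass_filter",
    "amplitude_envelope",
    "estimate_baseline",
    "detect_seizures",
    "detect_spikes",
    "group_spike_trains",
    "summarize_burden",
    "evaluate_detection",
    "analyze_recording",
]


@dataclass
class EegRecording:
    """A uniformly sampled single-channel voltage trace in microvolts."""

    samples: np.ndarray
    fs_hz: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    def time_axis(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass(frozen=True)
class DetectorParams:
    """Detection thresholds; defaults are the published protocol values.

    ``envelope_window_s`` and ``seizure_merge_gap_s`` parameterise the
    amplitude-envelope operationalisation and are package choices rather
    than protocol constants.
    """

    highpass_hz: float = 0.5
    baseline_window_s: float = 600.0
    baseline_multiplier: float = 2.0
    seizure_min_s: float = 15.0
    spike_min_uV: float = 200.0
    spike_max_uV: float = 5000.0
    spike_min_ms: float = 5.0
    spike_max_ms: float = 70.0
    train_min_spikes: int = 3
    train_max_total_s: float = 5.0
    train_min_interval_s: float = 0.05
    train_max_interval_s: float = 1.0
    envelope_window_s: float = 1.0
    seizure_merge_gap_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.spike_min_uV < self.spike_max_uV):
            raise ValueError("require 0 < spike_min_uV < spike_max_uV")
        if not (0 < self.spike_min_ms < self.spike_max_ms):
            raise ValueError("require 0 < spike_min_ms < spike_max_ms")
        if not (self.train_min_interval_s < self.train_max_interval_s):
            raise ValueError("require train_min_interval_s < train_max_interval_s")


@dataclass(frozen=True)
class BaselineEstimate:
    amplitude_uV: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.amplitude_uV <= 0:
            raise ValueError("baseline amplitude must be positive")


@dataclass
class SpikeEvent:
    onset_s: float
    offset_s: float
    peak_uV: float
    in_seizure: bool = False

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SpikeTrain:
    spikes: list[SpikeEvent]

    @property
    def onset_s(self) -> float:
        return self.spikes[0].onset_s

    @property
    def total_duration_s(self) -> float:
        return self.spikes[-1].offset_s - self.spikes[0].onset_s

    @property
    def n_spikes(self) -> int:
        return len(self.spikes)


@dataclass
class SeizureEvent:
    onset_s: float
    duration_s: float

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class BurdenSummary:
    n_spikes: int
    n_spike_trains: int
    n_seizures: int
    total_seizure_s: float
    mean_seizure_s: float
    total_time_s: float

    def as_dict(self) -> dict:
        return {
            "n_spikes": self.n_spikes,
            "n_spike_trains": self.n_spike_trains,
            "n_seizures": self.n_seizures,
            "total_seizure_s": self.total_seizure_s,
            "mean_seizure_s": self.mean_seizure_s,
            "total_time_s": self.total_time_s,
        }


@dataclass
class EventSet:
    """Detected or injected events; the common currency of the pipeline."""

    spikes: list[SpikeEvent] = field(default_factory=list)
    trains: list[SpikeTrain] = field(default_factory=list)
    seizures: list[SeizureEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# preprocessing


def highpass_filter(rec: EegRecording, cutoff_hz: float = 0.5) -> EegRecording:
    """Zero-phase 4th-order Butterworth high-pass; removes DC, keeps length.

    Applied forward-backward (``filtfilt``) so event onsets are not delayed.
    """
    nyquist = rec.fs_hz / 2.0
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff_hz={cutoff_hz} must be below Nyquist ({nyquist} Hz)")
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=rec.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=filtered)


def amplitude_envelope(rec: EegRecording, window_s: float = 1.0) -> np.ndarray:
    """Centred moving max of |x|; edges use truncated windows.

    This is the "amplitude level" statistic the seizure screen thresholds.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    size = int(round(window_s * rec.fs_hz))
    size += 1 - size % 2  # odd size -> exactly centred window
    absx = np.abs(rec.samples)
    # cval=0 with non-negative input is equivalent to truncating the window
    return maximum_filter1d(absx, size=size, mode="constant", cval=0.0)


def estimate_baseline(
    rec: EegRecording,
    window: tuple[float, float],
    truth_seizures: Sequence[SeizureEvent] | None = None,
) -> BaselineEstimate:
    """Baseline amplitude = median over non-overlapping 1-s windows of max|x|.

    Expects the preprocessed (high-pass filtered) trace. When
    ``truth_seizures`` is supplied the window is checked to be seizure-free.
    """
    start_s, end_s = window
    if start_s < 0 or end_s > rec.duration_s + 1e-9 or end_s - start_s < 1.0:
        raise ValueError("baseline window must lie within the recording and span >= 1 s")
    if truth_seizures is not None:
        for sz in truth_seizures:
            if sz.onset_s < end_s and sz.offset_s > start_s:
                raise ValueError("baseline not seizure-free")
    i0 = int(round(start_s * rec.fs_hz))
    i1 = int(round(end_s * rec.fs_hz))
    seg = np.abs(rec.samples[i0:i1])
    per_sec = int(round(rec.fs_hz))
    n_sub = seg.size // per_sec
    peaks = seg[: n_sub * per_sec].reshape(n_sub, per_sec).max(axis=1)
    return BaselineEstimate(amplitude_uV=float(np.median(peaks)), window=(start_s, end_s))


# ---------------------------------------------------------------------------
# run-length helpers


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2], edges[1::2]))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Merge runs separated by gaps strictly shorter than ``max_gap`` samples."""
    if not runs:
        return []
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < max_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return [(a, b) for a, b in merged]


# ---------------------------------------------------------------------------
# detectors


def detect_seizures(
    rec: EegRecording,
    baseline: BaselineEstimate,
    params: DetectorParams = DetectorParams(),
) -> list[SeizureEvent]:
    """Screen for seizures: envelope above ``baseline_multiplier`` x baseline
    lasting strictly more than ``seizure_min_s``.

    Candidate regions come from the amplitude envelope (gaps shorter than
    ``seizure_merge_gap_s`` merged); each region's onset/offset is then
    refined to the first/last raw |x| threshold crossing so that the
    reported onset is not padded by the envelope window.
    """
    if baseline.amplitude_uV <= 0:
        raise ValueError("baseline amplitude must be positive")
    threshold = params.baseline_multiplier * baseline.amplitude_uV
    env = amplitude_envelope(rec, params.envelope_window_s)
    runs = _runs(env > threshold)
    runs = _merge_runs(runs, int(round(params.seizure_merge_gap_s * rec.fs_hz)))

    absx = np.abs(rec.samples)
    half = int(round(params.envelope_window_s * rec.fs_hz)) // 2
    events: list[SeizureEvent] = []
    for start, stop in runs:
        lo = max(0, start - half)
        hi = min(absx.size, stop + half)
        above = np.flatnonzero(absx[lo:hi] > threshold)
        if above.size == 0:  # pragma: no cover - envelope guarantees a crossing
            continue
        first = lo + above[0]
        last = lo + above[-1]
        duration = (last - first + 1) / rec.fs_hz
        if duration > params.seizure_min_s:
            events.append(SeizureEvent(onset_s=first / rec.fs_hz, duration_s=duration))
    # refinement can in principle make neighbours touch; keep them disjoint
    out: list[SeizureEvent] = []
    for ev in sorted(events, key=lambda e: e.onset_s):
        if out and ev.onset_s < out[-1].offset_s:
            merged_end = max(out[-1].offset_s, ev.offset_s)
            out[-1] = SeizureEvent(out[-1].onset_s, merged_end - out[-1].onset_s)
        else:
            out.append(ev)
    return out


def detect_spikes(
    rec: EegRecording,
    params: DetectorParams = DetectorParams(),
    seizures: Sequence[SeizureEvent] | None = None,
) -> list[SpikeEvent]:
    """Detect interictal spikes as maximal runs of |x| >= ``spike_min_uV``.

    Sub-threshold gaps shorter than ``spike_min_ms`` are merged first (a
    biphasic discharge crosses the threshold twice); an event is kept iff
    its duration lies in [spike_min_ms, spike_max_ms] and its peak does not
    exceed ``spike_max_uV`` (artifact rejection). Events whose onset falls
    inside a supplied seizure interval are flagged ``in_seizure``.
    """
    absx = np.abs(rec.samples)
    runs = _runs(absx >= params.spike_min_uV)
    runs = _merge_runs(runs, int(round(params.spike_min_ms / 1000.0 * rec.fs_hz)))
    events: list[SpikeEvent] = []
    for start, stop in runs:
        duration_ms = (stop - start) / rec.fs_hz * 1000.0
        if not (params.spike_min_ms <= duration_ms <= params.spike_max_ms):
            continue
        peak = float(absx[start:stop].max())
        if peak > params.spike_max_uV:
            continue
        signed_peak = float(rec.samples[start + int(np.argmax(absx[start:stop]))])
        events.append(
            SpikeEvent(onset_s=start / rec.fs_hz, offset_s=stop / rec.fs_hz, peak_uV=signed_peak)
        )
    if seizures:
        for ev in events:
            ev.in_seizure = any(
                sz.onset_s <= ev.onset_s < sz.offset_s for sz in seizures
            )
    return events


def group_spike_trains(
    spikes: Sequence[SpikeEvent],
    params: DetectorParams = DetectorParams(),
    exclude_in_seizure: bool = True,
) -> list[SpikeTrain]:
    """Greedy left-to-right grouping of spikes into trains.

    A run is extended while the inter-onset interval to the next spike lies
    in [train_min_interval_s, train_max_interval_s] and the extended span
    (last offset minus first onset) would stay below ``train_max_total_s``;
    runs of at least ``train_min_spikes`` members become trains (longest
    valid prefix rule). Each spike belongs to at most one train.
    """
    onsets = [s.onset_s for s in spikes]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("spikes must be sorted by onset")
    pool = [s for s in spikes if not (exclude_in_seizure and s.in_seizure)]
    trains: list[SpikeTrain] = []
    i = 0
    while i < len(pool):
        j = i
        while j + 1 < len(pool):
            gap = pool[j + 1].onset_s - pool[j].onset_s
            if not (params.train_min_interval_s <= gap <= params.train_max_interval_s):
                break
            if pool[j + 1].offset_s - pool[i].onset_s >= params.train_max_total_s:
                break
            j += 1
        if j - i + 1 >= params.train_min_spikes:
            trains.append(SpikeTrain(spikes=list(pool[i : j + 1])))
        i = j + 1
    return trains


def summarize_burden(
    spikes: Sequence[SpikeEvent],
    trains: Sequence[SpikeTrain],
    seizures: Sequence[SeizureEvent],
    total_time_s: float,
) -> BurdenSummary:
    """Aggregate counts and seizure-duration totals over a recording."""
    if total_time_s <= 0:
        raise ValueError("total_time_s must be positive")
    total = float(sum(sz.duration_s for sz in seizures))
    n_sz = len(seizures)
    return BurdenSummary(
        n_spikes=len(spikes),
        n_spike_trains=len(trains),
        n_seizures=n_sz,
        total_seizure_s=total,
        mean_seizure_s=total / n_sz if n_sz else 0.0,
        total_time_s=total_time_s,
    )


def evaluate_detection(
    predicted: EventSet, truth: EventSet, tol_s: float = 0.05
) -> pd.DataFrame:
    """Precision/recall/F1 per event class by greedy one-to-one onset matching."""
    if tol_s < 0:
        raise ValueError("tol_s must be non-negative")

    def _match(pred_onsets: list[float], true_onsets: list[float]) -> int:
        pred = sorted(pred_onsets)
        used = [False] * len(pred)
        tp = 0
        for t in sorted(true_onsets):
            best, best_d = -1, tol_s
            for k, p in enumerate(pred):
                if used[k]:
                    continue
                d = abs(p - t)
                if d <= best_d:
                    best, best_d = k, d
            if best >= 0:
                used[best] = True
                tp += 1
        return tp

    rows = []
    for cls, pred, true in [
        ("spike", predicted.spikes, truth.spikes),
        ("train", predicted.trains, truth.trains),
        ("seizure", predicted.seizures, truth.seizures),
    ]:
        tp = _match([e.onset_s for e in pred], [e.onset_s for e in true])
        n_pred, n_true = len(pred), len(true)
        precision = tp / n_pred if n_pred else (1.0 if n_true == 0 else 0.0)
        recall = tp / n_true if n_true else 1.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        rows.append(
            {
                "event_class": cls,
                "n_true": n_true,
                "n_predicted": n_pred,
                "tp": tp,
                "precision": precision,
                "recall": recall,
                "f1": f1,
            }
        )
    return pd.DataFrame(rows).set_index("event_class")


def analyze_recording(
    rec: EegRecording,
    baseline_window: tuple[float, float],
    params: DetectorParams = DetectorParams(),
) -> tuple[EventSet, BurdenSummary, BaselineEstimate]:
    """Full pipeline: filter, baseline, seizures, spikes, trains, summary."""
    filtered = highpass_filter(rec, params.highpass_hz)
    baseline = estimate_baseline(filtered, baseline_window)
    seizures = detect_seizures(filtered, baseline, params)
    spikes = detect_spikes(filtered, params, seizures=seizures)
    trains = group_spike_trains(spikes, params)
    events = EventSet(spikes=spikes, trains=trains, seizures=seizures)
    summary = summarize_burden(spikes, trains, seizures, rec.duration_s)
    return events, summary, baseline
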