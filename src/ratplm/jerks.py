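"""Limb-EMG jerk detection.

A phasic motor event ("jerk") is scored when the EMG envelope exceeds
``amplitude_factor`` (default 2) times the local tonic background, for a
duration between 0.2 and 5 s. The envelope is full-wave rectification
followed by a short moving RMS; the tonic background is a 20-s running
median of the envelope with one outlier-excluding refinement pass, so that
the jerks themselves do not inflate their own background.

Because the threshold is purely relative, detection is invariant to scaling
the raw trace by any positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d

from .errors import ValidationError
from .signal_io import SignalTrace

#: stride (s) of the reduced series on which the running median is evaluated
_BASELINE_STRIDE_S = 0.1


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detection parameters (all durations in seconds)."""

    amplitude_factor: float = 2.0
    min_duration: float = 0.2
    max_duration: float = 5.0
    envelope_smoothing: float = 0.05
    baseline_window: float = 20.0
    merge_gap: float = 0.2
    bilateral_window: float = 0.5

    def __post_init__(self):
        if not (0 < self.min_duration < self.max_duration):
            raise ValidationError("need 0 < min_duration < max_duration")
        if self.amplitude_factor <= 1:
            raise ValidationError("amplitude_factor must exceed 1")
        for name in ("envelope_smoothing", "baseline_window", "merge_gap",
                     "bilateral_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class MotorEvent:
    """One detected limb jerk (times in seconds from recording start)."""

    limb: str
    onset: float
    offset: float
    peak_amplitude: float
    baseline: float
    stage: str | None = None

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def envelope(trace: SignalTrace, smoothing: float = 0.05) -> SignalTrace:
    """Full-wave rectification followed by a moving RMS of width `smoothing`."""
    n_win = int(round(smoothing * trace.sampling_rate))
    if n_win < 2:
        raise ValidationError("envelope smoothing shorter than 2 samples")
    sq = np.asarray(trace.samples, dtype=np.float64) ** 2
    env = np.sqrt(np.clip(uniform_filter1d(sq, size=n_win, mode="nearest"), 0, None))
    return SignalTrace(trace.label, trace.sampling_rate, env,
                       start_time=trace.start_time, zt0_offset=trace.zt0_offset)


def _reduce_blocks(x: np.ndarray, block: int) -> np.ndarray:
    """Per-block RMS reduction (tail block padded by edge values)."""
    n = x.size
    n_blocks = -(-n // block)
    pad = n_blocks * block - n
    if pad:
        x = np.concatenate([x, np.full(pad, x[-1])])
    return np.sqrt(np.mean(x.reshape(n_blocks, block) ** 2, axis=1))


def tonic_baseline(env: SignalTrace, baseline_window: float = 20.0,
                   amplitude_factor: float = 2.0) -> SignalTrace:
    """Robust per-sample tonic background of an envelope.

    Running medians over a centered ``baseline_window`` (and over a quarter
    of it — see below), computed on a 0.1-s block-RMS reduction of the
    envelope and linearly interpolated back to full resolution, followed by
    one refinement pass in which blocks already exceeding
    ``amplitude_factor`` times the first-pass baseline are replaced by that
    baseline before re-medianing.

    The background is the elementwise maximum of the full-window median
    and the quarter-window median: after an abrupt rise of the tonic level
    (e.g. at a sleep-to-wake transition) the long median lags by several
    seconds, and a jerk threshold referenced to it alone would briefly sit
    inside the new tonic noise. The short median tracks the rise, while
    both remain robust to jerks, which occupy well under half of either
    window.
    """
    if baseline_window > env.duration:
        raise ValidationError("baseline_window longer than the trace")
    fs = env.sampling_rate
    block = max(1, int(round(_BASELINE_STRIDE_S * fs)))
    reduced = _reduce_blocks(np.asarray(env.samples, float), block)

    def _odd_win(seconds: float) -> int:
        w = max(3, int(round(seconds * fs / block)) | 1)
        return min(w, reduced.size if reduced.size % 2 else reduced.size - 1)

    windows = [_odd_win(baseline_window), _odd_win(baseline_window / 4.0)]

    def _median_max(x: np.ndarray) -> np.ndarray:
        meds = [median_filter(x, size=w, mode="nearest") for w in windows]
        return np.maximum.reduce(meds)

    base1 = _median_max(reduced)
    cleaned = np.where(reduced > amplitude_factor * base1, base1, reduced)
    base2 = _median_max(cleaned)
    centers = (np.arange(base2.size) + 0.5) * block
    full = np.interp(np.arange(env.samples.size), centers, base2)
    return SignalTrace(env.label, fs, full, start_time=env.start_time,
                       zt0_offset=env.zt0_offset)


def detect_jerks(env: SignalTrace, baseline: SignalTrace,
                 params: DetectionParams = DetectionParams(),
                 limb: str = "L") -> list[MotorEvent]:
    """Threshold the envelope against the local baseline into MotorEvents.

    Candidate intervals where ``env >= amplitude_factor * baseline`` are
    merged across gaps shorter than ``merge_gap`` and kept iff their
    duration lies within ``[min_duration, max_duration]`` (inclusive).
    """
    if env.samples.size != baseline.samples.size:
        raise ValidationError("envelope and baseline are not aligned")
    fs = env.sampling_rate
    above = env.samples >= params.amplitude_factor * baseline.samples
    if not above.any():
        return []
    padded = np.concatenate([[0], above.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive

    # merge gaps shorter than merge_gap
    gap_samples = params.merge_gap * fs
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    tol = 0.5 / fs  # half a sample of slack on the duration criterion
    events = []
    for s, e in merged:
        dur = (e - s) / fs
        if params.min_duration - tol <= dur <= params.max_duration + tol:
            seg = env.samples[s:e]
            k = int(np.argmax(seg))
            events.append(
                MotorEvent(
                    limb=limb,
                    onset=env.start_time + s / fs,
                    offset=env.start_time + e / fs,
                    peak_amplitude=float(seg[k]),
                    baseline=float(baseline.samples[s + k]),
                )
            )
    return events


def _check_sorted(events) -> None:
    onsets = [ev.onset for ev in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValidationError("event list must be onset-sorted")


def merge_bilateral(events_l, events_r, bilateral_window: float = 0.5) -> list[MotorEvent]:
    """Fuse near-simultaneous left/right events into single bilateral events.

    Events whose onsets differ by less than ``bilateral_window`` are fused
    into one event spanning their union (one movement, never two); all
    others pass through unchanged. Greedy matching on onset-sorted lists is
    optimal here because closeness on a line is an interval relation.
    """
    _check_sorted(events_l)
    _check_sorted(events_r)
    out, i, j = [], 0, 0
    while i < len(events_l) and j < len(events_r):
        a, b = events_l[i], events_r[j]
        if abs(a.onset - b.onset) < bilateral_window:
            lead = a if a.onset <= b.onset else b
            peak = a if a.peak_amplitude >= b.peak_amplitude else b
            out.append(
                MotorEvent(
                    limb="bilateral",
                    onset=min(a.onset, b.onset),
                    offset=max(a.offset, b.offset),
                    peak_amplitude=peak.peak_amplitude,
                    baseline=peak.baseline,
                    stage=lead.stage,
                )
            )
            i += 1
            j += 1
        elif a.onset < b.onset:
            out.append(a)
            i += 1
        else:
            out.append(b)
            j += 1
    out.extend(events_l[i:])
    out.extend(events_r[j:])
    out.sort(key=lambda ev: ev.onset)
    return out


def detect_limb_events(traces: dict, params: DetectionParams = DetectionParams(),
                       limb_channels: dict | None = None) -> list[MotorEvent]:
    """Full per-recording detection: envelope, baseline, threshold, fuse.

    ``limb_channels`` maps limb codes to channel labels (default
    ``{"L": "LegL", "R": "LegR"}``).
    """
    limb_channels = limb_channels or {"L": "LegL", "R": "LegR"}
    per_limb = {}
    for limb, label in limb_channels.items():
        if label not in traces:
            raise ValidationError(f"missing channel {label!r}")
        env = envelope(traces[label], params.envelope_smoothing)
        base = tonic_baseline(env, params.baseline_window, params.amplitude_factor)
        per_limb[limb] = detect_jerks(env, base, params, limb=limb)
    if set(per_limb) == {"L", "R"}:
        return merge_bilateral(per_limb["L"], per_limb["R"], params.bilateral_window)
    merged = [ev for evs in per_limb.values() for ev in evs]
    merged.sort(key=lambda ev: ev.onset)
    return merged


__all__ = [
    "DetectionParams",
    "MotorEvent",
    "envelope",
    "tonic_baseline",
    "detect_jerks",
    "merge_bilateral",
    "detect_limb_events",
]
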