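"""Sleep-architecture metrics from epoch-wise hypnograms.

Episodes (bouts) are maximal runs of a single stage; a run of any length,
down to one epoch, counts (no smoothing rule is applied). For wake metrics
the active-wake (AW) and quiet-wake (QW) labels are merged into a single
``Wake`` stage, matching how wake is conventionally reported.

Windows: episodes are clipped to the analysis window before any duration is
averaged, which keeps the per-window conservation law exact:
sum of clipped episode durations of a stage == stage time in the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError, ValidationError
from .signal_io import Hypnogram, WAKE_STAGES


@dataclass(frozen=True)
class Episode:
    stage: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class AnalysisWindow:
    label: str
    start: float
    end: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError("window end must exceed start")

    @property
    def hours(self) -> float:
        return (self.end - self.start) / 3600.0


def _merged_labels(hyp: Hypnogram, merge_wake: bool) -> np.ndarray:
    labels = np.asarray(hyp.stages, dtype=object).copy()
    if merge_wake:
        labels[np.isin(labels, WAKE_STAGES)] = "Wake"
    return labels


def segment_episodes(hyp: Hypnogram, merge_wake: bool = False) -> list[Episode]:
    """Run-length encode the hypnogram into a gapless tiling of episodes."""
    if hyp.n_epochs == 0:
        raise ValidationError("empty hypnogram")
    labels = _merged_labels(hyp, merge_wake)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [hyp.n_epochs]])
    eps = hyp.epoch_length
    return [
        Episode(str(labels[s]), s * eps, e * eps) for s, e in zip(starts, ends)
    ]


def clip_episodes(episodes, window: AnalysisWindow) -> list[Episode]:
    """Intersect episodes with a window, dropping empty intersections."""
    out = []
    for ep in episodes:
        s = max(ep.start, window.start)
        e = min(ep.end, window.end)
        if e > s:
            out.append(Episode(ep.stage, s, e))
    return out


def stage_percentages(hyp: Hypnogram, window: AnalysisWindow | None = None,
                      merge_wake: bool = True) -> dict:
    """Percent of window time per stage (Wake/SWS/REM when merged)."""
    if window is None:
        window = AnalysisWindow("24h", 0.0, hyp.duration)
    seconds = hyp.stage_seconds(window.start, window.end)
    total = window.end - window.start
    if total <= 0:
        raise ValidationError("zero-length window")
    if merge_wake:
        merged = {"Wake": sum(seconds[s] for s in WAKE_STAGES)}
        merged["SWS"] = seconds["SWS"]
        merged["REM"] = seconds["REM"]
        seconds = merged
    return {k: 100.0 * v / total for k, v in seconds.items()}


def mean_episode_duration(hyp: Hypnogram, stage: str,
                          window: AnalysisWindow | None = None) -> float:
    """Arithmetic mean duration (minutes) of a stage's episodes in a window.

    ``stage='Wake'`` merges AW and QW before segmentation. Episodes are
    clipped to the window boundary before averaging.
    """
    merge = stage == "Wake"
    episodes = segment_episodes(hyp, merge_wake=merge)
    if window is not None:
        episodes = clip_episodes(episodes, window)
    durations = [ep.duration for ep in episodes if ep.stage == stage]
    if not durations:
        raise UndefinedMetricError(f"no {stage} episodes intersect the window")
    return float(np.mean(durations)) / 60.0


def make_windows(hyp: Hypnogram, scheme: str) -> list[AnalysisWindow]:
    """Standard analysis windows in recording time.

    ``24h``      — the full 24-h recording.
    ``phases``   — light = [ZT0, ZT12), dark = [ZT12, ZT24).
    ``post_injection`` — the 8-h window [ZT2, ZT10).
    """
    def zt(hours: float) -> float:
        # recording time of Zeitgeber time `hours`
        return hyp.zt0_offset + hours * 3600.0

    def _check(win: AnalysisWindow) -> AnalysisWindow:
        if win.start < -1e-9 or win.end > hyp.duration + 1e-9:
            raise ValidationError(
                f"window {win.label} [{win.start}, {win.end}) s outside the "
                f"{hyp.duration:g}-s recording"
            )
        return win

    if scheme == "24h":
        if hyp.duration < 24 * 3600 - 1e-9:
            raise ValidationError("recording shorter than 24 h")
        return [AnalysisWindow("24h", 0.0, 24 * 3600.0)]
    if scheme == "phases":
        light = hyp.light_duration_h
        return [
            _check(AnalysisWindow("light", zt(0.0), zt(light))),
            _check(AnalysisWindow("dark", zt(light), zt(24.0))),
        ]
    if scheme == "post_injection":
        return [_check(AnalysisWindow("post_injection", zt(2.0), zt(10.0)))]
    raise ValidationError(f"unknown window scheme {scheme!r}")


def architecture_summary(hyp: Hypnogram, window: AnalysisWindow | None = None) -> dict:
    """Stage percentages plus mean episode durations (min) for one window."""
    out = {}
    pct = stage_percentages(hyp, window)
    for stage in ("Wake", "SWS", "REM"):
        out[f"pct_{stage}"] = pct[stage]
        try:
            out[f"bout_{stage}_min"] = mean_episode_duration(hyp, stage, window)
        except UndefinedMetricError:
            out[f"bout_{stage}_min"] = float("nan")
    return out


__all__ = [
    "Episode",
    "AnalysisWindow",
    "segment_episodes",
    "clip_episodes",
    "stage_percentages",
    "mean_episode_duration",
    "make_windows",
    "architecture_summary",
]
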