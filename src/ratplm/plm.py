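"""Periodic-leg-movement sequencing and state-conditioned indices.

Jerks satisfying the amplitude and duration criteria are partitioned into
*periodic* sequences and *isolated* movements using the two periodicity
criteria: consecutive inter-movement intervals (IMIs, onset-to-onset) must
be strictly below 90 s, and a qualifying run must contain at least 4
consecutive jerks. Grouping is state-blind — trains may span the
wake-to-sleep transition — and each member event is afterwards attributed
to an index by the stage of the epoch containing its onset:

* ``PLMWI`` — periodic (sequence-member) events in quiet wake, per hour of
  quiet wake;
* ``PLMSI`` — periodic events in SWS, per hour of SWS;
* ``ILMSI`` — isolated events in sleep (SWS, and REM by default), per hour
  of total sleep.

A zero denominator yields an undefined index (``None``), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .hypnogram import AnalysisWindow
from .signal_io import Hypnogram

MAX_IMI_S = 90.0
MIN_RUN = 4


@dataclass
class PLMSequence:
    """A run of >= 4 jerks with all consecutive IMIs < 90 s."""

    events: list
    imis: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.imis is None:
            onsets = np.array([ev.onset for ev in self.events])
            self.imis = np.diff(onsets)
        self.imis = np.asarray(self.imis, float)
        if len(self.events) < MIN_RUN:
            raise ValidationError("PLM sequence needs at least 4 events")
        if np.any(self.imis < 0):
            raise ValidationError("PLM sequence events must be onset-sorted")
        if np.any(self.imis >= MAX_IMI_S):
            raise ValidationError("all IMIs in a sequence must be < 90 s")


def _check_sorted(events) -> None:
    onsets = [ev.onset for ev in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValidationError("event list must be onset-sorted")


def group_sequences(events, max_imi: float = MAX_IMI_S,
                    min_run: int = MIN_RUN):
    """Partition events into (periodic sequences, isolated events).

    Maximal runs of consecutive events with onset-to-onset intervals
    strictly below ``max_imi`` become :class:`PLMSequence` objects when they
    contain at least ``min_run`` events; all other events are isolated. The
    partition is exhaustive and disjoint.
    """
    _check_sorted(events)
    sequences, isolated = [], []
    run = []
    for ev in events:
        if run and (ev.onset - run[-1].onset) < max_imi:
            run.append(ev)
        else:
            if len(run) >= min_run:
                sequences.append(PLMSequence(run))
            else:
                isolated.extend(run)
            run = [ev]
    if len(run) >= min_run:
        sequences.append(PLMSequence(run))
    else:
        isolated.extend(run)
    return sequences, isolated


def assign_states(events, hyp: Hypnogram) -> list:
    """Return events with ``stage`` set to the stage of the epoch containing
    each onset (half-open epochs: a boundary onset takes the later epoch)."""
    out = []
    for ev in events:
        out.append(replace(ev, stage=hyp.stage_at(ev.onset)))
    return out


@dataclass
class IndexReport:
    """State-conditioned motor indices over one analysis window."""

    window: AnalysisWindow
    plmwi: float | None
    plmsi: float | None
    ilmsi: float | None
    counts: dict
    hours: dict

    def as_dict(self) -> dict:
        d = {"window": self.window.label,
             "plmwi": self.plmwi, "plmsi": self.plmsi, "ilmsi": self.ilmsi}
        d.update({f"n_{k}": v for k, v in self.counts.items()})
        d.update({f"h_{k}": v for k, v in self.hours.items()})
        return d


def _index(count: int, hours: float) -> float | None:
    return count / hours if hours > 0 else None


def compute_indices(sequences, isolated, hyp: Hypnogram,
                    window: AnalysisWindow | None = None,
                    ilms_include_rem: bool = True) -> IndexReport:
    """Compute PLMWI, PLMSI and ILMSI for one window.

    Requires stages to have been assigned. ``ilms_include_rem`` controls
    whether isolated events in REM count toward ILMS (the denominator is
    total sleep time either way).
    """
    if window is None:
        window = AnalysisWindow("24h", 0.0, hyp.duration)
    seq_events = [ev for s in sequences for ev in s.events]
    for ev in seq_events + list(isolated):
        if ev.stage is None:
            raise ValidationError("assign_states must run before compute_indices")

    def in_window(ev):
        return window.start <= ev.onset < window.end

    ilms_stages = {"SWS", "REM"} if ilms_include_rem else {"SWS"}
    n_plmw = sum(1 for ev in seq_events if in_window(ev) and ev.stage == "QW")
    n_plms = sum(1 for ev in seq_events if in_window(ev) and ev.stage == "SWS")
    n_ilms = sum(1 for ev in isolated if in_window(ev) and ev.stage in ilms_stages)

    sec = hyp.stage_seconds(max(0.0, window.start), min(hyp.duration, window.end))
    h_qw = sec["QW"] / 3600.0
    h_sws = sec["SWS"] / 3600.0
    h_sleep = (sec["SWS"] + sec["REM"]) / 3600.0

    return IndexReport(
        window=window,
        plmwi=_index(n_plmw, h_qw),
        plmsi=_index(n_plms, h_sws),
        ilmsi=_index(n_ilms, h_sleep),
        counts={"plmw": n_plmw, "plms": n_plms, "ilms": n_ilms},
        hours={"qw": h_qw, "sws": h_sws, "sleep": h_sleep},
    )


def score_events(events, hyp: Hypnogram,
                 windows=None, ilms_include_rem: bool = True) -> list:
    """Assign states, group into sequences, and compute indices per window."""
    events = assign_states(events, hyp)
    sequences, isolated = group_sequences(events)
    if windows is None:
        windows = [AnalysisWindow("24h", 0.0, hyp.duration)]
    return [
        compute_indices(sequences, isolated, hyp, w, ilms_include_rem)
        for w in windows
    ]


__all__ = [
    "MAX_IMI_S",
    "MIN_RUN",
    "PLMSequence",
    "IndexReport",
    "group_sequences",
    "assign_states",
    "compute_indices",
    "score_events",
]
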