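"""Core recording types and file I/O.

A recording session is represented as a :class:`RecordingBundle`: a set of
EMG/EEG traces (:class:`SignalTrace`), an epoch-wise hypnogram
(:class:`Hypnogram`) and per-animal metadata (group, pramipexole dose,
hematocrit).

Formats
-------
* **EDF** is the interchange format for signals (read through :mod:`mne`;
  written by a minimal built-in EDF encoder, since no installed library
  writes EDF).
* **CSV signals** — one header row ``time_s,<label>,<label>,...`` — are the
  human-inspectable fixture format.
* **Hypnograms** are TSV with ``epoch_index``/``stage`` columns and
  ``#``-prefixed header lines carrying ``epoch_length_s``, ``zt0_offset_s``
  and ``light_duration_h``.
* **Events** round-trip through a one-row-per-event CSV.

Time convention: seconds from recording start; intervals are half-open
``[onset, offset)``; ``zt0_offset`` is the signed offset in seconds from
recording start to Zeitgeber 0 (lights on), so a recording begun at ZT2 has
``zt0_offset = -7200``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError

STAGES = ("AW", "QW", "SWS", "REM")
WAKE_STAGES = ("AW", "QW")
SLEEP_STAGES = ("SWS", "REM")


@dataclass
class SignalTrace:
    """One channel of sampled signal (e.g. a hindlimb EMG)."""

    label: str
    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0
    zt0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"non-finite samples in channel {self.label!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class Hypnogram:
    """Epoch-wise vigilance-state labels.

    Stages are drawn from ``AW`` (active wake), ``QW`` (quiet wake), ``SWS``
    (slow-wave sleep) and ``REM``.
    """

    epoch_length: float
    stages: np.ndarray
    zt0_offset: float = 0.0
    light_duration_h: float = 12.0

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        if self.epoch_length <= 0:
            raise ValidationError("epoch_length must be positive")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_length

    def stage_at(self, t: float) -> str:
        """Stage of the epoch containing time ``t`` (half-open epochs)."""
        idx = int(np.floor(t / self.epoch_length))
        if t < 0 or idx >= self.n_epochs:
            raise ValidationError(f"time {t} s outside hypnogram span")
        return str(self.stages[idx])

    def stage_seconds(self, start: float = 0.0, end: float | None = None) -> dict:
        """Seconds spent in each stage within ``[start, end)``."""
        if end is None:
            end = self.duration
        if end <= start:
            raise ValidationError("window end must exceed start")
        edges = np.arange(self.n_epochs + 1) * self.epoch_length
        overlap = np.minimum(edges[1:], end) - np.maximum(edges[:-1], start)
        overlap = np.clip(overlap, 0.0, None)
        out = {s: 0.0 for s in STAGES}
        for s in STAGES:
            out[s] = float(overlap[self.stages == s].sum())
        return out


@dataclass
class RecordingBundle:
    """One animal-session: traces + hypnogram + covariates."""

    animal_id: str
    traces: dict = field(default_factory=dict)
    hypnogram: Hypnogram | None = None
    group: str | None = None
    dose_mg_per_kg: float | None = None
    hematocrit: float | None = None

    def __post_init__(self) -> None:
        if self.hematocrit is not None and not (0 < self.hematocrit <= 100):
            raise ValidationError("hematocrit must be in (0, 100]")
        self.validate_durations()

    @property
    def duration(self) -> float:
        if self.traces:
            return next(iter(self.traces.values())).duration
        if self.hypnogram is not None:
            return self.hypnogram.duration
        raise ValidationError("empty bundle has no duration")

    def validate_durations(self, tol: float = 1e-6) -> None:
        durations = [t.duration for t in self.traces.values()]
        if self.hypnogram is not None:
            durations.append(self.hypnogram.duration)
        if durations and (max(durations) - min(durations)) > tol:
            raise ConsistencyError(
                f"traces/hypnogram durations disagree: {sorted(set(durations))}"
            )


# ---------------------------------------------------------------------------
# CSV signals
# ---------------------------------------------------------------------------

def write_signals_csv(traces: dict, path) -> None:
    """Write traces as CSV: ``time_s`` column plus one column per channel."""
    traces = dict(traces)
    if not traces:
        raise ValidationError("no traces to write")
    rates = {t.sampling_rate for t in traces.values()}
    sizes = {t.samples.size for t in traces.values()}
    if len(rates) > 1 or len(sizes) > 1:
        raise ConsistencyError("CSV signal dialect requires a common time base")
    first = next(iter(traces.values()))
    df = pd.DataFrame({"time_s": first.times()})
    for label, tr in traces.items():
        df[label] = tr.samples
    df.to_csv(path, index=False, float_format="%.6g")


def read_signals_csv(path) -> dict:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("CSV signal file must have a time_s column")
    if len(df) < 2:
        raise FormatError("CSV signal file must have at least 2 samples")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError("time_s must be uniformly sampled")
    fs = 1.0 / dt[0]
    labels = [c for c in df.columns if c != "time_s"]
    if not labels:
        raise FormatError("CSV signal file has no channel columns")
    return {
        lab: SignalTrace(lab, float(round(fs, 9)), df[lab].to_numpy(float),
                         start_time=float(t[0]))
        for lab in labels
    }


# ---------------------------------------------------------------------------
# Hypnogram TSV
# ---------------------------------------------------------------------------

def write_hypnogram_tsv(hyp: Hypnogram, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# epoch_length_s: {hyp.epoch_length:g}\n")
        fh.write(f"# zt0_offset_s: {hyp.zt0_offset:g}\n")
        fh.write(f"# light_duration_h: {hyp.light_duration_h:g}\n")
        fh.write("epoch_index\tstage\n")
        for i, s in enumerate(hyp.stages):
            fh.write(f"{i}\t{s}\n")


def read_hypnogram_tsv(path) -> Hypnogram:
    meta = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, val = line[1:].split(":", 1)
                except ValueError as exc:
                    raise FormatError(f"bad hypnogram header line: {line!r}") from exc
                meta[key.strip()] = float(val)
            elif not line.startswith("epoch_index"):
                idx, stage = line.split("\t")
                rows.append((int(idx), stage))
    if "epoch_length_s" not in meta:
        raise FormatError("hypnogram TSV missing epoch_length_s header")
    rows.sort()
    if [i for i, _ in rows] != list(range(len(rows))):
        raise FormatError("hypnogram epoch indices must be 0..n-1")
    return Hypnogram(
        epoch_length=meta["epoch_length_s"],
        stages=np.array([s for _, s in rows], dtype=object),
        zt0_offset=meta.get("zt0_offset_s", 0.0),
        light_duration_h=meta.get("light_duration_h", 12.0),
    )


# ---------------------------------------------------------------------------
# Minimal EDF writer (16-bit, one data record per second)
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_signals_edf(traces: dict, path) -> None:
    """Write traces to a plain EDF file.

    One data record per second; every channel's sampling rate must be a
    positive integer and all channels must share an integer duration in
    seconds. Samples are quantized to 16 bits over each channel's observed
    physical range.
    """
    traces = dict(traces)
    if not traces:
        raise ValidationError("no traces to write")
    durations = {round(t.duration, 9) for t in traces.values()}
    if len(durations) > 1:
        raise ConsistencyError("EDF channels must share one duration")
    dur = durations.pop()
    n_records = int(round(dur))
    if abs(dur - n_records) > 1e-9 or n_records < 1:
        raise ValidationError("EDF writer requires a whole-second duration")
    for t in traces.values():
        if abs(t.sampling_rate - round(t.sampling_rate)) > 1e-9:
            raise ValidationError("EDF writer requires integer sampling rates")

    ns = len(traces)
    header = b""
    header += _edf_field("0", 8)                       # version
    header += _edf_field("ratplm", 80)                 # patient id
    header += _edf_field("ratplm synthetic", 80)       # recording id
    header += _edf_field("01.01.00", 8)                # start date
    header += _edf_field("00.00.00", 8)                # start time
    header += _edf_field(256 * (ns + 1), 8)            # header bytes
    header += _edf_field("", 44)                       # reserved
    header += _edf_field(n_records, 8)
    header += _edf_field("1", 8)                       # record duration, s
    header += _edf_field(ns, 4)

    labels, phys_min, phys_max, spr, scaled = [], [], [], [], []
    for label, tr in traces.items():
        lo = float(np.min(tr.samples)) if tr.samples.size else -1.0
        hi = float(np.max(tr.samples)) if tr.samples.size else 1.0
        if hi <= lo:  # constant channel: widen to a valid range
            hi = lo + 1.0
        labels.append(label)
        phys_min.append(lo)
        phys_max.append(hi)
        n_per_rec = int(round(tr.sampling_rate))
        spr.append(n_per_rec)
        dig = np.round(
            (np.asarray(tr.samples, float) - lo) / (hi - lo) * 65535.0 - 32768.0
        ).astype("<i2")
        scaled.append(dig.reshape(n_records, n_per_rec))

    for lab in labels:
        header += _edf_field(lab, 16)
    for _ in labels:
        header += _edf_field("", 80)                   # transducer
    for _ in labels:
        header += _edf_field("uV", 8)                  # physical dimension
    for v in phys_min:
        header += _edf_field(f"{v:.8g}"[:8], 8)
    for v in phys_max:
        header += _edf_field(f"{v:.8g}"[:8], 8)
    for _ in labels:
        header += _edf_field(-32768, 8)
    for _ in labels:
        header += _edf_field(32767, 8)
    for _ in labels:
        header += _edf_field("", 80)                   # prefiltering
    for n in spr:
        header += _edf_field(n, 8)
    for _ in labels:
        header += _edf_field("", 32)                   # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for ch in range(ns):
                fh.write(struct.pack(f"<{spr[ch]}h", *scaled[ch][rec]))


def read_signals_edf(path) -> dict:
    """Read EDF signals via MNE, restoring the header's physical units."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    out = {}
    data = raw.get_data()  # MNE rescales uV -> V; undo below
    for i, label in enumerate(raw.ch_names):
        out[label] = SignalTrace(label, fs, data[i] * 1e6)
    return out


# ---------------------------------------------------------------------------
# Bundle-level read/write
# ---------------------------------------------------------------------------

def write_psg(bundle: RecordingBundle, path, fmt: str | None = None) -> None:
    """Write a bundle's signals (EDF or CSV by suffix) plus hypnogram sidecar."""
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        write_signals_edf(bundle.traces, path)
    elif fmt == "csv":
        write_signals_csv(bundle.traces, path)
    else:
        raise FormatError(f"unknown signal format {fmt!r}")
    if bundle.hypnogram is not None:
        write_hypnogram_tsv(bundle.hypnogram, path.with_suffix(".hypnogram.tsv"))


def read_psg(
    path,
    format_hint: str | None = None,
    hypnogram_path=None,
    animal_id: str | None = None,
    **metadata,
) -> RecordingBundle:
    """Read signals (+ optional hypnogram sidecar) into a RecordingBundle."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format_hint or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        traces = read_signals_edf(path)
    elif fmt == "csv":
        traces = read_signals_csv(path)
    else:
        raise FormatError(f"unknown signal format {fmt!r}")

    hyp = None
    if hypnogram_path is None:
        sidecar = path.with_suffix(".hypnogram.tsv")
        if sidecar.exists():
            hypnogram_path = sidecar
    if hypnogram_path is not None:
        hyp = read_hypnogram_tsv(hypnogram_path)
        for tr in traces.values():
            tr.zt0_offset = hyp.zt0_offset
    return RecordingBundle(
        animal_id=animal_id or path.stem,
        traces=traces,
        hypnogram=hyp,
        **metadata,
    )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["limb", "onset_s", "offset_s", "peak_amplitude", "baseline", "stage"]


def write_events(events, path) -> None:
    """Write motor events to CSV, one onset-sorted row per event."""
    rows = []
    last_onset = -np.inf
    for ev in events:
        if ev.onset < 0 or ev.offset <= ev.onset:
            raise ValidationError(f"invalid event times: {ev.onset}, {ev.offset}")
        if ev.onset < last_onset:
            raise ValidationError("events must be onset-sorted")
        last_onset = ev.onset
        rows.append(
            {
                "limb": ev.limb,
                "onset_s": ev.onset,
                "offset_s": ev.offset,
                "peak_amplitude": ev.peak_amplitude,
                "baseline": ev.baseline,
                "stage": ev.stage if ev.stage is not None else "",
            }
        )
    # %.17g guarantees exact float round-trip through the text format
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_events(path) -> list:
    from .jerks import MotorEvent

    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event CSV missing columns: {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            MotorEvent(
                limb=str(row.limb),
                onset=float(row.onset_s),
                offset=float(row.offset_s),
                peak_amplitude=float(row.peak_amplitude),
                baseline=float(row.baseline),
                stage=str(row.stage) or None,
            )
        )
    return events


__all__ = [
    "STAGES",
    "WAKE_STAGES",
    "SLEEP_STAGES",
    "SignalTrace",
    "Hypnogram",
    "RecordingBundle",
    "read_psg",
    "write_psg",
    "read_signals_csv",
    "write_signals_csv",
    "read_signals_edf",
    "write_signals_edf",
    "read_hypnogram_tsv",
    "write_hypnogram_tsv",
    "read_events",
    "write_events",
]
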