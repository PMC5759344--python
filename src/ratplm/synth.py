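"""Synthetic rat polysomnography with programmed ground truth.

The generator produces, per animal, a 24-h (or 8-h post-injection)
hypnogram, a set of "true" limb jerks organized into periodic trains and
isolated movements, bilateral leg-EMG traces with those jerks embedded in
state-dependent tonic noise, and a hematocrit value — all drawn from a
named :class:`GroupPreset` whose parameters are calibrated to the study's
printed group means.

Model summary
-------------
*Hypnogram.* An alternating-renewal chain over Wake/SWS/REM: bout lengths
in epochs are geometric (the discrete analogue of an exponential bout
duration, so the mean bout duration is matched exactly); transitions are
Wake->SWS always, SWS->REM with probability ``q`` else Wake, REM->SWS with
probability ``r`` else Wake. ``q`` and ``r`` are solved from the preset's
stage percentages and mean bout durations. Wake bouts carry an active-wake
head and a quiet-wake tail (fraction ``qw_fraction``).

*Motor events.* The generator is index-parameterized: it places periodic
trains in SWS bouts (and, when the preset programs PLM in wake, trains that
begin in the pre-sleep quiet-wake tail and run across the sleep-onset
boundary) until the programmed events-per-hour targets are met, then places
isolated movements in sleep. Train lengths are 4 plus a geometric excess;
IMIs are truncated-normal within [5, 89] s, so every train satisfies the
periodicity criteria by construction. Isolated events are kept at least
90 s away from any train event and never form runs of four, so the
classifier's state-blind grouping reproduces the generator's labels — and
hence the programmed indices — exactly.

*EMG.* Per-limb traces are Gaussian tonic noise with state-dependent
amplitude (wake > SWS > REM) plus cosine-tapered noise bursts at the true
event times, each 3.5-5x the local tonic level and 0.3-0.8 s long; events
are unilateral or bilateral per a preset probability.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import ValidationError
from .hypnogram import AnalysisWindow
from .jerks import MotorEvent
from .plm import IndexReport, _index
from .signal_io import Hypnogram, RecordingBundle, SignalTrace

DEFAULT_EPOCH_S = 10.0
MIN_EMG_RATE_HZ = 100.0
#: minimum absolute separation (s) between an isolated event and any train event
ISOLATION_GAP_S = 90.0


@dataclass(frozen=True)
class GroupPreset:
    """All parameters defining one synthetic cohort condition."""

    name: str
    group: str
    hct_mean: float
    hct_sd: float
    stage_percent: dict
    bout_min: dict
    plms_rate: float
    ilms_rate: float
    plmw_prob_nonzero: float
    plmw_nonzero_mean: float
    plmw_nonzero_sd: float
    plms_sd: float = 0.0
    ilms_sd: float = 0.0
    dose_mg_per_kg: float | None = None
    hct_alt: tuple | None = None
    epoch_s: float = DEFAULT_EPOCH_S
    qw_fraction: float = 0.4
    p_bilateral: float = 0.5
    imi_mean: float = 25.0
    imi_sd: float = 10.0
    imi_min: float = 5.0
    imi_max: float = 89.0
    train_length_mean: float = 7.0
    amp_factor_range: tuple = (3.5, 5.0)
    duration_range: tuple = (0.3, 0.8)
    tone: dict = field(default_factory=lambda: {"AW": 0.85, "QW": 0.85,
                                                "SWS": 0.6, "REM": 0.5})
    rate_cv: float = 0.10
    bout_cv: float = 0.05
    duration_h: float = 24.0
    zt_start: float = 0.0

    def __post_init__(self):
        if min(self.plms_rate, self.ilms_rate, self.plmw_nonzero_mean) < 0:
            raise ValidationError("motor rates must be nonnegative")
        total = sum(self.stage_percent.values())
        if abs(total - 100.0) > 0.5:
            raise ValidationError(f"stage percentages sum to {total}, not 100")
        if not (self.imi_min <= self.imi_mean < 90.0):
            raise ValidationError("imi_mean must lie in [imi_min, 90)")
        lo, hi = self.duration_range
        if not (0.2 <= lo < hi <= 5.0):
            raise ValidationError("true jerk durations must lie within [0.2, 5] s")
        if self.amp_factor_range[0] < 2.0:
            raise ValidationError("true jerk amplitude factors must be >= 2")

    @property
    def plmw_rate_mean(self) -> float:
        """Cohort-mean PLMW rate (events/h QW), zeros included."""
        return self.plmw_prob_nonzero * self.plmw_nonzero_mean


def load_presets() -> dict:
    """Load the versioned preset table shipped with the package."""
    text = (importlib.resources.files("ratplm") / "presets.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, cfg in raw["presets"].items():
        cfg = dict(cfg)
        if "hct_alt" in cfg:
            cfg["hct_alt"] = tuple(cfg["hct_alt"])
        for key in ("amp_factor_range", "duration_range"):
            cfg[key] = tuple(cfg[key])
        out[name] = GroupPreset(name=name, **cfg)
    return out


def get_preset(name: str) -> GroupPreset:
    presets = load_presets()
    if name not in presets:
        raise ValidationError(f"unknown preset {name!r}; known: {sorted(presets)}")
    return presets[name]


# ---------------------------------------------------------------------------
# Hypnogram sampling
# ---------------------------------------------------------------------------

def solve_transitions(stage_percent: dict, bout_min: dict) -> tuple:
    """Transition probabilities (q: SWS->REM, r: REM->SWS) matching targets.

    With bout-start rates n_stage proportional to fraction/mean-duration,
    stationarity of the chain requires n_SWS = n_Wake + r*n_REM and
    n_REM = q*n_SWS. Probabilities are clipped to [0, 1]; presets shipped
    with the package are chosen to be feasible without clipping.
    """
    n = {s: stage_percent[s] / bout_min[s] for s in ("Wake", "SWS", "REM")}
    if n["Wake"] == 0 or n["SWS"] == 0:
        return 0.0, 0.0  # degenerate chain: no Wake<->SWS alternation
    a = n["SWS"] / n["Wake"]
    b = n["REM"] / n["Wake"]
    q = float(np.clip(b / a, 0.0, 1.0))
    r = float(np.clip((a - 1.0) / b, 0.0, 1.0)) if b > 0 else 0.0
    return q, r


def _rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def sample_hypnogram(preset: GroupPreset, duration_h: float | None = None,
                     epoch_s: float | None = None, seed=None,
                     rng: np.random.Generator | None = None) -> Hypnogram:
    """Sample one hypnogram from the preset's renewal chain.

    Bout lengths in epochs are geometric with mean ``bout_min*60/epoch_s``
    (minimum one epoch), so mean bout durations match the preset exactly.
    """
    rng = _rng(seed, rng)
    duration_h = preset.duration_h if duration_h is None else duration_h
    epoch_s = preset.epoch_s if epoch_s is None else epoch_s
    n_epochs = int(round(duration_h * 3600.0 / epoch_s))
    if n_epochs < 1:
        raise ValidationError("duration shorter than one epoch")
    p_geo = {}
    for s in ("Wake", "SWS", "REM"):
        if preset.stage_percent[s] == 0:
            p_geo[s] = 1.0  # stage never entered
            continue
        mean_epochs = preset.bout_min[s] * 60.0 / epoch_s
        if mean_epochs < 1.0:
            raise ValidationError(f"mean {s} bout shorter than one epoch")
        p_geo[s] = 1.0 / mean_epochs
    q, r = solve_transitions(preset.stage_percent, preset.bout_min)
    if preset.stage_percent["REM"] == 0:
        q = 0.0
    enter_sleep = preset.stage_percent["SWS"] > 0

    labels = []
    state = "Wake"
    while len(labels) < n_epochs:
        n = int(rng.geometric(p_geo[state]))
        if state == "Wake":
            n_qw = int(round(preset.qw_fraction * n))
            labels.extend(["AW"] * (n - n_qw) + ["QW"] * n_qw)
            state = "SWS" if enter_sleep else "Wake"
        elif state == "SWS":
            labels.extend(["SWS"] * n)
            state = "REM" if rng.random() < q else "Wake"
        else:
            labels.extend(["REM"] * n)
            state = "SWS" if rng.random() < r else "Wake"
    return Hypnogram(
        epoch_length=epoch_s,
        stages=np.array(labels[:n_epochs], dtype=object),
        zt0_offset=-preset.zt_start * 3600.0,
        light_duration_h=12.0,
    )


# ---------------------------------------------------------------------------
# Ground-truth event placement
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Programmed events plus the indices they imply.

    ``train_ids[i]`` is the train index of ``events[i]`` or -1 for isolated
    movements; ``amp_factors[i]`` is the burst amplitude as a multiple of
    the local tonic level, realized at EMG synthesis time.
    """

    events: list
    train_ids: np.ndarray
    amp_factors: np.ndarray
    true_indices: IndexReport

    @property
    def n_events(self) -> int:
        return len(self.events)


def _bouts_of(hyp: Hypnogram):
    """(stage, start_s, end_s) runs of the raw AW/QW/SWS/REM labels."""
    labels = np.asarray(hyp.stages, dtype=object)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    eps = hyp.epoch_length
    return [(str(labels[s]), s * eps, e * eps) for s, e in zip(starts, ends)]


def _sample_imi(preset: GroupPreset, rng) -> float:
    while True:  # rejection sampling of the truncated normal
        x = rng.normal(preset.imi_mean, preset.imi_sd)
        if preset.imi_min <= x <= preset.imi_max:
            return float(x)


def _sample_train_len(preset: GroupPreset, rng) -> int:
    extra_mean = max(preset.train_length_mean - 4.0, 0.0)
    if extra_mean == 0:
        return 4
    return 4 + int(rng.geometric(1.0 / (extra_mean + 1.0))) - 1


def place_events(hyp: Hypnogram, preset: GroupPreset,
                 seed=None, rng: np.random.Generator | None = None,
                 rates: dict | None = None) -> GroundTruth:
    """Place periodic trains and isolated movements onto a hypnogram.

    ``rates`` may override the preset's ``plms_rate``/``plmw_rate``/
    ``ilms_rate`` (events per hour of SWS / quiet wake / sleep) — used by
    :func:`generate_animal` to inject per-animal variability.
    """
    rng = _rng(seed, rng)
    rates = rates or {}
    plms_rate = rates.get("plms_rate", preset.plms_rate)
    plmw_rate = rates.get("plmw_rate", preset.plmw_rate_mean)
    ilms_rate = rates.get("ilms_rate", preset.ilms_rate)

    sec = hyp.stage_seconds()
    h_qw = sec["QW"] / 3600.0
    h_sws = sec["SWS"] / 3600.0
    h_sleep = (sec["SWS"] + sec["REM"]) / 3600.0
    if (plms_rate > 0 and h_sws == 0) or (plmw_rate > 0 and h_qw == 0) \
            or (ilms_rate > 0 and h_sleep == 0):
        raise ValidationError("programmed rates incompatible with state time")

    bouts = _bouts_of(hyp)
    n_plmw_left = int(round(plmw_rate * h_qw))
    n_plms_left = int(round(plms_rate * h_sws))
    n_ilms = int(round(ilms_rate * h_sleep))

    placed = []  # (onset, train_id)
    train_counter = 0
    sws_cursor = {}  # bout index -> next free time

    # --- trains crossing the quiet-wake -> SWS boundary -------------------
    crossings = [i for i in range(len(bouts) - 1)
                 if bouts[i][0] == "QW" and bouts[i + 1][0] == "SWS"]
    rng.shuffle(crossings)
    for i in crossings:
        if n_plmw_left <= 0:
            break
        _, qw0, qw1 = bouts[i]
        _, sws0, sws1 = bouts[i + 1]
        t = qw1 - rng.uniform(2.0, 4.0)
        qw_times = []
        k_target = min(int(rng.integers(1, 4)), n_plmw_left)
        while len(qw_times) < k_target and t >= qw0 + 1.0:
            qw_times.append(t)
            t -= rng.uniform(6.0, 12.0)
        if not qw_times:
            continue
        qw_times.sort()
        target_len = max(4, len(qw_times) + _sample_train_len(preset, rng) - 4)
        sws_times = []
        t = sws0 + rng.uniform(2.0, 5.0)
        while len(qw_times) + len(sws_times) < target_len and t <= sws1 - 1.5:
            sws_times.append(t)
            t += _sample_imi(preset, rng)
        if len(qw_times) + len(sws_times) < 4:
            continue
        for tt in qw_times + sws_times:
            placed.append((tt, train_counter))
        train_counter += 1
        n_plmw_left -= len(qw_times)
        n_plms_left -= len(sws_times)
        sws_cursor[i + 1] = (sws_times[-1] if sws_times else sws0) \
            + rng.uniform(20.0, 40.0)

    # --- trains within SWS bouts ------------------------------------------
    sws_idx = [i for i, b in enumerate(bouts) if b[0] == "SWS"]
    rng.shuffle(sws_idx)
    exhausted = set()
    while n_plms_left > 2 and len(exhausted) < len(sws_idx):
        for i in sws_idx:
            if n_plms_left <= 2:
                break
            if i in exhausted:
                continue
            _, s0, s1 = bouts[i]
            t = sws_cursor.get(i, s0 + rng.uniform(1.5, 4.0))
            target_len = max(4, min(_sample_train_len(preset, rng),
                                    max(4, n_plms_left)))
            times = []
            while len(times) < target_len and t <= s1 - 1.5:
                times.append(t)
                t += _sample_imi(preset, rng)
            if len(times) < 4:
                exhausted.add(i)
                continue
            for tt in times:
                placed.append((tt, train_counter))
            train_counter += 1
            n_plms_left -= len(times)
            sws_cursor[i] = times[-1] + rng.uniform(20.0, 40.0)

    train_onsets = np.sort([t for t, _ in placed])

    # --- isolated movements in sleep --------------------------------------
    sleep_spans = [(s0 + 0.5, s1 - 0.5) for st, s0, s1 in bouts
                   if st in ("SWS", "REM") and (s1 - s0) > 1.0]
    iso_times: list[float] = []
    if n_ilms > 0 and sleep_spans:
        lengths = np.array([e - s for s, e in sleep_spans])
        weights = lengths / lengths.sum()
        attempts = 0
        max_attempts = 200 * n_ilms
        while len(iso_times) < n_ilms and attempts < max_attempts:
            attempts += 1
            k = rng.choice(len(sleep_spans), p=weights)
            s, e = sleep_spans[k]
            t = rng.uniform(s, e)
            # keep clear of trains so grouping cannot absorb this event
            j = np.searchsorted(train_onsets, t)
            near_train = (
                (j > 0 and t - train_onsets[j - 1] < ISOLATION_GAP_S)
                or (j < train_onsets.size and train_onsets[j] - t < ISOLATION_GAP_S)
            )
            if near_train:
                continue
            srt = sorted(iso_times)
            jj = np.searchsorted(srt, t)
            if (jj > 0 and t - srt[jj - 1] < 2.5) or \
               (jj < len(srt) and srt[jj] - t < 2.5):
                continue
            # forbid isolated runs of >= 4 (they would become sequences)
            trial = srt[:jj] + [t] + srt[jj:]
            lo = jj
            while lo > 0 and trial[lo] - trial[lo - 1] < ISOLATION_GAP_S:
                lo -= 1
            hi = jj
            while hi < len(trial) - 1 and trial[hi + 1] - trial[hi] < ISOLATION_GAP_S:
                hi += 1
            if hi - lo + 1 >= 4:
                continue
            iso_times.append(t)

    # --- materialize events -----------------------------------------------
    records = [(t, tid) for t, tid in placed] + [(t, -1) for t in iso_times]
    records.sort()
    events, train_ids, amp_factors = [], [], []
    for t, tid in records:
        dur = rng.uniform(*preset.duration_range)
        f = rng.uniform(*preset.amp_factor_range)
        stage = hyp.stage_at(t)
        if rng.random() < preset.p_bilateral:
            limb = "bilateral"
        else:
            limb = "L" if rng.random() < 0.5 else "R"
        tone = preset.tone[stage]
        events.append(MotorEvent(limb=limb, onset=t, offset=t + dur,
                                 peak_amplitude=f * tone, baseline=tone,
                                 stage=stage))
        train_ids.append(tid)
        amp_factors.append(f)

    train_ids = np.asarray(train_ids)
    amp_factors = np.asarray(amp_factors)

    # --- programmed indices, by direct counting from the labels ------------
    stages = np.array([ev.stage for ev in events], dtype=object)
    in_train = train_ids >= 0
    n_plmw = int(np.sum(in_train & (stages == "QW")))
    n_plms = int(np.sum(in_train & (stages == "SWS")))
    n_iso_sleep = int(np.sum(~in_train & np.isin(stages, ("SWS", "REM"))))
    window = AnalysisWindow("24h" if preset.duration_h >= 24 else "recording",
                            0.0, hyp.duration)
    true_indices = IndexReport(
        window=window,
        plmwi=_index(n_plmw, h_qw),
        plmsi=_index(n_plms, h_sws),
        ilmsi=_index(n_iso_sleep, h_sleep),
        counts={"plmw": n_plmw, "plms": n_plms, "ilms": n_iso_sleep},
        hours={"qw": h_qw, "sws": h_sws, "sleep": h_sleep},
    )
    return GroundTruth(events=events, train_ids=train_ids,
                       amp_factors=amp_factors, true_indices=true_indices)


# ---------------------------------------------------------------------------
# EMG synthesis
# ---------------------------------------------------------------------------

def synthesize_emg(hyp: Hypnogram, truth: GroundTruth, preset: GroupPreset,
                   rate_hz: float = 250.0, seed=None,
                   rng: np.random.Generator | None = None) -> dict:
    """Render bilateral leg-EMG traces containing the programmed jerks."""
    if rate_hz < MIN_EMG_RATE_HZ:
        raise ValidationError("sampling rate below 100 Hz cannot resolve jerks")
    rng = _rng(seed, rng)
    n = int(round(hyp.duration * rate_hz))
    epoch_idx = np.minimum(
        (np.arange(n) / (hyp.epoch_length * rate_hz)).astype(np.int64),
        hyp.n_epochs - 1,
    )
    tone_per_epoch = np.array([preset.tone[s] for s in hyp.stages], np.float32)
    sigma = tone_per_epoch[epoch_idx]

    traces = {}
    for label in ("LegL", "LegR"):
        x = rng.standard_normal(n, dtype=np.float32)
        x *= sigma
        traces[label] = x

    ramp_n = max(1, int(round(0.025 * rate_hz)))
    for ev, f in zip(truth.events, truth.amp_factors):
        i0 = int(round(ev.onset * rate_hz))
        i1 = min(int(round(ev.offset * rate_hz)), n)
        m = i1 - i0
        if m <= 0:
            continue
        taper = np.ones(m, np.float32)
        k = min(ramp_n, m // 2)
        if k > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(1, k + 1) / (k + 1)))
            taper[:k] = ramp
            taper[-k:] = ramp[::-1]
        sigma_b = np.float32(f * preset.tone[ev.stage])
        burst = rng.standard_normal(m, dtype=np.float32) * sigma_b * taper
        targets = ("LegL", "LegR") if ev.limb == "bilateral" else (
            ("LegL",) if ev.limb == "L" else ("LegR",))
        for label in targets:
            traces[label][i0:i1] += burst

    return {
        label: SignalTrace(label, rate_hz, x, zt0_offset=hyp.zt0_offset)
        for label, x in traces.items()
    }


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _jitter(rng, cv: float) -> float:
    return float(max(0.2, 1.0 + rng.normal(0.0, cv)))


def generate_animal(preset: GroupPreset, animal_id: str,
                    duration_h: float | None = None,
                    rng: np.random.Generator | None = None, seed=None,
                    with_emg: bool = True, rate_hz: float = 250.0):
    """One synthetic animal: (RecordingBundle, GroundTruth).

    Per-animal variability: motor rates are scaled by a factor with CV
    ``rate_cv``; mean bout durations by a factor with CV ``bout_cv``; PLMW
    is zero with probability ``1 - plmw_prob_nonzero`` (some animals show
    no periodic movements in wake); hematocrit is normal with the preset's
    group mean and SD.
    """
    rng = _rng(seed, rng)
    bout = {s: m * _jitter(rng, preset.bout_cv)
            for s, m in preset.bout_min.items()}
    animal_preset = replace(preset, bout_min=bout)
    rates = {
        "plms_rate": preset.plms_rate * _jitter(rng, preset.rate_cv),
        "ilms_rate": preset.ilms_rate * _jitter(rng, preset.rate_cv),
        "plmw_rate": 0.0,
    }
    if preset.plmw_prob_nonzero > 0 and rng.random() < preset.plmw_prob_nonzero:
        rates["plmw_rate"] = max(0.5, rng.normal(preset.plmw_nonzero_mean,
                                                 preset.plmw_nonzero_sd))
    hct = float(np.clip(rng.normal(preset.hct_mean, preset.hct_sd), 1.0, 100.0))

    hyp = sample_hypnogram(animal_preset, duration_h=duration_h, rng=rng)
    truth = place_events(hyp, preset, rng=rng, rates=rates)
    traces = {}
    if with_emg:
        traces = synthesize_emg(hyp, truth, preset, rate_hz=rate_hz, rng=rng)
    bundle = RecordingBundle(
        animal_id=animal_id,
        traces=traces,
        hypnogram=hyp,
        group=preset.group,
        dose_mg_per_kg=preset.dose_mg_per_kg,
        hematocrit=hct,
    )
    return bundle, truth


def iter_cohort(preset: GroupPreset, n_animals: int,
                duration_h: float | None = None, seed=None,
                with_emg: bool = True, rate_hz: float = 250.0):
    """Yield (bundle, truth) pairs from independent per-animal substreams.

    Reproducible from (preset, seed); each animal's stream is independent,
    so results do not depend on how many animals are consumed.
    """
    if n_animals < 1:
        raise ValidationError("need at least one animal")
    children = np.random.SeedSequence(seed).spawn(n_animals)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        yield generate_animal(
            preset, animal_id=f"{preset.name}-{i + 1:02d}",
            duration_h=duration_h, rng=rng, with_emg=with_emg, rate_hz=rate_hz,
        )


def generate_cohort(preset: GroupPreset, n_animals: int,
                    duration_h: float | None = None, seed=None,
                    with_emg: bool = True, rate_hz: float = 250.0) -> list:
    """Materialized list version of :func:`iter_cohort`."""
    return list(iter_cohort(preset, n_animals, duration_h=duration_h,
                            seed=seed, with_emg=with_emg, rate_hz=rate_hz))


__all__ = [
    "GroupPreset",
    "GroundTruth",
    "load_presets",
    "get_preset",
    "solve_transitions",
    "sample_hypnogram",
    "place_events",
    "synthesize_emg",
    "generate_animal",
    "iter_cohort",
    "generate_cohort",
]
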