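"""Multi-tone masker / target stimulus generation.

Trials are 12 s mixtures of a random multi-tone masker and, on 2/3 of
trials, a regularly repeating target tone.  Masker tones live on a
log-spaced frequency grid between 239 and 5000 Hz; each grid frequency is
an independent renewal process whose inter-tone (onset-to-onset) intervals
are uniform on [iti_min, iti_max].  A protected region of one equivalent
rectangular bandwidth (ERB) on each side of the target frequency is kept
masker-free so that masking is informational rather than energetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

MASKER_F_LO = 239.0
MASKER_F_HI = 5000.0
TARGET_F_LO = 489.0
TARGET_F_HI = 2924.0
N_TARGET_FREQUENCIES = 6
TRIAL_DURATION_S = 12.0
TARGET_START_MS = 600.0
ITI_MIN_MS = 100.0
RAMP_S = 0.010
DEFAULT_SAMPLE_RATE = 44100

N_TRIALS = 243
N_TARGET_TRIALS = 162
N_CATCH_TRIALS = 81
BLOCK_SIZES = (41, 41, 41, 40, 40, 40)


def log_spaced_frequencies(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """``n`` frequencies with constant neighbor ratio from ``f_lo`` to
    ``f_hi`` inclusive, rounded to the nearest integer Hz."""
    if n < 2:
        raise ValueError("need at least two frequencies")
    if not (0 < f_lo < f_hi):
        raise ValueError("require f_hi > f_lo > 0")
    return np.rint(np.geomspace(f_lo, f_hi, n))


def target_frequency_set() -> np.ndarray:
    """The six equiprobable log-spaced target frequencies (Hz)."""
    return log_spaced_frequencies(TARGET_F_LO, TARGET_F_HI, N_TARGET_FREQUENCIES)


def erb(f_t_khz: float) -> float:
    """Equivalent rectangular bandwidth in Hz at frequency ``f_t_khz`` (kHz).

    ERB = 24.7 (4.37 F_t + 1), the standard moderate-level approximation
    of the auditory-filter bandwidth.
    """
    if f_t_khz <= 0:
        raise ValueError("frequency must be positive")
    return 24.7 * (4.37 * f_t_khz + 1.0)


def protected_region(f_t_hz: float) -> tuple[float, float]:
    """Masker-free interval around the target: one ERB on each side."""
    bw = erb(f_t_hz / 1000.0)
    return (f_t_hz - bw, f_t_hz + bw)


@dataclass(frozen=True)
class MaskerSpec:
    """Masker parameterization: tone duration, spectral density (fpo) and
    temporal density (inter-tone-interval range)."""

    tone_duration_ms: float
    fpo: int
    iti_max_ms: float
    iti_min_ms: float = ITI_MIN_MS
    f_lo: float = MASKER_F_LO
    f_hi: float = MASKER_F_HI

    def __post_init__(self) -> None:
        if self.fpo < 1:
            raise ValueError("fpo must be >= 1")
        if self.iti_max_ms <= self.iti_min_ms:
            raise ValueError("iti_max must exceed iti_min")
        if self.tone_duration_ms <= 0:
            raise ValueError("tone duration must be positive")

    @property
    def miti_ms(self) -> float:
        """Mean inter-tone interval (uniform gap mean)."""
        return 0.5 * (self.iti_min_ms + self.iti_max_ms)

    @property
    def delta_ms(self) -> float:
        """Range of the inter-tone-interval distribution."""
        return self.iti_max_ms - self.iti_min_ms


@dataclass(frozen=True)
class TargetSpec:
    """Regular target stream: fixed-duration tones at ``rate_hz``
    (onset-to-onset), starting 600 ms after masker onset."""

    tone_duration_ms: float
    rate_hz: float
    frequency_hz: float
    start_ms: float = TARGET_START_MS

    def __post_init__(self) -> None:
        if 1000.0 / self.rate_hz < self.tone_duration_ms:
            raise ValueError("successive target tones would overlap")
        if self.frequency_hz not in set(target_frequency_set()):
            raise ValueError(
                f"target frequency {self.frequency_hz} not in the six-frequency set"
            )


@dataclass(frozen=True)
class ToneEvent:
    """One tone in a trial."""

    onset_s: float
    duration_s: float
    frequency_hz: float
    role: str  # "target" | "masker"
    amplitude: float = 1.0


@dataclass
class TrialSpec:
    """Full parameterization of one 12 s trial."""

    trial_id: int
    masker: MaskerSpec
    target: TargetSpec | None
    block: int
    seed: int
    condition: dict = field(default_factory=dict)
    trial_duration_s: float = TRIAL_DURATION_S
    events: list[ToneEvent] | None = None

    @property
    def is_catch(self) -> bool:
        return self.target is None


@dataclass
class ExperimentSchedule:
    """Ordered 243-trial schedule for one experiment."""

    experiment: str
    trials: list[TrialSpec]
    master_seed: int

    def conditions_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            row = dict(t.condition)
            row.update(
                trial_id=t.trial_id,
                block=t.block,
                target_present=not t.is_catch,
                target_frequency_hz=(t.target.frequency_hz if t.target else np.nan),
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            if t.events is None:
                continue
            for e in t.events:
                rows.append(
                    dict(
                        trial_id=t.trial_id,
                        block=t.block,
                        role=e.role,
                        onset_s=e.onset_s,
                        duration_s=e.duration_s,
                        frequency_hz=e.frequency_hz,
                        amplitude=e.amplitude,
                    )
                )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path, events: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.conditions_frame().to_csv(out / f"schedule_{self.experiment}.csv", index=False)
        if events:
            self.events_frame().to_csv(out / f"events_{self.experiment}.csv", index=False)
        meta = dict(experiment=self.experiment, master_seed=self.master_seed,
                    n_trials=len(self.trials))
        (out / f"schedule_{self.experiment}.json").write_text(json.dumps(meta, indent=2))


def masker_frequency_grid(spec: MaskerSpec) -> np.ndarray:
    """Log-spaced masker grid at ``fpo`` frequencies per octave.

    Both endpoints are included; the count is round(fpo * octave span) + 1.
    """
    n_oct = np.log2(spec.f_hi / spec.f_lo)
    n = int(round(spec.fpo * n_oct)) + 1
    return np.geomspace(spec.f_lo, spec.f_hi, n)


def draw_channel_onsets(
    rng: np.random.Generator,
    iti_min_ms: float,
    iti_max_ms: float,
    trial_duration_s: float = TRIAL_DURATION_S,
) -> np.ndarray:
    """Onset times (s) of one masker frequency channel.

    The channel is a renewal process: the first onset is uniform on
    [0, iti_max] and successive onset-to-onset gaps are i.i.d. uniform on
    [iti_min, iti_max], truncated at the trial end.
    """
    if iti_max_ms < iti_min_ms or iti_min_ms < 0:
        raise ValueError("require iti_max >= iti_min >= 0")
    if trial_duration_s <= 0:
        return np.empty(0)
    horizon_ms = trial_duration_s * 1000.0
    mean_gap = max(0.5 * (iti_min_ms + iti_max_ms), 1e-9)
    onsets = [rng.uniform(0.0, iti_max_ms)]
    # draw gaps in batches sized to the expected remaining count
    while onsets[-1] < horizon_ms:
        remaining = horizon_ms - onsets[-1]
        n_batch = max(8, int(remaining / mean_gap * 1.5) + 8)
        gaps = rng.uniform(iti_min_ms, iti_max_ms, size=n_batch)
        new = onsets[-1] + np.cumsum(gaps)
        onsets.extend(new.tolist())
    arr = np.asarray(onsets)
    return arr[arr < horizon_ms] / 1000.0


def _materialize_events(
    masker: MaskerSpec,
    target: TargetSpec | None,
    rng: np.random.Generator,
    protected_center_hz: float,
    trial_duration_s: float = TRIAL_DURATION_S,
) -> list[ToneEvent]:
    lo, hi = protected_region(protected_center_hz)
    grid = masker_frequency_grid(masker)
    grid = grid[(grid < lo) | (grid > hi)]
    dur_s = masker.tone_duration_ms / 1000.0
    events: list[ToneEvent] = []
    for f in grid:
        onsets = draw_channel_onsets(
            rng, masker.iti_min_ms, masker.iti_max_ms, trial_duration_s
        )
        for onset in onsets:
            if onset + dur_s <= trial_duration_s:
                events.append(ToneEvent(onset, dur_s, float(f), "masker"))
    if target is not None:
        t_dur = target.tone_duration_ms / 1000.0
        period_s = 1.0 / target.rate_hz
        onset = target.start_ms / 1000.0
        while onset + t_dur <= trial_duration_s:
            events.append(ToneEvent(onset, t_dur, target.frequency_hz, "target"))
            onset += period_s
    events.sort(key=lambda e: (e.onset_s, e.frequency_hz))
    return events


def build_trial(
    masker: MaskerSpec,
    target: TargetSpec | None,
    rng: np.random.Generator,
    trial_id: int = 0,
    block: int = 1,
    seed: int = 0,
    condition: dict | None = None,
    materialize: bool = True,
) -> TrialSpec:
    """Build one trial; catch trials draw a virtual target frequency whose
    protected region is applied, keeping target and catch maskers
    statistically indistinguishable."""
    if target is not None:
        center = target.frequency_hz
    else:
        center = float(rng.choice(target_frequency_set()))
    events = None
    if materialize:
        events = _materialize_events(masker, target, rng, center)
    return TrialSpec(
        trial_id=trial_id,
        masker=masker,
        target=target,
        block=block,
        seed=seed,
        condition=dict(condition or {}),
        events=events,
    )


# ---------------------------------------------------------------------------
# Experiment presets (three-factor grids, 27 conditions each)

def experiment_conditions(experiment: str) -> list[dict]:
    """The 27-condition grid of one experiment.

    Keys: masker_duration_ms, fpo, iti_max_ms, target_duration_ms, rate_hz.
    """
    conds = []
    if experiment == "I":
        for md in (20, 60, 100):
            for fpo in (4, 16, 64):
                for td in (20, 60, 100):
                    conds.append(dict(masker_duration_ms=md, fpo=fpo,
                                      iti_max_ms=1500, target_duration_ms=td,
                                      rate_hz=1))
    elif experiment == "II":
        for md in (20, 60, 100):
            for fpo in (4, 16, 64):
                for rate in (5, 10, 20):
                    conds.append(dict(masker_duration_ms=md, fpo=fpo,
                                      iti_max_ms=1500, target_duration_ms=20,
                                      rate_hz=rate))
    elif experiment == "III":
        for fpo in (16, 32, 64):
            for iti_max in (300, 1100, 2300):
                for rate in (1, 2, 5):
                    conds.append(dict(masker_duration_ms=20, fpo=fpo,
                                      iti_max_ms=iti_max, target_duration_ms=60,
                                      rate_hz=rate))
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return conds


def masker_spec_for(condition: dict) -> MaskerSpec:
    return MaskerSpec(
        tone_duration_ms=condition["masker_duration_ms"],
        fpo=condition["fpo"],
        iti_max_ms=condition["iti_max_ms"],
    )


def target_spec_for(condition: dict, frequency_hz: float) -> TargetSpec:
    return TargetSpec(
        tone_duration_ms=condition["target_duration_ms"],
        rate_hz=condition["rate_hz"],
        frequency_hz=frequency_hz,
    )


def build_schedule(
    experiment: str,
    master_seed: int,
    materialize: bool = False,
) -> ExperimentSchedule:
    """Full 243-trial schedule: 162 target trials (each of the 27 conditions
    once per target frequency) plus 81 catch trials (each condition three
    times), randomly ordered into 6 blocks of 41 or 40 trials.

    With ``materialize=False`` only trial parameters are generated (the
    per-trial seeds still make later event materialization reproducible).
    """
    conds = experiment_conditions(experiment)
    rng = np.random.default_rng(master_seed)
    freqs = target_frequency_set()
    plan: list[tuple[dict, float | None]] = []
    for cond in conds:
        for f in freqs:
            plan.append((cond, float(f)))
        for _ in range(N_CATCH_TRIALS // len(conds)):
            plan.append((cond, None))
    assert len(plan) == N_TRIALS
    order = rng.permutation(len(plan))
    block_sizes = list(BLOCK_SIZES)
    rng.shuffle(block_sizes)
    block_of = np.repeat(np.arange(1, 7), block_sizes)
    trials = []
    for i, idx in enumerate(order):
        cond, freq = plan[idx]
        seed = int(rng.integers(0, 2**31 - 1))
        trial_rng = np.random.default_rng(seed)
        target = None if freq is None else target_spec_for(cond, freq)
        trial = build_trial(
            masker_spec_for(cond), target, trial_rng,
            trial_id=i, block=int(block_of[i]), seed=seed,
            condition=cond, materialize=materialize,
        )
        trials.append(trial)
    return ExperimentSchedule(experiment=experiment, trials=trials,
                              master_seed=master_seed)


def build_training_block(rng: np.random.Generator) -> Iterator[TrialSpec]:
    """Open-ended stream of training trials: 1 kHz, 100 ms targets at 1 or
    2 Hz over maskers with tone duration 20 or 60 ms and mean inter-tone
    interval 600 or 800 ms; 1/3 of trials are catch trials."""
    trial_id = 0
    while True:
        md = float(rng.choice([20, 60]))
        miti = float(rng.choice([600, 800]))
        fpo = int(rng.choice([4, 16, 64]))
        iti_max = 2 * miti - ITI_MIN_MS
        masker = MaskerSpec(tone_duration_ms=md, fpo=fpo, iti_max_ms=iti_max)
        if rng.uniform() < 1.0 / 3.0:
            target = None
        else:
            rate = float(rng.choice([1, 2]))
            target = TargetSpec(tone_duration_ms=100, rate_hz=rate,
                                frequency_hz=1000.0)
        yield build_trial(masker, target, rng, trial_id=trial_id, block=0,
                          condition=dict(masker_duration_ms=md, fpo=fpo,
                                         iti_max_ms=iti_max))
        trial_id += 1


# ---------------------------------------------------------------------------
# Audio rendering

def _ramped_tone(duration_s: float, frequency_hz: float, sample_rate: int) -> np.ndarray:
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    wave = np.sin(2 * np.pi * frequency_hz * t)
    n_ramp = min(int(round(RAMP_S * sample_rate)), n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / (RAMP_S * sample_rate)))
        wave[:n_ramp] *= ramp
        wave[-n_ramp:] *= ramp[::-1]
    return wave


def _max_polyphony(events: Sequence[ToneEvent]) -> int:
    if not events:
        return 0
    edges = []
    for e in events:
        edges.append((e.onset_s, 1))
        edges.append((e.onset_s + e.duration_s, -1))
    edges.sort()
    best = cur = 0
    for _, d in edges:
        cur += d
        best = max(best, cur)
    return best


def render_audio(trial: TrialSpec, sample_rate: int = DEFAULT_SAMPLE_RATE) -> np.ndarray:
    """Render the trial to a mono float waveform in [-1, 1].

    Each tone gets 10 ms raised-cosine on/off ramps; every tone has the same
    peak amplitude (0 dB target-to-masker ratio) and the common gain is
    0.9 / (max instantaneous polyphony) so that the mixture never clips.
    """
    if trial.events is None:
        raise ValueError("trial events not materialized")
    n_total = int(round(trial.trial_duration_s * sample_rate))
    out = np.zeros(n_total)
    poly = _max_polyphony(trial.events)
    if poly == 0:
        return out
    gain = 0.9 / poly
    for e in trial.events:
        tone = gain * e.amplitude * _ramped_tone(e.duration_s, e.frequency_hz, sample_rate)
        i0 = int(round(e.onset_s * sample_rate))
        out[i0:i0 + len(tone)] += tone[: max(0, n_total - i0)]
    peak = np.max(np.abs(out))
    if peak > 1.0 - 2.0**-15:
        raise RuntimeError("rendered mixture clips despite polyphony gain")
    return out


def write_wav(path: str | Path, waveform: np.ndarray,
              sample_rate: int = DEFAULT_SAMPLE_RATE) -> None:
    """Write a waveform as RIFF WAV, 16-bit PCM, mono (diotic presentation)."""
    pcm = np.clip(waveform, -1.0, 1.0)
    wavfile.write(str(path), sample_rate, (pcm * 32767.0).astype(np.int16))
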