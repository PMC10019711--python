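"""Evidence-accumulation model of target detection.

Activity accumulates toward a saturation level T strictly below the
detection threshold:

    X_{n+1} = X_n + r (T - X_n) + eps_{n+1},   eps ~ N(0, sigma^2)

With 0 < r < 1 the noise-free trajectory is X_n = T (1 - (1 - r)^n), so
the threshold can only be crossed through noise.  First-passage times of
the threshold give a detection-time distribution whose empirical hazard
can be compared qualitatively with the fitted behavioral hazards.  Updates
are tone-locked by default (one step per target tone, step_dt = 1/rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AccumulatorParams:
    """Model configuration; defaults follow the published example
    (T = 0.9, X0 = 0, r = 0.7, sigma = 0.15) with threshold 1."""

    T: float = 0.9
    r: float = 0.7
    sigma: float = 0.15
    x0: float = 0.0
    threshold: float = 1.0
    step_dt_s: float = 1.0
    max_time_s: float = 12.0

    def __post_init__(self) -> None:
        if not (0 < self.r <= 1):
            raise ValueError("rate r must be in (0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.T >= self.threshold:
            raise ValueError("saturation level T must be below the threshold")
        if self.step_dt_s <= 0 or self.max_time_s <= 0:
            raise ValueError("time parameters must be positive")

    @classmethod
    def for_rate(cls, rate_hz: float, **kw) -> "AccumulatorParams":
        """Tone-locked stepping: one update per target tone."""
        return cls(step_dt_s=1.0 / rate_hz, **kw)

    @property
    def n_steps(self) -> int:
        return int(np.floor(self.max_time_s / self.step_dt_s))

    def noise_free(self, n: np.ndarray | int) -> np.ndarray | float:
        """Closed-form sigma = 0 trajectory T (1 - (1-r)^n) + x0 (1-r)^n."""
        decay = (1.0 - self.r) ** np.asarray(n, dtype=float)
        return self.T * (1.0 - decay) + self.x0 * decay


def simulate_path(params: AccumulatorParams, rng: np.random.Generator
                  ) -> tuple[np.ndarray, int | None]:
    """One trajectory (X_0..X_N) and the first step n with X_n >= threshold
    (None if never crossed within max_time)."""
    n_steps = params.n_steps
    xs = np.empty(n_steps + 1)
    xs[0] = params.x0
    crossing = None
    for n in range(1, n_steps + 1):
        eps = rng.normal(0.0, params.sigma) if params.sigma > 0 else 0.0
        xs[n] = xs[n - 1] + params.r * (params.T - xs[n - 1]) + eps
        if crossing is None and xs[n] >= params.threshold:
            crossing = n
    return xs, crossing


@dataclass
class FirstPassageSample:
    """First-passage times (s) with censoring at max_time."""

    times_s: np.ndarray
    censored: np.ndarray
    params: AccumulatorParams

    @property
    def n_trials(self) -> int:
        return len(self.times_s)

    @property
    def crossing_fraction(self) -> float:
        return float(1.0 - self.censored.mean())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s,
                             "censored": self.censored})


def first_passage_times(params: AccumulatorParams, n_trials: int,
                        rng: np.random.Generator) -> FirstPassageSample:
    """Independent replicate simulations, vectorized across trials.

    Censored trials get time = max_time with the censored flag set.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    n_steps = params.n_steps
    x = np.full(n_trials, params.x0)
    cross_step = np.zeros(n_trials, dtype=int)
    for n in range(1, n_steps + 1):
        eps = (rng.normal(0.0, params.sigma, size=n_trials)
               if params.sigma > 0 else 0.0)
        x = x + params.r * (params.T - x) + eps
        newly = (cross_step == 0) & (x >= params.threshold)
        cross_step[newly] = n
    censored = cross_step == 0
    times = np.where(censored, params.max_time_s, cross_step * params.step_dt_s)
    return FirstPassageSample(times_s=times, censored=censored, params=params)


def empirical_hazard(sample: FirstPassageSample | pd.DataFrame,
                     bins: np.ndarray) -> pd.DataFrame:
    """Binned hazard: events in bin / (at-risk at bin start * bin width).

    Censored trials stay in the risk set until their censoring time.
    Bins with an empty risk set are dropped (curve truncated).
    """
    if isinstance(sample, FirstPassageSample):
        times, censored = sample.times_s, sample.censored
    else:
        times = sample["time_s"].to_numpy(float)
        censored = sample["censored"].to_numpy(bool)
    bins = np.asarray(bins, float)
    if len(bins) < 2 or np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be strictly increasing edges")
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        at_risk = int(np.sum(times >= lo))
        if at_risk == 0:
            break
        events = int(np.sum((~censored) & (times > lo) & (times <= hi)))
        rows.append(dict(bin_start=lo, bin_end=hi, at_risk=at_risk,
                         events=events,
                         hazard=events / (at_risk * (hi - lo))))
    return pd.DataFrame(rows)


def smoothed_hazard(hazard: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Optional moving-average smoothing of the binned hazard, clearly
    separate from the raw estimate."""
    out = hazard.copy()
    out["hazard_smoothed"] = (out["hazard"]
                              .rolling(window, center=True, min_periods=1)
                              .mean())
    return out
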