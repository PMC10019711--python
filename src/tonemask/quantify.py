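"""Stimulus-level statistics.

Masker uncertainty is the entropy of the masker tone distribution: each of
the ``fpo`` frequencies per octave is an independent renewal process whose
inter-tone interval is uniform with range ``delta`` (ms), so
H(M) = fpo * ln(delta) in nats.  Masker-target similarity is the signed
duration difference (masker - target, ms).  Spectro-temporal density is
the masker tone rate per octave, fpo / miti.  The segregation time
constant tau is the time at which the detection-time CDF reaches 0.63.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stimulus

SEGREGATION_LEVEL = 0.63


@dataclass(frozen=True)
class StimulusMetrics:
    """Per-condition stimulus statistics."""

    entropy_nats: float
    similarity_ms: float
    std: float  # spectro-temporal density, tones s^-1 oct^-1
    miti_ms: float
    delta_ms: float
    fpo: int


@dataclass(frozen=True)
class SegregationTau:
    """Segregation time constant: first time the CDF reaches ``level``.

    ``censored`` flags a CDF that never reaches the level within the trial.
    """

    tau_s: float | None
    censored: bool
    level: float = SEGREGATION_LEVEL


def masker_entropy(fpo: int, iti_min_ms: float, iti_max_ms: float) -> float:
    """Masker uncertainty H = fpo * ln(iti_max - iti_min), nats (delta in ms)."""
    delta = iti_max_ms - iti_min_ms
    if delta <= 0:
        raise ValueError("inter-tone-interval range must be positive")
    return fpo * math.log(delta)


def similarity(masker_duration_ms: float, target_duration_ms: float) -> float:
    """Masker-target temporal similarity: masker minus target tone duration
    (ms); negative when the target tone is the longer one."""
    if masker_duration_ms <= 0 or target_duration_ms <= 0:
        raise ValueError("durations must be positive")
    return masker_duration_ms - target_duration_ms


def spectro_temporal_density(fpo: int, miti_ms: float) -> float:
    """Masker tones per second per octave: fpo / miti (miti in seconds)."""
    if miti_ms <= 0:
        raise ValueError("mean inter-tone interval must be positive")
    return fpo / (miti_ms / 1000.0)


def condition_metrics(condition: dict) -> StimulusMetrics:
    """Metrics for one experiment condition dict (see stimulus presets)."""
    spec = stimulus.masker_spec_for(condition)
    return StimulusMetrics(
        entropy_nats=masker_entropy(spec.fpo, spec.iti_min_ms, spec.iti_max_ms),
        similarity_ms=similarity(condition["masker_duration_ms"],
                                 condition["target_duration_ms"]),
        std=spectro_temporal_density(spec.fpo, spec.miti_ms),
        miti_ms=spec.miti_ms,
        delta_ms=spec.delta_ms,
        fpo=spec.fpo,
    )


def metrics_table(experiment: str) -> pd.DataFrame:
    """Tidy per-condition metrics for one experiment preset."""
    rows = []
    for cond in stimulus.experiment_conditions(experiment):
        m = condition_metrics(cond)
        rows.append({**cond, "entropy_nats": m.entropy_nats,
                     "similarity_ms": m.similarity_ms, "std": m.std,
                     "miti_ms": m.miti_ms, "delta_ms": m.delta_ms})
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)


def segregation_tau(
    times_s: np.ndarray,
    cdf_values: np.ndarray,
    level: float = SEGREGATION_LEVEL,
) -> SegregationTau:
    """Smallest t with F(t) >= level, linearly interpolated between the
    evaluation points; censored when the level is never reached."""
    t = np.asarray(times_s, dtype=float)
    f = np.asarray(cdf_values, dtype=float)
    if t.shape != f.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("need matching 1-d time and CDF arrays")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    if np.any(np.diff(f) < -1e-12):
        raise ValueError("CDF must be non-decreasing")
    if f.min() < -1e-12 or f.max() > 1 + 1e-12:
        raise ValueError("CDF values must lie in [0, 1]")
    if f[-1] < level:
        return SegregationTau(tau_s=None, censored=True, level=level)
    i = int(np.argmax(f >= level))
    if i == 0 or f[i] == f[i - 1] or t[i] == t[i - 1]:
        return SegregationTau(tau_s=float(t[i]), censored=False, level=level)
    frac = (level - f[i - 1]) / (f[i] - f[i - 1])
    tau = t[i - 1] + frac * (t[i] - t[i - 1])
    return SegregationTau(tau_s=float(tau), censored=False, level=level)
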