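"""Seeded generator of experimental-style gait event streams.

Per-cycle durations are drawn from parametric speed curves -- a power-law
cycle curve ``T(v) = a * v**-k`` and a linear swing curve
``swing(v) = c0 + c1 * v`` -- with multiplicative lognormal noise and a
subject-level random effect on ``a``.  Hemisection effects are injected per
condition on the ipsilesional (right) limb's swing and as a cycle extension
absorbed by stance.  Durations are then accumulated into contact and
stance-end timestamps, yielding :class:`~hemigait.gait_analysis.GaitEventSeries`
collections that exercise the analysis pipeline without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gait_analysis import GaitEventSeries

__all__ = [
    "HemisectionEffect",
    "SynthParams",
    "generate",
    "default_speed_grid",
    "recover_parameters",
]

CONDITIONS = ("tied", "split_Ls_Rf", "split_Lf_Rs")
IPSILESIONAL_LIMB = "right"  # hemisection is always on the right, as in the protocols

#: floor for a single drawn stance duration (guards rare extreme noise draws)
MIN_STANCE_S = 0.02


@dataclass(frozen=True)
class HemisectionEffect:
    """Condition-specific injury effect.

    ``swing_scale`` multiplies the ipsilesional swing curve; ``swing_slope``
    adds an extra speed-proportional swing term (per m/s above the slow-belt
    speed) on the ipsilesional limb; ``stance_add_s`` extends the cycle, and
    because swing is unchanged the extension is absorbed by stance
    (predominantly visible on the contralesional limb).
    """

    swing_scale: float = 1.0
    swing_slope: float = 0.0
    stance_add_s: float = 0.0


def _default_effects() -> dict[str, HemisectionEffect]:
    return {
        "tied": HemisectionEffect(swing_scale=1.25, swing_slope=0.0, stance_add_s=0.03),
        "split_Ls_Rf": HemisectionEffect(swing_scale=1.35, swing_slope=0.75, stance_add_s=0.08),
        "split_Lf_Rs": HemisectionEffect(swing_scale=1.12, swing_slope=0.0, stance_add_s=0.0),
    }


@dataclass(frozen=True)
class SynthParams:
    a: float = 0.72  # s, cycle-curve scale
    k: float = 0.45  # dimensionless, cycle-curve exponent
    c0: float = 0.25  # s, swing baseline
    c1: float = -0.03  # s per m/s, swing slope
    sigma: float = 0.05  # lognormal per-cycle noise (log scale)
    subject_sd: float = 0.04  # lognormal subject random effect on a (log scale)
    n_subjects: int = 6
    cycles_per_speed: int = 15
    slow_speed: float = 0.4  # m/s, fixed slow belt for split protocols
    effects: dict[str, HemisectionEffect] = field(default_factory=_default_effects)

    def cycle_mean(self, v_condition: float) -> float:
        return self.a * v_condition ** (-self.k)

    def swing_mean(self, v_limb: float) -> float:
        return self.c0 + self.c1 * v_limb

    def validate(self, condition: str, speeds) -> None:
        if self.sigma < 0 or self.subject_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        for v in speeds:
            for state in ("intact", "hemisected"):
                for limb in ("left", "right"):
                    cyc, sw = _mean_durations(self, condition, state, v, limb)
                    if cyc - sw <= 0:
                        raise ValueError(
                            f"non-positive mean stance for {state}/{condition}/{limb} "
                            f"at {v} m/s (cycle {cyc:.3f}s, swing {sw:.3f}s)"
                        )


def default_speed_grid(condition: str) -> np.ndarray:
    """Condition speeds used in the protocols: tied 0.4-1.0, split fast 0.5-1.0."""
    if condition == "tied":
        return np.round(np.arange(0.4, 1.01, 0.1), 10)
    return np.round(np.arange(0.5, 1.01, 0.1), 10)


def _limb_speed(params: SynthParams, condition: str, v_condition: float, limb: str) -> float:
    if condition == "tied":
        return v_condition
    slow_limb = "left" if condition == "split_Ls_Rf" else "right"
    return params.slow_speed if limb == slow_limb else v_condition


def _mean_durations(params: SynthParams, condition: str, state: str, v_condition: float, limb: str):
    """Mean cycle and swing duration for one cell, effects included."""
    if condition == "tied":
        v_cycle = v_condition
    else:
        v_cycle = 0.5 * (params.slow_speed + v_condition)
    cycle = params.cycle_mean(v_cycle)
    swing = params.swing_mean(_limb_speed(params, condition, v_condition, limb))
    if state == "hemisected":
        eff = params.effects.get(condition, HemisectionEffect())
        cycle = cycle + eff.stance_add_s
        if limb == IPSILESIONAL_LIMB:
            v_limb = _limb_speed(params, condition, v_condition, limb)
            swing = eff.swing_scale * swing + eff.swing_slope * max(0.0, v_limb - params.slow_speed)
    return cycle, swing


def _cell_rng(seed: int, subject: int, state: str, v_idx: int, limb: str) -> np.random.Generator:
    # fixed per-cell stream so effect injection never shifts other cells' draws
    return np.random.default_rng(
        [seed, subject, 0 if state == "intact" else 1, v_idx, 0 if limb == "left" else 1]
    )


def generate(
    params: SynthParams,
    condition: str,
    speeds=None,
    states=("intact", "hemisected"),
    seed: int = 0,
) -> list[GaitEventSeries]:
    """Generate event series for every subject x state x condition speed.

    Identical seeds yield identical output.  Each (subject, state, speed,
    limb) cell consumes an independent, deterministically derived random
    stream, so changing an effect parameter perturbs only the cells that the
    effect touches.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    speeds = default_speed_grid(condition) if speeds is None else np.asarray(speeds, dtype=float)
    params.validate(condition, speeds)

    out = []
    for subj in range(params.n_subjects):
        subj_rng = np.random.default_rng([seed, 999, subj])
        a_factor = float(np.exp(subj_rng.normal(0.0, params.subject_sd)))
        for state in states:
            for v_idx, v in enumerate(speeds):
                series = GaitEventSeries(
                    subject=f"cat{subj + 1:02d}",
                    state=state,
                    condition=condition,
                    speed_mps=float(v),
                )
                for limb in ("left", "right"):
                    rng = _cell_rng(seed, subj, state, v_idx, limb)
                    cycle_mu, swing_mu = _mean_durations(params, condition, state, float(v), limb)
                    cycle_mu = cycle_mu * a_factor
                    n = params.cycles_per_speed
                    cycles = cycle_mu * np.exp(rng.normal(0.0, params.sigma, n))
                    swings = swing_mu * np.exp(rng.normal(0.0, params.sigma, n))
                    stances = np.maximum(cycles - swings, MIN_STANCE_S)
                    contacts = np.concatenate([[0.0], np.cumsum(cycles)])
                    stance_ends = contacts[:-1] + stances
                    series.contacts[limb] = contacts
                    series.stance_ends[limb] = stance_ends
                series.validate()
                out.append(series)
    return out


def recover_parameters(metrics) -> dict:
    """Per-subject regression estimates of the generator's curve parameters.

    From intact tied per-cycle metrics: the cycle-curve exponent ``-k`` is the
    slope of log(cycle) on log(speed); the swing slope ``c1`` is the slope of
    swing on speed.  Estimates are averaged across subjects with the standard
    error of that subject-level mean.
    """
    sub = metrics[(metrics["state"] == "intact") & (metrics["condition"] == "tied")]
    if sub.empty:
        raise ValueError("parameter recovery requires intact tied metrics")
    neg_k, c1 = [], []
    for _, df in sub.groupby("subject"):
        x = np.log(df["speed_mps"].to_numpy(dtype=float))
        y = np.log(df["cycle_s"].to_numpy(dtype=float))
        neg_k.append(np.polyfit(x, y, 1)[0])
        c1.append(np.polyfit(df["speed_mps"].to_numpy(dtype=float), df["swing_s"].to_numpy(dtype=float), 1)[0])
    neg_k, c1 = np.asarray(neg_k), np.asarray(c1)
    n = neg_k.size
    return {
        "neg_k_mean": float(neg_k.mean()),
        "neg_k_se": float(neg_k.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        "c1_mean": float(c1.mean()),
        "c1_se": float(c1.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        "n_subjects": int(n),
    }
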