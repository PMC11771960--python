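"""Numerical integration, phase-event detection, gait metrics and speed sweeps."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    SIDES,
    BeltCondition,
    DriveSchedule,
    LesionSpec,
    Network,
    UnitState,
    rhs,
)

__all__ = [
    "SimulationResult",
    "PhaseEvents",
    "GaitMetrics",
    "SimulationError",
    "InsufficientCyclesError",
    "default_initial_state",
    "simulate",
    "detect_events",
    "compute_gait_metrics",
    "speed_sweep",
    "find_crossing",
    "find_crossing_in_sweep",
    "write_sweep_csv",
    "write_events_csv",
]

SWEEP_COLUMNS = [
    "condition",
    "model_state",
    "beta_L",
    "beta_R",
    "side",
    "cycle_s",
    "stance_s",
    "swing_s",
    "duty_factor",
    "n_cycles",
    "regime",
]


class SimulationError(RuntimeError):
    """Solver failure; carries the last valid time reached."""

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class InsufficientCyclesError(RuntimeError):
    """Fewer than the required number of complete cycles were detected."""


@dataclass
class SimulationResult:
    t: np.ndarray  # s, uniform 1 ms grid
    f: np.ndarray  # (n_units, n_t) unit outputs in [0, 1]
    V: np.ndarray
    h: np.ndarray
    chi: np.ndarray  # (2, n_t)
    feedback: np.ndarray  # (4, n_t): SF_E1_L, SF_E1_R, SF_E2_L, SF_E2_R (gated)
    network: Network
    belts: BeltCondition
    drives: DriveSchedule
    diagnostics: dict = field(default_factory=dict)

    def output_of(self, side: str, name: str) -> np.ndarray:
        return self.f[self.network.index(side, name)]

    @property
    def final_state(self) -> np.ndarray:
        return np.concatenate([self.V[:, -1], self.h[:, -1], self.chi[:, -1]])


@dataclass
class PhaseEvents:
    """Per-side flexion onset/offset times in seconds.

    Onsets and offsets alternate, starting with an onset; both lists are
    strictly increasing.
    """

    onsets: dict[str, np.ndarray]
    offsets: dict[str, np.ndarray]

    def validate(self) -> None:
        for side in self.onsets:
            on, off = self.onsets[side], self.offsets[side]
            if np.any(np.diff(on) <= 0) or np.any(np.diff(off) <= 0):
                raise ValueError(f"{side}: event times not strictly increasing")
            k = min(len(on), len(off))
            if k and not np.all((off[:k] > on[:k])):
                raise ValueError(f"{side}: onsets and offsets do not alternate")


@dataclass
class GaitMetrics:
    side: str
    cycle_s: float
    stance_s: float
    swing_s: float
    duty_factor: float
    n_cycles: int
    cycle_sd: float
    stance_sd: float
    swing_sd: float
    cycles: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    stances: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    swings: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


def default_initial_state(network: Network) -> np.ndarray:
    """Deterministic initial condition with a small left-leading asymmetry.

    All units start at their leak reversal with moderately recovered
    inactivation; the left flexor is depolarized slightly to break the
    left/right symmetry toward the antiphase (alternating) solution.
    """
    cn = network.compiled()
    V0 = cn.E_leak.copy()
    V0[network.index("left", "F")] = -45.0
    h0 = np.full(cn.burster_idx.size, 0.7)
    chi0 = np.zeros(2)
    return np.concatenate([V0, h0, chi0])


def simulate(
    network: Network,
    belts: BeltCondition,
    duration: float = 30.0,
    drives: DriveSchedule | None = None,
    initial_state: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = 5e-3,
    output_step: float = 1e-3,
) -> SimulationResult:
    """Integrate the network over ``duration`` seconds.

    Drives default to the belt-derived schedule for the network's lesion
    state.  Integration uses LSODA (stiff-capable, adaptive); the trajectory
    is reported on a uniform 1 ms grid.
    """
    if drives is None:
        drives = DriveSchedule.from_belts(
            belts, network.lesion, gamma=network.constants.get("gamma_drive", 0.5)
        )
    cn = network.compiled()
    y0 = initial_state if initial_state is not None else default_initial_state(network)

    t_eval = np.arange(0.0, duration + output_step / 2, output_step)
    sol = solve_ivp(
        rhs,
        (0.0, duration),
        y0,
        args=(cn, drives, belts),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else None
        raise SimulationError(f"solver failed: {sol.message}", last_valid_time=last)

    n = cn.C.size
    nb = cn.burster_idx.size
    V = sol.y[:n]
    h = sol.y[n : n + nb]
    chi = sol.y[n + nb : n + nb + 2]
    f = np.clip((V - cn.V_threshold) / (cn.V_max - cn.V_threshold), 0.0, 1.0)

    f_E = f[cn.E_idx]
    active = np.clip(f_E / cn.ext_on_scale, 0.0, 1.0)
    beta = belts.beta[:, None]
    sf_e1 = cn.k_e1 * beta * np.minimum(chi, 1.0) * active
    sf_e2 = cn.k_e2 * f_E * active
    gains = np.maximum(0.0, 1.0 - cn.k_psi * drives.vector[:2])
    feedback = np.vstack([sf_e1 * gains[:, None], sf_e2 * gains[:, None]])
    feedback = feedback[[0, 1, 2, 3]]

    return SimulationResult(
        t=sol.t,
        f=f,
        V=V,
        h=h,
        chi=chi,
        feedback=feedback,
        network=network,
        belts=belts,
        drives=drives,
        diagnostics={"nfev": sol.nfev, "message": sol.message, "n_lsoda_steps": len(sol.t)},
    )


def _threshold_crossings(t: np.ndarray, x: np.ndarray, threshold: float):
    """Sub-step up/down crossing times of ``x`` through ``threshold``."""
    above = x > threshold
    idx_up = np.flatnonzero(~above[:-1] & above[1:])
    idx_dn = np.flatnonzero(above[:-1] & ~above[1:])

    def interp(idx):
        x0, x1 = x[idx], x[idx + 1]
        frac = (threshold - x0) / (x1 - x0)
        return t[idx] + frac * (t[idx + 1] - t[idx])

    return interp(idx_up) if idx_up.size else np.array([]), interp(idx_dn) if idx_dn.size else np.array([])


def _debounce(times: np.ndarray, min_gap: float) -> np.ndarray:
    if times.size == 0:
        return times
    keep = [times[0]]
    for tt in times[1:]:
        if tt - keep[-1] >= min_gap:
            keep.append(tt)
    return np.asarray(keep)


def detect_events(
    result: SimulationResult,
    threshold: float = 0.05,
    transient: float = 10.0,
    debounce: float = 0.05,
    min_cycles: int = 3,
) -> PhaseEvents:
    """Extract flexion onset/offset times from the flexor output traces.

    Onset = upward crossing of the flexor output through ``threshold``,
    offset = downward crossing, both with linear sub-step interpolation and a
    minimum gap ``debounce`` between same-type events.  Events in the first
    ``transient`` seconds are discarded.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    onsets, offsets = {}, {}
    for side in SIDES:
        x = result.output_of(side, "F")
        up, dn = _threshold_crossings(result.t, x, threshold)
        up = _debounce(up[up >= transient], debounce)
        dn = _debounce(dn[dn >= transient], debounce)
        if up.size:
            dn = dn[dn > up[0]]  # start the series with an onset
        onsets[side], offsets[side] = up, dn
        if up.size < min_cycles + 1:
            raise InsufficientCyclesError(
                f"{side}: {max(0, up.size - 1)} complete cycles after transient, "
                f"need >= {min_cycles}"
            )
    ev = PhaseEvents(onsets=onsets, offsets=offsets)
    ev.validate()
    return ev


def compute_gait_metrics(events: PhaseEvents, min_cycles: int = 3) -> dict[str, GaitMetrics]:
    """Per-side temporal metrics from phase events.

    cycle_i = onset_{i+1} - onset_i; swing_i = offset_i - onset_i;
    stance_i = cycle_i - swing_i (exact by construction);
    duty factor = mean stance / mean cycle.
    """
    events.validate()
    out = {}
    for side, on in events.onsets.items():
        off = events.offsets[side]
        n_cyc = on.size - 1
        if n_cyc < min_cycles:
            raise InsufficientCyclesError(f"{side}: {n_cyc} cycles, need >= {min_cycles}")
        cycles = np.diff(on)
        swings = off[:n_cyc] - on[:n_cyc]
        if np.any(swings <= 0) or np.any(swings >= cycles):
            raise ValueError(f"{side}: event ordering violated (swing outside cycle)")
        stances = cycles - swings
        out[side] = GaitMetrics(
            side=side,
            cycle_s=float(np.mean(cycles)),
            stance_s=float(np.mean(stances)),
            swing_s=float(np.mean(swings)),
            duty_factor=float(np.mean(stances) / np.mean(cycles)),
            n_cycles=int(n_cyc),
            cycle_sd=float(np.std(cycles, ddof=1)) if n_cyc > 1 else 0.0,
            stance_sd=float(np.std(stances, ddof=1)) if n_cyc > 1 else 0.0,
            swing_sd=float(np.std(swings, ddof=1)) if n_cyc > 1 else 0.0,
            cycles=cycles,
            stances=stances,
            swings=swings,
        )
    return out


def _belts_for(protocol: str, beta: float) -> BeltCondition:
    if protocol == "tied":
        return BeltCondition(beta, beta, "tied")
    if protocol == "split_Ls_Rf":
        return BeltCondition(0.4, beta, "split_Ls_Rf")
    if protocol == "split_Lf_Rs":
        return BeltCondition(beta, 0.4, "split_Lf_Rs")
    raise ValueError(f"unknown protocol {protocol!r}")


def speed_sweep(
    network: Network,
    protocol: str,
    beta_grid,
    duration: float = 30.0,
    transient: float = 10.0,
    warm_start: bool = True,
    classify: bool = False,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Run one simulation per grid point and tabulate per-side gait metrics.

    For split protocols the grid applies to the fast belt (the slow belt is
    held at 0.4).  Each point is warm-started from the previous point's final
    state to shorten transients.  Per-point failures are recorded as flagged
    rows (NaN metrics, regime="failed: ..."), not raised.
    """
    rows = []
    state = None
    for beta in np.atleast_1d(np.asarray(beta_grid, dtype=float)):
        belts = _belts_for(protocol, float(beta))
        regime_by_side = {s: "" for s in SIDES}
        try:
            res = simulate(network, belts, duration=duration, initial_state=state)
            if warm_start:
                state = res.final_state
            events = detect_events(res, threshold=threshold, transient=transient)
            metrics = compute_gait_metrics(events)
            if classify:
                from .regimes import classify_regime

                for s in SIDES:
                    regime_by_side[s] = classify_regime(network, s, belts).label
            for s in SIDES:
                m = metrics[s]
                rows.append(
                    {
                        "condition": protocol,
                        "model_state": network.lesion.state,
                        "beta_L": belts.beta_left,
                        "beta_R": belts.beta_right,
                        "side": s,
                        "cycle_s": m.cycle_s,
                        "stance_s": m.stance_s,
                        "swing_s": m.swing_s,
                        "duty_factor": m.duty_factor,
                        "n_cycles": m.n_cycles,
                        "regime": regime_by_side[s],
                    }
                )
        except (SimulationError, InsufficientCyclesError, ValueError) as exc:
            for s in SIDES:
                rows.append(
                    {
                        "condition": protocol,
                        "model_state": network.lesion.state,
                        "beta_L": belts.beta_left,
                        "beta_R": belts.beta_right,
                        "side": s,
                        "cycle_s": np.nan,
                        "stance_s": np.nan,
                        "swing_s": np.nan,
                        "duty_factor": np.nan,
                        "n_cycles": 0,
                        "regime": f"failed: {exc}",
                    }
                )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


@dataclass
class CrossingResult:
    roots: list[float]
    monotonic: bool

    @property
    def value(self) -> float | None:
        return self.roots[0] if self.roots else None


def find_crossing(beta, swing, stance) -> CrossingResult:
    """Locate swing/stance equality by linear interpolation on a grid.

    Returns all interpolated roots of ``swing - stance``; ``monotonic`` is
    False when more than one sign change is present.  Grid points where the
    difference is exactly zero count as roots.
    """
    beta = np.asarray(beta, dtype=float)
    d = np.asarray(swing, dtype=float) - np.asarray(stance, dtype=float)
    if beta.size < 2:
        raise ValueError("need at least 2 grid rows to bracket a crossing")
    roots = []
    for i in range(d.size - 1):
        d0, d1 = d[i], d[i + 1]
        if d0 == 0.0:
            roots.append(float(beta[i]))
        elif d0 * d1 < 0:
            roots.append(float(beta[i] + (beta[i + 1] - beta[i]) * d0 / (d0 - d1)))
    if d[-1] == 0.0:
        roots.append(float(beta[-1]))
    return CrossingResult(roots=roots, monotonic=len(roots) <= 1)


def find_crossing_in_sweep(sweep: pd.DataFrame, side: str) -> CrossingResult:
    """Apply :func:`find_crossing` to one side of a sweep table.

    The abscissa is the belt parameter that varies across rows (the fast
    belt for split protocols, the common belt for tied).
    """
    sub = sweep[sweep["side"] == side].dropna(subset=["swing_s", "stance_s"])
    var = "beta_R" if sub["beta_R"].nunique() > sub["beta_L"].nunique() else "beta_L"
    sub = sub.sort_values(var)
    if len(sub) < 2:
        return CrossingResult(roots=[], monotonic=True)
    return find_crossing(sub[var].to_numpy(), sub["swing_s"].to_numpy(), sub["stance_s"].to_numpy())


def write_sweep_csv(sweep: pd.DataFrame, path) -> None:
    sweep.to_csv(path, index=False, float_format="%.6f")


def write_events_csv(events: PhaseEvents, path) -> None:
    rows = []
    for side in SIDES:
        for tt in events.onsets[side]:
            rows.append({"time_s": tt, "side": side, "event_type": "flexion_onset"})
        for tt in events.offsets[side]:
            rows.append({"time_s": tt, "side": side, "event_type": "flexion_offset"})
    df = pd.DataFrame(rows).sort_values(["time_s", "side"]).reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.6f")
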