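"""Operational classification of a rhythm generator's operating regime.

A side's RG is probed with a fixed decision procedure:

1. simulate the side's RG in isolation (commissural inputs removed) with all
   phasic feedback frozen at zero; if no rhythmic alternation appears, the
   label is ``state_machine`` when the full model (feedback intact) does
   oscillate on that side, else ``non_oscillating``;
2. otherwise isolate the flexor half-center, holding its synaptic
   conductances constant at the time-averaged values it received in situ; if
   it bursts intrinsically in that steady environment the regime is
   ``flexor_driven``;
3. otherwise, the rhythm requires the coupled pair's mutual inhibition:
   ``half_center``.

"Oscillation" means at least 3 flexor bursts within the classification
window (30 s with a 10 s transient).  Borderline trajectories (1-2 bursts)
are flagged.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    SIDES,
    BeltCondition,
    Connectome,
    DriveSchedule,
    Network,
)
from .sim_engine import SimulationError, simulate

__all__ = ["RegimeLabel", "RegimeResult", "classify_regime", "count_bursts"]

REGIME_LABELS = ("state_machine", "flexor_driven", "half_center", "non_oscillating")

#: classification window (s) and transient (s)
WINDOW = 30.0
TRANSIENT = 10.0
MIN_BURSTS = 3


@dataclass(frozen=True)
class RegimeLabel:
    value: str

    def __post_init__(self):
        if self.value not in REGIME_LABELS:
            raise ValueError(f"unknown regime label {self.value!r}")

    def __str__(self):
        return self.value


@dataclass(frozen=True)
class RegimeResult:
    label: str
    side: str
    ambiguous: bool = False
    detail: str = ""

    def __str__(self):
        return self.label


def count_bursts(t: np.ndarray, f: np.ndarray, threshold: float = 0.05, transient: float = TRANSIENT) -> int:
    """Number of upward threshold crossings of an output trace after transient."""
    mask = t >= transient
    x = f[mask]
    above = x > threshold
    return int(np.count_nonzero(~above[:-1] & above[1:]))


def _zero_feedback(network: Network) -> Network:
    net = copy.deepcopy(network)
    net.constants["k_e1"] = 0.0
    net.constants["k_e2"] = 0.0
    net._compiled = None
    return net


def _isolate_side(network: Network, side: str) -> Network:
    """Remove connections crossing the midline, keeping within-side circuitry."""
    net = copy.deepcopy(network)
    conns = [c for c in net.connectome.connections if c.source_side == c.target_side]
    drives = [d for d in net.connectome.drives if d.drive_side == d.target_side]
    fb = [f for f in net.connectome.feedback if f.feedback_side == f.target_side]
    net.connectome = Connectome(connections=conns, drives=drives, feedback=fb)
    net._compiled = None
    return net


def _side_bursts(network: Network, side: str, belts: BeltCondition, drives, duration=WINDOW) -> tuple[int, int]:
    """Counts of flexor and extensor bursts on one side (rhythmic alternation
    requires both half-centers to cycle, not a free-running flexor alone)."""
    try:
        res = simulate(network, belts, duration=duration, drives=drives)
    except (SimulationError, FloatingPointError):
        return 0, 0
    return (
        count_bursts(res.t, res.output_of(side, "F")),
        count_bursts(res.t, res.output_of(side, "E")),
    )


def _mean_flexor_conductances(network: Network, side: str, belts: BeltCondition, drives) -> tuple[float, float]:
    """Time-averaged excitatory and inhibitory conductance onto the flexor in situ."""
    cn = network.compiled()
    res = simulate(network, belts, duration=WINDOW, drives=drives)
    sel = res.t >= TRANSIENT
    g_exc = cn.W_exc @ res.f[:, sel] + (cn.D_exc @ res.drives.vector)[:, None]
    g_exc = g_exc + cn.FB_exc @ res.feedback[:, sel]
    g_inh = cn.W_inh @ res.f[:, sel] + (cn.D_inh @ res.drives.vector)[:, None]
    g_inh = g_inh + cn.FB_inh @ res.feedback[:, sel]
    i = network.index(side, "F")
    return float(np.mean(g_exc[i])), float(np.mean(g_inh[i]))


def isolated_burster_bursts(
    spec,
    g_exc: float,
    g_inh: float = 0.0,
    duration: float = WINDOW,
    E_syn_exc: float = -10.0,
    E_syn_inh: float = -75.0,
) -> int:
    """Simulate one burster with constant synaptic conductances; count bursts."""

    def rhs(t, y):
        V, h = y
        m = 1.0 / (1.0 + np.exp(-(V - spec.theta_m) / spec.sigma_m))
        I = (
            -spec.g_nap * m * h * (V - spec.E_na)
            - spec.g_leak * (V - spec.E_leak)
            - g_exc * (V - E_syn_exc)
            - g_inh * (V - E_syn_inh)
        )
        h_inf = 1.0 / (1.0 + np.exp((V - spec.theta_h) / spec.sigma_h))
        tau = (spec.tau_h0 / 1000.0) / np.cosh((V - spec.theta_h) / (2.0 * spec.sigma_h))
        return [1000.0 * I / spec.C, (h_inf - h) / tau]

    sol = solve_ivp(
        rhs,
        (0.0, duration),
        [spec.E_leak, 0.7],
        method="LSODA",
        t_eval=np.arange(0.0, duration, 0.001),
        rtol=1e-8,
        atol=1e-10,
        max_step=5e-3,
    )
    f = np.clip((sol.y[0] + 50.0) / 50.0, 0.0, 1.0)
    return count_bursts(sol.t, f)


def classify_regime(
    network: Network,
    side: str,
    belts: BeltCondition,
    drives: DriveSchedule | None = None,
) -> RegimeResult:
    """Classify the operating regime of one side's rhythm generator."""
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    if drives is None:
        drives = DriveSchedule.from_belts(
            belts, network.lesion, gamma=network.constants.get("gamma_drive", 0.5)
        )

    iso = _isolate_side(_zero_feedback(network), side)
    nf_iso, ne_iso = _side_bursts(iso, side, belts, drives)
    alternating_iso = min(nf_iso, ne_iso) >= MIN_BURSTS

    if not alternating_iso:
        nf_full, ne_full = _side_bursts(network, side, belts, drives)
        if min(nf_full, ne_full) >= MIN_BURSTS:
            return RegimeResult(
                "state_machine", side, ambiguous=0 < min(nf_iso, ne_iso),
                detail=(
                    f"no alternation without feedback (F/E bursts {nf_iso}/{ne_iso}), "
                    f"full model rhythmic ({nf_full}/{ne_full})"
                ),
            )
        return RegimeResult(
            "non_oscillating", side, ambiguous=0 < min(nf_full, ne_full),
            detail=f"no alternation with ({nf_full}/{ne_full}) or without ({nf_iso}/{ne_iso}) feedback",
        )

    g_exc, g_inh = _mean_flexor_conductances(iso, side, belts, drives)
    spec = network.populations[f"{side}_F"]
    n_single = isolated_burster_bursts(spec, g_exc, g_inh)
    if n_single >= MIN_BURSTS:
        return RegimeResult(
            "flexor_driven", side, ambiguous=False,
            detail=f"flexor bursts alone at g_exc={g_exc:.2f}, g_inh={g_inh:.2f} nS ({n_single} bursts)",
        )
    return RegimeResult(
        "half_center", side, ambiguous=0 < n_single,
        detail=f"pair alternates ({nf_iso}/{ne_iso} bursts) but flexor alone does not ({n_single})",
    )
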