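"""Bilateral spinal locomotor circuit: populations, wiring, drives and feedback.

The circuit consists of two rhythm generators (one per side), each built from
a flexor (F) and an extensor (E) conditional burster coupled through
inhibitory interneurons (InF, InE), plus commissural pathways (V0D, V0V/V2a,
V3, V3E, Ini) that coordinate left-right alternation.  Supraspinal drives
(alpha to flexor circuits, gamma to extensors) and two belt-speed-dependent
somatosensory feedback signals (SF-E1, SF-E2) enter the network at defined
points; feedback entries are attenuated by drive-dependent presynaptic
inhibition.

Membrane dynamics follow the activity-based (non-spiking) formulation:
bursters carry a persistent-sodium current with slow inactivation ``h``;
simple units are leaky integrators.  Unit output is a piecewise-linear
function of membrane potential, bounded in [0, 1].
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "POPULATION_LABELS",
    "BURSTER_LABELS",
    "SIDES",
    "PopulationSpec",
    "Connection",
    "DriveInput",
    "FeedbackInput",
    "Connectome",
    "DriveSchedule",
    "BeltCondition",
    "LesionSpec",
    "UnitState",
    "FeedbackState",
    "Network",
    "ConfigError",
    "load_default_config",
    "build_network",
    "apply_lesion",
    "presynaptic_gain",
    "output",
    "compute_feedback",
    "rhs",
]

POPULATION_LABELS = ("F", "E", "InF", "InE", "V0D", "V0V", "V2a", "V3", "V3E", "Ini")
BURSTER_LABELS = ("F", "E")
SIDES = ("left", "right")

#: order of the drive vector used throughout: (alpha_L, alpha_R, gamma_L, gamma_R)
DRIVE_ORDER = (("alpha", "left"), ("alpha", "right"), ("gamma", "left"), ("gamma", "right"))
#: order of the feedback vector: (SF_E1_L, SF_E1_R, SF_E2_L, SF_E2_R)
FEEDBACK_ORDER = (("SF_E1", "left"), ("SF_E1", "right"), ("SF_E2", "left"), ("SF_E2", "right"))


class ConfigError(ValueError):
    """Raised for invalid network configuration input."""


def _other(side: str) -> str:
    return "right" if side == "left" else "left"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """Intrinsic parameters of one unit (one population, one side)."""

    name: str
    side: str
    kind: str  # "burster" | "simple"
    C: float = 20.0  # pF
    g_leak: float = 4.5  # nS
    E_leak: float = -62.5  # mV
    # persistent-Na parameters; meaningful for bursters only
    g_nap: float = 0.0  # nS
    E_na: float = 50.0  # mV
    theta_m: float = -40.0  # mV
    sigma_m: float = 6.0  # mV
    theta_h: float = -55.0  # mV
    sigma_h: float = 4.0  # mV
    tau_h0: float = 600.0  # ms

    def __post_init__(self) -> None:
        if self.name not in POPULATION_LABELS:
            raise ConfigError(f"unknown population label {self.name!r}")
        if self.side not in SIDES:
            raise ConfigError(f"unknown side {self.side!r}")
        expected = "burster" if self.name in BURSTER_LABELS else "simple"
        if self.kind != expected:
            raise ConfigError(f"population {self.name} must be kind={expected!r}")

    @property
    def key(self) -> str:
        return f"{self.side}_{self.name}"


@dataclass(frozen=True)
class Connection:
    source: str  # population label
    source_side: str
    target: str
    target_side: str
    weight: float  # nS, >= 0
    sign: str  # "excitatory" | "inhibitory"

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ConfigError(f"negative weight on {self.source}->{self.target}")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ConfigError(f"bad sign {self.sign!r}")

    def mirrored(self) -> "Connection":
        return replace(self, source_side=_other(self.source_side), target_side=_other(self.target_side))


@dataclass(frozen=True)
class DriveInput:
    drive: str  # "alpha" | "gamma"
    drive_side: str
    target: str
    target_side: str
    weight: float
    sign: str

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ConfigError(f"negative drive weight on {self.drive}->{self.target}")

    def mirrored(self) -> "DriveInput":
        return replace(self, drive_side=_other(self.drive_side), target_side=_other(self.target_side))


@dataclass(frozen=True)
class FeedbackInput:
    feedback: str  # "SF_E1" | "SF_E2"
    feedback_side: str
    target: str
    target_side: str
    weight: float
    sign: str
    gated: bool = True

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ConfigError(f"negative feedback weight on {self.feedback}->{self.target}")

    def mirrored(self) -> "FeedbackInput":
        return replace(self, feedback_side=_other(self.feedback_side), target_side=_other(self.target_side))

    @property
    def gate_drive(self) -> tuple[str, str]:
        """The drive acting as presynaptic gate: always the ipsilateral alpha."""
        return ("alpha", self.feedback_side)


@dataclass
class Connectome:
    connections: list[Connection] = field(default_factory=list)
    drives: list[DriveInput] = field(default_factory=list)
    feedback: list[FeedbackInput] = field(default_factory=list)

    def check_mirror_symmetry(self) -> None:
        """Every connection must have an equal-weight side-swapped twin."""
        pool = set((c.source, c.source_side, c.target, c.target_side, c.weight, c.sign) for c in self.connections)
        for c in self.connections:
            m = c.mirrored()
            if (m.source, m.source_side, m.target, m.target_side, m.weight, m.sign) not in pool:
                raise ConfigError(f"connection {c} lacks its mirrored twin")


@dataclass(frozen=True)
class BeltCondition:
    """Left/right belt-speed parameters; beta is numerically the speed in m/s."""

    beta_left: float
    beta_right: float
    protocol: str = "tied"  # "tied" | "split_Ls_Rf" | "split_Lf_Rs"

    def __post_init__(self) -> None:
        for b in (self.beta_left, self.beta_right):
            if not (0.3 <= b <= 1.1):
                raise ConfigError(f"belt parameter {b} outside [0.3, 1.1]")
        if self.protocol == "tied":
            if self.beta_left != self.beta_right:
                raise ConfigError("tied protocol requires beta_left == beta_right")
        elif self.protocol == "split_Ls_Rf":
            if not (self.beta_left == 0.4 <= self.beta_right):
                raise ConfigError("split_Ls_Rf requires beta_left == 0.4 <= beta_right")
        elif self.protocol == "split_Lf_Rs":
            if not (self.beta_right == 0.4 <= self.beta_left):
                raise ConfigError("split_Lf_Rs requires beta_right == 0.4 <= beta_left")
        else:
            raise ConfigError(f"unknown protocol {self.protocol!r}")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta_left, self.beta_right])


LESION_STATES = ("intact", "right_hemisected", "left_hemisected", "transected")


@dataclass(frozen=True)
class LesionSpec:
    state: str = "intact"

    def __post_init__(self) -> None:
        if self.state not in LESION_STATES:
            raise ConfigError(f"unknown lesion state {self.state!r}")

    @property
    def hemisected_sides(self) -> tuple[str, ...]:
        return {
            "intact": (),
            "right_hemisected": ("right",),
            "left_hemisected": ("left",),
            "transected": ("left", "right"),
        }[self.state]


@dataclass(frozen=True)
class DriveSchedule:
    """Supraspinal drive values; hemisected sides are forced to zero."""

    alpha_left: float
    alpha_right: float
    gamma_left: float
    gamma_right: float

    def __post_init__(self) -> None:
        for d in self.vector:
            if d < 0 or d > 1.1:
                raise ConfigError(f"drive value {d} outside [0, 1.1]")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.alpha_left, self.alpha_right, self.gamma_left, self.gamma_right])

    @classmethod
    def from_belts(
        cls,
        belts: BeltCondition,
        lesion: LesionSpec = LesionSpec("intact"),
        gamma: float = 0.5,
        alpha_override: Mapping[str, float] | None = None,
    ) -> "DriveSchedule":
        """Map belt speeds to drives: alpha_i = beta_i on intact sides, gamma constant.

        ``alpha_override`` replaces the identity map per side (used for drive
        scans); hemisected sides are zeroed regardless.
        """
        hemis = lesion.hemisected_sides
        vals = {}
        for side, beta in zip(SIDES, (belts.beta_left, belts.beta_right)):
            a = beta if alpha_override is None else alpha_override.get(side, beta)
            vals[f"alpha_{side}"] = 0.0 if side in hemis else a
            vals[f"gamma_{side}"] = 0.0 if side in hemis else gamma
        return cls(vals["alpha_left"], vals["alpha_right"], vals["gamma_left"], vals["gamma_right"])


@dataclass
class UnitState:
    """Membrane potentials for every unit plus burster inactivation variables."""

    V: np.ndarray  # mV, one per population (length 20)
    h: np.ndarray  # in [0, 1], one per burster (length 4)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.V, self.h])

    @property
    def size(self) -> int:
        return self.V.size + self.h.size


@dataclass
class FeedbackState:
    sf_e1_left: float
    sf_e1_right: float
    sf_e2_left: float
    sf_e2_right: float
    chi_left: float
    chi_right: float

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.sf_e1_left, self.sf_e1_right, self.sf_e2_left, self.sf_e2_right])


# ---------------------------------------------------------------------------
# network container and compilation
# ---------------------------------------------------------------------------


@dataclass
class Network:
    populations: dict[str, PopulationSpec]
    connectome: Connectome
    constants: dict[str, float]
    lesion: LesionSpec = LesionSpec("intact")

    _compiled: "CompiledNetwork | None" = field(default=None, repr=False, compare=False)

    # -- indexing ---------------------------------------------------------
    @property
    def unit_keys(self) -> list[str]:
        return [f"{side}_{name}" for side in SIDES for name in POPULATION_LABELS]

    @property
    def burster_keys(self) -> list[str]:
        return [f"{side}_{name}" for side in SIDES for name in BURSTER_LABELS]

    def index(self, side: str, name: str) -> int:
        return SIDES.index(side) * len(POPULATION_LABELS) + POPULATION_LABELS.index(name)

    @property
    def n_units(self) -> int:
        return len(self.unit_keys)

    @property
    def n_bursters(self) -> int:
        return len(self.burster_keys)

    @property
    def state_size(self) -> int:
        """Unit-state vector length: membrane potentials + inactivation variables."""
        return self.n_units + self.n_bursters

    # -- structural equality for lesion algebra ---------------------------
    def structurally_equal(self, other: "Network") -> bool:
        return (
            self.populations == other.populations
            and self.connectome.connections == other.connectome.connections
            and self.connectome.drives == other.connectome.drives
            and self.connectome.feedback == other.connectome.feedback
            and self.constants == other.constants
        )

    def compiled(self) -> "CompiledNetwork":
        if self._compiled is None:
            self._compiled = CompiledNetwork(self)
        return self._compiled


class CompiledNetwork:
    """Dense-matrix view of a :class:`Network` used by the right-hand side."""

    def __init__(self, net: Network):
        n = net.n_units
        self.net = net
        self.C = np.empty(n)
        self.g_leak = np.empty(n)
        self.E_leak = np.empty(n)
        self.burster_idx = np.array([net.index(s, p) for s in SIDES for p in BURSTER_LABELS])
        nb = self.burster_idx.size
        self.g_nap = np.empty(nb)
        self.E_na = np.empty(nb)
        self.theta_m = np.empty(nb)
        self.sigma_m = np.empty(nb)
        self.theta_h = np.empty(nb)
        self.sigma_h = np.empty(nb)
        self.tau_h0 = np.empty(nb)  # seconds

        for key in net.unit_keys:
            spec = net.populations[key]
            i = net.index(spec.side, spec.name)
            self.C[i] = spec.C
            self.g_leak[i] = spec.g_leak
            self.E_leak[i] = spec.E_leak
        for j, key in enumerate(net.burster_keys):
            spec = net.populations[key]
            self.g_nap[j] = spec.g_nap
            self.E_na[j] = spec.E_na
            self.theta_m[j] = spec.theta_m
            self.sigma_m[j] = spec.sigma_m
            self.theta_h[j] = spec.theta_h
            self.sigma_h[j] = spec.sigma_h
            self.tau_h0[j] = spec.tau_h0 / 1000.0

        self.W_exc = np.zeros((n, n))
        self.W_inh = np.zeros((n, n))
        for c in net.connectome.connections:
            src = net.index(c.source_side, c.source)
            tgt_side = c.target_side if c.target_side in SIDES else None
            tgt = net.index(tgt_side, c.target)
            W = self.W_exc if c.sign == "excitatory" else self.W_inh
            W[tgt, src] += c.weight

        self.D_exc = np.zeros((n, 4))
        self.D_inh = np.zeros((n, 4))
        for d in net.connectome.drives:
            col = DRIVE_ORDER.index((d.drive, d.drive_side))
            tgt = net.index(d.target_side, d.target)
            D = self.D_exc if d.sign == "excitatory" else self.D_inh
            D[tgt, col] += d.weight

        self.FB_exc = np.zeros((n, 4))
        self.FB_inh = np.zeros((n, 4))
        for fb in net.connectome.feedback:
            col = FEEDBACK_ORDER.index((fb.feedback, fb.feedback_side))
            tgt = net.index(fb.target_side, fb.target)
            FB = self.FB_exc if fb.sign == "excitatory" else self.FB_inh
            FB[tgt, col] += fb.weight

        k = net.constants
        self.E_syn_exc = k["E_syn_exc"]
        self.E_syn_inh = k["E_syn_inh"]
        self.V_threshold = k["V_threshold"]
        self.V_max = k["V_max"]
        self.k_psi = k["k_psi"]
        self.k_e1 = k["k_e1"]
        self.k_e2 = k["k_e2"]
        self.t_ramp = k["t_ramp"]
        self.chi_reset_tau = k["chi_reset_tau"]
        self.ext_on_scale = k.get("extensor_on_scale", 0.05)
        self.E_idx = np.array([net.index(s, "E") for s in SIDES])
        self.F_idx = np.array([net.index(s, "F") for s in SIDES])
        # which alpha gates each feedback column: (L, R, L, R)
        self.gate_alpha_col = np.array([0, 1, 0, 1])


# ---------------------------------------------------------------------------
# config loading / network construction
# ---------------------------------------------------------------------------


def load_default_config() -> dict:
    """Load the canonical parameter file shipped with the package."""
    text = resources.files("hemigait.data").joinpath("default_network.yaml").read_text()
    return yaml.safe_load(text)


def _expand_sided(rec: dict, kind: str) -> list[dict]:
    """Expand a config record into left and right instances.

    ``side: both`` (default) produces the mirrored pair; a single-side record
    without ``allow_asymmetric: true`` is rejected, because the intact circuit
    is left-right symmetric by construction.
    """
    side = rec.get("side", "both")
    rel = rec.get("target_rel", "ipsi")
    if rel not in ("ipsi", "contra"):
        raise ConfigError(f"bad target_rel {rel!r} in {kind} record")
    if side == "both":
        out = []
        for s in SIDES:
            t = s if rel == "ipsi" else _other(s)
            out.append({**rec, "side": s, "_target_side": t})
        return out
    if side not in SIDES:
        raise ConfigError(f"bad side {side!r} in {kind} record")
    if not rec.get("allow_asymmetric", False):
        raise ConfigError(
            f"{kind} record on side {side!r} given without allow_asymmetric; "
            "the intact network must be specified mirror-symmetrically"
        )
    t = side if rel == "ipsi" else _other(side)
    return [{**rec, "_target_side": t}]


def build_network(config: dict | None = None) -> Network:
    """Construct the intact bilateral network from a configuration mapping.

    With ``config=None`` the built-in default parameter file is used.  The
    returned network is mirror-symmetric; use :func:`apply_lesion` to derive
    hemisected or transected variants.
    """
    cfg = copy.deepcopy(config) if config is not None else load_default_config()

    burster_defaults = cfg.get("burster_defaults", {})
    simple_defaults = cfg.get("simple_defaults", {})
    overrides = cfg.get("population_overrides", {})

    populations: dict[str, PopulationSpec] = {}
    for side in SIDES:
        for name in POPULATION_LABELS:
            kind = "burster" if name in BURSTER_LABELS else "simple"
            params = dict(burster_defaults if kind == "burster" else simple_defaults)
            params.update(overrides.get(name, {}))
            populations[f"{side}_{name}"] = PopulationSpec(name=name, side=side, kind=kind, **params)

    connectome = Connectome()
    for rec in cfg.get("connections", []):
        for r in _expand_sided(rec, "connection"):
            if r["source"] not in POPULATION_LABELS or r["target"] not in POPULATION_LABELS:
                raise ConfigError(f"unknown population label in connection {r['source']}->{r['target']}")
            connectome.connections.append(
                Connection(
                    source=r["source"],
                    source_side=r["side"],
                    target=r["target"],
                    target_side=r["_target_side"],
                    weight=float(r["weight"]),
                    sign=r["sign"],
                )
            )
    for rec in cfg.get("drives", []):
        for r in _expand_sided(rec, "drive"):
            if r["target"] not in POPULATION_LABELS:
                raise ConfigError(f"unknown population label in drive target {r['target']!r}")
            connectome.drives.append(
                DriveInput(
                    drive=r["drive"],
                    drive_side=r["side"],
                    target=r["target"],
                    target_side=r["_target_side"],
                    weight=float(r["weight"]),
                    sign=r["sign"],
                )
            )
    for rec in cfg.get("feedback", []):
        for r in _expand_sided(rec, "feedback"):
            if r["target"] not in POPULATION_LABELS:
                raise ConfigError(f"unknown population label in feedback target {r['target']!r}")
            if not r.get("gated", True):
                raise ConfigError("all feedback entries must be gated by presynaptic inhibition")
            connectome.feedback.append(
                FeedbackInput(
                    feedback=r["feedback"],
                    feedback_side=r["side"],
                    target=r["target"],
                    target_side=r["_target_side"],
                    weight=float(r["weight"]),
                    sign=r["sign"],
                    gated=True,
                )
            )

    connectome.check_mirror_symmetry()
    constants = dict(cfg["constants"])

    net = Network(populations=populations, connectome=connectome, constants=constants)
    lesion = cfg.get("lesion", "intact")
    if lesion != "intact":
        net = apply_lesion(net, LesionSpec(lesion))
    return net


def apply_lesion(network: Network, lesion: LesionSpec) -> Network:
    """Return the lesioned variant of ``network``.

    Hemisection on a side zeroes that side's drive-entry weights (alpha and
    gamma); with alpha forced to 0 the presynaptic gate on that side's
    feedback opens fully (gain 1) through the ordinary gain formula.  No
    synaptic connection weight changes.  Application is idempotent and
    composes: left then right hemisection equals transection.
    """
    hemis = set(lesion.hemisected_sides) | set(network.lesion.hemisected_sides)
    if hemis == {"left", "right"}:
        state = "transected"
    elif hemis == {"right"}:
        state = "right_hemisected"
    elif hemis == {"left"}:
        state = "left_hemisected"
    else:
        state = "intact"

    new_drives = [
        replace(d, weight=0.0) if d.drive_side in hemis else d
        for d in network.connectome.drives
    ]
    connectome = Connectome(
        connections=list(network.connectome.connections),
        drives=new_drives,
        feedback=list(network.connectome.feedback),
    )
    return Network(
        populations=dict(network.populations),
        connectome=connectome,
        constants=dict(network.constants),
        lesion=LesionSpec(state),
    )


# ---------------------------------------------------------------------------
# elementary functions
# ---------------------------------------------------------------------------


def presynaptic_gain(alpha: float, k_psi: float = 2.0) -> float:
    """Drive-dependent attenuation of gated feedback: ``max(0, 1 - k_psi*alpha)``."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return max(0.0, 1.0 - k_psi * alpha)


def output(V: np.ndarray | float, V_threshold: float = -50.0, V_max: float = 0.0):
    """Piecewise-linear unit output: 0 below threshold, 1 above V_max."""
    return np.clip((np.asarray(V, dtype=float) - V_threshold) / (V_max - V_threshold), 0.0, 1.0)


def compute_feedback(
    state: UnitState,
    chi: Sequence[float],
    belts: BeltCondition,
    network: Network,
) -> FeedbackState:
    """Evaluate the two somatosensory feedback signals for both sides.

    SF-E1 ramps with normalized time-in-extension ``chi`` scaled by the
    ipsilateral belt parameter; SF-E2 is proportional to extensor output.
    Both vanish whenever the ipsilateral extensor output is zero.
    """
    cn = network.compiled()
    f_E = output(state.V[cn.E_idx], cn.V_threshold, cn.V_max)
    active = np.clip(f_E / cn.ext_on_scale, 0.0, 1.0)
    beta = belts.beta
    sf_e1 = cn.k_e1 * beta * np.minimum(np.asarray(chi, dtype=float), 1.0) * active
    sf_e2 = cn.k_e2 * f_E * active
    return FeedbackState(
        sf_e1_left=float(sf_e1[0]),
        sf_e1_right=float(sf_e1[1]),
        sf_e2_left=float(sf_e2[0]),
        sf_e2_right=float(sf_e2[1]),
        chi_left=float(chi[0]),
        chi_right=float(chi[1]),
    )


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------


def rhs(
    t: float,
    y: np.ndarray,
    network: Network | CompiledNetwork,
    drives: DriveSchedule,
    belts: BeltCondition,
) -> np.ndarray:
    """Time derivative of the full state vector ``[V (20), h (4), chi (2)]``.

    Voltages in mV, time in seconds.  The stance-phase clocks ``chi`` grow at
    ``1/t_ramp`` while the ipsilateral extensor is active and relax to zero
    quickly (time constant ``chi_reset_tau``) once flexion starts, which
    implements the flexion-onset reset without solver event handling.
    """
    cn = network.compiled() if isinstance(network, Network) else network
    n = cn.C.size
    nb = cn.burster_idx.size
    V = y[:n]
    h = y[n : n + nb]
    chi = y[n + nb : n + nb + 2]
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state encountered (solver blow-up)")

    f = np.clip((V - cn.V_threshold) / (cn.V_max - cn.V_threshold), 0.0, 1.0)

    f_E = f[cn.E_idx]
    active = np.clip(f_E / cn.ext_on_scale, 0.0, 1.0)
    beta = belts.beta
    sf_e1 = cn.k_e1 * beta * np.minimum(chi, 1.0) * active
    sf_e2 = cn.k_e2 * f_E * active
    sf = np.array([sf_e1[0], sf_e1[1], sf_e2[0], sf_e2[1]])

    d = drives.vector
    alpha = d[:2]
    gains = np.maximum(0.0, 1.0 - cn.k_psi * alpha)  # per side
    sf_gated = sf * gains[cn.gate_alpha_col]

    g_exc = cn.W_exc @ f + cn.D_exc @ d + cn.FB_exc @ sf_gated
    g_inh = cn.W_inh @ f + cn.D_inh @ d + cn.FB_inh @ sf_gated

    I = -cn.g_leak * (V - cn.E_leak) - g_exc * (V - cn.E_syn_exc) - g_inh * (V - cn.E_syn_inh)

    Vb = V[cn.burster_idx]
    m_inf = 1.0 / (1.0 + np.exp(-(Vb - cn.theta_m) / cn.sigma_m))
    I_nap = -cn.g_nap * m_inf * h * (Vb - cn.E_na)
    I[cn.burster_idx] += I_nap

    dV = 1000.0 * I / cn.C  # pA/pF = mV/ms -> mV/s

    h_inf = 1.0 / (1.0 + np.exp((Vb - cn.theta_h) / cn.sigma_h))
    tau_h = cn.tau_h0 / np.cosh((Vb - cn.theta_h) / (2.0 * cn.sigma_h))
    dh = (h_inf - h) / tau_h

    dchi = active / cn.t_ramp - (1.0 - active) * chi / cn.chi_reset_tau

    return np.concatenate([dV, dh, dchi])
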