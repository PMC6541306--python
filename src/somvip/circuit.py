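"""Construction of the PC--PV--SOM--VIP cortical microcircuit.

The network consists of excitatory pyramidal cells (PCs), modelled with a
somatic and a dendritic compartment, and three inhibitory interneuron
classes: PV (soma-targeting), SOM (dendrite-targeting) and VIP
(SOM-targeting, disinhibitory).  Connectivity is random but degree-regular:
every postsynaptic cell of a class receives exactly ``K = round(p * N_pre)``
inputs from each presynaptic class, and per-synapse weights are scaled as
``w_hat / K`` so that the summed input per cell equals the total class
strength ``w_hat`` exactly.  This makes the population (mean-field) dynamics
independent of population sizes.

Connection classes are indexed by ``(post, pre)`` pairs over the labels

* ``"E"`` -- PC somatic compartment,
* ``"D"`` -- PC dendritic compartment (postsynaptic only),
* ``"P"`` -- PV interneurons,
* ``"S"`` -- SOM interneurons,
* ``"V"`` -- VIP interneurons.

Totals are stored as positive magnitudes; the sign is applied from the
presynaptic class (inhibitory for PV/SOM/VIP, excitatory for PCs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np

__all__ = [
    "CLASSES",
    "PopulationLayout",
    "ConnectivityParams",
    "PCParams",
    "AdaptationParams",
    "STFParams",
    "WeightMatrices",
    "CircuitSpec",
    "Circuit",
    "stf_steady_state",
    "build_connectivity",
    "assign_weights",
    "rescale_for_stf",
    "calibrate_background",
    "configure_mismatch_circuit",
    "build_circuit",
    "reference_of",
]

CLASSES = ("E", "D", "P", "S", "V")

#: presynaptic classes whose synapses are inhibitory (entries negated)
INHIBITORY_PRE = frozenset({"P", "S", "V"})

#: connection classes with short-term facilitation (Tsodyks-Markram)
FACILITATING = (("S", "V"), ("V", "S"))

#: connection classes where pre and post are the same neurons (no autapses)
_SELF_PAIRS = frozenset({("P", "P"), ("S", "S"), ("V", "V"), ("D", "E")})

# Connection probabilities (post, pre).  Parenthesised table entries
# (within-class SOM and VIP recurrence) are only used when the recurrence
# flags are set.
DEFAULT_PROB = {
    ("E", "P"): 0.6,
    ("D", "E"): 0.1,
    ("D", "S"): 0.55,
    ("P", "E"): 0.45,
    ("P", "P"): 0.5,
    ("P", "S"): 0.6,
    ("S", "E"): 0.35,
    ("S", "S"): 0.5,
    ("S", "V"): 0.5,
    ("V", "E"): 0.1,
    ("V", "S"): 0.45,
    ("V", "V"): 0.5,
}

# Total absolute connection strengths w_hat (post, pre).  The mutual
# SOM<->VIP strengths and the within-class recurrences are the parameters
# varied throughout; the values here are the baseline configuration.
DEFAULT_TOTAL = {
    ("E", "P"): 0.7,
    ("D", "S"): 1.96,
    ("D", "E"): 0.42,
    ("P", "E"): 1.0,
    ("P", "P"): 1.5,
    ("P", "S"): 1.3,
    ("S", "E"): 1.0,
    ("S", "S"): 0.0,
    ("S", "V"): 0.7,
    ("V", "E"): 1.0,
    ("V", "S"): 0.7,
    ("V", "V"): 0.0,
}

VARIANTS = ("full_circuit", "interneuron_only", "reference_no_vip", "som_vip_only")


class SpecError(ValueError):
    """Inconsistent circuit specification."""


@dataclass(frozen=True)
class PopulationLayout:
    """Population sizes.

    ``size_multiplier`` scales the three interneuron populations (used e.g.
    in correlation experiments where statistics require larger populations);
    PC count is unaffected.
    """

    n_pc: int = 70
    n_pv: int = 10
    n_som: int = 10
    n_vip: int = 10
    size_multiplier: int = 1

    def __post_init__(self):
        for name in ("n_pc", "n_pv", "n_som", "n_vip"):
            if getattr(self, name) < 1:
                raise SpecError(f"{name} must be >= 1")
        if self.size_multiplier < 1:
            raise SpecError("size_multiplier must be a positive integer")

    def n(self, cls: str) -> int:
        m = self.size_multiplier
        return {
            "E": self.n_pc,
            "D": self.n_pc,
            "P": self.n_pv * m,
            "S": self.n_som * m,
            "V": self.n_vip * m,
        }[cls]


@dataclass(frozen=True)
class ConnectivityParams:
    """Connection probabilities and total strengths per (post, pre) class."""

    prob: dict = field(default_factory=lambda: dict(DEFAULT_PROB))
    total: dict = field(default_factory=lambda: dict(DEFAULT_TOTAL))
    include_som_recurrence: bool = False
    include_vip_recurrence: bool = False

    def __post_init__(self):
        for pair, p in self.prob.items():
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"probability out of [0,1] for {pair}: {p}")
        for pair, w in self.total.items():
            if w < 0:
                raise SpecError(f"negative total strength for {pair}: {w}")

    def with_mutual_inhibition(self, w_sv: float, w_vs: float | None = None) -> "ConnectivityParams":
        """Return a copy with the SOM<->VIP mutual totals set (symmetric if
        only one value given)."""
        if w_vs is None:
            w_vs = w_sv
        total = dict(self.total)
        total[("S", "V")] = w_sv
        total[("V", "S")] = w_vs
        return replace(self, total=total)

    def with_recurrence(self, w_r: float) -> "ConnectivityParams":
        """Return a copy with artificial within-class SOM and VIP recurrence
        of total strength ``w_r`` enabled."""
        total = dict(self.total)
        total[("S", "S")] = w_r
        total[("V", "V")] = w_r
        return replace(
            self,
            total=total,
            include_som_recurrence=w_r > 0,
            include_vip_recurrence=w_r > 0,
        )


@dataclass(frozen=True)
class PCParams:
    """Two-compartment pyramidal-cell parameters.

    ``theta`` is the rheobase, ``lambda_e``/``lambda_d`` the fractions of
    current leaking away from soma and dendrite, ``c_amp`` the amplitude of
    the dendritic calcium event triggered when the synaptically generated
    dendritic input exceeds ``theta_c``.  All rate-like quantities in 1/s,
    times in seconds.
    """

    theta: float = 14.0
    lambda_e: float = 0.31
    lambda_d: float = 0.27
    c_amp: float = 7.0
    theta_c: float = 28.0
    tau_e: float = 0.01

    def __post_init__(self):
        if not (0.0 <= self.lambda_e <= 1.0 and 0.0 <= self.lambda_d <= 1.0):
            raise SpecError("lambda_e and lambda_d must lie in [0, 1]")
        if self.theta_c <= 0:
            raise SpecError("theta_c must be positive")
        if self.tau_e <= 0:
            raise SpecError("tau_e must be positive")


@dataclass(frozen=True)
class AdaptationParams:
    """Spike-frequency adaptation of SOM and VIP cells.

    The adaptation variable approaches ``b * r`` with time constant
    ``tau_a``; ``b = 0`` disables adaptation (PV cells never adapt).
    """

    b_som: float = 0.0
    b_vip: float = 0.0
    tau_a_som: float = 0.1
    tau_a_vip: float = 0.1

    def __post_init__(self):
        if self.b_som < 0 or self.b_vip < 0:
            raise SpecError("adaptation strength b must be >= 0")
        if self.tau_a_som <= 0 or self.tau_a_vip <= 0:
            raise SpecError("adaptation time constants must be positive")

    @classmethod
    def symmetric(cls, b: float, tau_a: float = 0.1) -> "AdaptationParams":
        return cls(b_som=b, b_vip=b, tau_a_som=tau_a, tau_a_vip=tau_a)

    def b(self, cls_label: str) -> float:
        return {"P": 0.0, "S": self.b_som, "V": self.b_vip}[cls_label]


@dataclass(frozen=True)
class STFParams:
    """Short-term facilitation (Tsodyks-Markram) of the SOM<->VIP synapses.

    ``u_s`` is the initial release probability; ``u_s = 1`` disables
    facilitation.  When facilitation is enabled, the nominal mutual weights
    are divided by ``u_s`` so that the initial synaptic response after a
    long silent period is unchanged.
    """

    u_s: float = 1.0
    tau_f: float = 0.2

    def __post_init__(self):
        if not 0.0 < self.u_s <= 1.0:
            raise SpecError("u_s must lie in (0, 1]")
        if self.tau_f <= 0:
            raise SpecError("tau_f must be positive")

    @property
    def enabled(self) -> bool:
        return self.u_s < 1.0


def stf_steady_state(u_s: float, tau_f: float, r) -> np.ndarray | float:
    """Steady-state facilitation variable at constant presynaptic rate ``r``.

    Returns ``u_s (1 + tau_f r) / (1 + u_s tau_f r)``, which lies in
    ``[u_s, 1)`` and increases monotonically with ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("presynaptic rate must be >= 0")
    out = u_s * (1.0 + tau_f * r) / (1.0 + u_s * tau_f * r)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CircuitSpec:
    """Full parameterization of one circuit variant.

    ``variant`` selects which populations are present:

    * ``full_circuit`` -- PCs (soma + dendrite) and all three interneuron
      classes; background inputs are the fixed in-vivo-like values.
    * ``interneuron_only`` -- PV, SOM and VIP with PC drive absorbed into
      constant background inputs calibrated to a spontaneous rate ``r0``.
    * ``reference_no_vip`` -- the same network without VIP cells; the
      modulatory input targets SOM cells with inverted sign.  Set
      ``include_pc`` to obtain the full-circuit reference.
    * ``som_vip_only`` -- the mutually inhibiting SOM-VIP motif alone.

    ``background`` optionally overrides per-class background inputs (1/s).
    """

    layout: PopulationLayout = field(default_factory=PopulationLayout)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    pc: PCParams = field(default_factory=PCParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    stf: STFParams = field(default_factory=STFParams)
    interneuron_tau: float = 0.01
    variant: str = "interneuron_only"
    include_pc: bool | None = None
    background: dict | None = None
    r0: float = 3.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise SpecError(f"unknown variant {self.variant!r}")
        if self.interneuron_tau <= 0:
            raise SpecError("interneuron_tau must be positive")

    @property
    def has_pc(self) -> bool:
        if self.variant == "full_circuit":
            return True
        if self.variant == "reference_no_vip":
            return bool(self.include_pc)
        return False

    def classes_present(self) -> tuple[str, ...]:
        inter = {
            "full_circuit": ("P", "S", "V"),
            "interneuron_only": ("P", "S", "V"),
            "reference_no_vip": ("P", "S"),
            "som_vip_only": ("S", "V"),
        }[self.variant]
        return (("E", "D") if self.has_pc else ()) + inter

    def modulatory_target(self) -> tuple[str, float]:
        """Class and sign receiving the modulatory input ``x_mod``.

        In networks without VIP cells the modulatory input is applied to SOM
        cells with inverted sign for comparability.
        """
        if "V" in self.classes_present():
            return "V", 1.0
        return "S", -1.0

    def active_pairs(self) -> list[tuple[str, str]]:
        present = set(self.classes_present())
        pairs = []
        for (post, pre) in DEFAULT_PROB:
            if post not in present or pre not in present:
                continue
            if (post, pre) == ("S", "S") and not self.connectivity.include_som_recurrence:
                continue
            if (post, pre) == ("V", "V") and not self.connectivity.include_vip_recurrence:
                continue
            pairs.append((post, pre))
        return pairs

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["connectivity"]["prob"] = {f"{k[0]}<-{k[1]}": v for k, v in d["connectivity"]["prob"].items()}
        d["connectivity"]["total"] = {f"{k[0]}<-{k[1]}": v for k, v in d["connectivity"]["total"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitSpec":
        d = dict(d)
        conn = dict(d.pop("connectivity", {}))
        if conn:
            for key in ("prob", "total"):
                if key in conn:
                    conn[key] = {
                        (pair.split("<-")[0], pair.split("<-")[1]): v
                        for pair, v in conn[key].items()
                    }
            d["connectivity"] = ConnectivityParams(**conn)
        for key, typ in (
            ("layout", PopulationLayout),
            ("pc", PCParams),
            ("adaptation", AdaptationParams),
            ("stf", STFParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "CircuitSpec":
        return cls.from_dict(json.loads(s))


def reference_of(spec: CircuitSpec) -> CircuitSpec:
    """Reference network of ``spec``: the VIP population is removed and the
    modulatory input targets SOM with inverted sign.  PC presence is kept."""
    return replace(
        spec,
        variant="reference_no_vip",
        include_pc=spec.has_pc,
    )


# ---------------------------------------------------------------------------
# connectivity and weights
# ---------------------------------------------------------------------------


def _balanced_in_degree(n_post: int, n_pre: int, k: int, exclude_self: bool,
                        rng: np.random.Generator) -> np.ndarray:
    """Boolean adjacency (n_post, n_pre) with exact in-degree ``k`` per row
    and out-degrees balanced to within a spread of one.

    Target out-degrees split ``k * n_post`` as evenly as the presynaptic
    population permits (exactly even when divisible).  Rows are filled in
    random order, each drawing the ``k`` presynaptic units with the most
    remaining capacity (random tie-break, self excluded for within-class
    pairs); this greedy dealing realizes the target degrees exactly and is
    deterministic for a fixed generator state.
    """
    if exclude_self and k > n_pre - 1:
        raise SpecError(f"in-degree {k} impossible without autapses (N_pre={n_pre})")
    if k > n_pre:
        raise SpecError(f"in-degree {k} exceeds presynaptic population {n_pre}")
    base, extra = divmod(k * n_post, n_pre)
    target = np.full(n_pre, base, dtype=int)
    if extra:
        target[rng.choice(n_pre, size=extra, replace=False)] += 1

    for _ in range(100):
        counts = target.astype(float)
        rows = np.empty((n_post, k), dtype=int)
        ok = True
        for i in rng.permutation(n_post):
            score = counts + rng.random(n_pre)  # random tie-break
            score[counts <= 0] = -np.inf
            if exclude_self:
                score[i] = -np.inf
            if np.isfinite(score).sum() < k:
                ok = False
                break
            sel = np.argpartition(-score, k - 1)[:k]
            rows[i] = sel
            counts[sel] -= 1
        if ok:
            adj = np.zeros((n_post, n_pre), dtype=bool)
            adj[np.repeat(np.arange(n_post), k), rows.ravel()] = True
            return adj
    raise RuntimeError("could not construct a balanced adjacency (degenerate layout?)")


def build_connectivity(spec_or_layout, conn: ConnectivityParams | None = None,
                       seed: int | np.random.SeedSequence | None = 0,
                       pairs: list[tuple[str, str]] | None = None) -> dict:
    """Random degree-regular adjacency per connection class.

    Every postsynaptic unit receives ``K = round(p * N_pre)`` connections
    drawn without replacement (excluding autapses for within-class pairs);
    out-degrees are balanced to a spread of at most one.  Deterministic for
    a fixed seed.

    Accepts either a :class:`CircuitSpec` (recommended; the active pairs are
    derived from the variant) or a :class:`PopulationLayout` plus explicit
    ``conn`` and ``pairs``.
    """
    if isinstance(spec_or_layout, CircuitSpec):
        spec = spec_or_layout
        layout, conn = spec.layout, spec.connectivity
        if pairs is None:
            pairs = spec.active_pairs()
    else:
        layout = spec_or_layout
        if conn is None or pairs is None:
            raise SpecError("conn and pairs are required when passing a bare layout")
    rng = np.random.default_rng(seed)
    adjacency = {}
    for (post, pre) in pairs:
        n_pre, n_post = layout.n(pre), layout.n(post)
        p = conn.prob.get((post, pre), 0.0)
        w_hat = conn.total.get((post, pre), 0.0)
        if p > 0 and n_pre == 0:
            raise SpecError(f"{post}<-{pre}: p > 0 but no presynaptic units")
        k = int(round(p * n_pre))
        if (post, pre) in _SELF_PAIRS and p == 1.0:
            k = n_pre - 1  # fully connected within class: all partners but self
        if k == 0:
            if w_hat > 0:
                raise SpecError(f"{post}<-{pre}: total strength {w_hat} but in-degree 0")
            adjacency[(post, pre)] = np.zeros((n_post, n_pre), dtype=bool)
            continue
        adjacency[(post, pre)] = _balanced_in_degree(
            n_post, n_pre, k, (post, pre) in _SELF_PAIRS, rng
        )
    return adjacency


@dataclass
class WeightMatrices:
    """Signed per-synapse weight matrices, one per connection class.

    All nonzero entries of a class share the same magnitude ``w_hat / K``;
    inhibitory presynaptic classes carry non-positive entries.  ``total``
    returns the signed per-row sum (exact by construction).
    """

    matrices: dict
    in_degree: dict

    def __getitem__(self, pair):
        return self.matrices[pair]

    def __contains__(self, pair):
        return pair in self.matrices

    def pairs(self):
        return list(self.matrices)

    def total(self, pair) -> float:
        w = self.matrices[pair]
        if w.size == 0 or self.in_degree[pair] == 0:
            return 0.0
        return float(w.sum(axis=1)[0])


def assign_weights(adjacency: dict, conn: ConnectivityParams) -> WeightMatrices:
    """Per-synapse signed weights from adjacency and class totals.

    Magnitude is ``w_hat / K`` so that each postsynaptic unit's summed input
    equals ``w_hat`` exactly; sign follows the presynaptic class.
    """
    matrices, in_degree = {}, {}
    for (post, pre), adj in adjacency.items():
        w_hat = conn.total.get((post, pre), 0.0)
        k = int(adj.sum(axis=1)[0]) if adj.size else 0
        in_degree[(post, pre)] = k
        if w_hat == 0.0 or k == 0:
            matrices[(post, pre)] = np.zeros(adj.shape)
            continue
        sign = -1.0 if pre in INHIBITORY_PRE else 1.0
        matrices[(post, pre)] = sign * (w_hat / k) * adj.astype(float)
    return WeightMatrices(matrices, in_degree)


def rescale_for_stf(weights: WeightMatrices, stf: STFParams) -> WeightMatrices:
    """Divide the facilitating (SOM<->VIP) weights by ``u_s``.

    The facilitation variable starts at ``u_s`` after a long silent period,
    so dividing keeps the initial synaptic response equal to the nominal
    weight while the steady-state efficacy grows with presynaptic rate.
    """
    if stf.u_s <= 0:
        raise SpecError("u_s must be positive")
    matrices = dict(weights.matrices)
    for pair in FACILITATING:
        if pair in matrices:
            matrices[pair] = matrices[pair] / stf.u_s
    return WeightMatrices(matrices, dict(weights.in_degree))


# ---------------------------------------------------------------------------
# background calibration
# ---------------------------------------------------------------------------

#: printed background inputs of the full microcircuit (1/s)
FULL_CIRCUIT_BACKGROUND = {"E": 17.5, "D": 21.0, "P": 3.0, "S": 3.0, "V": 3.0}


def calibrate_background(spec: CircuitSpec, weights: WeightMatrices,
                         r0: float | None = None) -> dict:
    """Background inputs placing the spontaneous state at rate ``r0``.

    For interneuron-level variants each class receives
    ``x_i = (1 + b_i) r0 - sum_j w_ij u_ij r0`` with the steady-state
    facilitation value for facilitating synapses, so that at zero modulatory
    input every interneuron fires at exactly ``r0`` (valid outside the
    winner-take-all regime; a warning is emitted if the coexistence state is
    not admissible).  For PC-containing variants the fixed printed values
    are used.  ``spec.background`` entries override either source.
    """
    r0 = spec.r0 if r0 is None else r0
    present = spec.classes_present()
    if spec.has_pc:
        bg = {c: float(FULL_CIRCUIT_BACKGROUND[c]) for c in present}
    else:
        _warn_if_wta(spec, weights)
        bg = {}
        for cls in present:
            total = 0.0
            for (post, pre), w in weights.matrices.items():
                if post != cls or w.size == 0:
                    continue
                u = 1.0
                if (post, pre) in FACILITATING and spec.stf.enabled:
                    u = stf_steady_state(spec.stf.u_s, spec.stf.tau_f, r0)
                total += weights.total((post, pre)) * u
            bg[cls] = (1.0 + spec.adaptation.b(cls)) * r0 - total * r0
    if spec.background:
        bg.update({k: float(v) for k, v in spec.background.items() if k in present})
    return {c: np.full(spec.layout.n(c), bg[c]) for c in bg}


def _effective_total(spec: CircuitSpec, weights: WeightMatrices, pair, r0: float) -> float:
    w = abs(weights.total(pair)) if pair in weights else 0.0
    if pair in FACILITATING and spec.stf.enabled:
        w *= stf_steady_state(spec.stf.u_s, spec.stf.tau_f, r0)
    return w


def _warn_if_wta(spec: CircuitSpec, weights: WeightMatrices) -> None:
    """Admissibility pre-check: the coexistence steady state exists only if
    the effective SOM-VIP competition is weaker than the effective leaks."""
    r0 = spec.r0
    if "V" not in spec.classes_present():
        return
    w_sv = _effective_total(spec, weights, ("S", "V"), r0)
    w_vs = _effective_total(spec, weights, ("V", "S"), r0)
    leak_s = 1.0 + spec.adaptation.b_som + _effective_total(spec, weights, ("S", "S"), r0)
    leak_v = 1.0 + spec.adaptation.b_vip + _effective_total(spec, weights, ("V", "V"), r0)
    if leak_s * leak_v - w_sv * w_vs <= 0:
        warnings.warn(
            "circuit is in the winner-take-all regime; the background "
            "calibration formula assumes a coexistence steady state",
            stacklevel=3,
        )


def configure_mismatch_circuit(spec: CircuitSpec) -> CircuitSpec:
    """Mismatch-detection configuration of the full circuit.

    Sets the SOM->PV total to 0.2 and the PV->PV total to 1.0, and tunes the
    PV->soma strength to ``(1 + w_PP) / (1 - w_PS)`` so that somatic visual
    drive is cancelled by PV feedback and PCs respond only when the
    motor-related prediction arrives without visual input.  The PC time
    constant is increased sixfold to suppress onset transients.
    """
    if not spec.has_pc:
        raise SpecError("mismatch configuration requires the full circuit")
    total = dict(spec.connectivity.total)
    total[("P", "S")] = 0.2
    total[("P", "P")] = 1.0
    w_ps, w_pp = total[("P", "S")], total[("P", "P")]
    if w_ps >= 1.0:
        raise SpecError("SOM->PV total must be < 1 (cancellation formula singular)")
    total[("E", "P")] = (1.0 + w_pp) / (1.0 - w_ps)
    return replace(
        spec,
        connectivity=replace(spec.connectivity, total=total),
        pc=replace(spec.pc, tau_e=spec.pc.tau_e * 6.0),
    )


# ---------------------------------------------------------------------------
# realized circuit
# ---------------------------------------------------------------------------


@dataclass
class Circuit:
    """A realized network: spec plus weight matrices and background inputs."""

    spec: CircuitSpec
    weights: WeightMatrices
    background: dict

    def n(self, cls: str) -> int:
        return self.spec.layout.n(cls)

    @property
    def classes(self) -> tuple[str, ...]:
        return self.spec.classes_present()

    def w(self, post: str, pre: str) -> np.ndarray | None:
        return self.weights.matrices.get((post, pre))


def build_circuit(spec: CircuitSpec, seed: int | np.random.SeedSequence | None = 0,
                  calibrate: bool = True) -> Circuit:
    """Build connectivity, assign and (if needed) STF-rescale weights, and
    calibrate background inputs."""
    adjacency = build_connectivity(spec, seed=seed)
    weights = assign_weights(adjacency, spec.connectivity)
    if spec.stf.enabled:
        weights = rescale_for_stf(weights, spec.stf)
    if calibrate:
        background = calibrate_background(spec, weights)
    else:
        background = {c: np.zeros(spec.layout.n(c)) for c in spec.classes_present()}
    return Circuit(spec=spec, weights=weights, background=background)
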