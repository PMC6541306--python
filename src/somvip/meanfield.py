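"""Mean-field steady states, amplification index, linear stability and
regime classification of the interneuron network.

The population-level dynamics of the PV/SOM/VIP network (ignoring the
rectification) are linear, so steady states and response slopes have closed
forms.  The amplification index

    A = log2(m_full / m_ref)

compares the slope of the somato-dendritic inhibition difference
(r_PV - r_SOM) with respect to the modulatory input when the input acts
through VIP cells (full network) versus directly on SOM cells (reference
network without VIP).  A > 0 means the SOM-VIP motif amplifies weak
modulatory signals.

Regimes of the symmetric SOM-VIP motif are classified from numerically
computed eigenvalues of the linearized block system and cross-checked
against the closed-form boundary conditions:

* within-population winner-take-all when the total recurrence
  ``w_r_hat >= n - 1``;
* between-population winner-take-all (switch) when the total mutual
  inhibition exceeds leak plus recurrence, ``w_hat > 1 + w_r_hat``
  (with adaptation: ``w_hat >= b + 1``);
* oscillations (with adaptation) when ``b > w_hat - 1`` and
  ``w_hat > 1 + tau / tau_a``;
* otherwise a stable coexistence state, split into amplification and
  attenuation by a threshold on A.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .circuit import Circuit, stf_steady_state

__all__ = [
    "MeanFieldParams",
    "RegimeReport",
    "params_from_circuit",
    "meanfield_steady_state",
    "slope_full",
    "slope_ref",
    "amplification_index_analytic",
    "build_linearized_system",
    "classify_regime_theory",
    "oscillation_frequency_theory",
    "transfer_amplitude_theory",
    "wta_onset_bisection",
]

REGIMES = (
    "attenuation",
    "amplification",
    "wta_switch",
    "oscillation",
    "wta_within_population",
    "total_wta",
)


@dataclass(frozen=True)
class MeanFieldParams:
    """Population-level totals and inputs.

    ``w_*`` are total absolute strengths (per-synapse values follow from
    ``w_r_hat = (n - 1) w_r`` and ``w_hat = n w``); ``n`` is the size of
    each of the SOM and VIP populations.  ``b``/``tau_a`` describe the
    (symmetric) adaptation of SOM and VIP cells.
    """

    w_sv: float = 0.7
    w_vs: float = 0.7
    w_ss: float = 0.0
    w_vv: float = 0.0
    w_ps: float = 1.3
    w_pp: float = 1.5
    x_pv: float = 0.0
    x_som: float = 0.0
    x_vip: float = 0.0
    x_mod: float = 0.0
    tau: float = 0.01
    n: int = 10
    b: float = 0.0
    tau_a: float = 0.1

    @property
    def w_hat(self) -> float:
        if not math.isclose(self.w_sv, self.w_vs, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("symmetric analysis requires w_sv == w_vs")
        return self.w_sv

    @property
    def w_r_hat(self) -> float:
        if not math.isclose(self.w_ss, self.w_vv, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("symmetric analysis requires w_ss == w_vv")
        return self.w_ss


def params_from_circuit(circuit: Circuit, r0: float | None = None) -> MeanFieldParams:
    """Extract population totals and calibrated inputs from a built
    circuit.  Facilitating totals are taken at their steady-state efficacy
    for the spontaneous rate (mean-field closed forms assume constant
    synapses)."""
    spec = circuit.spec
    r0 = spec.r0 if r0 is None else r0

    def tot(pair):
        if pair not in circuit.weights:
            return 0.0
        w = abs(circuit.weights.total(pair))
        from .circuit import FACILITATING

        if pair in FACILITATING and spec.stf.enabled:
            w *= stf_steady_state(spec.stf.u_s, spec.stf.tau_f, r0)
        return w

    def bg(cls):
        return float(circuit.background[cls][0]) if cls in circuit.background else 0.0

    return MeanFieldParams(
        w_sv=tot(("S", "V")),
        w_vs=tot(("V", "S")),
        w_ss=tot(("S", "S")),
        w_vv=tot(("V", "V")),
        w_ps=tot(("P", "S")),
        w_pp=tot(("P", "P")),
        x_pv=bg("P"),
        x_som=bg("S"),
        x_vip=bg("V"),
        tau=spec.interneuron_tau,
        n=spec.layout.n("S"),
        b=spec.adaptation.b_som,
        tau_a=spec.adaptation.tau_a_som,
    )


# ---------------------------------------------------------------------------
# steady states and slopes
# ---------------------------------------------------------------------------


def _denominator(p: MeanFieldParams) -> float:
    return (1.0 + p.w_ss) * (1.0 + p.w_vv) - p.w_sv * p.w_vs


def meanfield_steady_state(p: MeanFieldParams) -> tuple[float, float, float]:
    """Closed-form coexistence steady state (r_PV, r_SOM, r_VIP).

    Negative values indicate that the linear solution has left the
    admissible cone (the rectified network is then in a winner-take-all
    state); the caller decides how to handle them.
    """
    den = _denominator(p)
    if abs(den) < 1e-12:
        raise ZeroDivisionError("singular denominator: winner-take-all boundary")
    r_som = (p.x_som * (1.0 + p.w_vv) - p.w_sv * (p.x_vip + p.x_mod)) / den
    r_vip = (p.x_vip + p.x_mod - p.w_vs * r_som) / (1.0 + p.w_vv)
    r_pv = (p.x_pv - p.w_ps * r_som) / (1.0 + p.w_pp)
    return r_pv, r_som, r_vip


def slope_full(p: MeanFieldParams) -> float:
    """d(r_PV - r_SOM)/dx_mod when modulation acts through VIP cells."""
    den = _denominator(p)
    if abs(den) < 1e-12:
        raise ZeroDivisionError("singular denominator: winner-take-all boundary")
    return (1.0 + p.w_ps / (1.0 + p.w_pp)) * p.w_sv / den


def slope_ref(p: MeanFieldParams) -> float:
    """d(r_PV - r_SOM)/dx_mod in the reference network where the (sign
    inverted) modulation targets SOM cells directly."""
    return (1.0 + p.w_ps / (1.0 + p.w_pp)) / (1.0 + p.w_ss)


def amplification_index_analytic(p: MeanFieldParams) -> float:
    """Closed-form amplification index
    ``A = log2(w_sv (1 + w_ss) / ((1 + w_ss)(1 + w_vv) - w_sv w_vs))``.

    At or beyond the winner-take-all boundary the denominator is
    non-positive; this is reported as an explicit ``inf`` sentinel (with a
    warning when strictly beyond), never as a floating overflow.  For a
    network with adaptation, pass ``b`` folded into ``w_ss``/``w_vv``
    (steady-state equivalence of adaptation and recurrence); see
    :func:`effective_selfinhibition`.
    """
    den = _denominator(p)
    if den <= 0:
        if den < 0:
            warnings.warn("beyond the WTA boundary: amplification index diverged",
                          stacklevel=2)
        return math.inf
    return math.log2(p.w_sv * (1.0 + p.w_ss) / den)


def effective_selfinhibition(p: MeanFieldParams) -> MeanFieldParams:
    """Fold the adaptation strength into the within-population totals: at
    steady state, adaptation of strength b acts like total recurrence b."""
    return replace(p, w_ss=p.w_ss + p.b, w_vv=p.w_vv + p.b, b=0.0)


# ---------------------------------------------------------------------------
# linearized block system
# ---------------------------------------------------------------------------


def build_linearized_system(p: MeanFieldParams, with_adaptation: bool = False) -> np.ndarray:
    """Jacobian of the symmetric SOM-VIP motif around coexistence.

    Without adaptation: a ``2n x 2n`` matrix over the rates
    ``[rS1..rSn, rV1..rVn]`` with per-synapse recurrence
    ``w_r = w_r_hat / (n-1)`` (no autapses) and mutual inhibition
    ``w = w_hat / n``.  With adaptation: ``4n x 4n`` over
    ``[rS1, aS1, ..., rVn, aVn]``; adaptation rows are
    ``a' = (b r - a)/tau_a``.  No rectification.
    """
    n, tau = p.n, p.tau
    w_hat, w_r_hat = p.w_hat, p.w_r_hat
    w = w_hat / n
    w_r = w_r_hat / (n - 1) if n > 1 else 0.0
    rec = -w_r * (np.ones((n, n)) - np.eye(n))
    mut = -w * np.ones((n, n))
    w_syn = np.block([[rec, mut], [mut, rec]])
    if not with_adaptation:
        return (-np.eye(2 * n) + w_syn) / tau
    m = np.zeros((4 * n, 4 * n))
    for i in range(2 * n):
        ri, ai = 2 * i, 2 * i + 1
        m[ri, ri] = -1.0 / tau
        m[ri, ai] = -1.0 / tau
        m[ai, ri] = p.b / p.tau_a
        m[ai, ai] = -1.0 / p.tau_a
        for j in range(2 * n):
            if w_syn[i, j] != 0.0:
                m[ri, 2 * j] += w_syn[i, j] / tau
    return m


def _mode_matrix_antisymmetric(p: MeanFieldParams) -> np.ndarray:
    """2x2 block governing the competition mode (SOM up / VIP down): the
    mutual inhibition acts as positive feedback of total strength w_hat."""
    return np.array([
        [(p.w_hat - 1.0 - p.w_r_hat) / p.tau, -1.0 / p.tau],
        [p.b / p.tau_a, -1.0 / p.tau_a],
    ])


@dataclass
class RegimeReport:
    """Classification of a parameter point with supporting statistics."""

    label: str
    leading_eigenvalues: list
    margins: dict
    amplification_index: float | None = None
    boundary_flag: bool = False

    def __post_init__(self):
        if self.label not in REGIMES:
            raise ValueError(f"unknown regime label {self.label!r}")


def classify_regime_theory(p: MeanFieldParams, with_adaptation: bool | None = None,
                           amplification_threshold: float = 0.0,
                           margin_tol: float = 0.05) -> RegimeReport:
    """Regime label of a symmetric parameter point.

    The label is derived from the numerically computed eigenvalues of the
    linearized system; signed distances to the closed-form boundary
    conditions are evaluated alongside and the two routes must agree (a
    disagreement raises).  ``amplification_threshold`` splits the stable
    coexistence regime by the amplification index (0 by the sign
    convention; 1 for the bifurcation-diagram convention).
    """
    if with_adaptation is None:
        with_adaptation = p.b > 0
    w_hat, w_r_hat = p.w_hat, p.w_r_hat
    jac = build_linearized_system(p, with_adaptation=with_adaptation)
    eig = np.linalg.eigvals(jac)
    leading = sorted(eig, key=lambda z: -z.real)[:4]
    max_re = float(np.max(eig.real))

    if with_adaptation:
        if p.w_r_hat != 0:
            raise ValueError("classify with either adaptation or recurrence, not both")
        margins = {
            "switch": w_hat - (p.b + 1.0),
            "oscillation": min(p.b - (w_hat - 1.0), w_hat - (1.0 + p.tau / p.tau_a)),
        }
        mode = _mode_matrix_antisymmetric(p)
        mode_eig = np.linalg.eigvals(mode)
        unstable = float(np.max(mode_eig.real)) > 0 or margins["switch"] >= 0
        if margins["switch"] >= 0:
            label = "wta_switch"
        elif unstable:
            label = "oscillation"
        else:
            label = None
        # consistency: closed form vs numerical eigenvalues
        numeric_unstable = max_re > 1e-9
        closed_unstable = margins["switch"] >= 0 or margins["oscillation"] > 0
        if numeric_unstable != closed_unstable and \
                min(abs(margins["switch"]), abs(margins["oscillation"])) > 1e-6:
            raise RuntimeError(
                "eigenvalue analysis disagrees with closed-form boundaries "
                f"(max Re = {max_re:.3g}, margins = {margins})"
            )
    else:
        margins = {
            "within_population_wta": w_r_hat - (p.n - 1.0),
            "switch": w_hat - (1.0 + w_r_hat),
            "total_wta": min(w_hat - (1.0 + w_r_hat), w_hat - p.n),
        }
        within = margins["within_population_wta"] >= 0
        between = margins["switch"] > 0
        if within and between:
            label = "total_wta"
        elif within:
            label = "wta_within_population"
        elif between:
            label = "wta_switch"
        else:
            label = None
        numeric_unstable = max_re > 1e-9
        closed_unstable = within or between
        if numeric_unstable != closed_unstable and \
                min(abs(margins["within_population_wta"]), abs(margins["switch"])) > 1e-6:
            raise RuntimeError(
                "eigenvalue analysis disagrees with closed-form boundaries "
                f"(max Re = {max_re:.3g}, margins = {margins})"
            )

    a_index = None
    if label is None:
        eff = effective_selfinhibition(p) if with_adaptation else p
        a_index = amplification_index_analytic(eff)
        margins["amplification"] = a_index - amplification_threshold
        label = "amplification" if a_index > amplification_threshold else "attenuation"

    boundary = any(
        abs(v) < margin_tol for v in margins.values() if math.isfinite(v)
    )
    return RegimeReport(
        label=label,
        leading_eigenvalues=[complex(z) for z in leading],
        margins=margins,
        amplification_index=a_index,
        boundary_flag=boundary,
    )


def oscillation_frequency_theory(p: MeanFieldParams, closed_form: bool = False) -> float:
    """Oscillation frequency (Hz) of the adapting SOM-VIP motif.

    The authoritative value is the imaginary part of the leading complex
    eigenvalue pair of the ``4n``-dimensional linearization.  With
    ``closed_form=True`` the printed approximation

        f = (1/4 pi) sqrt(4 b / (tau tau_a) - (1/tau - 1/tau_a - w_hat/tau)^2)

    is returned instead; it coincides with the eigenvalue route wherever
    its discriminant is positive.  Raises if the linearization has no
    complex pair (relaxation-type oscillation: the nonlinear system can
    still oscillate, but the linear theory assigns no frequency).
    """
    if closed_form:
        disc = 4.0 * p.b / (p.tau * p.tau_a) - (1.0 / p.tau - 1.0 / p.tau_a - p.w_hat / p.tau) ** 2
        if disc <= 0:
            raise ValueError("closed form inapplicable: negative discriminant")
        return math.sqrt(disc) / (4.0 * math.pi)
    jac = build_linearized_system(p, with_adaptation=True)
    eig = np.linalg.eigvals(jac)
    complex_eig = eig[np.abs(eig.imag) > 1e-9]
    if complex_eig.size == 0:
        raise ValueError("no complex eigenvalue pair (no linear oscillation frequency)")
    lead = complex_eig[np.argmax(complex_eig.real)]
    return float(abs(lead.imag) / (2.0 * math.pi))


# ---------------------------------------------------------------------------
# frequency response and WTA onset
# ---------------------------------------------------------------------------


def transfer_amplitude_theory(p: MeanFieldParams, freq_hz: float,
                              network: str = "full") -> float:
    """Linear-response amplitude of (r_PV - r_SOM) to a unit sine on the
    modulatory input at frequency ``freq_hz``.

    Adaptation contributes a frequency-dependent self-term
    ``b / (1 + i omega tau_a)`` per population.  ``network`` selects the
    full PV/SOM/VIP circuit (modulation on VIP) or the reference PV/SOM
    circuit (modulation on SOM with inverted sign).
    """
    om = 2.0 * np.pi * freq_hz
    beta = p.b / (1.0 + 1j * om * p.tau_a)
    gp = 1.0 + 1j * om * p.tau  # PV has no adaptation
    gs = gp + beta
    if network == "full":
        m = np.array([
            [gp + p.w_pp, p.w_ps, 0.0],
            [0.0, gs + p.w_ss, p.w_sv],
            [0.0, p.w_vs, gs + p.w_vv],
        ], dtype=complex)
        rhs = np.array([0.0, 0.0, 1.0], dtype=complex)
    elif network == "reference":
        m = np.array([
            [gp + p.w_pp, p.w_ps],
            [0.0, gs + p.w_ss],
        ], dtype=complex)
        rhs = np.array([0.0, -1.0], dtype=complex)
    else:
        raise ValueError("network must be 'full' or 'reference'")
    r = np.linalg.solve(m, rhs)
    return float(abs(r[0] - r[1]))


def wta_onset_bisection(lo: float = 0.5, hi: float = 2.0, n: int = 10,
                        tau: float = 0.01, tol: float = 1e-9) -> float:
    """Critical product ``w_sv_hat * w_vs_hat`` at which the coexistence
    state of the SOM-VIP motif (no adaptation, no recurrence) loses
    stability, located by bisection on the leading eigenvalue's real part
    of the linearized rate system.

    This is where the analytic amplification index diverges.
    """

    def max_re(product: float) -> float:
        w = math.sqrt(product)
        p = MeanFieldParams(w_sv=w, w_vs=w, w_ss=0.0, w_vv=0.0, tau=tau, n=n, b=0.0)
        jac = build_linearized_system(p, with_adaptation=False)
        return float(np.max(np.linalg.eigvals(jac).real))

    f_lo, f_hi = max_re(lo), max_re(hi)
    if f_lo >= 0 or f_hi <= 0:
        raise ValueError("bracket does not straddle the stability boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if max_re(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
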