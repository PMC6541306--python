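"""Simulation-side measurements: steady-state response curves and slopes,
amplification index, frequency-resolved amplification and resonance,
pairwise correlations, oscillation frequency, empirical regime
classification, input-stream decomposition and hysteresis statistics.

All steady states are obtained by integrating to convergence (maximum rate
change below ``1e-4``/s over a trailing 200 ms window, capped at 10 s of
simulated time); stimulus grids and parameter sweeps run as one batched
integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .circuit import Circuit, CircuitSpec, build_circuit, reference_of
from .dynamics import DEFAULT_DT, CircuitState, SimulationResult, Simulator
from .protocols import Sinusoid, constant_protocol
from . import meanfield

__all__ = [
    "MeasureError",
    "SteadyStateCurve",
    "FrequencyResponse",
    "InputDecomposition",
    "simulate_to_steady_state",
    "steady_state_curve",
    "sigmoid_slope",
    "amplification_index_sim",
    "measure_amplification",
    "frequency_response",
    "pairwise_correlations",
    "dominant_frequency",
    "oscillation_frequency_estimate",
    "classify_regime_sim",
    "classify_regime_sim_batch",
    "input_coefficients",
    "hysteresis_scan",
    "hysteresis_stats",
]

SILENCE_THRESHOLD = 0.01  # 1/s; a unit below this is considered silenced
CONVERGENCE_TOL = 1e-4  # 1/s
CONVERGENCE_WINDOW = 0.2  # s
MAX_SETTLE_TIME = 10.0  # s


class MeasureError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------


def response_trace(result: SimulationResult, spec: CircuitSpec) -> np.ndarray:
    """The scalar response signal of a network variant: PC population rate
    for PC-containing circuits, PV-minus-SOM population rate for
    interneuron networks (somatic minus dendritic inhibition), and the
    negated SOM rate for the bare SOM-VIP motif."""
    if spec.has_pc:
        return result.population_mean("E")
    if "P" in spec.classes_present():
        return result.population_mean("P") - result.population_mean("S")
    return -result.population_mean("S")


def _response_from_state(state: CircuitState, spec: CircuitSpec) -> np.ndarray:
    if spec.has_pc:
        return state.r_e.mean(axis=-1)
    if "P" in spec.classes_present():
        return state.r_p.mean(axis=-1) - state.r_s.mean(axis=-1)
    return -state.r_s.mean(axis=-1)


def simulate_to_steady_state(circuit: Circuit, protocol=None, batch: int | None = None,
                             initial: CircuitState | None = None, dt: float = DEFAULT_DT,
                             max_time: float = MAX_SETTLE_TIME, chunk: float = 0.5,
                             tol: float = CONVERGENCE_TOL,
                             window: float = CONVERGENCE_WINDOW):
    """Integrate until every (batched) run reaches a rate steady state.

    Convergence: the maximum absolute deviation of every rate variable from
    its final value over the trailing ``window`` is below ``tol``.
    Returns ``(final_state, converged, elapsed_time)``.
    """
    sim = Simulator(circuit, batch=batch)
    if protocol is None:
        protocol = constant_protocol(circuit)
    state = initial
    t = 0.0
    converged = None
    while t < max_time - 1e-12:
        res = sim.run(protocol, chunk, dt=dt, initial=state, store_stride=1e-3, t0=t)
        state, t = res.final_state, t + chunk
        rate_keys = [k for k in res.data if k.startswith("r_")]
        n_win = max(2, int(round(window / 1e-3)))
        dev = []
        for k in rate_keys:
            arr = res.data[k][-n_win:]
            dev.append(np.abs(arr - arr[-1]).max(axis=(0, -1)))
        dev = np.max(dev, axis=0)
        converged = dev < tol
        if np.all(converged):
            break
    return state, np.asarray(converged), t


@dataclass
class SteadyStateCurve:
    """Steady-state response along a monotone modulatory-input grid."""

    x_mod: np.ndarray
    response: np.ndarray
    converged: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.x_mod) <= 0):
            raise MeasureError("x_mod grid must be strictly increasing")


def steady_state_curve(circuit: Circuit, grid: np.ndarray, dt: float = DEFAULT_DT,
                       max_time: float = MAX_SETTLE_TIME) -> SteadyStateCurve:
    """Simulate every grid point (batched, default initial state) to
    convergence and record the response signal."""
    grid = np.asarray(grid, dtype=float)
    proto = constant_protocol(circuit, x_mod=grid)
    state, conv, _ = simulate_to_steady_state(
        circuit, proto, batch=grid.size, dt=dt, max_time=max_time)
    resp = _response_from_state(state, circuit.spec)
    return SteadyStateCurve(x_mod=grid, response=resp, converged=conv)


def sigmoid_slope(curve: SteadyStateCurve, require_plateaus: bool = False,
                  plateau_frac: float = 0.15) -> float:
    """Maximum central finite-difference derivative magnitude of the curve.

    With ``require_plateaus`` the derivative at both grid ends must have
    dropped below ``plateau_frac`` of the maximum (both saturation plateaus
    reached), otherwise the grid is too narrow.
    """
    ok = np.asarray(curve.converged, dtype=bool)
    if ok.sum() < 5:
        raise MeasureError("need at least 5 converged grid points")
    x, y = curve.x_mod[ok], curve.response[ok]
    deriv = np.abs((y[2:] - y[:-2]) / (x[2:] - x[:-2]))
    m = float(deriv.max())
    if require_plateaus and m > 0:
        if deriv[0] > plateau_frac * m or deriv[-1] > plateau_frac * m:
            raise MeasureError("saturation plateaus not reached; widen the grid")
    return m


def amplification_index_sim(full_curve: SteadyStateCurve, ref_curve: SteadyStateCurve,
                            require_plateaus: bool = False) -> float:
    """log2 ratio of the sigmoid slopes of the full and reference curves.

    The plateau requirement only applies to the full curve: the reference
    network (modulation directly onto SOM) has a rectified-linear response
    that saturates on one side only.
    """
    m_full = sigmoid_slope(full_curve, require_plateaus=require_plateaus)
    m_ref = sigmoid_slope(ref_curve)
    if m_ref == 0:
        raise MeasureError("reference slope is zero")
    return math.log2(m_full / m_ref)


def _auto_grid(circuit: Circuit, n_points: int) -> np.ndarray:
    """Grid spanning both saturation plateaus, derived from the mean-field
    silencing points of SOM and VIP cells."""
    p = meanfield.effective_selfinhibition(meanfield.params_from_circuit(circuit))
    # x_mod silencing SOM: numerator of r_SOM = 0; silencing VIP: r_VIP = 0
    if p.w_sv > 0:
        x_sat_som = (p.x_som * (1.0 + p.w_vv) - 0.0) / p.w_sv - p.x_vip
    else:
        x_sat_som = 5.0
    # r_VIP = 0 when x_vip + x_mod = w_vs * r_SOM with r_SOM = x_som/(1+w_ss)
    x_sat_vip = p.w_vs * p.x_som / (1.0 + p.w_ss) - p.x_vip
    half = 1.5 * max(abs(x_sat_som), abs(x_sat_vip), 0.5)
    return np.linspace(-half, half, n_points)


def measure_amplification(spec: CircuitSpec, seed: int = 0, grid=None,
                          n_points: int = 21, dt: float = DEFAULT_DT,
                          require_plateaus: bool = True) -> dict:
    """Build the full and reference networks, measure both steady-state
    curves and return slopes, the simulated amplification index and the
    closed-form prediction."""
    full = build_circuit(spec, seed=seed)
    ref = build_circuit(reference_of(spec), seed=seed)
    if grid is None:
        grid = _auto_grid(full, n_points)
    c_full = steady_state_curve(full, grid, dt=dt)
    c_ref = steady_state_curve(ref, grid, dt=dt)
    a_sim = amplification_index_sim(c_full, c_ref, require_plateaus=require_plateaus)
    p = meanfield.params_from_circuit(full)
    a_th = meanfield.amplification_index_analytic(meanfield.effective_selfinhibition(
        replace(p, b=spec.adaptation.b_som)))
    return {
        "curve_full": c_full,
        "curve_ref": c_ref,
        "slope_full": sigmoid_slope(c_full, require_plateaus=require_plateaus),
        "slope_ref": sigmoid_slope(c_ref),
        "A_sim": a_sim,
        "A_theory": a_th,
    }


# ---------------------------------------------------------------------------
# frequency response
# ---------------------------------------------------------------------------


@dataclass
class FrequencyResponse:
    """Response amplitudes of full and reference networks to sinusoidal
    modulation, and the frequency-resolved amplification index."""

    periods: np.ndarray
    amplitude_full: np.ndarray
    amplitude_ref: np.ndarray
    index: np.ndarray
    resonance_freq: float
    drift_flags: np.ndarray

    @property
    def freqs(self) -> np.ndarray:
        return 1.0 / self.periods


def _oscillation_amplitudes(circuit: Circuit, periods: np.ndarray,
                            n_transient: int, n_measure: int, dt: float,
                            amplitude: float) -> tuple[np.ndarray, np.ndarray]:
    periods = np.asarray(periods, dtype=float)
    target, sign = circuit.spec.modulatory_target()
    proto = constant_protocol(circuit, x_mod=np.zeros(periods.size))
    proto.add(target, Sinusoid(period=periods[:, None], amplitude=sign * amplitude))
    t_max = (n_transient + n_measure) * periods.max()
    duration = math.ceil(t_max / dt) * dt
    stride = 1e-3
    res = Simulator(circuit, batch=periods.size).run(
        proto, duration, dt=dt, store_stride=stride)
    resp = response_trace(res, circuit.spec)  # (nt, B)
    amps = np.empty(periods.size)
    drift = np.zeros(periods.size, dtype=bool)

    def project(sel, i):
        tt = res.t[sel]
        y = resp[sel, i]
        y = y - y.mean()
        ph = np.exp(-2j * np.pi * tt / periods[i])
        return 2.0 * abs(np.mean(y * ph))

    for i, T in enumerate(periods):
        t0, t1 = n_transient * T, (n_transient + n_measure) * T
        sel = (res.t >= t0 - 1e-12) & (res.t < t1)
        amps[i] = project(sel, i)
        half = 0.5 * (t0 + t1)
        a1 = project((res.t >= t0 - 1e-12) & (res.t < half), i)
        a2 = project((res.t >= half) & (res.t < t1), i)
        if amps[i] > 0 and abs(a1 - a2) > 0.01 * amps[i]:
            drift[i] = True
    return amps, drift


def frequency_response(full: Circuit, ref: Circuit, periods,
                       n_transient: int = 5, n_measure: int = 10,
                       dt: float = DEFAULT_DT, amplitude: float = 1.0) -> FrequencyResponse:
    """Frequency-resolved amplification: response amplitude (first Fourier
    coefficient at the stimulation frequency) of the full vs the reference
    network under unit sinusoidal modulation, after discarding transient
    cycles.  Resonance is the scanned frequency maximizing the index."""
    periods = np.asarray(periods, dtype=float)
    amp_full, drift_f = _oscillation_amplitudes(full, periods, n_transient, n_measure,
                                                dt, amplitude)
    amp_ref, drift_r = _oscillation_amplitudes(ref, periods, n_transient, n_measure,
                                               dt, amplitude)
    if np.any(amp_ref <= 0):
        raise MeasureError("zero reference amplitude")
    index = np.log2(amp_full / amp_ref)
    res_freq = float(1.0 / periods[np.argmax(index)])
    return FrequencyResponse(
        periods=periods, amplitude_full=amp_full, amplitude_ref=amp_ref,
        index=index, resonance_freq=res_freq, drift_flags=drift_f | drift_r,
    )


# ---------------------------------------------------------------------------
# correlations and oscillation frequency
# ---------------------------------------------------------------------------


def pairwise_correlations(result: SimulationResult, population: str = "S",
                          discard: float = 0.5) -> float:
    """Mean Pearson correlation over all unordered within-population pairs
    of rate traces (transient discarded)."""
    key = f"r_{population.lower()}"
    arr = result.data[key]
    if arr.ndim != 2:
        raise MeasureError("pairwise correlations require an unbatched run")
    sel = result.t >= result.t[0] + discard
    x = arr[sel]
    if np.any(x.std(axis=0) == 0):
        raise MeasureError("zero-variance trace")
    c = np.corrcoef(x.T)
    n = c.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(c[iu].mean())


def dominant_frequency(y: np.ndarray, fs: float, min_rel_power: float = 10.0,
                       cross_check_tol: float = 0.05) -> float:
    """Dominant frequency (Hz) of a trace: largest periodogram peak
    (parabolically refined), cross-validated against the mean inter-peak
    interval of the time-domain signal; the two must agree within 5%."""
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    if y.std() < 1e-6:
        raise MeasureError("not oscillating: constant trace")
    freqs, pxx = sps.periodogram(y, fs=fs, window="hann")
    k = int(np.argmax(pxx[1:])) + 1
    floor = np.median(pxx[1:]) + 1e-30
    if pxx[k] < min_rel_power * floor:
        raise MeasureError("not oscillating: no spectral peak above floor")
    # parabolic refinement of the peak position
    if 1 <= k < len(pxx) - 1:
        a, b, c = np.log(pxx[k - 1] + 1e-300), np.log(pxx[k] + 1e-300), np.log(pxx[k + 1] + 1e-300)
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
        f_spec = freqs[k] + shift * (freqs[1] - freqs[0])
    else:
        f_spec = freqs[k]
    # inter-peak cross-check
    prom = 0.25 * (y.max() - y.min())
    peaks, _ = sps.find_peaks(y, prominence=prom)
    if len(peaks) >= 3:
        f_ipi = fs / np.mean(np.diff(peaks))
        if abs(f_ipi - f_spec) > cross_check_tol * f_spec:
            raise MeasureError(
                f"spectral ({f_spec:.3g} Hz) and inter-peak ({f_ipi:.3g} Hz) "
                "estimates disagree by more than 5%"
            )
    return float(f_spec)


def oscillation_frequency_estimate(result: SimulationResult, population: str = "S",
                                   discard: float = 2.0) -> float | np.ndarray:
    """Dominant frequency of the population-mean rate after discarding the
    transient.  For batched results, one frequency per batch row."""
    trace = result.population_mean(population)
    sel = result.t >= result.t[0] + discard
    fs = 1.0 / (result.t[1] - result.t[0])
    if trace.ndim == 1:
        return dominant_frequency(trace[sel], fs)
    return np.array([dominant_frequency(trace[sel, i], fs)
                     for i in range(trace.shape[1])])


# ---------------------------------------------------------------------------
# empirical regime classification
# ---------------------------------------------------------------------------


def _asymmetric_initial(sim: Simulator, kick: float = 0.5) -> CircuitState:
    """Default initial state plus small deterministic rate offsets that
    break both the SOM/VIP population symmetry and the within-population
    permutation symmetry (the perfectly symmetric manifolds are invariant
    under the exact dynamics)."""
    st = sim.initial_state()
    st.r_v = st.r_v + kick + np.linspace(0.0, 0.01, st.r_v.shape[-1])
    st.r_s = st.r_s + np.linspace(0.01, 0.0, st.r_s.shape[-1])
    return st


def classify_regime_sim_batch(circuits: list[Circuit], duration: float = 6.0,
                              dt: float = DEFAULT_DT, window: float = 4.0,
                              delta: float = 0.05,
                              amplification_threshold: float = 0.0) -> list[meanfield.RegimeReport]:
    """Empirical regime labels for a batch of SOM-VIP motifs.

    Each circuit is integrated from a weakly asymmetric initial state; the
    final window is analysed for silenced populations (winner-take-all),
    alternating winners with a spectral peak (oscillation) or coexistence.
    Coexistence points are split into amplification/attenuation from the
    measured amplification index (steady-state SOM-rate slopes of motif vs
    reference under a +-delta modulatory perturbation).
    """
    sim = Simulator(circuits)
    res = sim.run(_BatchConstant(sim), duration, dt=dt,
                  initial=_asymmetric_initial(sim), store_stride=1e-3)
    nb = len(circuits)
    t = res.t
    win = t >= t[-1] - window
    tail = t >= t[-1] - 0.5
    fs = 1.0 / (t[1] - t[0])
    reports: list[meanfield.RegimeReport | None] = [None] * nb

    s_mean = res.population_mean("S")
    v_mean = res.population_mean("V")
    coexist_idx = []
    for i in range(nb):
        s_units = res.data["r_s"][tail][:, i, :].mean(axis=0)
        v_units = res.data["r_v"][tail][:, i, :].mean(axis=0)
        n_s = int((s_units > SILENCE_THRESHOLD).sum())
        n_v = int((v_units > SILENCE_THRESHOLD).sum())
        sw, vw = s_mean[win, i], v_mean[win, i]
        oscillatory = sw.std() > 0.05 and vw.std() > 0.05
        label = None
        if oscillatory:
            try:
                dominant_frequency(sw, fs)
                label = "oscillation"
            except MeasureError:
                label = None
        if label is None:
            if (n_s == 0) != (n_v == 0):
                n_win = max(n_s, n_v)
                n_pop = res.data["r_s"].shape[-1]
                if n_win == n_pop:
                    label = "wta_switch"
                elif n_win == 1:
                    label = "total_wta"
                else:
                    label = "wta_switch"  # partial winner; boundary-ish
            elif n_s == 1 and n_v == 1 and res.data["r_s"].shape[-1] > 1:
                label = "wta_within_population"
            else:
                coexist_idx.append(i)
        if label is not None:
            reports[i] = meanfield.RegimeReport(
                label=label, leading_eigenvalues=[], margins={},
            )

    if coexist_idx:
        a_vals = _motif_amplification_sim(circuits, delta=delta, dt=dt)
        for i in coexist_idx:
            a = a_vals[i]
            label = "amplification" if a > amplification_threshold else "attenuation"
            reports[i] = meanfield.RegimeReport(
                label=label, leading_eigenvalues=[], margins={},
                amplification_index=float(a),
                boundary_flag=abs(a - amplification_threshold) < 0.1 * max(
                    abs(amplification_threshold), 1.0),
            )
    return reports


class _BatchConstant:
    def __init__(self, sim: Simulator):
        self.baseline = sim.baseline

    def drives(self, t, t_step, classes):
        return {c: self.baseline[c] for c in classes}


def _motif_amplification_sim(circuits: list[Circuit], delta: float, dt: float) -> np.ndarray:
    """Measured amplification index per motif: slope of the SOM rate with
    respect to the modulatory input in the motif vs its no-VIP reference."""

    def som_slope(circs, sign_grid):
        sim = Simulator(circs)
        states = []
        for s in sign_grid:
            proto = _PerturbedConstant(sim, s * delta)
            st, conv, _ = _steady_batched(sim, proto)
            states.append(st.r_s.mean(axis=-1))
        return (states[1] - states[0]) / (2 * delta)

    refs = [build_circuit(replace(reference_of(c.spec), include_pc=False), seed=0)
            for c in circuits]
    m_full = np.abs(som_slope(circuits, (-1.0, 1.0)))
    m_ref = np.abs(som_slope(refs, (-1.0, 1.0)))
    with np.errstate(divide="ignore"):
        return np.log2(m_full / m_ref)


class _PerturbedConstant:
    def __init__(self, sim: Simulator, x_mod: float):
        self.baseline = dict(sim.baseline)
        target, sign = sim.spec.modulatory_target()
        self.baseline[target] = self.baseline[target] + sign * x_mod

    def drives(self, t, t_step, classes):
        return {c: self.baseline[c] for c in classes}


def _steady_batched(sim: Simulator, proto, max_time: float = MAX_SETTLE_TIME,
                    chunk: float = 0.5, dt: float = DEFAULT_DT,
                    initial: CircuitState | None = None):
    state, t = initial, 0.0
    conv = None
    while t < max_time - 1e-12:
        res = sim.run(proto, chunk, dt=dt, initial=state, store_stride=1e-3, t0=t)
        state, t = res.final_state, t + chunk
        n_win = max(2, int(round(CONVERGENCE_WINDOW / 1e-3)))
        dev = []
        for k in (k for k in res.data if k.startswith("r_")):
            arr = res.data[k][-n_win:]
            dev.append(np.abs(arr - arr[-1]).max(axis=(0, -1)))
        conv = np.max(dev, axis=0) < CONVERGENCE_TOL
        if np.all(conv):
            break
    return state, conv, t


def classify_regime_sim(circuit: Circuit, duration: float = 6.0, dt: float = DEFAULT_DT,
                        **kw) -> meanfield.RegimeReport:
    """Empirical regime label of one SOM-VIP motif (see the batch variant)."""
    return classify_regime_sim_batch([circuit], duration=duration, dt=dt, **kw)[0]


# ---------------------------------------------------------------------------
# input decomposition and hysteresis
# ---------------------------------------------------------------------------


@dataclass
class InputDecomposition:
    """Least-squares gains of the bottom-up (alpha) and top-down (beta)
    input streams in the PC population rate."""

    alpha: float
    beta: float
    residual: float


def input_coefficients(result: SimulationResult, x_e: np.ndarray, x_d: np.ndarray,
                       discard: float = 1.0) -> InputDecomposition:
    """Regress the PC population rate on [1, x_E(t), x_D(t)] over the
    post-transient window."""
    y = result.population_mean("E")
    if y.ndim != 1:
        raise MeasureError("input decomposition requires an unbatched run")
    sel = result.t >= result.t[0] + discard
    X = np.column_stack([np.ones(sel.sum()), np.asarray(x_e)[sel], np.asarray(x_d)[sel]])
    if np.linalg.matrix_rank(X) < 3:
        raise MeasureError("collinear regressors")
    coef, res_, *_ = np.linalg.lstsq(X, y[sel], rcond=None)
    resid = float(res_[0]) if len(res_) else 0.0
    return InputDecomposition(alpha=float(coef[1]), beta=float(coef[2]), residual=resid)


def hysteresis_scan(circuit: Circuit, x_lo: float, x_hi: float, n_steps: int,
                    settle_time: float = 2.0, dt: float = DEFAULT_DT,
                    tol: float = CONVERGENCE_TOL, direction: str = "both"):
    """Staircase the modulatory input up then down, warm-starting each step
    from the previous steady state.  Returns (up, down) response curves
    (the down branch is returned on the same increasing grid)."""
    grid = np.linspace(x_lo, x_hi, n_steps)
    sim = Simulator(circuit)
    state = None
    branches = {}
    orders = {"up": grid, "down": grid[::-1]}
    for name in ("up", "down") if direction == "both" else (direction,):
        resp, conv = [], []
        for x in orders[name]:
            proto = _PerturbedConstant(sim, float(x))
            state, c, _ = _steady_batched(sim, proto, max_time=settle_time, dt=dt,
                                          initial=state)
            resp.append(float(_response_from_state(state, circuit.spec)))
            conv.append(bool(np.all(c)))
        resp, conv = np.asarray(resp), np.asarray(conv)
        if name == "down":
            resp, conv = resp[::-1], conv[::-1]
        branches[name] = SteadyStateCurve(x_mod=grid, response=resp, converged=conv)
    if direction == "both":
        return branches["up"], branches["down"]
    return branches[direction]


def hysteresis_stats(up: SteadyStateCurve, down: SteadyStateCurve,
                     threshold: float = 0.5) -> float:
    """Width (1/s) of the modulatory-input interval over which the two
    branches differ by more than ``threshold`` (bistable range)."""
    if not np.array_equal(up.x_mod, down.x_mod):
        raise MeasureError("branches must share the same grid")
    if not (np.all(up.converged) and np.all(down.converged)):
        raise MeasureError("non-converged steps inside the hysteresis scan")
    mask = np.abs(up.response - down.response) > threshold
    if not mask.any():
        return 0.0
    dx = up.x_mod[1] - up.x_mod[0]
    return float(mask.sum() * dx)
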