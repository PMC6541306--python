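"""Rate dynamics and fixed-step Heun (RK2) integration.

Interneurons follow rectified linear rate equations

    tau r'_i = -r_i + sum_j w_ij u_ij r_j - a_i + x_i,   r_i >= 0,

with spike-frequency adaptation ``tau_a a' = -a + b r`` on SOM and VIP
cells and Tsodyks-Markram short-term facilitation ``u`` on the mutual
SOM<->VIP synapses.  PC somata follow ``tau_E r' = -r + [I - theta]_+``
where the total somatic drive combines attenuated dendritic input
(including a threshold-triggered calcium event) and somatic input.

Rectification is applied as a clamp after each integration (sub)step, not
inside the derivative; the calcium indicator is recomputed instantaneously
at every derivative evaluation.  Noise in stimulus protocols is held
constant within each integration step (piecewise-constant input).

The integrator supports a leading batch axis so that parameter sweeps and
stimulus grids integrate in lockstep; weight matrices may be shared
``(n_post, n_pre)`` or per-batch ``(B, n_post, n_pre)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import Circuit, CircuitSpec, PCParams, STFParams

__all__ = [
    "CircuitState",
    "PCInputs",
    "SimulationResult",
    "pc_inputs",
    "pc_rate_rhs",
    "adaptation_rhs",
    "stf_rhs",
    "interneuron_rhs",
    "Simulator",
    "step_rk2",
    "simulate",
    "DEFAULT_DT",
]

#: default integration step (s); the model is specified with a maximum
#: admissible step of 0.05 ms
DEFAULT_DT = 5e-5


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


@dataclass
class CircuitState:
    """All state variables at one time point.

    Arrays have shape ``(..., n_class)``; entries are ``None`` for absent
    populations.  ``u_s`` / ``u_v`` are the facilitation variables of the
    synapses with SOM resp. VIP presynaptic cells (identical across
    postsynaptic targets, since facilitation depends only on the
    presynaptic rate).
    """

    r_e: np.ndarray | None = None
    r_p: np.ndarray | None = None
    r_s: np.ndarray | None = None
    r_v: np.ndarray | None = None
    a_s: np.ndarray | None = None
    a_v: np.ndarray | None = None
    u_s: np.ndarray | None = None
    u_v: np.ndarray | None = None

    def rate(self, cls: str) -> np.ndarray | None:
        return {"E": self.r_e, "P": self.r_p, "S": self.r_s, "V": self.r_v}[cls]


@dataclass
class PCInputs:
    """Decomposed pyramidal-cell drive (all in 1/s)."""

    i_syn_e: np.ndarray
    i_syn_d: np.ndarray
    i_d0: np.ndarray
    c: np.ndarray
    i_total: np.ndarray


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------


def _mv(w: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Matrix-vector product supporting shared (n,n) or batched (B,n,n)
    weights against (..., n) rate vectors."""
    if w.ndim == 2:
        return r @ w.T
    return np.matmul(w, r[..., :, None])[..., 0]


def pc_inputs(r_e, r_p, r_s, x_e, x_d, w_ep, w_ds, w_de, pc: PCParams) -> PCInputs:
    """Somatic/dendritic synaptic inputs, calcium event and total drive.

    ``i_syn_e = x_e + W_EP r_p`` (W_EP carries the inhibitory sign),
    ``i_syn_d = x_d + W_DS r_s + W_DE r_e``.  A calcium event of amplitude
    ``c_amp`` fires when the synaptically generated dendritic input
    ``i_d0 = lambda_e * i_syn_e + (1 - lambda_d) * i_syn_d`` strictly
    exceeds ``theta_c`` (Heaviside convention H(0) = 0).
    """
    i_syn_e = x_e + (_mv(w_ep, r_p) if w_ep is not None else 0.0)
    i_syn_d = np.asarray(x_d, dtype=float) + 0.0
    if w_ds is not None:
        i_syn_d = i_syn_d + _mv(w_ds, r_s)
    if w_de is not None:
        i_syn_d = i_syn_d + _mv(w_de, r_e)
    i_syn_e = np.broadcast_to(np.asarray(i_syn_e, float), np.broadcast_shapes(
        np.shape(i_syn_e), np.shape(i_syn_d)))
    i_syn_d = np.broadcast_to(i_syn_d, i_syn_e.shape)
    i_d0 = pc.lambda_e * i_syn_e + (1.0 - pc.lambda_d) * i_syn_d
    c = np.where(i_d0 > pc.theta_c, pc.c_amp, 0.0)
    i_total = pc.lambda_d * np.maximum(i_syn_d + c, 0.0) + (1.0 - pc.lambda_e) * i_syn_e
    return PCInputs(i_syn_e=i_syn_e, i_syn_d=i_syn_d, i_d0=i_d0, c=c, i_total=i_total)


def pc_rate_rhs(r_e, inputs: PCInputs, pc: PCParams) -> np.ndarray:
    """``(-r + [I - theta]_+) / tau_E``; rectified above rheobase."""
    return (-r_e + np.maximum(inputs.i_total - pc.theta, 0.0)) / pc.tau_e


def adaptation_rhs(a, r, b, tau_a) -> np.ndarray:
    """``(-a + b r) / tau_a``; at constant rate, a -> b r exponentially."""
    return (-a + b * r) / tau_a


def stf_rhs(u, r_pre, stf: STFParams) -> np.ndarray:
    """Tsodyks-Markram facilitation: ``(U_s - u)/tau_f + U_s (1-u) r_pre``."""
    return (stf.u_s - u) / stf.tau_f + stf.u_s * (1.0 - u) * r_pre


def interneuron_rhs(r, syn, x, a, tau) -> np.ndarray:
    """Rate derivative ``(-r + syn + x - a) / tau``; rectification is
    applied by the integrator as a clamp, not inside the derivative."""
    return (-r + syn + x - a) / tau


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------


class _ConstantProtocol:
    """Minimal protocol: per-class constant drives."""

    def __init__(self, drives: dict):
        self._drives = drives

    def drives(self, t, t_step, classes):
        return {c: self._drives.get(c, 0.0) for c in classes}


@dataclass
class SimulationResult:
    """Stored trajectory of one (possibly batched) integration run."""

    t: np.ndarray
    data: dict
    final_state: CircuitState
    dt: float
    spec: CircuitSpec

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key]

    def population_mean(self, cls: str) -> np.ndarray:
        """Population-mean rate trace, shape (nt, ...)."""
        return self.data[f"r_{cls.lower()}"].mean(axis=-1)

    def to_frame(self):
        """Tidy long-format DataFrame (time, population, unit, variable, value).

        Only defined for unbatched runs.
        """
        import pandas as pd

        rows = []
        for key, arr in self.data.items():
            if arr.ndim != 2:
                raise ValueError("to_frame supports unbatched results only")
            var, cls = key.split("_")
            for unit in range(arr.shape[1]):
                rows.append(pd.DataFrame({
                    "time": self.t,
                    "population": cls.upper(),
                    "unit": unit,
                    "variable": var,
                    "value": arr[:, unit],
                }))
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> dict:
        """Final-state population means, JSON-friendly."""
        out = {}
        for key, arr in self.data.items():
            out[f"{key}_final_mean"] = float(np.mean(arr[-1]))
        return out


class Simulator:
    """Heun (explicit second-order Runge-Kutta) integrator for one circuit
    or a batch of structurally identical circuits.

    Within each step, the Euler predictor is clamped (interneuron rates at
    zero, facilitation to [0, 1]) before the corrector evaluation, and the
    corrected state is clamped again.  PC somatic rates need no clamp: with
    non-negative initialization the rectified drive keeps them
    non-negative.
    """

    def __init__(self, circuits: Circuit | list[Circuit], batch: int | None = None):
        if isinstance(circuits, Circuit):
            # a bare integer `batch` replicates one circuit across a drive
            # batch (shared weights, per-row stimuli)
            self.batch = batch
            members = [circuits]
        else:
            members = list(circuits)
            if not members:
                raise ValueError("empty circuit batch")
            self.batch = len(members)
        self.circuit = members[0]
        self.spec = self.circuit.spec
        for c in members[1:]:
            if c.spec.classes_present() != self.spec.classes_present():
                raise ValueError("batched circuits must share variant/layout")
        self.classes = self.spec.classes_present()
        self.has_pc = self.spec.has_pc

        def stack(vals):
            vals = [np.asarray(v, float) for v in vals]
            if len(members) == 1:
                return vals[0]
            if all(np.array_equal(vals[0], v) for v in vals[1:]):
                return vals[0]
            return np.stack(vals)

        self.w = {}
        for pair in members[0].weights.pairs():
            self.w[pair] = stack([c.weights.matrices[pair] for c in members])

        def scal(vals):
            if len(set(vals)) == 1:
                return vals[0]
            return np.asarray(vals, float)[:, None]

        self.tau = self.spec.interneuron_tau
        ad = [c.spec.adaptation for c in members]
        self.b_s = scal([a.b_som for a in ad])
        self.b_v = scal([a.b_vip for a in ad])
        self.tau_a_s = scal([a.tau_a_som for a in ad])
        self.tau_a_v = scal([a.tau_a_vip for a in ad])
        stfs = [c.spec.stf for c in members]
        self.stf_enabled = any(s.enabled for s in stfs)
        self.u_s0 = scal([s.u_s for s in stfs])
        self.tau_f = scal([s.tau_f for s in stfs])
        self.pc = self.spec.pc
        self.baseline = {
            c: stack([m.background[c] for m in members]) for c in self.classes
        }
        self._has_u = ("V", "S") in self.w or ("S", "V") in self.w
        self._sl, self._ndim = self._slices()

    # -- state packing -------------------------------------------------

    def _dims(self):
        dims = []
        if self.has_pc:
            dims.append(("r_e", self.circuit.n("E")))
        for c in ("P", "S", "V"):
            if c in self.classes:
                dims.append((f"r_{c.lower()}", self.circuit.n(c)))
        if "S" in self.classes:
            dims.append(("a_s", self.circuit.n("S")))
        if "V" in self.classes:
            dims.append(("a_v", self.circuit.n("V")))
        if self._has_u:
            dims.append(("u_s", self.circuit.n("S")))
            dims.append(("u_v", self.circuit.n("V")))
        return dims

    def _slices(self):
        sl, off = {}, 0
        for name, n in self._dims():
            sl[name] = slice(off, off + n)
            off += n
        return sl, off

    def initial_state(self) -> CircuitState:
        """Default initial conditions: rates and adaptation at zero,
        facilitation at the initial release probability ``U_s``."""
        shape = (self.batch,) if self.batch else ()
        st = CircuitState()
        for name, n in self._dims():
            val = np.zeros(shape + (n,))
            if name in ("u_s", "u_v"):
                val = val + self.u_s0
            setattr(st, name, val)
        return st

    def pack(self, state: CircuitState) -> np.ndarray:
        sl, total = self._sl, self._ndim
        shape = (self.batch,) if self.batch else ()
        y = np.zeros(shape + (total,))
        for name in sl:
            val = getattr(state, name)
            if val is None:
                raise ValueError(f"initial state missing {name}")
            y[..., sl[name]] = val
        return y

    def unpack(self, y: np.ndarray) -> CircuitState:
        sl = self._sl
        st = CircuitState()
        for name in sl:
            setattr(st, name, y[..., sl[name]].copy())
        return st

    # -- derivative ----------------------------------------------------

    def _rhs(self, y: np.ndarray, drive: dict) -> np.ndarray:
        sl = self._sl
        out = np.empty_like(y)
        w = self.w
        r_s = y[..., sl["r_s"]] if "r_s" in sl else None
        r_v = y[..., sl["r_v"]] if "r_v" in sl else None
        r_p = y[..., sl["r_p"]] if "r_p" in sl else None
        r_e = y[..., sl["r_e"]] if "r_e" in sl else None
        if self._has_u:
            u_s, u_v = y[..., sl["u_s"]], y[..., sl["u_v"]]
            rs_eff = u_s * r_s
            rv_eff = u_v * r_v
        else:
            rs_eff, rv_eff = r_s, r_v

        def syn(post):
            tot = 0.0
            for (po, pre), mat in w.items():
                if po != post:
                    continue
                if pre == "E":
                    pre_r = r_e
                elif pre == "P":
                    pre_r = r_p
                elif pre == "S":
                    pre_r = rs_eff if (po, pre) in (("V", "S"),) else r_s
                else:  # pre == "V"
                    pre_r = rv_eff if (po, pre) in (("S", "V"),) else r_v
                tot = tot + _mv(mat, pre_r)
            return tot

        if r_p is not None:
            out[..., sl["r_p"]] = interneuron_rhs(r_p, syn("P"), drive["P"], 0.0, self.tau)
        if r_s is not None:
            a_s = y[..., sl["a_s"]]
            out[..., sl["r_s"]] = interneuron_rhs(r_s, syn("S"), drive["S"], a_s, self.tau)
            out[..., sl["a_s"]] = adaptation_rhs(a_s, r_s, self.b_s, self.tau_a_s)
        if r_v is not None:
            a_v = y[..., sl["a_v"]]
            out[..., sl["r_v"]] = interneuron_rhs(r_v, syn("V"), drive["V"], a_v, self.tau)
            out[..., sl["a_v"]] = adaptation_rhs(a_v, r_v, self.b_v, self.tau_a_v)
        if self._has_u:
            out[..., sl["u_s"]] = (self.u_s0 - u_s) / self.tau_f + self.u_s0 * (1.0 - u_s) * r_s
            out[..., sl["u_v"]] = (self.u_s0 - u_v) / self.tau_f + self.u_s0 * (1.0 - u_v) * r_v
        if r_e is not None:
            inp = pc_inputs(
                r_e, r_p, r_s, drive["E"], drive["D"],
                w.get(("E", "P")), w.get(("D", "S")), w.get(("D", "E")), self.pc,
            )
            out[..., sl["r_e"]] = pc_rate_rhs(r_e, inp, self.pc)
        return out

    def _clamp(self, y: np.ndarray) -> np.ndarray:
        sl = self._sl
        for name in ("r_p", "r_s", "r_v"):
            if name in sl:
                np.maximum(y[..., sl[name]], 0.0, out=y[..., sl[name]])
        if self._has_u:
            for name in ("u_s", "u_v"):
                np.clip(y[..., sl[name]], 0.0, 1.0, out=y[..., sl[name]])
        return y

    def _expand_drive(self, protocol, t, t_step):
        return protocol.drives(t, t_step, self.classes)

    def step(self, y: np.ndarray, t: float, dt: float, protocol) -> np.ndarray:
        """One Heun step from t to t+dt (predictor clamped before the
        corrector evaluation; full step clamped afterwards)."""
        d0 = self._expand_drive(protocol, t, t)
        f0 = self._rhs(y, d0)
        y_pred = self._clamp(y + dt * f0)
        d1 = self._expand_drive(protocol, t + dt, t)
        f1 = self._rhs(y_pred, d1)
        return self._clamp(y + 0.5 * dt * (f0 + f1))

    # -- main loop -----------------------------------------------------

    def run(self, protocol, duration: float, dt: float = DEFAULT_DT,
            initial: CircuitState | None = None, store_stride: float = 1e-3,
            t0: float = 0.0, check_finite: bool = True) -> SimulationResult:
        if dt > DEFAULT_DT + 1e-12:
            raise ValueError(f"dt must not exceed {DEFAULT_DT} s")
        n_steps = int(round(duration / dt))
        if abs(n_steps * dt - duration) > 1e-9:
            raise ValueError("duration must be an integer number of steps")
        stride = max(1, int(round(store_stride / dt)))
        y = self.pack(initial if initial is not None else self.initial_state())

        sl = self._sl
        n_store = n_steps // stride + 1
        stored = {name: np.empty((n_store,) + y[..., s].shape) for name, s in sl.items()}
        t_out = np.empty(n_store)
        idx = 0

        def store(k, yv):
            nonlocal idx
            t_out[idx] = t0 + k * dt
            for name, s in sl.items():
                stored[name][idx] = yv[..., s]
            idx += 1

        store(0, y)
        for k in range(n_steps):
            y = self.step(y, t0 + k * dt, dt, protocol)
            if (k + 1) % stride == 0:
                if check_finite and not np.all(np.isfinite(y)):
                    raise FloatingPointError(
                        f"non-finite state at t = {t0 + (k + 1) * dt:.6f} s"
                    )
                store(k + 1, y)
        for name in stored:
            stored[name] = stored[name][:idx]
        return SimulationResult(
            t=t_out[:idx], data=stored, final_state=self.unpack(y), dt=dt,
            spec=self.spec,
        )


def step_rk2(circuit: Circuit, state: CircuitState, t: float, dt: float,
             protocol) -> CircuitState:
    """Single Heun step of the circuit; convenience wrapper around
    :class:`Simulator` for tests and inspection."""
    sim = Simulator(circuit)
    y = sim.pack(state)
    return sim.unpack(sim.step(y, t, dt, protocol))


def simulate(circuit: Circuit | list[Circuit], protocol=None, duration: float = 1.0,
             dt: float = DEFAULT_DT, initial: CircuitState | None = None,
             store_stride: float = 1e-3, t0: float = 0.0,
             batch: int | None = None) -> SimulationResult:
    """Integrate the circuit under a stimulus protocol.

    ``protocol`` defaults to the circuit's calibrated constant background.
    Initial conditions default to zero rates and adaptation with
    facilitation at ``U_s``.  A list of structurally identical circuits is
    integrated as one batch (leading axis of all stored arrays).
    """
    sim = Simulator(circuit, batch=batch)
    if protocol is None:
        protocol = _ConstantProtocol(sim.baseline)
    return sim.run(protocol, duration, dt=dt, initial=initial,
                   store_stride=store_stride, t0=t0)
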