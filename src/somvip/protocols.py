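"""Stimulus protocols: constant backgrounds, modulatory grids, sinusoids,
frozen noise, pulse trains, visuomotor sessions and hysteresis ramps.

A :class:`StimulusProtocol` maps each population (or PC compartment) to a
baseline drive plus additive time-dependent components.  Deterministic
components are evaluated at the exact integration stage time; noise
components are frozen over windows of length ``noise_dt`` and keyed by the
window index, so a protocol reproduces bit-identical drive sequences for a
fixed seed regardless of how the simulation horizon is chunked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import Circuit

__all__ = [
    "StimulusProtocol",
    "SessionSchedule",
    "Constant",
    "Sinusoid",
    "PulseTrain",
    "FrozenNoise",
    "CorrelatedNoise",
    "SessionDrive",
    "constant_protocol",
    "modulatory_grid",
    "sinusoidal_modulation",
    "correlated_noise",
    "pulse_train",
    "visuomotor_session",
    "hysteresis_ramp",
]


class ProtocolError(ValueError):
    pass


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------


class Component:
    """Additive drive component.  ``value(t, t_step)`` returns a scalar or
    an array broadcastable to the target population's rate vector; ``t`` is
    the stage time, ``t_step`` the start of the enclosing integration step
    (used by frozen-noise components)."""

    static = False

    def value(self, t: float, t_step: float):  # pragma: no cover - interface
        raise NotImplementedError


class Constant(Component):
    static = True

    def __init__(self, value):
        self.const = np.asarray(value, dtype=float)

    def value(self, t, t_step):
        return self.const


class Sinusoid(Component):
    """``amplitude * sin(2 pi (t - t_on) / period + phase)``, optionally
    gated to ``[t_on, t_off)``.  ``period`` may be an array for batched
    runs (one period per batch row; shape ``(B, 1)``)."""

    def __init__(self, period, amplitude=1.0, phase=0.0, t_on=0.0, t_off=None):
        period = np.asarray(period, dtype=float)
        if np.any(period <= 0):
            raise ProtocolError("period must be positive")
        self.period = period
        self.amplitude = amplitude
        self.phase = phase
        self.t_on = t_on
        self.t_off = t_off

    def value(self, t, t_step):
        if t < self.t_on or (self.t_off is not None and t >= self.t_off):
            return 0.0
        return self.amplitude * np.sin(2.0 * np.pi * (t - self.t_on) / self.period + self.phase)


class AngularSinusoid(Component):
    """``offset + amplitude * sin(omega t)`` with angular frequency in
    rad/s (used by the top-down/bottom-up input pair)."""

    def __init__(self, omega, amplitude, offset=0.0):
        self.omega = omega
        self.amplitude = amplitude
        self.offset = offset

    def value(self, t, t_step):
        return self.offset + self.amplitude * np.sin(self.omega * t)


class PulseTrain(Component):
    """Rectangular pulses added to the background.  ``amplitudes`` may be a
    scalar or one value per pulse; pulses must not overlap."""

    def __init__(self, times, width, amplitudes):
        times = np.asarray(times, dtype=float)
        if times.size > 1 and np.any(np.diff(np.sort(times)) < width):
            raise ProtocolError("overlapping pulses")
        self.times = np.sort(times)
        order = np.argsort(np.asarray(times, dtype=float))
        self.width = float(width)
        amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), times.shape).copy()
        self.amplitudes = amplitudes[order]

    def value(self, t, t_step):
        if self.times.size == 0:
            return 0.0
        i = np.searchsorted(self.times, t, side="right") - 1
        if i >= 0 and t < self.times[i] + self.width:
            return float(self.amplitudes[i])
        return 0.0

    def integral(self) -> float:
        return float(np.sum(self.amplitudes) * self.width)


class _IndexedNoise(Component):
    """Base for noise frozen over ``noise_dt`` windows; draws are keyed by
    the window index of the step start time, making them independent of
    chunking and restarts."""

    def __init__(self, seed, noise_dt):
        if noise_dt is None or noise_dt <= 0:
            raise ProtocolError("noise_dt must be positive")
        self.seed = int(seed)
        self.noise_dt = float(noise_dt)
        self._idx = None
        self._val = 0.0

    def _draw(self, rng: np.random.Generator):  # pragma: no cover - interface
        raise NotImplementedError

    def value(self, t, t_step):
        idx = int(np.floor(t_step / self.noise_dt + 1e-9))
        if idx != self._idx:
            self._idx = idx
            self._val = self._draw(np.random.default_rng((self.seed, idx)))
        return self._val


class FrozenNoise(_IndexedNoise):
    """Independent Gaussian noise per unit, SD ``sd`` (1/s)."""

    def __init__(self, sd, n_units, seed, noise_dt):
        super().__init__(seed, noise_dt)
        self.sd = float(sd)
        self.n_units = int(n_units)

    def _draw(self, rng):
        return self.sd * rng.standard_normal(self.n_units)


class CorrelatedNoise(_IndexedNoise):
    """Multiplicative shared + individual noise around a mean drive:
    ``x_i = x_bar (1 + c_shared xi_shared + c_indiv xi_i)`` with standard
    normal draws per window.  Returned as the deviation from ``x_bar`` (the
    mean itself lives in the protocol baseline)."""

    def __init__(self, x_bar, n_units, seed, noise_dt, c_shared=0.6, c_indiv=0.4):
        super().__init__(seed, noise_dt)
        self.x_bar = float(x_bar)
        self.n_units = int(n_units)
        self.c_shared = float(c_shared)
        self.c_indiv = float(c_indiv)

    def _draw(self, rng):
        shared = rng.standard_normal()
        indiv = rng.standard_normal(self.n_units) if self.c_indiv else 0.0
        return self.x_bar * (self.c_shared * shared + self.c_indiv * indiv)


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered contiguous blocks of (visual_on, motor_on, duration)."""

    blocks: tuple

    def __post_init__(self):
        for b in self.blocks:
            if len(b) != 3 or b[2] <= 0:
                raise ProtocolError("blocks must be (visual_on, motor_on, duration>0)")

    @property
    def duration(self) -> float:
        return float(sum(b[2] for b in self.blocks))

    def edges(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([b[2] for b in self.blocks])])

    def flags_at(self, t: float) -> tuple[bool, bool]:
        edges = self.edges()
        i = min(int(np.searchsorted(edges, t, side="right") - 1), len(self.blocks) - 1)
        v, m, _ = self.blocks[max(i, 0)]
        return bool(v), bool(m)


class SessionDrive(_IndexedNoise):
    """Sensory or motor drive of a visuomotor session: when the followed
    flag is on, ``amplitude + N(0, sd)`` per unit, frozen per noise
    window; zero otherwise."""

    def __init__(self, schedule: SessionSchedule, flag: str, n_units, seed,
                 noise_dt, amplitude=10.5, sd=3.5):
        super().__init__(seed, noise_dt)
        if flag not in ("visual", "motor"):
            raise ProtocolError("flag must be 'visual' or 'motor'")
        self.schedule = schedule
        self.flag = flag
        self.n_units = int(n_units)
        self.amplitude = float(amplitude)
        self.sd = float(sd)

    def _draw(self, rng):
        return self.amplitude + self.sd * rng.standard_normal(self.n_units)

    def value(self, t, t_step):
        visual, motor = self.schedule.flags_at(t_step)
        on = visual if self.flag == "visual" else motor
        if not on:
            return 0.0
        return super().value(t, t_step)


# ---------------------------------------------------------------------------
# protocol container
# ---------------------------------------------------------------------------


class StimulusProtocol:
    """Per-class baseline plus additive components.

    The baseline is typically the circuit's calibrated background.  Static
    components are folded into the baseline once; dynamic components are
    re-evaluated each integration stage.
    """

    def __init__(self, baseline: dict, noise_dt: float = 5e-5):
        self.baseline = {k: np.asarray(v, dtype=float) for k, v in baseline.items()}
        self.noise_dt = noise_dt
        self._static = None
        self._dynamic = []
        self._pending = []

    def add(self, target: str, component: Component) -> "StimulusProtocol":
        if target not in self.baseline:
            raise ProtocolError(f"unknown target class {target!r}")
        self._pending.append((target, component))
        self._static = None
        return self

    def _build(self):
        static = {k: v.copy() for k, v in self.baseline.items()}
        dynamic = []
        for target, comp in self._pending:
            if comp.static:
                static[target] = static[target] + comp.value(0.0, 0.0)
            else:
                dynamic.append((target, comp))
        self._static, self._dynamic = static, dynamic

    def drives(self, t: float, t_step: float, classes) -> dict:
        if self._static is None:
            self._build()
        d = dict(self._static)
        for target, comp in self._dynamic:
            d[target] = d[target] + comp.value(t, t_step)
        return d


def constant_protocol(circuit: Circuit, x_mod: float | np.ndarray = 0.0,
                      noise_dt: float = 5e-5) -> StimulusProtocol:
    """Calibrated background plus a constant modulatory input.

    ``x_mod`` targets VIP cells, or SOM cells with inverted sign in
    reference networks without VIP.  An array ``x_mod`` of shape ``(B, 1)``
    (or ``(B,)``) produces a batched drive, one constant level per batch
    row.
    """
    proto = StimulusProtocol(circuit.background, noise_dt=noise_dt)
    target, sign = circuit.spec.modulatory_target()
    x_mod = np.asarray(x_mod, dtype=float)
    if x_mod.ndim == 1 and x_mod.size > 1:
        x_mod = x_mod[:, None]
    if np.any(x_mod != 0):
        proto.add(target, Constant(sign * x_mod))
    return proto


# ---------------------------------------------------------------------------
# protocol factories
# ---------------------------------------------------------------------------


def modulatory_grid(x_lo: float, x_hi: float, n_points: int) -> np.ndarray:
    """Evenly spaced grid of constant modulatory input levels."""
    if n_points < 3:
        raise ProtocolError("n_points must be >= 3")
    if not x_lo < x_hi:
        raise ProtocolError("x_lo must be < x_hi")
    return np.linspace(x_lo, x_hi, n_points)


def sinusoidal_modulation(period: float | np.ndarray, amplitude: float = 1.0) -> Sinusoid:
    """Unit-amplitude sine ``sin(2 pi t / T)`` used for frequency-response
    analysis; add to the modulatory target on top of the calibrated
    background."""
    return Sinusoid(period=period, amplitude=amplitude)


def correlated_noise(x_bar: float, n_units: int, seed: int,
                     noise_dt: float = 5e-5, c_shared: float = 0.6,
                     c_indiv: float = 0.4) -> CorrelatedNoise:
    """Shared + individual Gaussian modulation around ``x_bar`` used for
    the population co-activity analysis."""
    return CorrelatedNoise(x_bar, n_units, seed, noise_dt, c_shared, c_indiv)


def pulse_train(times, width: float, amplitude) -> PulseTrain:
    """Non-overlapping rectangular pulses (e.g. 10 ms, 8.4/s switching
    pulses to VIP cells)."""
    return PulseTrain(times, width, amplitude)


def visuomotor_session(circuit: Circuit, schedule: SessionSchedule, seed: int,
                       noise_dt: float = 5e-5, amplitude: float = 10.5,
                       sd: float = 3.5) -> StimulusProtocol:
    """Session stimulus for the mismatch-detection experiment.

    Visual input (when on) drives SOM, PV and the PC soma; the motor-related
    prediction (when on) drives VIP and the PC dendrite.  Each stream is the
    block amplitude plus zero-mean Gaussian noise, frozen per noise window.
    Backgrounds come from the circuit (use overrides x_E = 28/s, x_D = 0/s
    in the mismatch preset).
    """
    proto = StimulusProtocol(circuit.background, noise_dt=noise_dt)
    ss = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    visual_targets = [("S", circuit.n("S")), ("P", circuit.n("P")), ("E", circuit.n("E"))]
    motor_targets = [("V", circuit.n("V")), ("D", circuit.n("D"))]
    for (tgt, n), sd_seed in zip(visual_targets, seeds[:3]):
        proto.add(tgt, SessionDrive(schedule, "visual", n, sd_seed, noise_dt,
                                    amplitude=amplitude, sd=sd))
    for (tgt, n), sd_seed in zip(motor_targets, seeds[3:]):
        proto.add(tgt, SessionDrive(schedule, "motor", n, sd_seed, noise_dt,
                                    amplitude=amplitude, sd=sd))
    return proto


def hysteresis_ramp(circuit: Circuit, x_lo: float, x_hi: float, n_steps: int,
                    settle_time: float = 2.0, dt: float = 5e-5,
                    tol: float = 1e-4, direction: str = "both"):
    """Staircase ramp of the modulatory input, each step warm-started from
    the previous steady state; returns the up and down branches.

    Delegates to :func:`somvip.measures.hysteresis_scan`.
    """
    from . import measures

    return measures.hysteresis_scan(circuit, x_lo, x_hi, n_steps,
                                    settle_time=settle_time, dt=dt, tol=tol,
                                    direction=direction)
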