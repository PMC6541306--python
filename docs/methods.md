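# Methods

## The model

`somvip` simulates a rate-based cortical microcircuit of excitatory
pyramidal cells (PCs) and three inhibitory interneuron classes — PV
(soma-targeting), SOM (dendrite-targeting) and VIP (SOM-targeting,
disinhibitory) — built around the hypothesis that mutual inhibition
between SOM and VIP cells amplifies weak modulatory inputs into large
shifts of the somato-dendritic distribution of inhibition onto PCs.

### Pyramidal cells

Each PC has a somatic and a dendritic compartment. The somatic rate obeys

    tau_E dr/dt = -r + [I - Theta]_+,

with rheobase `Theta = 14/s` and `tau_E = 10 ms`. The total somatic drive
combines the rectified dendritic input (including a calcium event) and the
somatic synaptic input:

    I = lambda_D [I_D + c]_+ + (1 - lambda_E) I_E,
    c = c_amp * H(I_D0 - Theta_c),     I_D0 = lambda_E I_E + (1 - lambda_D) I_D,

with `lambda_E = 0.31`, `lambda_D = 0.27`, `c_amp = 7/s`,
`Theta_c = 28/s`. The calcium event models the threshold-triggered apical
calcium spike: coincident somatic and dendritic drive boosts the somatic
rate. `H` is the Heaviside function with the convention `H(0) = 0`
(measure-zero choice, fixed and documented; the indicator is recomputed
instantaneously at every derivative evaluation, with no latency or
refractoriness).

### Interneurons

Each interneuron follows a rectified linear rate equation

    tau dr_i/dt = -r_i + sum_j w_ij u_ij r_j - a_i + x_i,    r_i >= 0,

with `tau = 10 ms` for all classes. SOM and VIP cells carry
spike-frequency adaptation `tau_a da/dt = -a + b r` (strength `b`
dimensionless, `tau_a` default 100 ms; PV cells do not adapt). The mutual
SOM↔VIP synapses facilitate following the Tsodyks–Markram release
variable

    du/dt = (U_s - u)/tau_f + U_s (1 - u) r_pre,

bounded in [0, 1]; `U_s = 1` disables facilitation. Because `u` depends
only on the presynaptic rate, one facilitation variable per presynaptic
cell suffices and is shared across its targets.

When the STF strength is varied, the nominal mutual weights are divided
by `U_s` so that the initial synaptic response after prolonged silence is
unchanged. The source phrasing ("scaling the weights by U_s") is
directionally ambiguous; division is the direction that keeps the initial
response constant, which is the stated intent.

### Connectivity

Populations default to 70 PCs and 10 cells per interneuron class.
Connectivity is random but degree-regular: every cell of a class receives
exactly `K = round(p * N_pre)` inputs per presynaptic class (`round` is
Python's nearest-even rounding; the sources do not state how fractional
expected degrees were treated). Per-synapse weights are `w_hat / K` so the
summed input per cell equals the class total `w_hat` *exactly*, making the
population dynamics independent of population size (verified to 1e-9 for
a fivefold size change). Out-degrees are balanced to a spread of at most
one by a greedy dealing scheme: rows are filled in random order, each
drawing the presynaptic units with the most remaining capacity (random
tie-break, no autapses within a class). Signs follow the presynaptic
class; table magnitudes are stored positive and negated for inhibitory
classes.

### Background calibration

For interneuron-level networks, background inputs are chosen so the
spontaneous state at zero modulatory input is exactly `r0 = 3/s` for every
cell:

    x_i = (1 + b_i) r0 - sum_j w_ij u_ij r0,

with the steady-state facilitation value substituted for facilitating
synapses. The formula assumes a coexistence steady state; building a
circuit in the winner-take-all regime emits a warning. The full circuit
uses the fixed values `x_E = 17.5/s`, `x_D = 21/s`, `x_PV = x_SOM = x_VIP
= 3/s` (preset-overridable).

### Variants

`full_circuit` (PCs + PV/SOM/VIP), `interneuron_only` (PV/SOM/VIP with PC
drive absorbed into the calibrated background), `reference_no_vip` (no
VIP; the modulatory input targets SOM with inverted sign — the control
against which amplification is defined) and `som_vip_only` (the bare
motif). The reference variant exists at both the interneuron level and,
via `include_pc`, the full-circuit level; `reference_of(spec)` preserves
PC presence.

## Numerics

Integration uses Heun's method (explicit second-order Runge–Kutta) at a
fixed step `dt = 0.05 ms` (the model's maximum admissible step; smaller
values are accepted). Rectification is applied as a clamp after each
substep: the Euler predictor is clamped (interneuron rates at 0,
facilitation to [0, 1]) before the corrector evaluation, and the corrected
state is clamped again. PC somatic rates need no clamp given non-negative
initialization. Deterministic stimulus components are evaluated at the
exact stage times (preserving second-order convergence, verified by step
halving); noise is held constant within each step.

Noise is frozen over windows of `noise_dt` (default equal to `dt`) and
keyed by the absolute window index, so a protocol reproduces bit-identical
drives regardless of how a simulation is chunked or warm-started. No
`1/sqrt(dt)` scaling is applied: the noise amplitude convention is
per-sample, deliberately replicating the stated stimulus definition rather
than a white-noise limit; `noise_dt` is recorded with the protocol.

Initial conditions default to zero rates and adaptation with facilitation
at `U_s`. Steady states are declared converged when every rate variable
moves less than 1e-4/s over a trailing 200 ms window (cap 10 s simulated
time). Stored trajectories default to a 1 ms stride.

### Symmetry breaking

The perfectly symmetric SOM/VIP state is invariant under the exact
dynamics, so noiseless simulations of the symmetric motif would never
leave the (unstable) coexistence manifold. Oscillation and regime probes
therefore start from a small deterministic perturbation: +0.5/s on the
VIP population plus ±0.01/s per-unit ramps that also break the
within-population permutation symmetry. The first 2 s are discarded
before any frequency is measured.

## Mean-field theory

Ignoring rectification, the population dynamics are linear. The package
provides the closed-form coexistence steady state, the response slopes of
`r_PV − r_SOM` to the modulatory input in the full and reference
networks, and the amplification index

    A = log2(m_full / m_ref)
      = log2( w_SV (1 + w_SS) / ((1 + w_SS)(1 + w_VV) − w_SV w_VS) ),

where the `w` are totals. At steady state, adaptation of strength `b` is
equivalent to within-class recurrence of total `b` and is folded into the
self-terms for A. At the winner-take-all boundary the denominator reaches
zero; A is reported as an explicit `inf` sentinel (plus the boundary
margin), never as a floating overflow.

Regimes of the symmetric motif are classified from numerically computed
eigenvalues of the linearized block system (2n rate variables, or 4n with
adaptation) and cross-checked against the closed-form boundaries; a
disagreement raises. The anti-symmetric (competition) mode governs the
transitions: a saddle instability (determinant < 0, i.e. total mutual
inhibition at least adaptation-plus-leak) gives the persistent switch,
instability with positive determinant gives the oscillation regime. Note
that part of the oscillation regime has a *real* unstable pair (an
unstable node): the nonlinear system still oscillates (relaxation-type,
bounded by rectification), but the linearization assigns no frequency
there. Even where a complex pair exists, the linear frequency is
quantitatively predictive only for weakly unstable (near-sinusoidal)
oscillations — the system tests compare simulation against theory only
where the leading pair is underdamped (imaginary part at least twice the
growth rate); deeper in the regime the rectified limit cycle is a
relaxation oscillation whose period the linearization does not describe.
The theoretical oscillation frequency is taken from the imaginary
part of the leading complex eigenvalue pair; the printed closed form

    f = (1/4pi) sqrt( 4 b / (tau tau_a) − ((w−1)/tau + 1/tau_a)^2 )

agrees with the eigenvalue route to 1e-9 wherever its discriminant is
positive, which fixed its (typographically ambiguous) bracketing.

With recurrence instead of adaptation, strong within-class inhibition
(`w_r_hat >= n − 1`) produces the pathological winner-take-all states
(one surviving cell per population, or one cell overall when the mutual
inhibition also exceeds the leak-plus-recurrence bound). These boundaries
assume a fully connected motif; with sparse within-class connectivity the
non-uniform mode spectrum differs, so the recurrence-regime preset uses
connection probability 1 (mean-field totals are degree-independent
either way).

Two conventions exist for splitting the stable coexistence regime into
amplification and attenuation: the sign of A (used by the amplification
analyses) and the threshold A = 1 (used by the bifurcation-diagram
presets). Both are implemented via the `amplification_threshold`
argument; neither is inferred from the other.

## Measurements

* **Slope / amplification index** — steady-state response curves over a
  modulatory grid (all grid points integrated as one batch); slope is the
  maximum central finite-difference derivative (the slope estimator is
  otherwise unspecified in the sources; grid spacing defaults to 0.05/s).
  The full network's sigmoid must span both saturation plateaus; the
  reference network's response is rectified-linear and saturates on one
  side only, so the plateau requirement applies to the full curve alone.
  Only slopes are compared; horizontal offsets are ignored.
* **Frequency response** — sinusoidal modulation of unit amplitude,
  period 50–600 ms; at least 5 transient cycles discarded, 10 measured;
  amplitude is the modulus of the first Fourier coefficient at the
  stimulation frequency (robust to rectification-distorted waveforms); a
  drift of the amplitude across the measurement window beyond 1% is
  flagged. The linearized transfer amplitude (with the adaptation term
  `b/(1 + i omega tau_a)`) serves as an independent oracle; without
  adaptation the simulation matches it to better than 2%.
* **Oscillation frequency** — largest periodogram peak (Hann window,
  parabolic refinement) of the SOM population-mean rate, cross-validated
  against the mean inter-peak interval; the two must agree within 5%.
* **Correlations** — mean Pearson coefficient over unordered
  within-population pairs, after discarding the transient; correlation
  experiments use fivefold interneuron populations and shared+individual
  noise with the 0.6/0.4 coefficient split. Window length and noise
  bandwidth are not stated in the sources; defaults (noise at the
  integration step, multi-second windows) are configurable.
* **Empirical regime labels** — decision tree on the final window:
  sustained population-mean variability with a validated spectral peak ⇒
  oscillation; exactly one silenced population with a stable winner ⇒
  switch (single-unit survivors ⇒ pathological labels); otherwise
  coexistence, split by the measured amplification index obtained from
  ±0.05/s steady-state perturbations of the motif and its no-VIP
  reference. A silence threshold of 0.01/s is used throughout; decision
  quantities within 10% of a threshold set a boundary flag.
* **Input decomposition** — least-squares regression of the PC population
  rate on `[1, x_E(t), x_D(t)]` over the post-transient window
  (regression and Fourier amplitude ratios are equivalent for the two
  distinct stimulation frequencies; regression chosen).
* **Hysteresis** — staircase ramp of the modulatory input, each step
  warm-started from the previous steady state (2 s settle per step,
  convergence criterion as above); the bistable width is the measure of
  the grid where the up and down branches differ by more than 0.5/s.

## Experiment presets and problem sizes

Each preset ships as a YAML file and runs as one pipeline
(build → calibrate → stimulate → simulate → measure). One global seed
expands deterministically into per-component seeds. Default problem sizes
are chosen to resolve each phenomenon comfortably on a single core:
steady-state grids of 15–21 points, frequency scans of 7–8 periods,
regime grids of 12–16 points at 5–6 s per point, 10 s oscillation runs,
and 1 s session blocks for the mismatch experiment; all are configurable
from the command line.

The mismatch preset tunes the PV-to-soma total to
`(1 + w_PP)/(1 − w_PS)` with `w_PS = 0.2`, `w_PP = 1.0` so that PV
feedback cancels the somatic visual drive, and increases the PC time
constant sixfold to suppress onset transients. Sessions interleave 1 s
baseline blocks with feedback (visual+motor), mismatch (motor only) and
playback (visual only) blocks; block durations are not stated in the
sources and default to 1 s.

## Design choices on genuinely open points

* The switch-configuration demonstration (top-down integration vs
  cancellation) keeps adaptation off, as stated for that experiment. With
  adaptation off, both the interneuron theory and the full-circuit
  simulations place the bistability onset at total mutual inhibition
  ≈ 1.0; the hysteresis preset therefore contrasts 0.9 (monostable,
  width 0) with 1.1 (bistable, width > 0), while the pulse-switching
  demonstration keeps the stated strength 1.2 with 10 ms, 8.4/s pulses.
* The bifurcation-diagram presets use the A = 1 threshold between
  attenuation and amplification; the amplification plots use A > 0.

## What the synthetic stimuli do and do not emulate

Stimuli are the model's own defined inputs (constants, sines, frozen
Gaussian noise, pulses, session schedules), so "synthetic data" here means
the stimulus ensembles, not recorded data. They emulate tonic drive,
slow modulatory control, shared population co-fluctuations and
sensory/motor event streams. They do not emulate spike-train statistics,
conductance effects, heterogeneous per-neuron parameters, or
distance-dependent connectivity — conclusions about real circuits inherit
those idealizations. Passing tests demonstrate internal consistency of
simulation and theory under the stated conditions, not biological
validity.

## Known limitations

* No adaptive step-size control or event detection at the calcium
  threshold; the threshold crossing is resolved only to the fixed step.
* Closed-form analyses cover the symmetric motif; asymmetric parameters
  are handled numerically only.
* The per-sample noise convention makes the effective noise power depend
  on `noise_dt`; comparisons across `noise_dt` values are not meaningful.
* Near regime boundaries, convergence slows critically; steady-state and
  hysteresis measurements flag non-converged points rather than resolving
  them.
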