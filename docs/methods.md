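# Methods

This note records the models implemented in `stnef`, the numerical choices
behind them, and what the synthetic experiments do and do not establish.

## Neuron model and tuning curves

The rate model is the standard leaky integrate-and-fire response
`G[J] = 1 / (τ_ref + τ_rc ln(1/(1 − 1/J)))` for `J > 1`, zero otherwise,
with defaults `τ_rc = 20 ms`, `τ_ref = 2 ms` (both configurable; these are
conventional values, not fitted). The spiking simulator uses the exact
exponential membrane update per step and credits the sub-step
time-over-threshold against the refractory hold, so constant-current spike
counts match `G` to machine precision at `dt = 1 ms`. Gains and biases are
solved by inverting `G` so each neuron's firing onset sits at a sampled
intercept and its rate at encoder similarity 1 equals a sampled maximum
rate (defaults: intercepts uniform on [−1, 1), maximum rates uniform on
[100, 200] Hz).

Temporal encoders are stored as samples on a lag grid with spacing equal
to the simulation `dt`; inner products with stimulus histories use the
trapezoid rule. Encoders are normalized before use by default (exposed as
a flag), so the drive is a cosine-style similarity between the actual and
preferred history.

## Temporal bases

`make_ldn` returns the standard closed-form state-space realization of the
optimal delay line (the [q−1/q] Padé approximant of `e^{−θs}`; the
realization's eigenvalues were verified against the Padé poles computed
independently). Its impulse response approximates the shifted Legendre
polynomials; the match per component degrades toward the system order
(correlations 0.73–0.97 at q = 7, rising with q), which is a property of
the approximant, not an implementation artifact. The delay readout is the
Legendre evaluation `w_i(θ') = P_i(2θ'/θ − 1)`; the sign convention was
fixed numerically by regressing the true delayed input on the state.

The Modified Fourier system is one decaying "constant" mode plus harmonic
oscillator pairs at multiples of `1/θ` sharing a decay rate `damping/θ`
(default damping 1). Its exact published matrices are not reproduced here;
this realization is a reconstruction that satisfies the defining
properties (Fourier-series impulse response; with zero damping it is the
same pure-rotation dynamics family as the trajectory integrator).
Discretization is zero-order hold via an augmented matrix exponential.

## Weight solving

Decoders and full weight matrices come from ridge regression with the
penalty scaled to the largest regressor (`reg × max|a|`, default
`reg = 0.1`; the dynamics-critical solves use 0.01–0.02). Because ridge
solutions are linear in the target, the factored path
(gain · encoder) × decoder reproduces the full solve exactly. Recurrent
dynamics through first-order exponential synapses use the low-pass
compensation `(A', B') = (τA + I, τB)`; anything else goes through the
full temporal regression, which integrates the desired LTI state over
probe signals, filters the tuning-curve activities through the synapse,
and regresses target currents on [filtered activities, filtered inputs]
jointly. The two regressor blocks are rescaled to a common RMS before the
ridge solve — rates are O(100) Hz and inputs O(1), and a uniform penalty
would silently zero the input pathway. Evaluation times are a uniform
subsample (every 4th step) of the probe runs.

## Time cells

Each neuron gets a target delay `θ_i ~ θ · Beta(1.5, 2.5)` (biased toward
short delays) and a static encoder equal to the normalized delay readout at
`θ_i`, i.e. a bump of the LDN basis at its lag; 50% of neurons carry
negated encoders ("off" cells for negative pulses). The state is
diagonally rescaled so the test pulse sweeps encoder similarities through
[0, 1], and the temporal solve is probed with a mix of pulses and gentle
band-limited noise so the regression covers the states the experiment
visits. On a pulse, the solved 200-neuron spiking network produces
unimodal activities whose peak times follow the assigned delays (Spearman
ρ ≈ 0.996).

## Online learning

**PES.** `Δd = −(λ/n) a ε dt` on the decoders of a learned readout. The
rule is applied to *synaptically filtered* activities, not raw spike
trains: spike shot noise enters the regression implied by the rule's fixed
point as a large diagonal term and shrinks the learned decoders severely
(we measured normalized errors of 0.6–0.9 with raw spikes versus 0.03–0.1
with filtered activities on the same task). Default λ = 0.01 with a 50 ms
filter; the doubling search for the largest stable rate (no sustained
normalized error above 1) found divergence at λ = 0.03.

**Pendulum task.** A point-mass pendulum (`m = l = 1`, `g = 9.81`, viscous
damping 0.1) driven by 1 Hz-band-limited torque with RMS 1.0 N·m; the RMS
was chosen so the pendulum never passes over the top (torque RMS 2 winds
the pendulum up, which makes the angle unbounded and the normalized error
meaningless). Torque and the 50 ms-delayed angle feed one recurrent
spiking population (default 1000 neurons) realizing two order-7,
θ = 0.5 s Legendre-delay systems; PES learns the current angle from zero
decoders. Over 200 s runs the final-quarter NRMSE settles at 3–8%
depending on the seed.

**LLP.** Prediction coefficients `M` map context activities to Legendre
coefficients of the predicted observation window [t, t+θ]. Two
Legendre-delay memories (order 12, window θ) store the activity history
and the emitted-coefficient history; when an observation arrives it is
compared, at 16 stored lags, against what was predicted for now, and `M`
takes a delta step through the stored activities and the Legendre basis at
the matching leads. The update is preconditioned by the inverse Gram
matrix of the lead basis at the lags — this leaves the fixed point
unchanged but equalizes convergence speed across Legendre orders, which
otherwise differ by orders of magnitude. Ball-prediction contexts: an LDN
summary of recent motion, an SSP of position, or an SSP of position bound
with an SSP of velocity, each feeding ~250 rate neurons; a linear-feature
LDN control verifies that straight-line motion (exactly representable) is
learned to a few percent of the travelled distance. Learning rates default
to the largest value that remained stable over long runs (1e-3 for the
neuron contexts). Known limitation: the LLP smooths what it stores, so
bounce-rich paths keep a residual error floor that fluctuates with the
path phase.

## Spatial Semantic Pointers

`ϕ(x) = IDFT[e^{iAx}]` with conjugate-symmetric `A` (odd `d`, zero row
first), so encodings are real and unit norm; binding is circular
convolution via FFT, and phases add: `ϕ(x) ⊛ ϕ(y) = ϕ(x+y)` to 1e−10.
Random spaces draw phase slopes uniformly from `[−π, π]^m / length_scale`
using a Latin-hypercube (stratified) draw — same marginal law as iid
sampling but with far lower Monte-Carlo error in the induced kernel, which
is what lets a d = 301 one-dimensional space match the sinc kernel to
0.005 sup-norm. Default `length_scale = 0.5` spatial units. Hex spaces
build `A` from triplets of wave vectors 120° apart, one triplet per
(scale, orientation) module; defaults are 5 geometric scales × 5
orientations (d = 151). Concept vectors are random unitary vectors
(all Fourier magnitudes 1, hence exactly invertible), each derived from a
per-name seeded stream so a vocabulary's vectors never depend on insertion
order. Region encodings integrate `ϕ` on a cell-centred grid with an
integer cell count per axis (spacing defaults to length_scale/4);
normalization by area is off by default, so a wall contributes total mass
proportional to its area. Map queries use raw dot products; decoding is a
coarse grid argmax refined by Nelder-Mead, flagged unreliable when the
normalized peak similarity falls below 0.5.

## Spatial cells

Grid cells confine each encoder's frequency support to one hex module with
random phases, so the input current is a three-plane-wave interference
pattern. Sparsity is pure bias control: each neuron's firing onset is
placed at the (1 − sparsity) quantile of its similarity distribution over
the arena, estimated from 2000 sampled locations. Grid-cell experiments
use length_scale 0.15 m with module scales 1–2.5 (grid spacings ~0.4–1.1 m
in a 1.8 m arena, in the range of rodent entorhinal modules). Place cells
use location encodings as encoders; object-vector and border cells live in
a population whose input is the SSP of the displacement to the nearest
object (unlimited view by default, max-range optional) or to the wall.
Rate maps divide spike (or rate) mass per spatial bin by occupancy time;
gridness is the standard rotational-autocorrelation contrast (min of the
60°/120° correlations minus max of 30°/90°/150°), used only for testing.

## Path and temporal integration

In the frequency domain the position encoding is a bank of unit phasors;
velocity `v` rotates phasor `j` at `a_j · v`. The ideal integrator applies
those rotations exactly (unitary, no drift). The spiking integrator gives
each conjugate pair a population representing (Re, Im, normalized rate)
— 1500 LIF neurons by default — whose recurrent weights are solved through
the 100 ms synapse for the rotation dynamics plus a radial stabilizer
`κ(1 − |z|²)z` (κ = 10/s) that cancels the slow amplitude decay of decoded
limit cycles. Rate inputs are normalized per oscillator, and the product,
radial, and identity readouts are solved separately so all oscillators
share one solved population. On a 60 s synthetic foraging run in a 1.8 m
circular arena (smooth reflected random walk, mean speed 0.15 m/s — a
synthetic stand-in for recorded rodent paths) the decoded position stays
within ~5 cm median error.

The trajectory memory adds constant baseline rotation rates `b` (drawn
like a 1-D stratified phase vector with a time length-scale, default 1 s
per radian): stepping `Φ ← e^{ib dt}Φ + ϕ(x(t)) dt` exactly reproduces the
integral of spacetime encodings over the elapsed path. No forgetting is
applied by default (an optional decay rate is exposed); the zero-frequency
channel is tracked explicitly. The spiking realization needs only the
(Re, Im) pairs since the rotation rates are constant; the readout is
deconvolved at each component's baseline rate to undo the readout filter.
Probing the memory at elapsed lag L recalls x(t_now − L); a ramp input
yields a similarity ridge of slope −1 that blurs with lag.

## Quasi-probability densities

The mean of encoded samples is a compressed kernel density estimate whose
kernel is the similarity function of the space (sinc for random spaces).
The raw similarity is divided by the kernel mass (`length_scale^m` for
uniformly drawn phase slopes) to put it on the density scale; the ReLU
offset ξ is then solved by bracketing + Brent on a quadrature grid
(default: data bounding box padded by 3 length scales, 200 points per
dimension), where the normalization integral is continuous and strictly
decreasing in ξ. Because the sinc kernel's side lobes never fully decay,
the corrected density far outside the support is small (an order of
magnitude below the peak) but not exactly zero.

## Simulation engine

Fixed-step simulator, default `dt = 1 ms`; per step: input nodes →
synaptic filters → currents (weights × filtered activity + bias) → neuron
updates → probes, in deterministic order. Spike trains carry amplitude
`1/dt` so filtered trains estimate rates in Hz; exponential synapses use
the exact one-step recurrence and alpha synapses a two-stage cascade, both
with unit DC gain. Non-finite currents abort with a diagnostic naming the
ensemble.

## What the synthetic data does and does not show

All inputs are generated: band-limited noise, RK4-integrated pendulum
traces, exactly folded bouncing-ball paths, and OU-velocity random walks
whose arena size and run length mirror the published rodent setups. The
generators reproduce the *statistics* the models need (speed
distributions, boundary reflections, spectral content) but none of the
behavioral structure of real animals (goal-directed runs, thigmotaxis,
theta-modulated speed); passing tests therefore demonstrate the
correctness and robustness of the constructions, not quantitative fits to
recorded neural or behavioral data. Problem sizes (200 s learning runs,
60 s integration runs, populations of 150–2000 neurons) were chosen as the
smallest at which the measured quantities are stable across seeds.
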