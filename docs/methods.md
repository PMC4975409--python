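# Methods

## The model

`atriafit` simulates a minimal phenomenological model of the human atrial
action potential with four state variables: the dimensionless membrane
potential `u` (0 ≈ rest, ≈1 ≈ plateau) and three gates `v, w, s ∈ [0, 1]`.
Three lumped currents drive the voltage,

    du/dt = D ∇²u − (J_fi + J_so + J_si) + I_stim

* `J_fi = −v·H(u−θ_v)·(u−θ_v)(u_u−u)/τ_fi` — fast inward (sodium-like),
  produces the upstroke;
* `J_so = (u−u_o)(1−H(u−θ_w))/τ_o(u) + H(u−θ_w)/τ_so(u)` — slow outward
  (potassium-like), produces repolarization;
* `J_si = −H(u−θ_w)·w·s/τ_si` — slow inward (calcium-like), sustains the
  plateau,

with gate kinetics relaxing toward voltage-dependent targets on
voltage-dependent time scales (`τ_v^−(u)`, `τ_w^−(u)`, `τ_s(u)`, sigmoidal
`τ_so(u)`, `s_∞(u) = (1+tanh(k_s(u−u_s)))/2`, and a piecewise `w_∞`).
The Heaviside convention is `H(0) = 1`: a state exactly at a threshold is
supra-threshold, consistently in the pointwise model, the tissue kernels
and the tests.

The full roster is 28 named constants (`atriafit.params.PARAM_ORDER`).
The bundled `data/default.json` is the published epicardial reference
parameterization of the minimal human model; it yields APD90 ≈ 275 ms,
CV ≈ 67 cm/s at a 500-ms cycle length on the default cable — inside the
clinical atrial range — and serves as the initial condition for fits.
Membrane capacitance is absorbed into the normalization (`C_m ≡ 1`), and
voltage is never mapped to mV: all clinical comparisons happen on min-max
normalized morphologies, so a mV scale would cancel anyway.

## Tissue simulation

The monodomain equation is integrated with explicit Euler on a homogeneous
1D cable (default: 100 elements, dx = 0.02 cm, dt = 0.01 ms, no-flux
mirror-ghost boundaries) and on isotropic 2D sheets (default 9.6 × 9.6 cm,
same discretization). The diffusion coefficient defaults to
D = 0.001 cm²/ms, a typical normalized atrial value; CV scale during
fitting is carried by `τ_fi` with D held fixed. Configurations violating
the explicit-scheme stability bound (`D·dt/dx² < 0.5` in 1D, `< 0.25` in
2D) are rejected before running, and any state leaving the voltage guard
range [−0.5, 2.0] aborts the run with an instability error rather than
propagating NaNs.

Stimuli are 2-ms current injections into a 3-cell block (1D) or an
edge strip / quadrant (2D). The default amplitude is auto-calibrated:
factor-of-2 bracketing plus bisection (1% tolerance) finds the smallest
amplitude that propagates an AP to the distal electrode, and twice that
value is used. During a fit the amplitude is calibrated once, at the
initial parameters, and held fixed so that the error functional is
deterministic across moves.

Kernels are numba-compiled. `tanh` inside the kernels uses the identity
`tanh(x) = 1 − 2/(e^{2x}+1)` with saturation at |x| ≥ 20; this is exact to
~1 ulp and roughly halves the per-node cost (three sigmoids per node per
step). The pointwise reference implementation (`ionic_derivatives`) uses
`np.tanh` directly; a test pins the two against each other at 1e-12.

## Trace analysis and protocols

* Activation time: upward crossing of u = 0.2 with sub-step linear
  interpolation and a 50-ms refractory guard. The 0.2 level is robust for
  normalized voltages and insensitive to the foot of the upstroke.
* APD90: from activation until voltage first falls below
  baseline + 0.1 × (peak − baseline), scanning from the beat peak, with
  sub-sample interpolation; the baseline is the pre-upstroke minimum
  (100-ms lookback). DI = next activation − (activation + APD90).
* CV: distance/Δt between activation at 0.5 cm and 1.5 cm (the central
  1.0 cm of the default cable), away from stimulus-foot and boundary
  effects. Measurement positions are physical (cm), so refining dx keeps
  the same electrode locations.
* Morphology: beat segment min-max rescaled to [0, 1], time rescaled so
  activation = 0 and 90% repolarization = 1, resampled on a fixed 200-point
  grid for all comparisons. An artifact window (normalized time below
  `artifact_cutoff`) can be masked, mirroring the masking of the pacing
  artifact in MAP recordings.
* Upstroke interval: time from the first 10%-amplitude crossing to the
  beat peak (global maximum), tolerant of non-monotone upstrokes.

S1-S2 protocol: 8 conditioning beats at the S1 cycle length (500 ms
baseline), one premature S2 per coupling interval; the conditioning phase
is simulated once and each S2 continues from the saved state, which cuts
the protocol cost by roughly the number of S2 values. DI is defined as
S2 − APD90 of the final conditioning beat at the distal site. Failed
captures are flagged points, never silently dropped. The default S2 ladder
descends in 20-ms steps, 10-ms below 300 ms, until loss of capture.

Dynamic (decremental) protocol: ≥ 84 beats per CL at 500, 450, 400, 350,
300 ms, then 10-ms decrements until 2:1 block (a stimulus with no distal
activation within one CL); tissue state carries over between stages.

## Fitting

The fit minimizes a weighted mean of percent errors (all components in
percent, weights default 1, 1, 1, 0):

* APD and CV restitution: mean over target points of
  100·|sim − target|/target, with the simulated curve linearly
  interpolated in DI; target points outside the simulated DI coverage
  (beyond a 2-ms edge tolerance) are charged a 100% penalty so that a fit
  cannot profit from losing capture;
* morphology: mean absolute difference × 100 on the unmasked part of the
  200-point grid, averaged over all compared S2 shapes (optionally only
  the largest-S2 shape);
* optionally the upstroke interval (weight 0 by default, since clinical
  upstrokes are unreliable near the pacing site).

Simulated annealing: candidates perturb every unfrozen parameter per move —
multiplicatively by `exp(σ·r·N(0,1))` for time constants and steepnesses,
additively by `σ·r·range·N(0,1)` for thresholds and midpoints — clipped to
bounds (an order of magnitude each way for scale parameters, ±0.5 of the
unit interval for levels). Uphill moves are accepted with Metropolis
probability `exp(−ΔE/T)`; T shrinks by 10% after each iteration of 20
moves (50 iterations by default), and the initial temperature is
auto-calibrated so the median uphill ΔE of a 20-move pilot is accepted
with probability 0.8. `u_o`, `u_u` and `θ_v` are frozen by default as
normalization/excitability anchors.

Two refinements of the textbook scheme proved necessary and are defaults
(both can be disabled):

* elitist restart (`restart_on_cooling`): at each temperature reduction
  the working point is re-anchored at the best-so-far. With only ~10³
  evaluations the high-temperature phase is a short diffusion; without
  re-anchoring the walk strands on high plateaus and the late, small moves
  refine the wrong neighborhood.
* move-scale floor (`min_move_ratio = 0.1`): the proposal scale is
  `σ·max(T/T0, 0.1)` rather than `σ·T/T0`. Pure proportional shrinkage
  freezes the search after ~25 iterations (moves < 0.5%); the floor keeps
  a finite refinement step while the low temperature already rejects
  uphill moves, turning the late phase into a local descent.

Candidates whose simulation blows up or fails the protocol receive
infinite error — counted and rejected, never hidden. Runs are reproducible
from the seed. The fit problem is non-unique by nature (parameters that
act outside the probed DI range, e.g. `τ_v2m`, are unconstrained); the
suite demonstrates this degeneracy explicitly rather than pretending the
optimum is a point.

## Synthetic patients

Clinical MAP/basket recordings of the kind this pipeline targets are not
publicly available, so `synthetic_patient` generates datasets with the
same structure:

* parametric mode: a logarithmic APD restitution APD = a + b·ln DI
  (the quoted maximum slope is anchored at a 40-ms reference DI, because
  anchoring it at the self-consistently realized shortest DI has no
  solution; the quoted maximum APD is placed at the baseline-CL DI), a
  flat or exponentially drooping CV(DI) profile, DI(CL) solved
  self-consistently on the clinical CL ladder, Gaussian noise per channel
  (defaults: APD 5 ms, CV 3 cm/s — chosen as realistic clinical
  magnitudes), and a morphology from a three-archetype template bank
  (plateaued, monotone decay, triangular) with a 10-ms artifact mask.
* model_truth mode: the full cable protocol run on known truth parameters
  and packaged as a dataset, for parameter-recovery studies. Simulated
  distal traces have no pacing artifact, so the artifact cutoff is 0 here.

What the generator does **not** emulate: beat-to-beat alternans,
measurement drift, fibrillatory electrograms, spatial heterogeneity of
the atrium, and realistic MAP noise spectra. Passing recovery tests
therefore show that the fitting machinery works when the model family is
correct and the data are clean — they do not show that clinical fits are
identifiable or unique (the degeneracy test shows the opposite).

## Spiral waves

Cross-field initiation: S1 planar wave from the x = 0 edge, S2 over a
quadrant at a time inside the S1 repolarization wake (auto-scanned in
10-ms steps around the 90%-repolarization time of the quadrant's far
corner when not given). Tips are the intersections of the `u = 0.5`
isoline with the `du/dt = 0` contour (consecutive-frame differencing),
extracted with marching-squares contours and exact polyline intersection,
then linked by greedy nearest-neighbor with a 0.3-cm gate. The rotation
period is reported two ways — mean inter-activation interval at a far
probe over the final two-thirds of the run, and 2π over the tip's mean
angular velocity about its trajectory centroid — and a run is classified
stable / breakup (>1 tip sustained > 200 ms) / terminated / no_reentry.

## Problem sizes in the test suite

The suite runs everything at desk scale, as the package's own choice of
test conditions: protocol tests use a 40-60-cell cable at dt = 0.02 ms;
the convergence checks use the full default cable at dt = 0.01/0.005 ms
and dx = 0.02/0.01 cm; the parameter-recovery test perturbs and fits four
influential parameters — τ_fi (CV), τ_si and τ_so1 (plateau/APD), τ_w1m
(restitution recovery) — with 12 moves per iteration over the full
50-iteration, 0.9-cooling schedule, scaling the search dimensionality
with the evaluation budget (the full-scale study fits ~20 parameters with
two orders of magnitude more compute); the
2D reentry test uses a 6.4-cm sheet at dx = 0.04 cm, dt = 0.02 ms with a
shortened-APD parameter variant so that the rotor fits the reduced domain.

## Known limitations

Isotropic, homogeneous monodomain tissue only; no anisotropy,
heterogeneity, 3D geometry or atrial anatomy. Explicit Euler first-order
accuracy (the convergence tests quantify the discretization sensitivity of
CV). The error functional fits restitution at the measured points of
smoothed curves; alternans is not analyzed. The annealer is a global
heuristic: it finds parameter sets that fit to the few-percent level, not
certified optima, and distinct parameter sets can fit equally well.
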