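# Methods

`uddal` implements uncertainty-driven dynamics (UDD) for active learning of
interatomic potentials: molecular dynamics on a committee-averaged machine-
learned energy surface, augmented by a bias energy that deepens wherever the
committee disagrees, inside a full active-learning (AL) loop. Expensive
reference calculations are replaced by cheap analytic oracle potentials so
the complete method can be exercised and tested on one CPU in minutes.

## Model

### Committee uncertainty

A query-by-committee (QBC) ensemble of `N_M` energy regressors (default 8)
is trained on the current dataset. Disagreement on a configuration with
`N_A` atoms is summarised as

    sigma_E^2 = (1/2) * sum_i (E_i - E_mean)^2
    rho       = sqrt(2 / (N_M * N_A)) * sigma_E

The 1/2 prefactor in `sigma_E^2` is a nonstandard variance normalisation
kept deliberately; the `sqrt(2/(N_M N_A))` factor in `rho` compensates, so
`rho` equals the population standard deviation of the member energies
divided by `sqrt(N_A)` (an identity the tests verify to 1e-12). With the
reference operating point `sigma_E = 0.15` kcal/mol, `N_M = 8`, `N_A = 10`,
this gives `rho = 0.0237`.

### Uncertainty bias

Dynamics runs on the combined surface `E_mean + E_bias` with

    E_bias(sigma_E^2) = A * [exp(-sigma_E^2 / (N_M * N_A * B^2)) - 1]

which is 0 at zero uncertainty, decreases monotonically, and saturates at
`-A`. Bias forces follow from the chain rule,

    -d(sigma_E^2)/dr = sum_i (E_i - E_mean) * (f_i - f_mean),

using only the member energies and forces already computed for the MD step,
so the bias adds essentially no cost. Because the derivative of `E_bias`
with respect to `sigma_E^2` is negative, the bias force always projects
non-negatively onto the uncertainty gradient: it pushes uphill in
disagreement.

**Choosing A and B.** Both are context-dependent empirical parameters. The
package documents (but does not enforce) the published guidance: `A` of
order the barriers of interest — about 5x the barrier for conformational
exploration, equal to the barrier for a reactive double-well — and `B` near
the in-domain `sigma_E`, or calibrated so that the ratio `r` of bias-force
to true-force magnitudes on samples from an initial unbiased-AL phase
matches ~0.36. `calibrate_bias_width` automates the latter: `r(B)` vanishes
as `B -> 0` (the exponential gate closes) and as `B -> infinity` (the bias
flattens) and peaks in between, so the routine grid-scans log-spaced `B`,
locates the peak, verifies a bracketing sign change on the decreasing
branch, and bisects there. If the target exceeds the achievable peak it
returns the peak-ratio width with a warning flag rather than guessing.

**A-escalation.** When a sampling run has spent a configurable fraction of
its step budget (default 0.7, mirroring the published 140 ps of a 200 ps
limit) without reaching the selection threshold, `A` is multiplied once by
1.15. The per-step `A` history is recorded so the schedule is auditable.

### Sampling runs and the AL loop

Each AL iteration trains a fresh committee on all accumulated data
(cross-validation folds re-drawn under an iteration-derived seed), runs
`n_sims_per_iteration` Langevin MD simulations from seed geometries drawn
uniformly with replacement from the first 25 initial-dataset
configurations, and stops each simulation at the first frame whose `rho`
reaches the threshold (default 0.35); a step-limited run contributes its
maximum-`rho` frame (earliest on ties). Selected frames are labeled by the
oracle and appended — growth is strictly append-only, with per-sample
iteration provenance. The bias is kept off for early iterations (default:
active from iteration 15 at full scale) because an under-trained surface is
not smooth enough to bias safely; in the unbiased regime plain MD still
meets the threshold quickly.

`rho` is checked at every MD step rather than on a stride: the committee is
already evaluated for the forces, so the check is free; this also makes the
termination step well defined.

### Integrator

Langevin dynamics uses the BAOAB splitting with `c1 = exp(-gamma dt)`; at
zero friction and zero temperature it reduces exactly to velocity Verlet
(energy-drift-bounded, which the tests check on a harmonic well). Internal
units are fixed package-wide to kcal/mol, Angstrom, fs, amu with
`k_B = 0.0019872041` kcal/(mol K); the only conversion constant is
`4.184e-4` (kcal/mol/amu in Angstrom^2/fs^2). The published "friction
0.01 a.u." is adopted as 0.01 fs^-1 (configurable), the convention of the
common atomistic simulation tooling. Degrees of freedom that a toy
landscape freezes (the z coordinate of the planar particle) receive zero
force, zero initial velocity, and no thermostat noise.

Trajectory storage is strided (default every 10 steps) to bound memory,
but the running maximum-`rho` frame is always retained exactly, so
selection semantics are independent of the stride. With the bias inactive
(or `A = 0`) the sampling driver is bit-identical to plain ensemble-mean
MD under the same seed — the UDD / MD-AL comparison is perfectly
controlled, and a test asserts the bitwise equality.

### Metadynamics baseline

For contrast with the CV-free bias, a minimal standard-metadynamics driver
deposits constant-height Gaussians along user-supplied collective variables
every `tau` steps, with analytic chain-rule forces. Zero height is
bit-identical to unbiased MD. It is used as the baseline rare-event sampler
on the proton-transfer toy.

## Surrogates

The committee members are small multilayer perceptrons (default hidden
sizes 32:16:8) with Gaussian activations `exp(-z^2)` in the hidden layers
and a linear output. Hidden biases are initialised from `N(0, 0.7)`
because at zero bias every Gaussian unit sits on the flat top of its
activation and gradients vanish. Descriptors are deliberately minimal —
raw (x, y) for the planar landscape, inverse pairwise distances for
molecular toys — because the bias/AL machinery under test is
descriptor-agnostic. Forces are exact negative gradients of the predicted
energy, chain-ruled through the descriptor Jacobian; member evaluation is
vectorised by stacking the weights of all members.

Training minimises energy MSE plus `force_weight` (default 1.0) times the
force-component MSE with Adam (lr 1e-3, batch 32). The gradient of the
force term with respect to the weights is computed exactly by double
backpropagation (a tangent-augmented forward pass followed by a reverse
pass) — no finite differences anywhere in training; a test checks these
parameter gradients against numerical differentiation to 1e-7.
Early stopping monitors the validation energy MSE with 50-epoch patience;
on a stall, training restarts from the current weights at half the
learning rate and terminates below 1e-5, finally restoring the best
validation checkpoint. Mid-training restores were tried and rejected: with
the prescribed 14:1:1 split the validation set of a desk-scale member is
~7 points, and restoring to a noisy early optimum repeatedly traps the
member (observed full-data RMSE ~0.4 kcal/mol versus ~0.15-0.2 with
restart-from-current semantics). A `max_epochs` cap (default 1000) bounds
the otherwise open-ended annealing ladder; members that exhaust the ladder
early simply contribute more committee spread. Energies are regressed on a
shared standardised scale (one offset and scale for the whole committee,
never per-member), so the variance formula operates on raw member
predictions exactly as written.

The data split is the hold-one-out committee structure: k folds (sizes
within one), member `j` trains on all folds but `j`, and its retained data
is divided 14:1:1 into train/validation/test. One master seed fans out to
the fold shuffle and the per-member initialisation seeds, so retraining is
bit-reproducible.

## Toy oracles

* **Muller-Brown landscape** (conformational-exploration analog): the
  literature-standard four-term exponential surface, rescaled by 0.1 so
  that the barriers out of the seeded global basin (~7.4 and ~10.6
  kcal/mol after scaling) sit in the few-kcal/mol regime where the
  published `A` heuristics transfer. The particle is a unit-mass species
  "X" with z frozen. Minima and saddles are refined numerically from the
  standard starting guesses.
* **Double-well bond** (proton-transfer analog): a 3-atom heavy-H-heavy
  system whose proton feels a symmetric quartic double well along the
  heavy-heavy axis (barrier configurable, default 6.3 kcal/mol — the value
  for which the `A = barrier` rule is exercised), plus harmonic restraints
  on the heavy-atom separation and the off-axis proton displacement. All
  forces are analytic; finite-difference consistency to 1e-6 is tested
  for both oracles.

**Initial datasets** mimic the published seeding protocol: a 5 ps
thermostatted trajectory at 350 K with 0.5 fs steps, keeping every 80th
frame — exactly 125 near-minimum samples. A configurable energy window
(default 10 kcal/mol above the relaxed seeding minimum) asserts the
near-minimum premise instead of silently accepting a diverged trajectory.

### What the toys do and do not show

The toys preserve the method's structure — multiple minima behind
few-kcal/mol barriers, a committee whose disagreement grows away from the
training data, near-minimum seeding — but not the dimensionality, the
descriptor sophistication, or the quantum-reference accuracy of a real
campaign. Passing tests demonstrate that the bias mathematics, schedules
and bookkeeping are correct and that the qualitative sampling claims
(faster threshold attainment, exploration without low-energy depletion)
hold on a landscape with the stated topology; they say nothing about
DFT-level accuracy numbers, which are out of scope.

## Desk-scale study conditions

Problem sizes were fixed once, as the package's own desk-scale choices:

* Paired biased/unbiased comparison: one committee of 8 members trained on
  the 125-sample seed set; 20 paired runs with shared seeds at 350 K,
  5,000-step limit; threshold = 95th percentile of `rho` over the seed set;
  `A = 5 x` escape barrier; `B` calibrated to `r = 0.36` on the seed data.
* AL-loop comparison: 10 iterations of 16 simulations, 1,500-step limit,
  bias active from iteration 3 (the 15-of-80 full-scale schedule scaled
  proportionally). Here `B` follows the width rule for conformational
  sampling — the median near-minimum `sigma_E` (0.44 on this committee) —
  rather than the force-ratio calibration: the toy's committee saturates
  far from data (Gaussian units die out), capping `sigma_E` near 1, so the
  calibrated `B = 2.45` would leave the bias gate essentially open and the
  energy tilt negligible against the 7.4 kcal/mol barrier. The two
  published rules coincide for a committee whose uncertainty keeps growing
  with distance; they diverge on a saturating one, and the `sigma_E` rule
  is the one that preserves the bias mechanism. The selection threshold is
  0.6 — above the basin-rim `rho` (~0.5) and below the saturation ceiling
  (~1.0), applying the principle of raising the criterion until sampling
  must reach new regions instead of densifying known ones. Samples are
  partitioned by `region_counts`: the seeded low-energy region is the
  global basin below its escape barrier (membership by gradient-descent
  relaxation plus an energy cut); everything else — other basins, barrier
  tops, high-energy walls — is the non-equilibrium region. A pure
  nearest-minimum basin label is kept as `basin_occupancy` but is not used
  for the headline comparison, because on a 2D landscape the uncertainty
  gradient points up the outer walls rather than through the narrow saddle
  corridor, so even 15-20 kcal/mol samples can relax back into the seeded
  basin.
* Metadynamics baseline: 6 repeats of 20,000 steps of the double-well toy
  (height 0.4 kcal/mol, width 0.15 in the bond-difference CV, deposits
  every 100 steps) against zero-height controls.
* Equipartition check: 5x10^5 BAOAB steps of a thermostatted 1D harmonic
  well (friction 0.05 fs^-1, dt 0.5 fs), mean kinetic energy within 3% of
  `k_B T / 2`.

Full-scale values (200,000-step limits, 16 simulations, 80 iterations)
remain plain configuration settings.

## Numerical choices and degenerate inputs

* `sigma_E^2 = 0` needs no special-casing anywhere: the bias energy and its
  force formula already evaluate to exactly zero.
* `force_ratio` excludes atoms whose true-force norm is below 1e-8 (and
  counts them); an all-excluded input is an error, not a zero.
* Argmax-`rho` ties select the earliest frame, for determinism.
* Failed (non-finite) MD runs yield no sample for their slot — no retries,
  so the accounting stays deterministic.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; derived seeds are kept below 2^31.

## Known limitations

* The force-variance bias variant and linear (non-exponential) bias
  functions are not implemented.
* No periodic cells, constraints, NVE/NPT, or well-tempered metadynamics.
* The committee members are toy regressors; no claim is made that their
  uncertainty is calibrated in the statistical sense — only that it grows
  away from the data, which is the property the method needs and the tests
  check.
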