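# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of the package, in the spirit of a methods appendix.

## Source model and forward problem

The source space is a triangulated cortical surface with one current dipole
per vertex, oriented along the outward surface normal (cortical current
density convention); source amplitude is a single scalar per vertex.  Vertex
areas use barycentric lumping (one third of each incident triangle), so patch
areas and area-weighted overlap metrics are consistent with the surface area.

The packaged volume conductor is a three-shell concentric-sphere head model:
brain, skull, scalp with conductivities **0.33, 0.0165, 0.33 S/m** and default
radii **80, 85, 92 mm** (standard adult values; the radii are this package's
defaults, not reference values).  The dipole potential is expanded in
spherical harmonics and, per order, the radial boundary-value problem
(continuity of potential and normal current at both interfaces, zero current
at the scalp) is solved as a 5x5 linear system in radii scaled by the scalp
radius.  This derivation covers any conductivity profile; with equal
conductivities the transfer coefficient reduces analytically to `(2n+1)/n`,
which is how the implementation is validated against the textbook
homogeneous-sphere series (agreement ~1e-11 relative at matched truncation).
Default truncation order is 60; for sources at 70 of 92 mm radius the
neglected tail is below 1e-7.  Realistic boundary-element or finite-element
head models are out of scope; a precomputed gain matrix can be supplied
instead.

Sensor noise is modeled by a covariance estimated from baseline with
diagonal shrinkage, `Sigma = (1-lambda) S + lambda diag(S)`, `lambda = 0.1`
by default — the shrinkage guarantees positive definiteness for short or
rank-deficient baselines.  SNR is defined as the broadband power ratio in dB,
powers being mean squared amplitude over all channels and samples; drawn
noise is rescaled exactly, so realized SNR equals nominal by construction.

## Temporal basis functions

The temporal prior `A` comes from blind source separation of the (filtered,
average-referenced) data: FastICA for real recordings, an exact SVD fallback
wherever bit-stable determinism matters (all tests, the Monte Carlo
pipeline).  Selection criteria quantify what is usually a visual judgement,
and their thresholds are package defaults, not reference values:

* seizure TBFs: post-onset RMS / pre-onset RMS >= 2.0, with a 10 s pre-onset
  window;
* spike TBFs: peak-locked average over 2 s epochs must exceed 3 baseline
  standard deviations within +-50 ms of the peak (baseline = first and last
  500 ms of the averaged epoch);
* components within 10% of either threshold are included with a warning
  (doubt favors inclusion).

Note a statistical subtlety: the spike criterion takes a *maximum* over the
+-50 ms window, an extreme statistic whose null exceedance probability is the
per-sample tail probability inflated by the window's effective degrees of
freedom (~10 for 1-50 Hz signals).  Pure-noise components are therefore
rejected at a rate around 0.8 rather than the ~0.997 a single-sample 3-sigma
bound would suggest.  The test suite asserts the measured behaviour.

Artifact flags (anterior-dominant spiky topographies for eye activity,
spectrally flat activations for muscle/movement) are advisory only, mirroring
a manual screening step.

## The inverse solver

Each reweighting iteration solves the convex program

```
min_J sum_i ||W_d,i (V j_i)||_1 + alpha sum_i ||W_i j_i||_1
s.t.  || Sigma^-1/2 (phi - K J A) ||_F^2 <= beta^2
```

**Temporal compression.** With `A = R Ao` (orthonormal rows `Ao`), the
residual splits into a constant off-subspace part and
`||Sigma^-1/2 phi Ao' - Kw J R||_F^2`; the problem is solved exactly on the
compressed data (T effectively equal to N_c) with the bound reduced by the
off-subspace energy.  If the off-subspace energy alone exceeds `beta^2` the
bound is infeasible and an error is raised.

**ADMM backend.** Splitting variables carry the stacked weighted operator
output (`z1`, soft-thresholded) and the whitened residual (`z2`, projected
onto the Frobenius ball of radius beta).  The x-update is a dense
normal-equations solve factorized once per subproblem (Cholesky of
`blockdiag(G_i'G_i) + (A A') kron (Kw'Kw)`).  Three normalizations make a
single penalty parameter workable across the problem family: the lead field
and TBF are scaled to unit spectral norm and the data by `beta` (the problem
is positively homogeneous in `J`, so the minimizer maps back exactly), and
each stacked operator `G_i` is scaled to unit spectral norm with the constant
folded into its L1 term.  Over-relaxation (1.7) and residual-balancing
adaptation of the penalty (frozen after 2000 iterations so the iteration can
settle) are used.  Stopping follows the standard primal/dual residual
criteria.

**Exact sparsity and stable reweighting dynamics.** The ADMM x-iterate
approaches zero only to solver tolerance; the solution's exact zeros live in
the soft-thresholded split variable.  Two distinct uses of the subproblem
solution call for different iterates.  The *weight updates* use the dense
x-iterate: it is continuous in the problem data, so the overall reweighting
iteration — which is a nonconvex fixed-point scheme and can otherwise jump
between support basins under perturbations as small as a 0.1% change in alpha
— behaves smoothly.  The *returned solution* (one final subproblem solve at
the converged weights) is reconstructed from `z1`'s support: if that
reconstruction satisfies the fidelity bound (within the documented 1e-6
relative slack) it is returned directly; otherwise the subproblem is
re-solved restricted to the support (cheap — the support is small), giving an
exactly sparse, certifiably feasible solution.  A convex-combination fallback
toward a feasible point covers the degenerate cases.  Backend optimality is
certified empirically rather than by a duality gap: on every tested instance
(E <= 25, N <= 60) the objective agrees with an independent generic-NLP
epigraph formulation to better than 1e-4 relative.

**Weight updates.** `W_i = 1/(|J| + eps)` and `W_d,i = 1/(|V J| + eps)` with
`eps = 0.01 x max` per component (a *relative* floor keeps reweighting
scale-invariant; the literature derives the reciprocal form from a log
approximation of the L0 norm but fixes no floor).  Each weight vector is
rescaled to unit maximum so alpha's meaning does not drift across iterations.
The loop stops when the relative solution change drops below `tol = 1e-4`
(default; the active set is insensitive to tightening to 1e-6, which the
acceptance suite asserts as a Dice overlap >= 0.95).

**beta.** `beta^2 = chi2.ppf(q, E*T)` with `q = 0.95` by default; `q="mean"`
gives exactly `E*T`.

**alpha (L-curve).** The identity-weight subproblem is solved on a log grid
(default 6-7 points over [0.1, 100]) and `log||V J||_1` is plotted against
`log||J||_1`.  Points dominated in both coordinates (solver noise off the
trade-off frontier) are discarded; both axes are min-max normalized; the knee
is the interior point farthest from the chord joining the curve endpoints.
This is the standard robust discrete-knee criterion and coincides with the
maximum-curvature corner for L-shaped curves, while raw three-point curvature
on a log grid is dominated by uneven-spacing artifacts.  Grid points whose
solve hit the iteration cap are excluded from the knee computation (an
unconverged objective places the point far off the true trade-off curve and
can drag the knee by a decade).  Alpha is tuned once
at identity weights and then held fixed.  The acceptance suite asserts the
documented robustness: the active set at the knee alpha and at 10x that alpha
overlap at Dice >= 0.9.

## Feature pipelines

Spike imaging: average peak-locked 2-s epochs per spike type (types handled
independently), solve, then summarize `S = J A` as mean squared amplitude over
a 40 ms window centered on the peak (symmetry of the window is an assumption;
only "around the peak" is prescribed).  Ictal imaging: image a 4 s
(configurable 3-5 s) post-onset span, find the dominant rhythm by averaging
five 1-s rectangular-window periodograms per side of onset (1 Hz resolution),
keep only the contiguous band containing the largest post-minus-pre increase
(side lobes rejected), band-pass the source time courses there (zero-phase
4th-order Butterworth; single-bin bands widened +-0.5 Hz), and take energy
over 1 s from onset.  The epileptogenic-zone estimate is the support of the
energy map above `1e-6 x max` — a numerical-dust cut, not a statistical
threshold, valid because the solver's background is exactly sparse.

## Synthetic world

The Monte Carlo generator emulates: geodesically grown cortical patches
(uniform random seed vertex, target area uniform in **2-20 cm^2**), a single
time course per patch (biphasic Gaussian-derivative spike pulse of 70 ms
FWHM, or a ramped ictal oscillation), uniform unit amplitude across the patch
(matching the piecewise-homogeneous model), forward projection, and white
sensor noise at SNR conditions **{20, 15, 10, 5} dB**.  Trials are pure
functions of `(scenario seed, trial index)`; noise additionally of the SNR
condition, so the same source is evaluated under every condition.

What the generator does **not** emulate: realistic cortical folding (the
"cortex" is a sphere, so no deep or tangentially-oriented sources), colored
or spatially correlated background EEG, forward-model error (the same lead
field generates and inverts the data), multiple simultaneous patches,
within-patch amplitude gradients, and TBF estimation error beyond what white
noise induces in a rank-1 SVD.  A green Monte Carlo test therefore
establishes internal consistency of the pipeline at realistic noise levels —
not clinical performance.  Pooled time-course correlations in this idealized
world come out near the top of the plausible range (the off-diagonal
structure, model mismatch and physiological noise of real recordings are what
pull such correlations down toward the reference value of 0.88).

## Metrics and statistics

Overlap uses area-weighted normalized overlap ratios (precision = overlap /
estimated area, recall = overlap / true area; vertex-count overlap available
as an option — which of the two the reference used is unstated).
Localization error averages, over seizure-onset-zone electrodes, the minimum
Euclidean distance to the boundary of the estimated zone; an electrode whose
nearest mesh vertex is interior to the estimate contributes zero (covered
electrodes represent zero error — the inside case is this package's
convention).  The permutation test shuffles group labels (default 10^4
permutations) and uses the add-one p estimator, never exactly zero.
Spike-type weighting combines per-type metrics by occurrence fractions; the
robustness resampling redraws weights uniformly on the simplex (normalized
exponential draws) and repeats the group test with common permutation draws
across repeats, so only the weights vary.

## Known limitations

* Extent is over-estimated at the smallest extents on coarse meshes: a
  3 cm^2 patch is ~5 vertices on a 1000-vertex spherical head, and a single
  ring of plateau overshoot can halve the area precision of one trial even
  when recall is 1.0.  This matches the reported scatter of extent recovery
  around the identity line and shrinks with mesh resolution.
* At the L-curve alpha, converged solutions around small patches can carry a
  low-amplitude shelf (~0.5% of the peak) that is genuinely part of the
  optimum (verified by independent tight solves), so support-based area
  counts it in full.  Stronger alpha removes it at the cost of recall on
  other instances; the package keeps the knee choice and reports the honest
  support.
* The ADMM backend's worst case (identity weights, large alpha, tight
  fidelity) can need several thousand iterations; tolerances below ~1e-8
  relative objective are not economical at N ~ 1000.
* The L-curve knee is a heuristic; on shallow trade-off curves the chosen
  alpha can sit an order of magnitude below the extent-optimal value for
  individual instances.  The reweighting's documented insensitivity (Dice
  bounds above) is what makes this tolerable.
* EDF input is unsupported (no EDF reader among the dependencies); recordings
  must be converted to the delimited-matrix + JSON sidecar format.
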