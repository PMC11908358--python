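# Methods

This note records the models, estimators, numerical choices and known
limitations of `twochain`, in the spirit of a package methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The HP model

Chains are Kremer–Grest bead–springs: FENE bonds
u_b(r) = −½ k R₀² ln(1 − r²/R₀²) with k = 30 kBT/σ² and R₀ = 1.5 σ (the
canonical parameters for this model), plus a unit-strength WCA core between
bonded neighbours.  Bonded pairs interact only through the bond potential;
all other pairs are nonbonded.  Units are reduced throughout: kBT = 1,
σ = 1.

Nonbonded pairs involving a polar (P) bead interact via WCA (Lennard-Jones
truncated at 2^{1/6}σ and shifted so its minimum is zero).  Hydrophobic
(H–H) pairs add an attractive tail of tunable strength:

u_HH(r) = u_WCA(r) + ε · u_tail(r),

where u_tail is the attractive branch of the unit-depth Lennard-Jones
potential, truncated and shifted to zero at the cutoff 3σ (constant at
−1 − u_LJ(3σ) inside the core).  At ε = 1 this is identical to the
truncated-and-shifted Lennard-Jones potential of depth 1; at ε = 0 it is
exactly WCA.  This decomposed form keeps the repulsive core fixed while ε
is tuned, and it makes the potential continuous at both cutoffs — a
requirement for well-behaved Metropolis acceptance.  Truncation is by
energy shift (not force shift); the discontinuity in the force at 3σ is
irrelevant to a Monte Carlo sampler.

Monomer diameters may differ per type (Lorentz mixing, σ_ij = (σ_i+σ_j)/2);
the HP instantiation uses σ = 1 for both types.  Charges are carried on
`MonomerType` for plug-in models but unused by the HP energies.  Any other
pairwise model enters as a callable `(r, type_i, type_j) -> energy` with a
declared finite cutoff.

## Sampling

Equilibrium averages are the only quantities consumed downstream, so the
sampler is Metropolis Monte Carlo rather than molecular dynamics.  A sweep
comprises 2N single-bead displacements (uniform in a cube of half-width
0.3 σ), one pivot per chain (random axis, angle uniform within ±π/2, head
or tail segment), a rigid rotation of each chain about its own centre of
mass, and a rigid translation of one chain.  All proposals are symmetric.
The first 10% of sweeps are burn-in; snapshots are retained once per sweep.
Inner loops are JIT-compiled (numba); the pure-Python energy functions are
the reference implementation and the two routes are cross-checked in the
tests.

Umbrella windows restrain the centre-of-mass distance r.  The default
scheme is hard-bounded windows of width 1 σ spaced 0.5 σ apart spanning
[0, N σ] — moves leaving [r_lo, r_hi) are rejected, which needs no force
evaluation — with harmonic windows (+ WHAM) available behind the same
interface.  Per-window seeds derive from the master seed via
`numpy.random.SeedSequence` spawn keys, so every result is a deterministic
function of (inputs, seed).

## PMF estimation and errors

Within a window the histogram of r, divided by the shell volume 4πr² and
the bin width, estimates the radial density; u(r) = −ln g(r).  Consecutive
windows are aligned by the log of the ratio of their *pooled* counts over
the jointly sampled bins.  (Weighting per-bin log-densities by their own
noisy counts — the first implementation — carries a Jensen-type bias of
order the per-bin variance per stitch, which accumulates across windows;
the pooled-count estimator's bias is O(1/counts) and was adopted instead.)
Aligned windows are merged per bin by inverse variance, and the profile is
anchored so its inverse-variance-weighted mean over the outermost 1 σ of
the grid is zero, fixing u(∞) = 0.

Errors have three parts, all propagated:

1. a delta-method per-bin variance (1 − p)/(c/τ), with τ the integrated
   autocorrelation time of the window's r series (effective sample size
   n/τ), floored so a window falling entirely into one bin does not claim
   infinite precision;
2. a frame-drift variance: each stitch contributes an offset variance, and
   a bin accumulates the stitch variances separating its window from the
   tail anchor (a random walk across windows);
3. the common anchor-offset variance.

Bins never visited carry u = +∞.  The attractive well is the maximal
contiguous interval around the minimum with u strictly within 1 kBT of the
minimum (strict, so a square well of depth exactly 1 kBT ends at its rim).

Integrated autocorrelation times use 1 + 2Σρ(t) with initial
positive-sequence truncation (sum stops at the first non-positive
autocorrelation); constant series return 1 with a degeneracy flag.

## B22 and ε-matching

B22 = 2π ∫ [1 − e^{−u(r)}] r² dr by composite trapezoid, with the integrand
treated as zero beyond the last grid point and as exactly 1 wherever
u > 50 kBT (e^{−50} is below double-precision relevance).  The tail must be
anchored (inverse-variance-weighted mean of u over the outermost region
within 0.05 kBT of zero) or the quadrature refuses.  Error propagation is
linear in the per-bin errors: independent parts add in quadrature; the
stitch drift enters exactly as a random walk (each stitch's variance times
the squared total sensitivity of the bins on its far side) and the anchor
offset as a common shift.  This correlated part usually dominates and is
the honest price of a tail-anchored profile; it shrinks as 1/√sweeps.

ε-matching inverts B22(ε) by bisection — robust to the statistical noise of
each B22 estimate, unlike secant steps — and stops when
|B22 − target| ≤ max(user tolerance, 1 SE), operationalising "matched to
within statistical error".  B22(ε) is monotone decreasing in ε, which the
tests verify on the square-well closed form.  The evaluator is pluggable so
closed-form toy systems exercise the same code path as sampled ones.

## Contact maps and spectra

Contacts are binary per configuration: centre-to-centre distance strictly
below r_c, with r_c = 3σ by default (the cutoff of the hydrophobic
attraction; a hyperparameter for other models).  Maps are averaged over
decorrelated well configurations — pooled across windows, thinned at a
stride at least the integrated autocorrelation time of the interchain
contact count, the observable whose statistics the map inherits; the
autocorrelation is measured per window, because concatenating independent
windows aliases the r-dependence of the contact count into a spurious
correlation time — and symmetrised with their transpose (homotypic chains
are exchangeable).

Spectra use the unnormalised forward 2-D DFT of the zero-mean map over
signed integer frequencies; P(0,0) is set to exactly zero.  Power is
aggregated over all modes (conjugate pairs included) sharing
k = √(kx²+ky²), with k compared after rounding to 9 decimals.  Parseval
gives Var(C) = ΣP/N⁴, so partial sums are reported in variance units.
Explained-variance curves run over unique nonzero wavenumbers; k = 0 is
excluded (it is the zeroed mean mode and would prepend a vacuous zero to
both curves).  In the descending-power ordering ties break by ascending k,
which is deterministic and minimises the divergence index under ties.
Lowpass reconstructions are not clipped to [0, 1]; they are diagnostics.

## Classifier

Features are z-scored with training-fold statistics (population 1/n
standard deviation); a zero-variance feature (B22 in a B22-matched dataset,
by construction) maps to zeros with a degeneracy flag rather than failing.
The fit is maximum-likelihood logistic regression by damped Newton/IRLS
with a ridge of 1e−8 on the coefficients (never the intercept) purely so
the optimum stays finite under perfect separation, which is detected and
flagged.  The tests cross-check the fit against an independent
implementation (scikit-learn at C = 1e8) and against a grid-search oracle
on a separable toy.  AUC is the rank-based (Mann–Whitney) statistic with
half-credit ties, via `sklearn.metrics.roc_auc_score`.

Split evaluation uses randomised, non-stratified 80/20 train–test splits
(185 by default); a split leaving one class absent from either part is
redrawn, with a cap.  The reported uncertainty is the standard deviation of
per-split values divided by √(number of splits).  Decile subsets of the
divergence index break boundary ties by sequence id, deterministically.

## Synthetic fixtures

The fixtures test the mathematics, not the physics.  Toy PMFs (hard sphere,
square well, Gaussian well) have closed-form or high-resolution quadrature
B22 oracles; hard cores are encoded as a large finite value (1e6 kBT).
Synthetic maps assign random Hermitian- and transpose-symmetric phases and
deterministic per-wavenumber power, so two seeds give different maps with
identical aggregated spectra whenever the target fits in [0, 1]; otherwise
the field is rescaled with a warning.  Labelled datasets draw per-sequence
variance levels from two overlapping lognormals (medians 0.004 and 0.012,
log-sd 0.45, threshold 0.008 — levels chosen so N = 20 maps at mean 0.4
remain feasible in [0, 1]), build real maps, compute all features through
the contact-map and spectral modules, label by thresholding the *computed*
variance (low variance → phase separating, mirroring the empirical
direction), and flip labels with probability q.  What passing tests show
is that the estimators and classifiers recover a known generative process;
they do not show that desk-scale HP sampling reproduces any particular
published dataset.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the whole
battery completes in minutes on one CPU: single-bead physics oracles at
2×10⁴ sweeps per window; the end-to-end demonstration on five N = 10
sequences at 5×10³ sweeps per window with 40 well configurations per map;
synthetic datasets of 250–300 sequences at N = 20.  At these budgets the
B22 statistical errors on chain systems are honest but large (hundreds of
σ³), dominated by the correlated PMF drift; the identities and recovery
checks are unaffected because they compare against references computed
under the same conditions.

## Known limitations

* Ground-truth phase labels are consumed as input; direct-coexistence
  simulation to produce them is out of scope.
* Heterotypic pairs (two different sequences) and temperature sweeps are
  not implemented.
* The harmonic-window WHAM route returns per-bin errors without the
  stitch-drift bookkeeping of the hard-window route (it has no stitches);
  its error model is correspondingly cruder.
* The sampler is serial Metropolis; deeply bound dimers (well depths beyond
  ~10 kBT) decorrelate slowly, and the pipeline then falls back to fewer
  well configurations (flagged in the row status) rather than failing.
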