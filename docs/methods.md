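# Methods

This note records the modelling choices, numerical details and known
limitations of the package, in the order the pipeline runs.

## Kinship and spectral rotation

The genomic relatedness matrix is the literal cross-product
Σ_u = Z Zᵀ / m of the sample-major genotype matrix Z (calls 0/1/2),
**uncentered** by default.  Centering each marker before forming the
matrix is common GRM practice and is available (`centered=True`,
`--kinship-mode centered`), but the default follows the covariance
definition the model stages assume.  An uncentered relatedness matrix has
a dominant eigenvalue aligned with the population mean direction; the
spectral rotation absorbs it harmlessly.

Eigenvalues are returned in descending order (deterministic output);
values below zero — possible only through rounding, since the matrix is a
Gram matrix — are clipped to zero, with a warning when they fall below
−1e−8.  Rank deficiency is permitted: zero eigenvalues simply make the
corresponding diagonal entries of V₀ = Λω̂_u + I equal to one.

## Stage 1: REML scan

All V⁻¹ products use the Sherman–Morrison identity on the
diagonal-plus-rank-one covariance and |V| uses the matrix determinant
lemma; nothing ever forms or inverts an n×n matrix per marker.  The
scan's cost is dominated by the one-off rotation QᵀX of the marker
matrix.

*Optimisation.*  Both variance ratios are optimised on log10(ω) with box
[−10, 10], which enforces positivity and puts the zero boundary at a
finite parameter value.  The null ratio ω_u starts at 1 and uses L-BFGS-B
with a central finite-difference gradient (step max(1e−6, 1e−6·|t|)).
Per-marker fits run two ways, tested equivalent:

* `fit_marker_reml` — L-BFGS-B started at ω̂_u, with a coarse-grid restart
  because the profile likelihood can be bimodal at small n (a flat
  boundary plateau plus an interior maximum);
* `scan` — all markers simultaneously: a 41-point grid on [−10, 10]
  brackets each marker's maximum, then ~30 vectorised golden-section
  iterations sharpen it.  This exists because per-marker optimiser
  overhead, not arithmetic, dominates a 10⁴-marker scan; it makes one
  500×10,000 replicate run in about a second.

Flat likelihoods (zero marker after rotation, zero eigenvalues) tie-break
to ω = 0, where the effect, its variance and the Wald statistic all
vanish and the p-value is 1 by continuity.  Monomorphic markers are
reported as skipped, never assigned a p-value, since var(β̂) is undefined
for them.

*Calibration.*  Because ω_g ≥ 0 is estimated per marker, the Wald test
inherits the boundary truncation of a variance-component test: whenever
the profile likelihood decreases at ω_g = 0 the statistic is exactly
zero.  Empirically the null rejection rate at α = 0.05 is nominal
(0.045–0.050) when the null polygenic ratio is itself estimated at the
boundary, and conservative (~0.027–0.032) when ω̂_u > 0; the test never
becomes materially anti-conservative at the 0.05 level.  The screening
stage therefore passes somewhat fewer null markers than its nominal
cutoff suggests — acceptable for a deliberately loose screen.

*Screening.*  Default cutoff p ≤ 0.01, the screening convention of the
multi-locus mixed-model family this method belongs to; configurable.  The
survivor count is additionally capped at n − c − 1 (smallest p first,
configurable off) so the stage-2 residual-variance update keeps positive
degrees of freedom.

## Stage 2: penalized maximum likelihood

The coordinate updates are the closed forms stated in the model: least
squares for b, the ridge-like scalar update for each βᵢ, mean squared
residual (divisor n) for σ_n², and the hyperparameter fixed points
μᵢ = βᵢ/(τ+1), σᵢ² = ½[(βᵢ−μᵢ)² + τμᵢ²].  Implementation choices that
required a decision:

* **Exact profiling of the fixed effects.**  The penalty touches only the
  marker effects, so maximising over b is equivalent to residualising y
  and every marker column against F once (Frisch–Waugh–Lovell) and
  running the sweeps on residualised data; the normal equation for b then
  holds identically at every iterate.  Updating b only once per sweep
  instead lets the nonzero marker means (0/2 coding) leak into
  within-sweep partial residuals; in testing this transiently drove
  strong markers to the wrong sign, and because deactivation is
  absorbing, lost them permanently.
* **Warm start.**  Hyperparameters are seeded from each marker's marginal
  least-squares estimate; the effects start at zero and are built up by
  the first penalized sweep in ascending-p order.  Seeding the effects
  themselves at their marginal estimates makes the start collectively
  overfit when many screened markers share sampling noise, with the same
  transient-deactivation failure mode.
* **Deactivation.**  σᵢ² < 1e−12 freezes the marker at zero for the rest
  of the fit.  With τ = 1 this corresponds to |βᵢ| < 2e−6, far below the
  final |βᵢ| > 1e−4 selection rule, so nothing selectable is ever frozen;
  the rule exists because the βᵢ update divides by σᵢ².
* **Hyper interleaving.**  Each marker's (μᵢ, σᵢ²) refresh happens
  immediately before its βᵢ update (from the second sweep on), keeping
  every step an exact coordinate maximisation, so the penalized
  log-likelihood is non-decreasing across sweeps while the active set is
  stable.  When a marker deactivates, its penalty terms leave the
  objective, which is a discrete jump between objectives rather than an
  ascent violation.
* **τ = 1 by default** (configurable).  The penalty only requires τ > 0.
  τ = 1 gives σᵢ² = βᵢ²/4 at the fixed point — shrinkage proportional to
  the effect itself.  This is the single most consequential free
  parameter: smaller τ weakens shrinkage (more, noisier calls), larger τ
  strengthens it (fewer, cleaner calls).  The default reproduces the
  intended severe small-effect shrinkage; anyone tuning it should re-run
  the shipped power studies at the candidate values.
* **Convergence**: largest absolute parameter change < 1e−6 within a
  sweep, at most 200 sweeps; non-convergence returns a flagged state
  rather than raising, and the calls are still made from it.

*LOD scores.*  A surviving effect is scored by
LR = n·log(RSS_reduced/RSS_full), where the reduced model removes that
effect, keeps the other marker effects fixed, and re-profiles both the
fixed effects and σ_n²; LOD = LR/(2 ln 10), declared at LOD ≥ 3.
Re-profiling the fixed effects matters with uncentered coding: freezing
the intercept would charge the reduced model an extra βᵢ²·n·x̄ᵢ² of
residual that an intercept refit trivially absorbs, inflating every LOD
by several units and with it the false-call rate.

## Simulation framework

The generator emulates an inbred (selfing) association panel: per-marker
allele frequency uniform on [0.1, 0.5], homozygous calls 0/2 with P(2)
equal to the frequency, markers independent, five chromosomes of equal
size.  The default trait design plants eight QTNs with heritabilities
(0.01, 0.03, 0.03, 0.05, 0.08, 0.01, 0.05, 0.05) — total genetic
heritability 0.31 — effects (0.4328, 0.7497, 0.7497, 0.9679, 1.2243,
0.4328, 0.9679, 0.9679) (effects scale as √h²), residual variance 10 and
population mean 10.  The polygenic design adds u ~ MVN(0, 2.0·K) with K
the realized relatedness of the simulated panel, drawn through the
eigendecomposition of K.  Each replicate draws fresh genotypes and
phenotypes from seeds derived deterministically from the master seed, and
a detected call must land on the exact simulated QTN marker (a ±window is
available and is the right choice under the optional block-LD generator,
which copies a marker from its left neighbour with probability `ld_rho`).

What the emulation does **not** share with a real panel: linkage
disequilibrium, population structure beyond what random relatedness
induces, and fixed marker frequencies.  Three consequences worth knowing:

* re-randomised allele frequencies mean a QTN's realized heritability
  varies across replicates, so even the h² = 0.08 QTN is occasionally
  drawn too weak to detect (its power plateaus near 94–98% rather than
  100%);
* without LD there is no linked-QTN competition, which raises
  mid-heritability power relative to a real panel where causal markers
  can sit within LD range of each other; the design-level average power
  lands around 61–70% across seeds at 50 replicates;
* power is an exact-marker match, so no window-induced false matches
  occur.

Power for a QTN is the fraction of replicates with a matching call; MSE
averages (β̂ − β)² over the replicates that detected it and is undefined
("na") when none did; design averages take the mean over QTNs (MSE over
the QTNs with at least one detection).

## Problem sizes used by the shipped studies

The test suite and the acceptance script run the reference designs at 50
replicates (20 per sample size for the 500/1000/2000 sample-size sweep),
which reproduces the design-level averages to within a few percentage
points of Monte-Carlo noise while keeping a full run in minutes on one
CPU.  One 500×10,000 replicate costs roughly a second; cost is dominated
by the kinship product and the marker rotation, both O(n²m) BLAS calls,
so it grows quadratically in sample size and linearly in marker count.

## Known limitations

* The single-locus test is a truncated variance-component Wald test; its
  p-values are not uniformly calibrated (see above) and should be treated
  as a screening score, not as publishable single-marker significance.
* Stage 2 fits no polygenic random term; confounding is expected to be
  handled by the stage-1 whitening that feeds the screen.  Strong
  residual structure that survives screening will inflate σ̂_n²
  underestimation from the many fitted effects and with it the LOD
  scores of borderline markers.
* The likelihood-ratio LOD treats the other fitted effects as fixed; it
  is a conditional, not a joint, test.
* Binary platform concerns (very large n) are out of scope: the
  eigendecomposition is dense and O(n³).
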