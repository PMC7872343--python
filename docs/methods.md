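# Methods

## Model

A patient's DXA T-score triple t = (t_spine, t_neck, t_hip) is modelled as
an elliptical vector centered at the young-adult reference point (the
T-score origin). When the young-adult reference mean and SD at each site
are estimated from m young adults, the classical distribution of
(X − X̄)/S makes each T-score a scaled univariate Student-t, and the triple
is modelled as trivariate t with

    dof   ν = m − 1,
    scale Σ = ((m + 1) / m) · R,

where R is the 3×3 inter-site correlation matrix (unit diagonal,
positive definite). With m = ∞ — the default, and the regime the
simulation study works in — the law is trivariate normal with covariance R.
The exact dof/scale constants for a finite reference are a standard
reconstruction of the textbook result, not asserted as unique; everything
downstream degrades continuously to the normal limit.

From this family the package provides:

* **joint density** — `scipy.stats.multivariate_t` / `multivariate_normal`;
* **marginals** — univariate t(ν, center_i, √Σ_ii), normal at ν = ∞;
* **conditionals** — one site given the other two: t with dof ν + 2,
  location μ₁ + Σ₁₂Σ₂₂⁻¹(x₂ − μ₂), scale inflated by (ν + d₂²)/(ν + 2)
  with d₂² the Mahalanobis distance of the observed pair (standard
  multivariate-t conditioning); the normal-theory conditional at ν = ∞;
* **Mahalanobis distance** d²(t) = tᵀR⁻¹t via Cholesky solves.

## The two diagnostic rules

*WHO/ISCD (univariate)*: osteoporosis iff min t ≤ −2.5; osteopenia iff
−2.5 < min t < −1 (both strict); else normal. Boundary conventions are
taken verbatim from the printed inequalities.

*Ellipsoid (multivariate)*: with d = √(tᵀR⁻¹t) and s = Σᵢ tᵢ,

    osteoporosis iff d ≥ 2.5 and s < 0
    osteopenia   iff 1 < d < 2.5 and s < 0
    normal       otherwise.

The boundary radii equal the magnitudes of the univariate thresholds —
that is the sense in which the ellipsoids are "equivalent" to the WHO
cut-offs — and the boundary conventions mirror the WHO ones (inclusive at
the osteoporosis radius, strict at both osteopenia radii).

**The low-direction gate.** An exterior point can lie on the high-BMD side
(e.g. (+4, +4, +4)); no published prescription exists for such points, so a
design choice was required. We gate on strict negativity of the unweighted
T-score sum. Rationale: by elliptical symmetry the hyperplane s = 0 splits
every Mahalanobis shell into equal halves, so the rule's expected category
rates are exactly half the χ²₃ shell probabilities — 5.00 % osteoporosis
and 35.06 % osteopenia — which bracket the simulation-study rates this
package reproduces. Moreover, under common random numbers with the
symmetric square root (below), both d² and the sign of s are invariant
across equicorrelation levels, which is what makes the ellipsoid-rule
columns of the simulation grid identical. s = 0 exactly (measure zero)
counts as normal. A consequence worth knowing: containment of WHO
osteoporosis in ellipsoid osteoporosis is *not* a theorem under this
reconstruction — a discordant profile like (−2.5, +2, +2) at R = I fails
the gate — so the package reports disagreement rates rather than assuming
containment.

**Analytic coverage.** `category_coverage` returns
(½·P(χ²₃ ≥ 6.25), ½·[P(χ²₃ ≥ 1) − P(χ²₃ ≥ 6.25)], rest)
= (0.050030, 0.350596, 0.599374) in the normal limit, and the scaled-F law
d²/3 ~ F(3, ν) for finite ν. The result is independent of R by
construction and is cross-checked against a 10⁶-draw Monte Carlo oracle in
the tests.

## Synthetic cohorts

`simulate_cohort` draws n rows of t = μ + σ ∘ (S z), z iid standard
normal, S a square root of R. Defaults are the simulation-study
conditions: n = 1000, marginally standard-normal T-scores (μ = 0, σ = 1 —
the simulated elderly population is set equal to the young-adult
reference; this identification is forced by the grid's WHO-normal rate at
zero correlation, 59.5 % ≈ Φ(1)³), equicorrelation grid
ρ ∈ {0, 0.2, 0.4, 0.6, 0.8}.

Two square roots are available. The default is the **symmetric
(principal) root**: S = R^{1/2} symmetric implies
d² = zᵀR^{1/2}R⁻¹R^{1/2}z = zᵀz, so with one shared z across the grid
(common random numbers) each patient's d² — and, for equicorrelated R, the
sign of their T-score sum — is identical at every correlation level;
ellipsoid counts are then bit-for-bit constant along the grid while WHO
counts move. Cholesky is provided for comparison; it reproduces the same
distributions but not the exact cross-column invariance.

`emulate_real_cohort` generates a trivariate-normal stand-in for a real
screening cohort of 1000 65-year-old women: T-score means
(−0.90, −1.54, −0.97), SDs (1.50, 0.93, 1.04), inter-site correlations
(0.6558, 0.6145, 0.7508), with optional independent Bernoulli covariates
(diabetes 7.1 %, prior fracture 2.4 %, supplementation 60.3 %). It matches
first and second moments only: no skewness, no machine mix, no
covariate–BMD dependence, and FRAX columns are never synthesized (FRAX is
proprietary and is consumed as input only). Tests that pass on this
emulation therefore establish the *direction* of the real-data findings
(the ellipsoid rule diagnoses more osteoporosis, fewer normals; both
McNemar dichotomizations significant), not the published patient counts,
which come from undeposited data.

## Study pipeline

`run_table3` produces the full simulation grid (congruence, WHO and
ellipsoid counts per correlation level). `mcnemar` uses the uncorrected
statistic (b − c)²/(b + c) against χ²₁ — the published χ² values are not
reconstructible from the published marginals under either convention, so
the simpler one is fixed. `compare_rules` reports the 3×3 paired
cross-tabulation and McNemar tests for the two dichotomizations
(osteoporosis vs not; osteopenia-or-worse vs normal); a fully concordant
dichotomy is reported as χ² = 0, p = 1 rather than an error.
`frax_group_compare` runs Welch two-sample t-tests on user-supplied FRAX
columns between WHO-osteopenic patients the ellipsoid rule reclassifies as
osteoporotic and those it does not.

## Numerical choices

* Mahalanobis forms and conditionals use Cholesky factorization; positive
  definiteness is validated at `CorrelationModel` construction (smallest
  eigenvalue > 0), so downstream solves cannot silently operate on a
  degenerate model.
* Quadrature cross-checks in the tests truncate at ±8 SD for normal-tail
  integrands (truncated mass < 10⁻¹⁴) and extend to ±2000 on a log-spaced
  grid for t(5) tails (polynomial decay; mass beyond the box < 10⁻⁹).
* WHO-rule orthant/band probabilities under correlation use
  `scipy.stats.multivariate_normal.cdf` with lower limits (quasi-Monte
  Carlo, abs. tolerance ~10⁻⁶).
* Ellipsoid boundary meshes map a latitude/longitude unit-sphere grid
  through radius·R^{1/2}, so mesh points satisfy the quadratic form to
  rounding error rather than to a mesh tolerance.
* Seeds: one integer seed feeds one `numpy.random.default_rng` stream per
  cohort; the grid study reuses a single draw across correlation levels by
  construction. Covariate draws use a derived `SeedSequence((seed, 1))`
  stream so adding covariates does not perturb the T-scores.
* Simulation sizes: n = 1000 per grid column (the study condition);
  distribution-law checks use 10⁵ draws (Kolmogorov–Smirnov against χ²₃)
  and the coverage oracle 10⁶ draws, sizes at which binomial/KS noise is
  well below the tested tolerances.

## Limitations

* Exactly three sites; forearm or trabecular-bone extensions would need a
  larger correlation model (the linear algebra generalizes, the fixed
  3-site schema does not).
* No estimation of ν from data; the reference sample size is supplied, not
  inferred.
* The gate choice (sum < 0) is one reasonable reconstruction; any
  half-space through the origin preserves the coverage halving, and other
  choices would reclassify individual discordant profiles differently.
* Z-score (age-matched) pediatric/premenopausal variants and treatment
  guidance are out of scope.
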