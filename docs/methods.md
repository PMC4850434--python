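# Methods

This note records the statistical model behind each stage of `mmtsa`,
the defaults and why they were chosen, the numerical choices, and what
the synthetic-data tests do and do not establish.

## Study-level effects

Each study is a pair of genotype-count triples (CC, CT, TT) for cases
and controls.  Under the allele model the 2×2 contrast counts alleles
(T = CT + 2·TT per arm, 2n alleles total); the four subject-level
models pool or drop genotype rows.  The study effect is the log odds
ratio `ln(ad/bc)` with Woolf variance `1/a + 1/b + 1/c + 1/d`.  A 0.5
continuity correction is added to all four cells only when a cell is
zero; the bundled dataset has no zero cells, so the correction only
ever affects synthetic or user-supplied edge cases, where it makes the
estimator deterministic and finite.

Hardy–Weinberg equilibrium in control arms is tested with the 1-df
Pearson χ² against expected counts from the sample allele frequency,
*without* the Yates correction: the continuity-corrected statistic does
not recover the HWE p-values printed alongside the bundled studies
(e.g. the 0.08 for the Moon controls), the uncorrected one does, to two
decimals, for all nine.  A monomorphic arm fits HWE trivially and is
reported as χ² = 0, p = 1 rather than an error.  Control arms violating
HWE are flagged (`hwe.csv` column `in_hwe`), not excluded — none of the
bundled studies violate it, so no exclusion policy is ever exercised.

## Pooling

Fixed-effect pooling is Mantel–Haenszel over the 2×2 tables with the
Robins–Breslow–Greenland variance.  The classical inverse-variance pool
of Woolf log ORs is also provided (`pool_fixed`), but MH is the default
in the table pipeline deliberately: it is what the standard
meta-analysis software computes for count data, and on the bundled
dataset the two disagree in the second decimal (homozygous 1.160 vs
1.165; recessive 1.134 vs 1.143) — the MH values are the ones the
published table prints.  Random-effects pooling is DerSimonian–Laird:
τ² is the moment estimator `max(0, (Q − df)/(Σw − Σw²/Σw))` from the
inverse-variance Q, and weights are `1/(se² + τ²)`.  Heterogeneity
(Q, I², τ²) is always computed from the inverse-variance fit, which is
what accompanies an MH pool in standard software output.

Model choice is `random` when *P*(Q) < 0.10 **or** I² > 50%, else
`fixed`.  The disjunction (not a conjunction) is required to reproduce
the published model column: the allele contrast has I² = 47 < 50 yet is
pooled random, which only the p-value branch explains.

Confidence intervals are Wald on the log-OR scale (no Knapp–Hartung),
matching the era and software of the source analysis.  Presentation
rounding is 2 dp for ORs/CIs and nearest integer for I².

Leave-one-out sensitivity re-runs the pool k times, re-selecting
fixed/random per subset.  On the bundled data no deletion moves any of
the five pooled ORs below 1.

## Publication-bias diagnostics

Egger's test is the classical unweighted OLS of the standardized effect
`θ/se` on precision `1/se`; the statistic is intercept/SE(intercept) on
k−2 df.  The weighted variant gives a different t and does not match
the published recessive-model value (t = 1.53), so it is not offered.
When every study shares one SE the regressor is constant and the test
is refused as undefined rather than silently returning a least-norm
solution.  Begg–Mazumdar correlates the variance-standardized deviates
`(θᵢ − θ̂_F)/√(vᵢ − v_F)` with the variances by Kendall's tau-a
(explicit pair counting; ties contribute zero) and uses the
continuity-corrected normal approximation for p.  `vᵢ − v_F` is floored
at 1e-12: at very small k a single study's variance can equal the
pooled variance to rounding.

## Trial sequential analysis

Diversity is `D² = (v_R − v_F)/v_R` from the two pooled variances; it
is ≥ I² on the same data and enters the required information size as
the factor `1/(1 − D²)`.

The information size uses the binary-outcome formula
`(z₁₋α/₂ + z_pow)² · 2·p̄(1−p̄)/δ²` with `p_e = p_c(1 + RRI)`,
`p̄ = (p_c + p_e)/2`, `δ = p_e − p_c`, rounded up.  Two conventions of
this constant circulate; the `4·p̄(1−p̄)/δ²` (total-size) variant is
available as `ris_variant="total"` and gives exactly twice the default.
The default (per-group-style) constant is the one consistent with the
published required size for the bundled analysis (≈2,823 subjects from
p_c = 38.02%, RRI = 16.81%, D² = 67%); the other variant would give
≈5,644.

The control-arm "event proportion" for the allele-model TSA is the T
allele frequency among control alleles (38.02% in the bundled data),
while information is counted in subjects — the convention of the
published run this package mirrors (its 2,823 is stated in subjects).
An `information_unit="alleles"` switch is exposed for users who prefer
consistent units.

Boundaries are two-sided O'Brien–Fleming-type Lan–DeMets: cumulative
spent alpha `α(t) = 4(1 − Φ(z₁₋α/₄/√t))`, which equals α at t = 1 so a
single look at full information reduces to the fixed-sample 1.96 test.
Boundary z-values at the actual looks are solved by the standard
recursion: the sub-density of the Brownian score process that has never
crossed is propagated on a 1,501-point trapezoid grid and each look's
boundary is found by Brent's method on the incremental crossing
probability.  Accuracy is ~1e-4 in z (the K=5 equal-spacing boundaries
reproduce the published reference values 4.88/3.36/2.68/2.29/2.03, and
a 10⁵-path Monte-Carlo check puts the overall crossing rate at the
nominal α).  Boundaries beyond z = 8 are capped; the crossing mass
there is < 1e-15.  Looks are the studies in ascending publication year
(ties broken by study label — standard cumulative-meta practice; the
ordering is a package convention).  Information fractions are capped at
1; looks past the required size share the final-look boundary.

The TSA-adjusted CI inflates the conventional Wald half-width by
`z_boundary(final look)/z₁₋α/₂`, so once the required information size
is reached it equals the conventional CI.  This is a transparent,
documented approximation: the original TSA desktop program computes its
adjusted interval by an internal algorithm that is not fully specified
in its manual, and on the bundled data (information 2.5× the required
size) its published interval is wider than the conventional one — an
output this approximation intentionally does not chase.  The boundary
table and Z-curve are exported so users can apply any alternative
adjustment.

## Mendelian randomization

The Wald ratio divides the allele-model pooled log OR by the
gene-exposure effect β (SD change in ln-homocysteine per T allele).
The default β = 0.158 is the estimate of the external GWAS
meta-analysis of 44,147 individuals that this instrument is anchored
to; with the bundled gene-outcome pool it yields OR 2.67 per SD ln-Hcy
(95% CI 1.12–6.37) and 96.5% analytic power — the full published MR
block — whereas the rounded 0.16 reproduces the point estimate but not
the interval tail.  `infer_beta_from_ors` back-derives β from any two
printed ORs for auditing.

The first-order delta SE `se/|β|` ignores instrument uncertainty (the
usual single-instrument practice when the instrument SE is not
reported); supplying `InstrumentEffect(se=...)` adds the second-order
term `θ̂²·se_β²/β²` to the ratio's variance (θ̂ the Wald-ratio estimate).
Under the first-order method the MR z and p equal the gene-outcome z
and p exactly — dividing numerator and SE by the same constant — which
the tests assert.

Power uses the binary-outcome approximation
`Φ(√(N·R²·p(1−p))·|ln OR| − z₁₋α/₂)` with R² the variance in exposure
explained by the instrument (default 0.01) and p the case fraction.

## Synthetic data

The generator draws, per study: a control T-allele frequency q uniform
on (0.20, 0.50); control genotypes multinomial under HWE; case
genotypes from the exponentially tilted HWE distribution
`P(g) ∝ HWE(g)·exp(θᵢ·dose(g))` — the exact generative counterpart of a
logistic disease model with per-allele log OR θᵢ; and
`θᵢ ~ N(θ, τ²)`.  Defaults emulate the bundled dataset's conditions:
nine studies, θ = ln(1.17), τ² = 0.0175 (its DL estimate), case sizes
30–1,300 and control sizes 80–1,800 (its observed span).  All
randomness flows through one `numpy.random.Generator` seeded from the
config; a fixed seed gives byte-identical CSV output.

What the simulations show: the HWE test is calibrated (5.0% rejections
at α = 0.05 over 5,000 control arms), the fixed-effect allele pool is
nearly unbiased (|bias| < 0.01 log-OR) with ~94–95% CI coverage at
τ² = 0, and the boundary machinery holds the familywise crossing rate
at ~5% over five looks.  What they do not show: robustness to
genotyping error, control-source confounding, population
stratification, or selective publication — the generator samples none
of these, so passing tests certify the estimators under the assumed
model, not the epidemiology of any real literature.

## Numerical and degenerate-input choices

* Zero cells: +0.5 to all four cells (only when a zero occurs).
* Monomorphic arms: HWE p = 1 by definition, not an error.
* `τ²` and `I²` floored at 0; `D²` floored at 0 and required < 1.
* Boundary solver: fractions must be strictly increasing in (0, 1];
  non-increasing schedules are rejected, spending is capped at α.
* `pool_random(..., tau2=0)` reproduces `pool_fixed` exactly (asserted).
* Simulation sizes in the test-suite: 2,000 replicates for coverage and
  bias, 5,000 for HWE calibration and boundary crossing — large enough
  that the Monte-Carlo SE is well inside each asserted tolerance, and
  the whole suite stays interactive (~10 s).
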