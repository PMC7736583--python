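# Methods

This note documents the models implemented in `sccadmix`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions that matter for reproducing results.

## The generative model

The simulator exists because the cohorts this analysis targets are
access-restricted; it provides the minimal generative structure under which
every downstream stage is testable by parameter recovery.

**Ancestral frequencies.** Each variant draws a shared ancestral frequency
`p ~ U(0.05, 0.95)`, then per-population frequencies
`p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` (Balding–Nichols), clamped to
[0.005, 0.995]. `F` (`divergence_scale`) is Fst-like: the ratio-of-averages
Hudson estimator over simulated variants recovers `F` to within sampling
error. Defaults: `F = 0.15` for neutral markers in the three-way admixed
design (EUR/NAM/AFR scale), `F = 0.02` for the within-European cline design.

**Pigmentation SNPs are directional.** Rather than symmetric perturbation,
the 36 pigment SNPs draw their dark-allele frequency from `Beta(2, 10)`
(clipped to [0.03, 0.97]) in the European-like population and `Beta(10, 2)`
elsewhere, emulating the strong continental differentiation of real
pigmentation loci; this is what makes predicted skin colour
ancestry-correlated and the mediation analysis non-trivial. Four pigment
SNPs and two risk SNPs are set near-monomorphic (frequency 0.005
everywhere) so the 1 % MAF polymorphism filter has something to remove
(36 → 32 and 16 → 14), as it does in real panels. Risk-SNP frequencies are
kept in [0.08, 0.92] so that only the designated pair sits near the filter
boundary.

**Genome and tracts.** The default marker map is 652 variants (600 neutral
+ 36 pigment + 16 risk) spread over 22 chromosomes at 2 Mb spacing under a
constant 1 cM/Mb map. The spacing is deliberately wide: it approximates an
ancestry-informative panel of weakly linked markers, so each individual's
realised genome-wide ancestry closely tracks their drawn Dirichlet
proportion (correlation ≈ 0.97 at `g = 10`), which is what lets PC1 recover
the *drawn* European fraction with |r| > 0.9. Global ancestry is
`Dirichlet(6, 3, 1)` (EUR, NAM, AFR) for the admixed design — mean 60 %
European, qualitatively matching Hispanic/Latino cohorts — and
`Dirichlet(5, 5)` for the two-way cline design. Tracts follow the Markov
chain with stay probability `exp(-g·Δd)`; the closed-form expected switch
count per haplotype is `Σ_gaps (1 − exp(−g·Δd))·(1 − Σπ_k²)`, which the
simulator reproduces within Monte-Carlo error.

**Liabilities.** Age is `N(60, 13²)` truncated to [18, 95]; sex is
Bernoulli(½). Age enters all liabilities centred per decade,
`(age − 60)/10`. Default log-odds effects: cSCC intercept −5.0 (≈ 11–12 %
prevalence under the defaults), age 0.55/decade, male 0.55, European
fraction 1.5 (a *direct* ancestry effect — the generating truth is "largely
but not entirely mediated"), collapsed pigment probabilities −1.2
(intermediate) and −2.5 (dark; pale group is reference, so negative means
darker skin is protective), GRS 1.0 (the published weights are exactly on
the cohort's log-odds scale), AK 1.4. AK itself: intercept −1.6, age
0.45/decade, ancestry 1.2, dark-probability −1.5. The negative-control
outcome uses intercept −4.3, age 0.2/decade, sex 0.3 and *no*
ancestry/pigment/GRS terms (prevalence ≈ 1.4 %). Tumour-site classes for
cases are multinomial (0.919, 0.039, 0.042) over sun-exposed /
sun-protected / both — the located-case proportions of large cSCC series,
renormalised. No published liability-scale effects exist for these
quantities; the values are realistic defaults chosen once, not calibration
targets.

**Pigment generating coefficients.** The generating multinomial model is an
adjacent-category structure: category rank `t ∈ {1..4}` times a dark-allele
burden score (slope 0.6 per allele copy) plus intercepts
(1.2, 3.6, 2.2, 0.4), centred on the cohort-expected burden. This yields a
balanced pale/intermediate/dark mix (~0.4/0.2/0.4) and ~85 % agreement
between the sampled true category and the modal predicted category —
consistent with the high published accuracy of genotype-based skin-colour
prediction. The analysis-side predictor is the general multinomial form and
accepts any coefficient file; no published coefficient values are bundled.

**What the simulator does not emulate.** Coalescent LD within ancestral
populations (markers are independent given local ancestry), recombination
hotspots, genotyping error, imputation uncertainty, family structure, and
environmental confounding that correlates with ancestry. Passing tests
therefore demonstrate the statistical machinery is correct under the stated
model, not that real-data effect sizes would be reproduced.

## Analysis conventions

**PCA.** Variants with MAF < 1 % are dropped; missing dosages are
mean-imputed; columns are centred at the empirical mean dosage and scaled by
`sqrt(p̂(1−p̂))` with the shrunk `p̂ = (1 + Σg)/(2 + 2n)` (the smartpca
convention; empirical centring makes score columns exactly zero-mean).
Scores are unit-norm left singular vectors — note the regression
coefficients on PCs are therefore scale-dependent and large in absolute
value; only their relative attenuation across models is interpretable.
Small problems use a full SVD; above 500 in the smaller dimension a Lanczos
solver with a fixed start vector computes the top components (bit-identical
across reruns). Component sign is fixed by making the largest-magnitude
variant loading positive.

**Model sequence.** Model 1: age + sex + ancestry PCs (6 for the admixed
group; 10 plus the Ashkenazi-fraction covariate for the European-cline
group). Model 2 adds the intermediate and dark collapsed pigment
*probabilities* (the combined pale group is the reference; probabilities
rather than hard labels are used because they are what the predictor
outputs — a hard-label alternative is a one-line change on the caller's
side). Model 3 adds the GRS; Model 4 adds AK. Site-stratified runs refit
Models 1–2 on cases of one site class against all controls; cases with
tumours at both classes are excluded from single-site strata. Logistic fits
use Newton/IRLS (tolerance 1e-8 on the gradient, 100 iterations max) with
observed-information standard errors; perfect separation is reported via
`converged=False` with a diagnostic, and rank-deficient designs raise an
error naming the collinear columns.

**Variance decomposition.** The per-block "variance explained" is the
increment in adjusted R² of an ordinary least-squares (linear-probability)
fit on cumulative covariate sets, reported as percentages; increments
telescope exactly to full-model-minus-baseline. A likelihood-based
pseudo-R² was considered and rejected as the default because it does not
decompose additively.

**Association scans.** Bonferroni thresholds divide by the number of
variants actually tested after the MAF filter (30, 14 and 16 are the
familiar counts). Monomorphic variants are skipped with a warning and do
not enter the denominator. Conditional scans add the (mean-imputed) risk-SNP
dosages as covariates; a tested variant identical to a conditioning variant
is reported as fully conditioned (β = 0, p = 1) rather than erroring.

**Local ancestry.** A marker-level allele-frequency HMM per haplotype:
stationary/initial distribution = the individual's global proportions,
transition over Δd Morgans = stay with `exp(-g·Δd)` else redraw from the
global proportions, emissions = clamped panel frequencies. This is a
deliberate simplification of window-based haplotype-cluster methods — it
ignores ancestral LD — but it is exact under the simulator's generative
model (forward–backward matches exhaustive path enumeration to 1e-10) and
is what the admixture-mapping statistic needs. In files mode without known
proportions, a supervised non-negative-least-squares moment estimator seeds
the stationary distribution. The admixture-map statistic is the case-control
difference in mean local European ancestry fraction with a label-permutation
null (add-one corrected, `p = (b+1)/(n_perm+1)`, default 10 000
permutations, reproducible given the seed). Known limitation: with a global
ancestry effect on risk, *every* locus shows a case-control local-ancestry
difference (local ancestry is correlated with global ancestry); the test
localises signal only beyond that genome-wide shift, as in any
admixture-mapping design — interpret locus flags against the genome-wide
background, or simulate the null with the global effect included.

**Fine-mapping.** Wakefield approximate Bayes factor
`sqrt(V/(V+W))·exp(z²W/(2(V+W)))` with prior effect variance `W = 0.04`
(prior SD 0.2 log-odds — a conventional weakly-informative choice for
complex-trait ORs); single-causal posteriors are ABFs normalised over a
±1 Mb window anchored at the smallest-p variant; the 95 % credible set is
the smallest posterior-sorted prefix reaching 0.95, ties broken by genomic
position. Normalisation is done on the log scale so extreme z-scores stay
finite. Multi-causal configurations are out of scope.

**Prevalence surface.** Nadaraya–Watson ratio of the kernel-weighted case
indicator, weight `φ(k·d(x,j)/d_max)` with `φ` the standard normal density,
`d_max` the exact 2-D diameter of the PC cloud (convex hull), `k = 15` by
default and a 100×100 grid over the observed PC range. The ratio form keeps
the surface inside [min(y), max(y)] and makes `k → 0` return the overall
prevalence; grid cells whose total weight underflows to zero are flagged
NaN. The weighted-sum (unnormalised) variant would plot case density
instead of prevalence and is not what a prevalence colour scale wants.

**Rounding.** Displayed percentages use half-up rounding at one decimal via
`decimal.Decimal` (locale-independent); thresholds are additionally
reported at 2–3 significant figures, matching how such tables are printed.

## Problem sizes used by the test suite and acceptance script

Cohorts of 1 500–10 000 individuals and 150–2 050 markers, replicate counts
of 10–500 depending on the per-replicate cost; each check states its size
inline. These are the package's chosen verification scales: large enough
that binomial/Monte-Carlo error is well inside every asserted margin,
small enough to keep the default suite fast on a single CPU.

## Known limitations

- The HMM ignores ancestral-population LD; accuracy claims hold under the
  simulator's model, not for real dense genotypes.
- The linear-probability R² decomposition is one of several defensible
  definitions of "variance explained" for a binary outcome.
- The meta-analytic combination of ethnic groups and multi-causal
  fine-mapping are out of scope.
- GRS weights are treated as fixed known constants; uncertainty in the
  published effect sizes is not propagated.
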