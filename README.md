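# sccadmix

Genetic ancestry, skin pigmentation and sun exposure in cutaneous squamous
cell carcinoma (cSCC) risk — a simulation and analysis pipeline for admixed
case-control cohorts.

## The scientific problem

cSCC is among the most common cancers in people of European descent, and its
prevalence varies strongly *within* populations: with the north-west-to-
south-east European ancestry cline among non-Hispanic whites, and with the
European vs Native-American/African ancestry balance among Hispanic/Latinos.
Three mechanisms plausibly link ancestry to risk: genetically determined
skin pigmentation (lighter skin gives less UVR protection), known cSCC risk
alleles whose frequencies differ between ancestral populations, and
cumulative sun exposure. Disentangling them requires a chain of analyses —
ancestry principal components, genotype-based pigmentation prediction,
genetic risk scores, nested logistic ("attenuation") models, local-ancestry
admixture mapping and credible-set fine-mapping — that this package
implements as one tested, reusable toolkit, for statistical geneticists and
epidemiologists working with admixed cohorts.

Because the biobank genotypes such studies rest on are access-restricted,
the package ships a first-class synthetic-cohort generator with fully known
ground truth, so every stage is validated by parameter recovery.

## The models

**Generator** (`sccadmix.simulate`). Ancestral allele frequencies follow a
Balding–Nichols model with an Fst-like divergence parameter. Per individual,
global ancestry π is Dirichlet; per haplotype, local-ancestry tracts form a
Markov chain along each chromosome (stay probability `exp(-g·Δd)` over Δd
Morgans after `g` generations of admixture), and alleles are drawn from the
tract population's frequency. Outcomes follow logistic liabilities:

    logit P(cSCC) = β₀ + β_age·age + β_sex·sex + β_anc·q_EUR
                    + β_int·P(intermediate) + β_dark·P(dark) + β_GRS·GRS + β_AK·AK

with actinic keratosis (AK, the sun-exposure marker) itself drawn from a
logistic model in ancestry and pigmentation, and a negative-control outcome
(non-cutaneous SCC) that depends on age and sex only.

**Analysis.** PCA uses Eigenstrat-style standardisation
(`(g − ḡ)/√(p̂(1−p̂))`, shrunk p̂). Skin colour is a multinomial logistic
model on up to 36 pigment-SNP dosages (HIrisPlex-S model form; coefficients
are configurable inputs), with the five categories collapsed to
pale / intermediate / dark for modelling. The GRS is the effect-size-weighted
allele count over risk SNPs passing the 1 % MAF filter. Models 1–4 add, in
order: ancestry PCs; pigmentation probabilities; GRS; AK — attenuation of
the PC coefficients measures mediation. Local ancestry is inferred by a
per-haplotype forward–backward HMM over ancestral origins; admixture mapping
compares mean local European ancestry between cases and controls with a
permutation null. Fine-mapping uses Wakefield approximate Bayes factors and
single-causal 95 % credible sets. Prevalence surfaces over (PC1, PC2) use a
radial Gaussian kernel, `w_j = φ(k·d(x,j)/d_max)` with smoothing value
`k = 15`.

## Worked example

```bash
sccadmix all --seed 1 --out out/demo    # or: python -m sccadmix.cli ...
```

with a config selecting a simulated three-way admixed cohort of 2 000
individuals prints a report ending in:

```
Cohort summary
stratum         level              cases  controls       %
overall         all                  231      1769    11.6
ak              1                    136       320    29.8
ak_among_cases  yes                  136         0    58.9
...

Ancestry attenuation (PC1 beta by model)
  model1: beta=-49.016 se=4.155 p=8.16e-32
  model2: beta=-6.754 se=6.582 p=0.61
  model3: beta=-10.221 se=6.664 p=0.25
  model4: beta=-10.705 se=6.844 p=0.236
```

Read: the cohort has 11.6 % cSCC prevalence; the ancestry effect on risk
(Model 1, PC1 β = −49, the sign reflecting PC orientation) collapses once
predicted pigmentation enters (Model 2, p = 0.61) — in this simulated cohort
the generating ancestry effect is largely pigment-mediated, which is exactly
what the nested sequence is designed to expose. Per-stage outputs
(`pcs.tsv`, `pigment_probs.tsv`, `grs.tsv`, `models.tsv`, `lrt.tsv`,
`variance_explained.tsv`, `admixture_map.tsv`, `credible_sets.tsv`,
`contour.tsv`) are tab-separated with the seed and config hash in their
headers; reruns are bit-identical.

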