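"""Synthetic admixed cohorts with known truth.

The real cohorts this package targets (large health-system biobanks with
restricted genotypes) cannot be redistributed, so every downstream stage is
exercised against cohorts simulated here with fully known ground truth:

* **Ancestral allele frequencies** follow a Balding–Nichols model: a shared
  ancestral frequency per variant, perturbed per population by a Beta draw
  whose spread is governed by ``divergence_scale`` (an Fst-like parameter).
* **Global ancestry** per individual is Dirichlet; **local ancestry** is laid
  down along each chromosome as a first-order Markov chain per haplotype:
  over a gap of ``Δd`` Morgans the tract label is kept with probability
  ``exp(-g·Δd)`` (``g`` generations since admixture) and otherwise redrawn
  from the individual's global proportions.  Alleles are drawn independently
  from the tract population's frequency.
* **Phenotypes** follow a logistic liability model: actinic keratosis (AK,
  the sun-exposure mediator) depends on ancestry and pigmentation; cSCC
  depends on age, sex, European ancestry fraction, predicted pigmentation,
  a weighted genetic risk score, and AK; the negative-control outcome
  (non-cutaneous SCC) depends on age and sex only.

Two preset study designs are provided: a three-way European/Native-American/
African admixed cohort (Hispanic/Latino-like) and a two-way north-west vs
south-east European cline cohort.  All draws are made from a single
``numpy`` Generator seeded from the configuration, so identical
configurations reproduce identical cohorts bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .data import SITE_CLASSES, GenotypeData, SNPPanel
from .errors import ConfigError, InvalidArgumentError, ValidationError
from .pigment import (
    CATEGORIES3,
    PigmentModel,
    collapse_categories,
    predict_skin_probabilities,
    sample_category5,
)

FREQ_CLAMP = (0.005, 0.995)


# ---------------------------------------------------------------------------
# ancestral panel
# ---------------------------------------------------------------------------
@dataclass
class AncestralPanel:
    """Per-variant, per-population ancestral allele frequencies plus a map.

    ``allele_freqs`` is ``(n_variants, n_pops)`` (alternate-allele frequency,
    clamped inside (0, 1)); ``pos_bp`` is the 1-based physical position and
    ``gpos`` the genetic position in Morgans, strictly increasing within a
    chromosome.
    """

    pop_labels: tuple[str, ...]
    variant_ids: list[str]
    allele_freqs: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    gpos: np.ndarray

    def __post_init__(self) -> None:
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.gpos = np.asarray(self.gpos, dtype=float)
        m = len(self.variant_ids)
        if self.allele_freqs.shape != (m, len(self.pop_labels)):
            raise ValidationError("allele_freqs must be n_variants x n_pops")
        if not ((self.allele_freqs > 0) & (self.allele_freqs < 1)).all():
            raise ValidationError("frequencies must lie strictly inside (0, 1)")
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            if not (np.diff(self.pos_bp[sel]) > 0).all() or not (
                np.diff(self.gpos[sel]) > 0
            ).all():
                raise ValidationError(
                    f"positions must be strictly increasing within chromosome {c}"
                )

    @property
    def n_pops(self) -> int:
        return len(self.pop_labels)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def variant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chrom": self.chrom.astype(str),
                "pos": self.pos_bp,
                "ref": "A",
                "alt": "G",
                "gpos": self.gpos,
            }
        )


def _default_map(
    n_snps: int,
    n_chromosomes: int,
    spacing_bp: int,
    cm_per_mb: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evenly spaced markers over equal-sized chromosomes, constant-rate map."""
    per = int(math.ceil(n_snps / n_chromosomes))
    chrom, pos, gpos = [], [], []
    k = 0
    for c in range(1, n_chromosomes + 1):
        for j in range(per):
            if k >= n_snps:
                break
            bp = (j + 1) * spacing_bp
            chrom.append(str(c))
            pos.append(bp)
            gpos.append(bp / 1e6 * cm_per_mb / 100.0)  # Morgans
            k += 1
    return np.array(chrom), np.array(pos, dtype=np.int64), np.array(gpos)


def simulate_ancestral_frequencies(
    n_snps: int,
    n_pops: int,
    divergence_scale: float,
    seed: int,
    *,
    pop_labels: tuple[str, ...] | None = None,
    n_chromosomes: int = 1,
    spacing_bp: int = 100_000,
    cm_per_mb: float = 1.0,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
    id_prefix: str = "snp",
) -> AncestralPanel:
    """Balding–Nichols ancestral panel.

    A shared ancestral frequency ``p`` is drawn uniformly on
    ``ancestral_range`` per variant; each population's frequency is then
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ``F = divergence_scale``, so that
    the expected pairwise Hudson-type differentiation between populations is
    approximately ``F``.  Frequencies are clamped to [0.005, 0.995].
    """
    if n_snps < 1 or n_pops < 1:
        raise InvalidArgumentError("n_snps and n_pops must be positive")
    if not 0.0 < divergence_scale <= 0.5:
        raise InvalidArgumentError("divergence_scale must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(*ancestral_range, size=n_snps)
    f = divergence_scale
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    freqs = rng.beta(a[:, None], b[:, None], size=(n_snps, n_pops))
    freqs = np.clip(freqs, *FREQ_CLAMP)
    labels = pop_labels or tuple(f"POP{i + 1}" for i in range(n_pops))
    chrom, pos, gpos = _default_map(n_snps, n_chromosomes, spacing_bp, cm_per_mb)
    width = max(4, len(str(n_snps)))
    ids = [f"{id_prefix}{i + 1:0{width}d}" for i in range(n_snps)]
    return AncestralPanel(
        pop_labels=tuple(labels),
        variant_ids=ids,
        allele_freqs=freqs,
        chrom=chrom,
        pos_bp=pos,
        gpos=gpos,
    )


def hudson_fst(p1: np.ndarray, p2: np.ndarray) -> float:
    """Ratio-of-averages Hudson-type differentiation between two populations
    from their per-variant allele frequencies."""
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class EffectBlock:
    """Log-odds effects of the liability models.

    Age enters all models centred and per decade (``(age - 60) / 10``); sex
    is coded 1 = male; ancestry is the fraction of the first (European-like)
    population; pigment effects multiply the collapsed category
    *probabilities* (the pale group is the reference); the GRS coefficient
    multiplies the weighted risk score, so 1.0 means the published weights
    are exactly on the cohort's log-odds scale.
    """

    intercept: float = -5.0
    age: float = 0.55
    sex: float = 0.55
    ancestry: float = 1.5
    pigment_intermediate: float = -1.2
    pigment_dark: float = -2.5
    grs: float = 1.0
    ak: float = 1.4
    # AK (sun-exposure mediator) model
    ak_intercept: float = -1.6
    ak_age: float = 0.45
    ak_ancestry: float = 1.2
    ak_pigment_dark: float = -1.5
    # negative-control outcome: no ancestry / pigment / GRS terms
    ncscc_intercept: float = -4.3
    ncscc_age: float = 0.2
    ncscc_sex: float = 0.3


@dataclass
class SimulationConfig:
    """Cohort-level generative settings; see module docstring for the model."""

    seed: int
    n_individuals: int
    dirichlet_alpha: tuple[float, ...] = (6.0, 3.0, 1.0)
    generations: int = 10
    effects: EffectBlock = field(default_factory=EffectBlock)
    site_probs: tuple[float, float, float] = (0.919, 0.039, 0.042)
    group_label: str = "admixed"
    age_mean: float = 60.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (18.0, 95.0)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise InvalidArgumentError("n_individuals must be positive")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise InvalidArgumentError("dirichlet_alpha entries must be > 0")
        if self.generations < 1:
            raise InvalidArgumentError("generations must be >= 1")
        if abs(sum(self.site_probs) - 1.0) > 1e-9:
            raise InvalidArgumentError("site_probs must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidArgumentError("missing_rate must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth retained for parameter-recovery tests."""

    pop_labels: tuple[str, ...]
    global_ancestry: np.ndarray  # (n, K), rows sum to 1
    local_ancestry_true: np.ndarray  # (n, 2, m) int8 population indices
    linear_predictor: np.ndarray | None = None  # cSCC log-odds, set later

    def __post_init__(self) -> None:
        ga = np.asarray(self.global_ancestry, dtype=float)
        if not np.allclose(ga.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("global ancestry rows must sum to 1")
        self.global_ancestry = ga

    def ancestry_fraction(self, pop: str) -> np.ndarray:
        return self.global_ancestry[:, self.pop_labels.index(pop)]

    def local_fraction(self, pop: str) -> np.ndarray:
        """(n, m) realised per-variant ancestry fraction (0, 0.5 or 1)."""
        k = self.pop_labels.index(pop)
        return (self.local_ancestry_true == k).sum(axis=1) / 2.0


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------
def _categorical_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One categorical draw per row of ``probs``."""
    u = rng.random(len(probs))
    return (u[:, None] > probs.cumsum(axis=1)).sum(axis=1).astype(np.int8)


def expected_switches(panel: AncestralPanel, props: np.ndarray, g: int) -> float:
    """Closed-form expected number of tract switches per haplotype.

    Under the generating Markov chain the probability of an ancestry change
    across a gap of ``Δd`` Morgans is ``(1 - exp(-g·Δd))·(1 - Σπ_k²)``;
    summing over gaps (within chromosomes) gives the expectation.
    """
    het = 1.0 - float((np.asarray(props) ** 2).sum())
    total = 0.0
    for c in np.unique(panel.chrom):
        gd = panel.gpos[panel.chrom == c]
        total += float((1.0 - np.exp(-g * np.diff(gd))).sum())
    return total * het


def simulate_admixed_cohort(
    panel: AncestralPanel,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeData, TruthRecord]:
    """Draw phased genotypes and true ancestry for one cohort."""
    if len(config.dirichlet_alpha) != panel.n_pops:
        raise InvalidArgumentError(
            f"dirichlet_alpha has {len(config.dirichlet_alpha)} entries but the "
            f"panel has {panel.n_pops} populations"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m, k = config.n_individuals, panel.n_variants, panel.n_pops
    props = rng.dirichlet(config.dirichlet_alpha, size=n)  # (n, K)
    pi_h = np.repeat(props, 2, axis=0)  # (2n, K)
    h = 2 * n

    states = np.empty((h, m), dtype=np.int8)
    alleles = np.empty((h, m), dtype=np.int8)
    for c in np.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        stay = np.exp(-config.generations * np.diff(panel.gpos[idx]))
        cur = _categorical_rows(rng, pi_h)
        states[:, idx[0]] = cur
        for t, j in enumerate(idx[1:]):
            keep = rng.random(h) < stay[t]
            redraw = _categorical_rows(rng, pi_h)
            cur = np.where(keep, cur, redraw).astype(np.int8)
            states[:, j] = cur
        freqs = panel.allele_freqs[idx]  # (L, K)
        for t, j in enumerate(idx):
            alleles[:, j] = rng.random(h) < freqs[t, states[:, j]]

    haplotypes = alleles.reshape(n, 2, m)
    dosages = haplotypes.sum(axis=1).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan
        haplotypes = haplotypes.copy()
        haplotypes[np.repeat(mask[:, None, :], 2, axis=1)] = -1

    samples = [f"ind{i + 1:06d}" for i in range(n)]
    genotypes = GenotypeData(
        samples=samples,
        variants=panel.variant_table(),
        dosages=dosages,
        haplotypes=haplotypes,
    )
    truth = TruthRecord(
        pop_labels=panel.pop_labels,
        global_ancestry=props,
        local_ancestry_true=states.reshape(n, 2, m),
    )
    return genotypes, truth


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------
def simulate_phenotypes(
    genotypes: GenotypeData,
    truth: TruthRecord,
    panel_meta: SNPPanel,
    config: SimulationConfig,
    pigment_model: PigmentModel | None,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw covariates and outcomes for a simulated cohort.

    Returns a phenotype table aligned with ``genotypes.samples`` carrying the
    outcomes (``cscc``, ``ncscc``), covariates (age, sex, AK, Ashkenazi
    fraction, tumour-site class) and, for recovery tests, the generating
    pigment category (``pigment3_true``) and true European-ancestry fraction
    (``eur_truth``).
    """
    eff = config.effects
    if pigment_model is None:
        raise ConfigError("pigment-model coefficients are required to simulate")
    rng = (
        np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        if rng is None
        else rng
    )
    n = genotypes.n_samples

    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    age_c = (age - 60.0) / 10.0
    sex = rng.random(n) < 0.5

    probs = predict_skin_probabilities(genotypes, pigment_model)
    p3 = probs.probs3.to_numpy()
    true5 = sample_category5(probs.probs5, rng)
    true3 = collapse_categories(
        pd.get_dummies(pd.Categorical(true5, categories=list(probs.probs5.columns)))
        .to_numpy()
        .astype(float)
    )
    true3_label = np.asarray(CATEGORIES3, dtype=object)[
        true3.to_numpy().argmax(axis=1)
    ]

    risk = panel_meta.variants_with_role("risk")
    grs = genotypes.effect_dosages(
        risk["variant_id"].tolist(), risk["effect_allele"].tolist()
    )
    grs = np.nan_to_num(grs, nan=0.0) @ risk["weight"].to_numpy(dtype=float)

    eur = truth.global_ancestry[:, 0]  # first population is the European-like one

    ak_logit = (
        eff.ak_intercept
        + eff.ak_age * age_c
        + eff.ak_ancestry * eur
        + eff.ak_pigment_dark * p3[:, 2]
    )
    ak = rng.random(n) < expit(ak_logit)

    lin = (
        eff.intercept
        + eff.age * age_c
        + eff.sex * sex
        + eff.ancestry * eur
        + eff.pigment_intermediate * p3[:, 1]
        + eff.pigment_dark * p3[:, 2]
        + eff.grs * grs
        + eff.ak * ak
    )
    cscc = rng.random(n) < expit(lin)
    truth.linear_predictor = lin

    nc_lin = eff.ncscc_intercept + eff.ncscc_age * age_c + eff.ncscc_sex * sex
    ncscc = rng.random(n) < expit(nc_lin)

    site = np.full(n, "", dtype=object)
    case_idx = np.flatnonzero(cscc)
    if len(case_idx):
        draw = _categorical_rows(
            rng, np.tile(np.asarray(config.site_probs), (len(case_idx), 1))
        )
        site[case_idx] = np.asarray(SITE_CLASSES, dtype=object)[draw]

    ashk = rng.beta(0.5, 4.5, size=n)

    return pd.DataFrame(
        {
            "individual_id": genotypes.samples,
            "cscc": cscc.astype(int),
            "ncscc": ncscc.astype(int),
            "age": age,
            "sex": sex.astype(int),
            "group": config.group_label,
            "ak": ak.astype(int),
            "site_class": site,
            "ashk": ashk,
            "pigment3_true": true3_label,
            "eur_truth": eur,
            "grs_truth": grs,
        }
    )


# ---------------------------------------------------------------------------
# preset study designs
# ---------------------------------------------------------------------------
def _pigment_generating_model(
    variant_ids: list[str],
    *,
    slope: float = 0.6,
    intercepts: tuple[float, float, float, float] = (1.2, 3.6, 2.2, 0.4),
    score_center: float | None = None,
    n_pops_mid_freq: float = 0.5,
) -> PigmentModel:
    """Adjacent-category generating model for skin colour.

    Category predictors share one dark-allele burden score (``slope`` per
    allele copy, multiplied by the category rank 1..4), so darker categories
    need a higher burden; the intercepts set the category mix at the centre
    of the score range.
    """
    m = len(variant_ids)
    center = score_center if score_center is not None else 2 * m * n_pops_mid_freq
    t = np.array([1.0, 2.0, 3.0, 4.0])
    coef = np.outer(t, np.full(m, slope))
    inter = np.asarray(intercepts) - t * slope * center
    return PigmentModel(
        variant_ids=list(variant_ids),
        effect_alleles=["G"] * m,
        intercepts=inter,
        coefficients=coef,
    )


@dataclass
class StudyDesign:
    """Bundle of everything needed to simulate one study cohort."""

    panel: AncestralPanel
    snp_panel: SNPPanel
    pigment_model: PigmentModel
    config: SimulationConfig


def default_study(
    kind: str = "admixed",
    n_individuals: int = 4000,
    seed: int = 0,
    *,
    n_neutral: int = 600,
    effects: EffectBlock | None = None,
) -> StudyDesign:
    """Preset three-way admixed or two-way European-cline study design.

    The admixed design uses populations (EUR, NAM, AFR) with Dirichlet
    concentration (6, 3, 1) and neutral-marker divergence 0.15; the cline
    design uses (NW, SE) with concentration (5, 5) and divergence 0.02.
    Pigmentation SNPs are directional: the dark allele is rare in the
    European(-like north-western) population and common elsewhere, so
    predicted skin colour correlates with ancestry as it does in admixed
    human cohorts.  Of 36 pigment SNPs, 4 are near-monomorphic, and of 16
    risk SNPs, 2 are near-monomorphic, mirroring panels that lose variants
    to the 1% MAF filter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    if kind == "admixed":
        pops = ("EUR", "NAM", "AFR")
        alpha: tuple[float, ...] = (6.0, 3.0, 1.0)
        neutral_scale = 0.15
        dark_light = (2.0, 10.0)  # Beta params: dark-allele freq, EUR-like pop
        dark_dark = (10.0, 2.0)  # other populations
    elif kind == "cline":
        pops = ("NW", "SE")
        alpha = (5.0, 5.0)
        neutral_scale = 0.02
        dark_light = (2.0, 8.0)
        dark_dark = (5.0, 5.0)
    else:
        raise InvalidArgumentError("kind must be 'admixed' or 'cline'")

    n_pig, n_risk = 36, 16
    n_snps = n_neutral + n_pig + n_risk
    base = simulate_ancestral_frequencies(
        n_snps,
        len(pops),
        neutral_scale,
        int(rng.integers(2**31)),
        pop_labels=pops,
        n_chromosomes=22,
        spacing_bp=2_000_000,
    )

    order = rng.permutation(n_snps)
    pig_idx = np.sort(order[:n_pig])
    risk_idx = np.sort(order[n_pig : n_pig + n_risk])

    freqs = base.allele_freqs.copy()
    freqs[pig_idx, 0] = np.clip(rng.beta(*dark_light, size=n_pig), 0.03, 0.97)
    for kpop in range(1, len(pops)):
        freqs[pig_idx, kpop] = np.clip(rng.beta(*dark_dark, size=n_pig), 0.03, 0.97)
    # keep scored risk variants clear of the 1% MAF boundary so only the two
    # designated near-monomorphic ones are lost to the filter
    freqs[risk_idx, :] = np.clip(freqs[risk_idx, :], 0.08, 0.92)
    freqs = np.clip(freqs, *FREQ_CLAMP)
    # near-monomorphic variants: fall below the 1% MAF polymorphism filter
    freqs[pig_idx[:4], :] = 0.005
    freqs[risk_idx[:2], :] = 0.005

    ids = np.asarray(base.variant_ids, dtype=object)
    ids[pig_idx] = [f"pig{i + 1:02d}" for i in range(n_pig)]
    ids[risk_idx] = [f"risk{i + 1:02d}" for i in range(n_risk)]
    panel = AncestralPanel(
        pop_labels=pops,
        variant_ids=list(ids),
        allele_freqs=freqs,
        chrom=base.chrom,
        pos_bp=base.pos_bp,
        gpos=base.gpos,
    )

    role = np.full(n_snps, "neutral", dtype=object)
    role[pig_idx] = "pigment"
    role[risk_idx] = "risk"
    weight = np.full(n_snps, np.nan)
    weight[risk_idx] = np.clip(rng.normal(0.15, 0.05, size=n_risk), 0.05, None)
    freq_cols = {f"freq_{p}": freqs[:, i] for i, p in enumerate(pops)}
    snp_panel = SNPPanel(
        table=pd.DataFrame(
            {
                "variant_id": list(ids),
                "role": role,
                "effect_allele": "G",
                "weight": weight,
                **freq_cols,
            }
        ),
        pop_labels=pops,
    )

    pig_ids = [v for v in ids if str(v).startswith("pig")]
    # centre the burden score on the cohort-expected dosage so the category
    # mix straddles pale / intermediate / dark at the mean ancestry
    mean_anc = np.asarray(alpha) / sum(alpha)
    mid = float(2.0 * (freqs[pig_idx] @ mean_anc).sum())
    pigment_model = _pigment_generating_model(pig_ids, score_center=mid)

    config = SimulationConfig(
        seed=seed,
        n_individuals=n_individuals,
        dirichlet_alpha=alpha,
        group_label=kind,
        effects=effects or EffectBlock(),
    )
    return StudyDesign(
        panel=panel, snp_panel=snp_panel, pigment_model=pigment_model, config=config
    )


@dataclass
class SimulatedStudy:
    genotypes: GenotypeData
    truth: TruthRecord
    phenotypes: pd.DataFrame
    design: StudyDesign


def simulate_study(design: StudyDesign) -> SimulatedStudy:
    """Run the full generative model for one study design."""
    genotypes, truth = simulate_admixed_cohort(design.panel, design.config)
    phenotypes = simulate_phenotypes(
        genotypes, truth, design.snp_panel, design.config, design.pigment_model
    )
    return SimulatedStudy(
        genotypes=genotypes, truth=truth, phenotypes=phenotypes, design=design
    )


def with_effects(design: StudyDesign, **updates) -> StudyDesign:
    """Copy of ``design`` with selected liability effects replaced."""
    return StudyDesign(
        panel=design.panel,
        snp_panel=design.snp_panel,
        pigment_model=design.pigment_model,
        config=replace(design.config, effects=replace(design.config.effects, **updates)),
    )
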