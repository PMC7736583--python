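"""Genetic risk scores and the logistic attenuation-model machinery.

This module carries the statistical core of the case-control analysis:

* a weighted/unweighted genetic risk score (GRS) over the known risk SNPs,
  after the 1% MAF polymorphism filter;
* maximum-likelihood logistic regression (Newton/IRLS with observed-
  information standard errors) wrapped in a :class:`ModelFit` results object;
* the nested Model 1–4 sequence — ancestry PCs; + pigmentation
  probabilities; + GRS; + actinic-keratosis history — whose coefficient
  attenuation quantifies how much of the ancestry effect is mediated by
  pigmentation and sun exposure;
* likelihood-ratio tests between nested fits and an incremental
  adjusted-R² variance decomposition per risk-factor block;
* per-variant and conditional association scans with Bonferroni flags, and
  haplotype LD statistics (D′, r²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from scipy.stats import chi2

from .data import GenotypeData, SNPPanel, check_aligned
from .errors import (
    ConfigError,
    DegenerateInputError,
    InvalidArgumentError,
    ValidationError,
)
from .pigment import PigmentProbabilities, filter_polymorphic

MAX_ITER = 100
TOL = 1e-8


# ---------------------------------------------------------------------------
# genetic risk score
# ---------------------------------------------------------------------------
@dataclass
class GRSVector:
    """Per-individual genetic risk score (log-odds-weighted allele count)."""

    samples: list[str]
    values: np.ndarray
    weighted: bool
    variants_used: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"individual_id": self.samples, "grs": self.values})


def compute_grs(
    genotypes: GenotypeData,
    panel: SNPPanel,
    weighted: bool = True,
    maf_min: float = 0.01,
) -> GRSVector:
    """Sum of effect-allele dosages over the risk SNPs, optionally weighted
    by the published per-allele effect sizes.

    Variants failing the MAF filter are excluded before scoring; missing
    dosages are replaced by the variant's mean observed dosage.
    """
    risk = panel.variants_with_role("risk")
    if risk.empty:
        raise DegenerateInputError("panel contains no risk variants")
    if maf_min > 0:
        kept = filter_polymorphic(risk["variant_id"].tolist(), genotypes, maf_min)
    else:  # maf_min = 0 disables the polymorphism filter
        kept = risk["variant_id"].tolist()
    if not kept:
        raise DegenerateInputError("no risk variant passes the MAF filter")
    sub = risk.set_index("variant_id").loc[kept]
    dos = genotypes.effect_dosages(kept, sub["effect_allele"].tolist())
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.where(np.isnan(dos))
        dos[nan_r, nan_c] = col_mean[nan_c]
    if weighted:
        w = sub["weight"].to_numpy(dtype=float)
        if np.isnan(w).any():
            raise ConfigError("weighted GRS requires a weight for every risk variant")
    else:
        w = np.ones(len(kept))
    return GRSVector(
        samples=list(genotypes.samples),
        values=dos @ w,
        weighted=weighted,
        variants_used=kept,
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------
@dataclass
class ModelFit:
    """One fitted logistic model: estimates, SEs, p-values, log-likelihood."""

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    llf: float
    n: int
    converged: bool
    message: str = ""
    outcome: str = "y"

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * chi2.sf(self.zvalues**2, 1)

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "beta": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )


def _check_design(x: np.ndarray, names: list[str]) -> None:
    """Reject rank-deficient designs, naming the collinear columns."""
    if x.shape[0] <= x.shape[1]:
        raise InvalidArgumentError(
            f"{x.shape[0]} observations cannot identify {x.shape[1]} parameters"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r, piv = qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        thresh = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= thresh]
        bad += [names[piv[i]] for i in range(len(diag), x.shape[1])]
        raise InvalidArgumentError(
            f"design matrix is rank deficient; collinear columns: {sorted(set(bad))}"
        )


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    outcome: np.ndarray,
    add_intercept: bool = True,
    outcome_name: str = "y",
) -> ModelFit:
    """Maximum-likelihood logistic fit (Newton/IRLS, observed information).

    ``design`` holds the covariates (an intercept column named ``const`` is
    prepended unless already present or ``add_intercept`` is false).  Perfect
    separation is reported through ``converged=False`` with a diagnostic
    message rather than silently returned estimates.
    """
    if isinstance(design, pd.DataFrame):
        xdf = design.copy()
    else:
        arr = np.atleast_2d(np.asarray(design, dtype=float))
        if arr.shape[0] == 1 and len(outcome) != 1:
            arr = arr.T
        xdf = pd.DataFrame(arr, columns=[f"x{i + 1}" for i in range(arr.shape[1])])
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(xdf):
        raise InvalidArgumentError("outcome length must match the design")
    if add_intercept and "const" not in xdf.columns:
        xdf.insert(0, "const", 1.0)
    x = xdf.to_numpy(dtype=float)
    names = list(xdf.columns)
    _check_design(x, names)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, x).fit(
                disp=0, method="newton", maxiter=MAX_ITER, tol=TOL
            )
        converged = bool(res.mle_retvals.get("converged", True)) and np.isfinite(
            res.params
        ).all()
        return ModelFit(
            names=names,
            params=np.asarray(res.params, dtype=float),
            bse=np.asarray(res.bse, dtype=float),
            llf=float(res.llf),
            n=len(y),
            converged=converged,
            message="" if converged else "maximum-likelihood fit did not converge",
            outcome=outcome_name,
        )
    except Exception as exc:  # separation / divergence
        return ModelFit(
            names=names,
            params=np.full(len(names), np.nan),
            bse=np.full(len(names), np.nan),
            llf=np.nan,
            n=len(y),
            converged=False,
            message=f"fit failed (possible perfect separation): {exc}",
            outcome=outcome_name,
        )


# ---------------------------------------------------------------------------
# the Model 1-4 attenuation sequence
# ---------------------------------------------------------------------------
GROUP_N_PCS = {"admixed": 6, "cline": 10}


def _sequence_design(
    phenotypes: pd.DataFrame,
    pcs,
    pigment: PigmentProbabilities,
    grs: GRSVector,
    group: str,
) -> pd.DataFrame:
    if group not in GROUP_N_PCS:
        raise InvalidArgumentError(f"group must be one of {sorted(GROUP_N_PCS)}")
    samples = phenotypes["individual_id"].tolist()
    check_aligned(samples, pcs.frame().rename(columns={"individual_id": "individual_id"}))
    if pigment.samples != samples or grs.samples != samples:
        raise ValidationError("pigment/GRS blocks are not aligned with the phenotypes")
    n_pcs = GROUP_N_PCS[group]
    if pcs.scores.shape[1] < n_pcs:
        raise ConfigError(
            f"group {group!r} requires {n_pcs} PCs but only "
            f"{pcs.scores.shape[1]} were computed"
        )
    design = pd.DataFrame(
        {
            "age": phenotypes["age"].to_numpy(dtype=float),
            "sex": phenotypes["sex"].to_numpy(dtype=float),
        }
    )
    for i in range(n_pcs):
        design[f"PC{i + 1}"] = pcs.scores[:, i]
    if group == "cline":
        if "ashk" not in phenotypes.columns:
            raise ConfigError("cline-group models require an 'ashk' column")
        design["ashk"] = phenotypes["ashk"].to_numpy(dtype=float)
    design["pigment_intermediate"] = pigment.probs3["intermediate"].to_numpy()
    design["pigment_dark"] = pigment.probs3["dark"].to_numpy()
    design["grs"] = grs.values
    if "ak" not in phenotypes.columns:
        raise ConfigError("phenotype table lacks the 'ak' covariate")
    design["ak"] = phenotypes["ak"].to_numpy(dtype=float)
    return design


def fit_model_sequence(
    phenotypes: pd.DataFrame,
    pcs,
    pigment: PigmentProbabilities,
    grs: GRSVector,
    group: str = "admixed",
    outcome: str = "cscc",
    mask: np.ndarray | None = None,
) -> dict[str, ModelFit]:
    """Fit the nested Model 1–4 sequence.

    Model 1: age + sex + ancestry PCs (6 for the admixed group, 10 plus the
    Ashkenazi fraction for the European-cline group).  Model 2 adds the
    intermediate and dark collapsed pigmentation probabilities (combined
    pale group as reference); Model 3 adds the GRS; Model 4 adds AK history.
    ``mask`` optionally restricts the fit (e.g. tumour-site strata).
    """
    design = _sequence_design(phenotypes, pcs, pigment, grs, group)
    y = phenotypes[outcome].to_numpy(dtype=float)
    if mask is not None:
        design = design.loc[np.asarray(mask)].reset_index(drop=True)
        y = y[np.asarray(mask)]
    base = [c for c in design.columns if c.startswith(("age", "sex", "PC", "ashk"))]
    blocks = {
        "model1": base,
        "model2": base + ["pigment_intermediate", "pigment_dark"],
        "model3": base + ["pigment_intermediate", "pigment_dark", "grs"],
        "model4": base + ["pigment_intermediate", "pigment_dark", "grs", "ak"],
    }
    return {
        name: fit_logistic(design[cols], y, outcome_name=outcome)
        for name, cols in blocks.items()
    }


def site_stratum_mask(phenotypes: pd.DataFrame, stratum: str) -> np.ndarray:
    """Cases whose tumour-site class equals ``stratum`` plus all controls.

    Cases with tumours at both site classes are excluded from single-site
    strata (they match neither stratum label).
    """
    cscc = phenotypes["cscc"].to_numpy(dtype=int)
    site = phenotypes["site_class"].astype(str).to_numpy()
    return (cscc == 0) | ((cscc == 1) & (site == stratum))


def attenuation(fit_a: ModelFit, fit_b: ModelFit, term: str = "PC1") -> float:
    """Fractional attenuation of ``|beta_term|`` from ``fit_a`` to ``fit_b``."""
    a, b = abs(fit_a.coef(term)), abs(fit_b.coef(term))
    return (a - b) / a


# ---------------------------------------------------------------------------
# model comparison and variance decomposition
# ---------------------------------------------------------------------------
@dataclass
class NestedModelComparison:
    lr_statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(
    nested: ModelFit, full: ModelFit
) -> NestedModelComparison:
    """Deviance difference between two nested fits on the same individuals."""
    if not set(nested.names) <= set(full.names):
        raise InvalidArgumentError("models are not nested (covariate sets)")
    if nested.n != full.n:
        raise InvalidArgumentError("models were fitted on different individuals")
    if not (nested.converged and full.converged):
        raise InvalidArgumentError("both fits must have converged")
    df = len(full.names) - len(nested.names)
    stat = max(2.0 * (full.llf - nested.llf), 0.0)
    p = 1.0 if df == 0 else float(chi2.sf(stat, df))
    return NestedModelComparison(lr_statistic=stat, df=df, p_value=p)


@dataclass
class VarianceExplainedTable:
    """Incremental adjusted R² (%) per risk-factor block, Model 1-4 order."""

    table: pd.DataFrame  # columns: block, adj_r2_increment_pct

    def increment(self, block: str) -> float:
        row = self.table.loc[self.table["block"] == block]
        return float(row["adj_r2_increment_pct"].iloc[0])


def variance_explained(
    outcome: np.ndarray,
    baseline: pd.DataFrame,
    blocks: dict[str, pd.DataFrame],
) -> VarianceExplainedTable:
    """Adjusted-R² increments of a linear-probability fit per covariate block.

    Ordinary least squares of the binary outcome on cumulative covariate
    sets (baseline = age + sex; then each block in Model 1–4 order); each
    block is credited with its increment in adjusted R², as a percentage.
    The increments telescope to the full-model adjusted R² minus baseline.
    """
    y = np.asarray(outcome, dtype=float)
    design = baseline.reset_index(drop=True).copy()
    if len(y) <= design.shape[1] + sum(b.shape[1] for b in blocks.values()) + 1:
        raise InvalidArgumentError("fewer individuals than parameters")

    def adj_r2(df: pd.DataFrame) -> float:
        x = sm.add_constant(df.to_numpy(dtype=float))
        return float(sm.OLS(y, x).fit().rsquared_adj)

    prev = adj_r2(design)
    rows = []
    for name, block in blocks.items():
        design = pd.concat([design, block.reset_index(drop=True)], axis=1)
        cur = adj_r2(design)
        rows.append({"block": name, "adj_r2_increment_pct": 100.0 * (cur - prev)})
        prev = cur
    return VarianceExplainedTable(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# per-variant association
# ---------------------------------------------------------------------------
def _single_variant_fits(
    genotypes: GenotypeData,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None,
    variant_ids: list[str] | None,
    alpha_family: float,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    ids = variant_ids if variant_ids is not None else genotypes.variant_ids
    if not ids:
        raise InvalidArgumentError("need at least one variant to test")
    y = np.asarray(outcome, dtype=float)
    cov = covariates.reset_index(drop=True) if covariates is not None else None
    rows = []
    tested = 0
    for vid in ids:
        dos = genotypes.dosages[:, genotypes.variant_indices([vid])[0]]
        finite = dos[np.isfinite(dos)]
        if finite.size == 0 or np.all(finite == finite[0]):
            warnings.warn(f"variant {vid} is monomorphic; skipped", stacklevel=2)
            continue
        dosage = np.where(np.isfinite(dos), dos, finite.mean())
        fully_conditioned = False
        if extra is not None:
            xm = extra.to_numpy(dtype=float)
            if any(np.array_equal(dosage, xm[:, j]) for j in range(xm.shape[1])):
                fully_conditioned = True
        tested += 1
        if fully_conditioned:
            rows.append(
                {
                    "variant_id": vid,
                    "beta": 0.0,
                    "se": np.nan,
                    "odds_ratio": 1.0,
                    "p": 1.0,
                    "converged": True,
                    "fully_conditioned": True,
                }
            )
            continue
        parts = [pd.DataFrame({"dosage": dosage})]
        if extra is not None:
            parts.append(extra.reset_index(drop=True))
        if cov is not None:
            parts.append(cov)
        fit = fit_logistic(pd.concat(parts, axis=1), y)
        rows.append(
            {
                "variant_id": vid,
                "beta": fit.coef("dosage") if fit.converged else np.nan,
                "se": fit.se("dosage") if fit.converged else np.nan,
                "odds_ratio": np.exp(fit.coef("dosage")) if fit.converged else np.nan,
                "p": fit.pvalue("dosage") if fit.converged else np.nan,
                "converged": fit.converged,
                "fully_conditioned": False,
            }
        )
    if tested == 0:
        raise DegenerateInputError("no testable (polymorphic) variant")
    out = pd.DataFrame(rows)
    threshold = alpha_family / tested
    out["bonferroni_significant"] = out["p"] < threshold
    out.attrs["n_tested"] = tested
    out.attrs["bonferroni_threshold"] = threshold
    return out


def per_snp_association(
    genotypes: GenotypeData,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    variant_ids: list[str] | None = None,
    alpha_family: float = 0.05,
) -> pd.DataFrame:
    """One logistic fit per variant (dosage + shared covariates).

    Monomorphic variants are skipped with a warning and do not count toward
    the Bonferroni denominator, which is the number of variants actually
    tested.  The returned frame carries ``attrs['bonferroni_threshold']``.
    """
    return _single_variant_fits(
        genotypes, outcome, covariates, variant_ids, alpha_family
    )


def conditional_association(
    genotypes: GenotypeData,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None,
    conditioning_variants: list[str],
    variant_ids: list[str] | None = None,
    alpha_family: float = 0.05,
) -> pd.DataFrame:
    """Per-variant association conditioning on the known risk-SNP dosages.

    A tested variant whose dosage is identical to a conditioning variant is
    reported as fully conditioned (beta 0, p 1) rather than raising.
    With no conditioning variants this reduces exactly to
    :func:`per_snp_association`.
    """
    extra = None
    if conditioning_variants:
        idx = genotypes.variant_indices(conditioning_variants)
        cols = {}
        for vid, i in zip(conditioning_variants, idx):
            dos = genotypes.dosages[:, i]
            finite = dos[np.isfinite(dos)]
            fill = finite.mean() if finite.size else 0.0
            cols[f"cond_{vid}"] = np.where(np.isfinite(dos), dos, fill)
        extra = pd.DataFrame(cols)
    return _single_variant_fits(
        genotypes, outcome, covariates, variant_ids, alpha_family, extra=extra
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------
@dataclass
class LDResult:
    r2: float
    d_prime: float
    d: float
    p_a: float
    p_b: float


def ld_stats(hap_a: np.ndarray, hap_b: np.ndarray) -> LDResult:
    """Haplotype LD between two variants.

    ``hap_a`` and ``hap_b`` are aligned 0/1 allele vectors over haplotypes.
    ``D = p_AB − p_A·p_B``; ``D′ = |D| / D_max`` given the margins;
    ``r² = D² / (p_A(1−p_A)·p_B(1−p_B))``.
    """
    a = np.asarray(hap_a, dtype=float).ravel()
    b = np.asarray(hap_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise InvalidArgumentError("haplotype vectors must be aligned")
    keep = np.isfinite(a) & np.isfinite(b) & (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise InvalidArgumentError("no complete haplotypes")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise DegenerateInputError("LD is undefined for a monomorphic variant")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d**2 / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDResult(r2=float(r2), d_prime=float(d_prime), d=float(d), p_a=float(p_a), p_b=float(p_b))
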