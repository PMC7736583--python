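"""Genotype-based skin-pigmentation prediction.

Skin colour is predicted from a panel of pigmentation SNPs (up to 36) with a
multinomial logistic model in the style of the HIrisPlex-S system: one linear
predictor per non-reference colour category, each an intercept plus a
per-variant coefficient times the effect-allele dosage, passed through a
softmax against the reference category ("very pale", whose predictor is 0).

The five predicted categories are collapsed to the three used in downstream
risk models — (very pale + pale), intermediate, (dark + dark to black) — the
combined pale group serving as the regression reference.  Published
coefficient values are not bundled; a :class:`PigmentModel` is a configurable
input (the simulator supplies a generating model for synthetic cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeData, SNPPanel
from .errors import DegenerateInputError, InvalidArgumentError, ValidationError

#: Five-category labels, reference first; order is fixed.
CATEGORIES5 = ("very pale", "pale", "intermediate", "dark", "dark to black")
#: Collapsed three-category labels, in downstream model order.
CATEGORIES3 = ("pale", "intermediate", "dark")

MISSING_POLICIES = ("mean", "drop")


@dataclass
class PigmentModel:
    """Multinomial skin-colour model.

    Parameters
    ----------
    variant_ids, effect_alleles
        The pigment SNPs and the allele whose dosage enters the predictors.
    intercepts
        Length-4 array, one per non-reference category (order:
        pale, intermediate, dark, dark to black).
    coefficients
        ``(4, n_variants)`` log-odds per effect-allele copy.
    """

    variant_ids: list[str]
    effect_alleles: list[str]
    intercepts: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.effect_alleles = list(self.effect_alleles)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n_cat = len(CATEGORIES5) - 1
        if self.intercepts.shape != (n_cat,):
            raise ValidationError("expected one intercept per non-reference category")
        if self.coefficients.shape != (n_cat, len(self.variant_ids)):
            raise ValidationError(
                f"coefficient matrix must be {n_cat} x {len(self.variant_ids)}"
            )
        if len(self.effect_alleles) != len(self.variant_ids):
            raise ValidationError("every variant needs an effect allele")

    def subset(self, variant_ids) -> "PigmentModel":
        keep = [self.variant_ids.index(v) for v in variant_ids]
        return PigmentModel(
            variant_ids=[self.variant_ids[i] for i in keep],
            effect_alleles=[self.effect_alleles[i] for i in keep],
            intercepts=self.intercepts,
            coefficients=self.coefficients[:, keep],
        )


@dataclass
class PigmentProbabilities:
    """Per-individual category probabilities (5-level and collapsed 3-level)."""

    samples: list[str]
    probs5: pd.DataFrame
    probs3: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.allclose(self.probs5.to_numpy().sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("five-category rows must sum to 1")


def filter_polymorphic(
    panel: SNPPanel | list[str],
    genotypes: GenotypeData,
    maf_min: float = 0.01,
) -> list[str]:
    """Variants whose sample minor allele frequency is at least ``maf_min``.

    Mirrors the polymorphism filter used before pigment/risk analyses: MAF is
    computed on non-missing dosages and variants with MAF < ``maf_min``
    (default 1%) are dropped.  A variant exactly at the threshold is kept.
    """
    if not 0.0 < maf_min < 0.5:
        raise InvalidArgumentError("maf_min must lie in (0, 0.5)")
    if genotypes.n_samples == 0 or genotypes.n_variants == 0:
        raise InvalidArgumentError("empty genotype set")
    ids = panel if isinstance(panel, list) else panel.table["variant_id"].tolist()
    idx = genotypes.variant_indices(ids)
    maf = genotypes.minor_allele_frequencies()[idx]
    return [v for v, m in zip(ids, maf) if np.isfinite(m) and m >= maf_min]


def _linear_predictors(dosages: np.ndarray, model: PigmentModel) -> np.ndarray:
    """(n, 5) predictors; reference category pinned at 0."""
    eta = dosages @ model.coefficients.T + model.intercepts
    return np.column_stack([np.zeros(len(dosages)), eta])


def softmax_probabilities(eta: np.ndarray) -> np.ndarray:
    shifted = eta - eta.max(axis=1, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=1, keepdims=True)


def predict_skin_probabilities(
    genotypes: GenotypeData,
    model: PigmentModel,
    missing_policy: str = "mean",
) -> PigmentProbabilities:
    """Predict five- and three-category skin-colour probabilities.

    ``missing_policy`` governs missing dosages: ``"mean"`` substitutes twice
    the sample effect-allele frequency (the dosage expected under
    Hardy-Weinberg); ``"drop"`` removes individuals with any missing pigment
    genotype.
    """
    if missing_policy not in MISSING_POLICIES:
        raise InvalidArgumentError(
            f"unknown missing_policy {missing_policy!r}; choose from {MISSING_POLICIES}"
        )
    dos = genotypes.effect_dosages(model.variant_ids, model.effect_alleles)
    samples = list(genotypes.samples)
    if np.isnan(dos).any():
        if missing_policy == "drop":
            keep = ~np.isnan(dos).any(axis=1)
            dos = dos[keep]
            samples = [s for s, k in zip(samples, keep) if k]
        else:
            col_mean = np.nanmean(dos, axis=0)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            nan_r, nan_c = np.where(np.isnan(dos))
            dos[nan_r, nan_c] = col_mean[nan_c]
    probs5 = softmax_probabilities(_linear_predictors(dos, model))
    probs5_df = pd.DataFrame(probs5, columns=list(CATEGORIES5))
    probs3_df = collapse_categories(probs5_df)
    return PigmentProbabilities(samples=samples, probs5=probs5_df, probs3=probs3_df)


def collapse_categories(probs5: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Collapse the five colour categories to three.

    (very pale + pale) -> ``pale``; ``intermediate`` unchanged;
    (dark + dark to black) -> ``dark``.  Rows must sum to 1 within 1e-6.
    """
    if isinstance(probs5, pd.DataFrame):
        arr = probs5[list(CATEGORIES5)].to_numpy(dtype=float)
    else:
        arr = np.asarray(probs5, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
    if arr.shape[1] != 5:
        raise ValidationError("expected five category columns")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("five-category rows must sum to 1 within 1e-6")
    out = np.column_stack([arr[:, 0] + arr[:, 1], arr[:, 2], arr[:, 3] + arr[:, 4]])
    return pd.DataFrame(out, columns=list(CATEGORIES3))


def modal_category3(probs3: pd.DataFrame) -> np.ndarray:
    """Most probable collapsed category per individual (ties -> first)."""
    arr = probs3[list(CATEGORIES3)].to_numpy()
    return np.asarray(CATEGORIES3, dtype=object)[arr.argmax(axis=1)]


def sample_category5(
    probs5: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Draw one five-level category per individual from its probability row."""
    arr = probs5[list(CATEGORIES5)].to_numpy()
    if arr.size == 0:
        raise DegenerateInputError("no individuals to sample")
    cum = arr.cumsum(axis=1)
    u = rng.random(len(arr))[:, None]
    idx = (u > cum).sum(axis=1)
    return np.asarray(CATEGORIES5, dtype=object)[idx]
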