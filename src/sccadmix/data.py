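"""Core in-memory containers shared by every analysis stage.

The package moves three objects between stages:

* :class:`GenotypeData` — an individuals × variants dosage matrix (alternate
  allele counts, ``NaN`` marking missing genotypes) with optional phased
  haplotypes, plus a variant table in VCF coordinate conventions (1-based,
  inclusive).
* :class:`SNPPanel` — variant metadata for the analysis panel: each variant's
  role (``pigment`` / ``risk`` / ``neutral``), its effect allele, its
  per-ancestral-population allele frequency, and, for risk variants, the
  published effect size used to weight the genetic risk score.
* phenotype tables — plain :class:`pandas.DataFrame` objects keyed by
  ``individual_id`` (see :data:`PHENOTYPE_COLUMNS`).

Sample alignment between stages always goes through individual identifiers;
misaligned inputs raise :class:`~sccadmix.errors.ValidationError` rather than
being silently reindexed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ValidationError

#: Columns a phenotype table may carry.  ``cscc`` is the primary outcome,
#: ``ncscc`` the negative-control outcome; ``ak`` is the actinic-keratosis
#: (chronic sun exposure) indicator; ``site_class`` classifies tumour location
#: for cases; ``ashk`` is an externally supplied Ashkenazi ancestry fraction.
PHENOTYPE_COLUMNS = (
    "individual_id",
    "cscc",
    "ncscc",
    "age",
    "sex",
    "group",
    "ak",
    "site_class",
    "ashk",
)

SITE_CLASSES = ("sun_exposed", "sun_protected", "both")

VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt")


@dataclass
class GenotypeData:
    """Dosage matrix with optional phased haplotypes.

    Parameters
    ----------
    samples
        Unique individual identifiers, one per dosage row.
    variants
        DataFrame with columns ``variant_id, chrom, pos, ref, alt`` (and
        optionally ``gpos``, the genetic position in Morgans).
    dosages
        ``(n_samples, n_variants)`` float array of alternate-allele counts in
        ``{0, 1, 2}``; ``NaN`` marks a missing genotype.
    haplotypes
        Optional ``(n_samples, 2, n_variants)`` int8 array of phased alleles
        (0 = reference, 1 = alternate); ``-1`` marks missing.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample identifiers must be unique")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValidationError(f"variant table lacks columns {missing}")
        if self.variants["variant_id"].duplicated().any():
            raise ValidationError("variant identifiers must be unique")
        self.variants = self.variants.reset_index(drop=True)
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (len(self.samples), 2, len(self.variants)):
                raise ValidationError("haplotype array shape mismatch")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    # -- lookups -----------------------------------------------------------
    def variant_indices(self, variant_ids) -> np.ndarray:
        """Positions of ``variant_ids`` in the variant table (order kept)."""
        lookup = {v: i for i, v in enumerate(self.variants["variant_id"])}
        try:
            return np.array([lookup[v] for v in variant_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - msg formatting
            raise InvalidArgumentError(f"unknown variant {exc.args[0]!r}") from exc

    def allele_frequencies(self) -> np.ndarray:
        """Sample alternate-allele frequency per variant on non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def effect_dosages(self, variant_ids, effect_alleles) -> np.ndarray:
        """Dosage of each variant's effect allele, ``(n, len(variant_ids))``.

        The effect allele must be the variant's ref or alt allele; ref-coded
        effect alleles flip the dosage to ``2 - dosage``.
        """
        idx = self.variant_indices(variant_ids)
        sub = self.dosages[:, idx].copy()
        ref = self.variants["ref"].to_numpy()[idx]
        alt = self.variants["alt"].to_numpy()[idx]
        for j, (allele, r, a) in enumerate(zip(effect_alleles, ref, alt)):
            if allele == a:
                continue
            if allele == r:
                sub[:, j] = 2.0 - sub[:, j]
            else:
                raise InvalidArgumentError(
                    f"effect allele {allele!r} is neither ref nor alt for "
                    f"variant {self.variants['variant_id'].iloc[idx[j]]!r}"
                )
        return sub

    def subset_variants(self, variant_ids) -> "GenotypeData":
        idx = self.variant_indices(variant_ids)
        return GenotypeData(
            samples=self.samples,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, idx],
        )


@dataclass
class SNPPanel:
    """Analysis-panel variant metadata.

    ``table`` columns: ``variant_id``, ``role`` (pigment/risk/neutral),
    ``effect_allele``, ``weight`` (published log-odds per effect allele for
    risk variants; NaN otherwise) and one ``freq_<pop>`` column per ancestral
    population.
    """

    table: pd.DataFrame
    pop_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        required = {"variant_id", "role", "effect_allele", "weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"SNP panel lacks columns {sorted(missing)}")
        if not self.pop_labels:
            self.pop_labels = tuple(
                c[len("freq_"):] for c in self.table.columns if c.startswith("freq_")
            )
        bad = set(self.table["role"]) - {"pigment", "risk", "neutral"}
        if bad:
            raise ValidationError(f"unknown variant roles {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    def variants_with_role(self, role: str) -> pd.DataFrame:
        return self.table[self.table["role"] == role].reset_index(drop=True)

    @property
    def pigment_variant_ids(self) -> list[str]:
        return self.variants_with_role("pigment")["variant_id"].tolist()

    @property
    def risk_variant_ids(self) -> list[str]:
        return self.variants_with_role("risk")["variant_id"].tolist()


def check_aligned(samples: list[str], table: pd.DataFrame) -> None:
    """Require ``table['individual_id']`` to equal ``samples`` in order."""
    ids = table["individual_id"].tolist()
    if ids != list(samples):
        raise ValidationError(
            "phenotype table is not aligned with genotype samples; join on "
            "individual_id before calling"
        )
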