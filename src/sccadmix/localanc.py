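"""Local-ancestry inference and admixture mapping.

Per haplotype, the ancestral origin along a chromosome is modelled as a
first-order hidden Markov chain whose hidden state is the ancestral
population.  The initial (and stationary) distribution is the individual's
global ancestry proportions; across a gap of ``Δd`` Morgans the state is
retained with probability ``exp(-g·Δd)`` (``g`` generations since
admixture) and otherwise redrawn from the global proportions.  Emissions are
the ancestral-panel allele frequencies of the carried allele.  Posteriors
come from the scaled forward–backward recursion; the per-individual
European-ancestry dosage at a site is the sum over the two haplotypes of the
posterior probability of the European state (a value in [0, 2]).

This is a marker-level allele-frequency HMM — a deliberate simplification of
window-based haplotype-cluster methods (LAMP-LD and kin), sufficient for the
statistical role local ancestry plays downstream and fully checkable against
simulated truth.

Admixture mapping then asks, locus by locus, whether mean local European
ancestry differs between cases and controls: the statistic is the difference
in mean ancestry fraction, its null distribution obtained by permuting case
labels (a nonparametric case-control ancestry test in the spirit of Montana
& Pritchard), with an add-one permutation p-value and a Bonferroni threshold
of alpha / number of loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeData
from .errors import DegenerateInputError, InvalidArgumentError, ValidationError
from .simulate import FREQ_CLAMP, AncestralPanel


@dataclass
class LocalAncestryMatrix:
    """Posterior expected European-origin allele counts per individual-locus."""

    samples: list[str]
    variant_ids: list[str]
    eur_dosage: np.ndarray  # (n, m) in [0, 2]
    posteriors: np.ndarray | None = None  # (n, 2, m, K) per-haplotype
    pop_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.eur_dosage = np.asarray(self.eur_dosage, dtype=float)
        if ((self.eur_dosage < -1e-9) | (self.eur_dosage > 2 + 1e-9)).any():
            raise ValidationError("European dosages must lie in [0, 2]")

    def locus_index(self, locus: str) -> int:
        try:
            return self.variant_ids.index(locus)
        except ValueError as exc:
            raise InvalidArgumentError(f"unknown locus {locus!r}") from exc


def _forward_backward(
    emissions: np.ndarray,  # (H, L, K)
    stay: np.ndarray,  # (L-1,)
    pi: np.ndarray,  # (H, K)
) -> np.ndarray:
    """Scaled forward-backward posteriors, vectorised over haplotypes."""
    h, ell, k = emissions.shape
    alpha = np.empty((h, ell, k))
    scale = np.empty((h, ell))
    a = pi * emissions[:, 0]
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / scale[:, 0][:, None]
    for t in range(1, ell):
        s = stay[t - 1]
        tot = alpha[:, t - 1].sum(axis=1)[:, None]  # ones, kept for clarity
        pred = s * alpha[:, t - 1] + (1.0 - s) * tot * pi
        a = pred * emissions[:, t]
        scale[:, t] = a.sum(axis=1)
        alpha[:, t] = a / scale[:, t][:, None]
    beta = np.empty((h, ell, k))
    beta[:, -1] = 1.0
    for t in range(ell - 2, -1, -1):
        s = stay[t]
        nxt = emissions[:, t + 1] * beta[:, t + 1]
        beta[:, t] = (s * nxt + (1.0 - s) * (pi * nxt).sum(axis=1)[:, None]) / scale[
            :, t + 1
        ][:, None]
    post = alpha * beta
    return post / post.sum(axis=2, keepdims=True)


def infer_local_ancestry(
    genotypes: GenotypeData,
    panel: AncestralPanel,
    g: int,
    global_props: np.ndarray,
    keep_posteriors: bool = False,
) -> LocalAncestryMatrix:
    """Forward–backward local-ancestry posteriors from phased haplotypes.

    ``global_props`` is ``(n, K)`` with rows summing to 1 (supplied from the
    truth record, from PCs, or any external estimate); the first panel
    population is taken as the European(-like) state for the dosage matrix.
    """
    if genotypes.haplotypes is None:
        raise InvalidArgumentError("phased haplotypes are required")
    props = np.asarray(global_props, dtype=float)
    if props.shape != (genotypes.n_samples, panel.n_pops):
        raise InvalidArgumentError("global_props must be n_individuals x n_pops")
    if not np.allclose(props.sum(axis=1), 1.0, atol=1e-6):
        raise InvalidArgumentError("global proportions must sum to 1 per individual")
    if genotypes.n_variants != panel.n_variants:
        raise InvalidArgumentError("genotypes and panel describe different variants")

    n, m, k = genotypes.n_samples, panel.n_variants, panel.n_pops
    haps = genotypes.haplotypes.reshape(2 * n, m)
    pi = np.repeat(np.clip(props, 1e-12, None), 2, axis=0)
    pi = pi / pi.sum(axis=1, keepdims=True)
    freqs = np.clip(panel.allele_freqs, *FREQ_CLAMP)

    post_full = np.empty((2 * n, m, k))
    for c in np.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        gd = panel.gpos[idx]
        if not (np.diff(gd) > 0).all():
            raise InvalidArgumentError("unsorted genetic positions")
        stay = np.exp(-g * np.diff(gd))
        alle = haps[:, idx]  # (H, L)
        f = freqs[idx]  # (L, K)
        em = np.where(alle[:, :, None] == 1, f[None, :, :], 1.0 - f[None, :, :])
        em = np.where(alle[:, :, None] < 0, 1.0, em)  # missing allele: flat
        post_full[:, idx, :] = _forward_backward(em, stay, pi)

    eur = post_full[:, :, 0].reshape(n, 2, m).sum(axis=1)
    return LocalAncestryMatrix(
        samples=list(genotypes.samples),
        variant_ids=genotypes.variant_ids,
        eur_dosage=eur,
        posteriors=post_full.reshape(n, 2, m, k) if keep_posteriors else None,
        pop_labels=panel.pop_labels,
    )


# ---------------------------------------------------------------------------
# admixture mapping
# ---------------------------------------------------------------------------
@dataclass
class AdmixtureMapResult:
    """Per-locus case-control local-ancestry comparison."""

    table: pd.DataFrame  # locus, case_mean, control_mean, statistic, p, flag
    bonferroni_threshold: float
    n_perm: int
    seed: int


def admixture_map_test(
    local: LocalAncestryMatrix,
    case_status: np.ndarray,
    loci: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> AdmixtureMapResult:
    """Permutation test of mean local European ancestry, case vs control.

    Statistic per locus: difference of mean ancestry fractions
    (``eur_dosage/2``) between cases and controls; two-sided permutation p
    with the add-one correction ``(b + 1)/(n_perm + 1)``; Bonferroni
    threshold ``alpha / len(loci)``.  Deterministic given ``seed``.
    """
    if n_perm < 1000:
        raise InvalidArgumentError("n_perm must be at least 1000")
    if not loci:
        raise InvalidArgumentError("need at least one locus")
    y = np.asarray(case_status, dtype=bool)
    if len(y) != len(local.samples):
        raise InvalidArgumentError("case_status length mismatch")
    n_case = int(y.sum())
    if n_case == 0 or n_case == len(y):
        raise InvalidArgumentError("need both cases and controls")

    idx = np.array([local.locus_index(v) for v in loci])
    frac = local.eur_dosage[:, idx] / 2.0  # (n, L)
    obs = frac[y].mean(axis=0) - frac[~y].mean(axis=0)

    rng = np.random.default_rng(seed)
    n = len(y)
    exceed = np.zeros(len(loci), dtype=int)
    # difference of means as a linear functional: mean_case - mean_ctrl
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ymask = np.zeros(n, dtype=bool)
        ymask[perm[:n_case]] = True
        stat = frac[ymask].mean(axis=0) - frac[~ymask].mean(axis=0)
        exceed += np.abs(stat) >= np.abs(obs) - 1e-15
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    threshold = alpha / len(loci)
    table = pd.DataFrame(
        {
            "locus": loci,
            "case_mean_pct": 100.0 * frac[y].mean(axis=0),
            "control_mean_pct": 100.0 * frac[~y].mean(axis=0),
            "statistic": obs,
            "p": pvals,
            "significant": pvals < threshold,
        }
    )
    return AdmixtureMapResult(
        table=table, bonferroni_threshold=threshold, n_perm=n_perm, seed=seed
    )


def mean_ancestry_by_status(
    local: LocalAncestryMatrix, case_status: np.ndarray, locus: str
) -> tuple[float, float]:
    """(case mean %, control mean %) European ancestry at one locus."""
    y = np.asarray(case_status, dtype=bool)
    j = local.locus_index(locus)
    frac = local.eur_dosage[:, j] / 2.0
    if y.sum() == 0 or (~y).sum() == 0:
        raise DegenerateInputError("need both cases and controls")
    return float(100.0 * frac[y].mean()), float(100.0 * frac[~y].mean())
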