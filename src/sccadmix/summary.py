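"""Cohort description tables and worked-example arithmetic.

Prevalences, stratum cross-tabulations, Bonferroni thresholds and
significant-fraction summaries, with half-up rounding at the displayed
precision (locale independent, via :mod:`decimal`).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .data import SITE_CLASSES
from .errors import DegenerateInputError, InvalidArgumentError, ValidationError


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Half-up rounding at ``ndigits`` decimals (unlike banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def round_significant(value: float, sig: int) -> float:
    """Half-up rounding to ``sig`` significant figures."""
    if value == 0:
        return 0.0
    exponent = int(np.floor(np.log10(abs(value))))
    return round_half_up(value, sig - 1 - exponent)


def prevalence(cases: int, controls: int) -> float:
    """Percentage of cases among cases + controls, half-up to 1 decimal."""
    if cases < 0 or controls < 0:
        raise InvalidArgumentError("counts must be non-negative")
    total = cases + controls
    if total == 0:
        raise DegenerateInputError("prevalence undefined for an empty stratum")
    return round_half_up(100.0 * cases / total, 1)


def percentage(part: int, total: int) -> float:
    """Part as a half-up 1-decimal percentage of total."""
    if total == 0:
        raise DegenerateInputError("percentage undefined with zero total")
    return round_half_up(100.0 * part / total, 1)


def bonferroni_threshold(alpha: float, m: int, sig: int = 3) -> tuple[float, float]:
    """Family-wise threshold ``alpha/m``: (exact, rounded to ``sig``
    significant figures)."""
    if m < 1:
        raise InvalidArgumentError("m must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise InvalidArgumentError("alpha must lie in (0, 1)")
    exact = alpha / m
    return exact, round_significant(exact, sig)


def proportion_significant(p_values, threshold: float) -> tuple[int, float]:
    """(count, percent) of p-values strictly below ``threshold``."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("need at least one p-value")
    count = int((p < threshold).sum())
    return count, percentage(count, p.size)


@dataclass
class CohortTable:
    """Stratified case/control counts with prevalences.

    ``rows`` columns: stratum, level, cases, controls, prevalence_pct (NaN
    where a stratum is empty).  Tumour-site rows report case counts and the
    percentage of cases instead of a prevalence.
    """

    rows: pd.DataFrame

    def to_text(self) -> str:
        lines = [f"{'stratum':<16}{'level':<16}{'cases':>8}{'controls':>10}{'%':>8}"]
        for _, r in self.rows.iterrows():
            pct = "" if pd.isna(r["prevalence_pct"]) else f"{r['prevalence_pct']:.1f}"
            lines.append(
                f"{r['stratum']:<16}{str(r['level']):<16}{int(r['cases']):>8}"
                f"{int(r['controls']):>10}{pct:>8}"
            )
        return "\n".join(lines)


def cohort_table(
    phenotypes: pd.DataFrame,
    outcome: str = "cscc",
    strata: tuple[str, ...] = ("sex", "group", "ak"),
) -> CohortTable:
    """Cross-tabulate cases and controls by stratum.

    Rows: overall; each level of the requested stratum columns; AK reported
    as case/control counts of AK-positive individuals with the percentage of
    cases that have AK; tumour-site rows give case counts with the
    percentage of all cases.
    """
    if outcome not in phenotypes.columns:
        raise ValidationError(f"phenotype table lacks outcome column {outcome!r}")
    y = phenotypes[outcome].astype(int)
    rows = []

    def add(stratum, level, cases, controls, pct):
        rows.append(
            {
                "stratum": stratum,
                "level": level,
                "cases": int(cases),
                "controls": int(controls),
                "prevalence_pct": pct,
            }
        )

    n_cases, n_controls = int((y == 1).sum()), int((y == 0).sum())
    add("overall", "all", n_cases, n_controls, prevalence(n_cases, n_controls))

    for col in strata:
        if col not in phenotypes.columns:
            raise ValidationError(f"phenotype table lacks stratum column {col!r}")
        for level, sub in phenotypes.groupby(col, sort=True):
            c = int((sub[outcome] == 1).sum())
            k = int((sub[outcome] == 0).sum())
            pct = np.nan if c + k == 0 else prevalence(c, k)
            add(col, level, c, k, pct)

    if "ak" in strata and n_cases > 0:
        ak_cases = int(((y == 1) & (phenotypes["ak"] == 1)).sum())
        add("ak_among_cases", "yes", ak_cases, 0, percentage(ak_cases, n_cases))

    if "site_class" in phenotypes.columns:
        case_rows = phenotypes[y == 1]
        for site in SITE_CLASSES:
            c = int((case_rows["site_class"] == site).sum())
            pct = np.nan if n_cases == 0 else percentage(c, n_cases)
            add("site_class", site, c, 0, pct)

    table = CohortTable(rows=pd.DataFrame(rows))
    # reconciliation: stratum case counts must sum back to the overall count
    for col in strata:
        sub = table.rows[table.rows["stratum"] == col]
        if int(sub["cases"].sum()) != n_cases or int(sub["controls"].sum()) != n_controls:
            raise ValidationError(f"stratum {col!r} does not reconcile with totals")
    return table
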