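"""GO-term enrichment among differentially expressed genes.

Each term with at least one DE gene is tested with Fisher's exact test on
the 2×2 table (DE × has-term) against the measured background, ranked by
ascending p-value within its ontology category. A Cochran–Mantel–Haenszel
test over category strata is available as an advisory pre-check of the
term/DE-status association; it is logged and reported, never used to drop
terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStratumError, EmptyInputError, ValidationError
from .formats_io import GO_CATEGORIES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a = DE with term, b = DE without, c = background with, d = background without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("negative contingency cell")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def build_contingency(
    de_genes: set[str], background: set[str], term_genes: set[str]
) -> ContingencyTable2x2:
    """2×2 table of DE status × term membership.

    The non-DE background is ``background - de_genes``, so the four cells
    partition the measured universe.
    """
    if not de_genes:
        raise EmptyInputError("empty DE gene set")
    bg = set(background) - set(de_genes)
    de = set(de_genes)
    term = set(term_genes)
    return ContingencyTable2x2(
        a=len(de & term), b=len(de - term), c=len(bg & term), d=len(bg - term)
    )


def fisher_exact(
    table: ContingencyTable2x2, alternative: str = "two-sided"
) -> float:
    """Exact hypergeometric p-value for a 2×2 table with fixed margins.

    Two-sided: the sum of probabilities of all tables with the observed
    margins whose point probability is at most that of the observed table,
    with a 1+1e-7 relative tolerance on the comparison (the convention of
    the standard R implementation). "greater" tests enrichment of a.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, c1, n = a + b, a + c, table.n
    if n == 0:
        return 1.0
    dist = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    if alternative == "two-sided":
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(p, 1.0)


@dataclass
class StratifiedTables:
    """K >= 1 2×2 strata with labels, for the CMH test."""

    tables: Sequence[ContingencyTable2x2]
    labels: Sequence[str] = ()

    def __post_init__(self) -> None:
        if len(self.tables) < 1:
            raise ValidationError("need at least one stratum")
        if not self.labels:
            self.labels = [f"stratum{i + 1}" for i in range(len(self.tables))]


def cmh_test(
    strata: StratifiedTables, continuity_correction: bool = True
) -> tuple[float, float]:
    """Cochran–Mantel–Haenszel chi-square test over stratified 2×2 tables.

    χ² = (|Σ(a−E)| − ½·[correction])² / ΣV with E = r₁c₁/n and
    V = r₁r₂c₁c₂ / (n²(n−1)) per stratum; p from χ²₁.
    """
    num = 0.0
    var = 0.0
    for t in strata.tables:
        n = t.n
        if n <= 1:
            raise DegenerateStratumError(f"stratum with n={n}")
        r1, r2 = t.a + t.b, t.c + t.d
        c1, c2 = t.a + t.c, t.b + t.d
        num += t.a - r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
    if var == 0:
        return 0.0, 1.0
    dev = abs(num) - (0.5 if continuity_correction else 0.0)
    statistic = dev**2 / var
    p_value = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p_value


@dataclass
class EnrichmentReport:
    """Per-category ranked enrichment tables plus the advisory CMH check."""

    results: dict[str, pd.DataFrame]
    cmh_statistic: float | None = None
    cmh_p_value: float | None = None


def rank_terms(
    de_genes: set[str],
    background: set[str],
    assignments: pd.DataFrame,
    gate: bool = True,
    alternative: str = "two-sided",
    top_n: int | None = None,
) -> EnrichmentReport:
    """Rank GO terms by Fisher's exact test p-value, per ontology category.

    ``assignments`` has columns gene, term, category. Terms without any DE
    gene are not tested. Within a category, results are sorted by ascending
    p-value (ties broken by term id) with consecutive ranks from 1. When
    ``gate`` is set, a CMH test of annotation status × DE status stratified
    by category is computed and logged alongside the results.
    """
    if len(assignments) == 0:
        raise EmptyInputError("no GO assignments supplied")
    de = set(de_genes)
    universe = set(background) | de
    results: dict[str, pd.DataFrame] = {}
    any_overlap = False
    for category in GO_CATEGORIES:
        sub = assignments[assignments["category"] == category]
        if len(sub) == 0:
            continue
        rows = []
        for term, genes in sorted(sub.groupby("term")["gene"].apply(set).items()):
            genes = genes & universe
            n_de_with_term = len(genes & de)
            if n_de_with_term == 0:
                continue
            any_overlap = True
            table = build_contingency(de, universe, genes)
            rows.append(
                {
                    "term": term,
                    "category": category,
                    "n_de_genes": n_de_with_term,
                    "p_value": fisher_exact(table, alternative=alternative),
                }
            )
        df = pd.DataFrame(rows, columns=["term", "category", "n_de_genes", "p_value"])
        if len(df):
            df = df.sort_values(["p_value", "term"]).reset_index(drop=True)
            df["rank"] = np.arange(1, len(df) + 1)
            if top_n is not None:
                df = df.head(top_n)
        results[category] = df
    if not any_overlap:
        logger.warning("no GO term overlaps any DE gene; empty enrichment output")
    report = EnrichmentReport(results=results)
    if gate:
        strata = _category_strata(de, universe, assignments)
        if strata is not None:
            stat, p = cmh_test(strata)
            report.cmh_statistic, report.cmh_p_value = stat, p
            logger.info(
                "CMH pre-check (annotation x DE status, stratified by category): "
                "statistic=%.4f p=%.4g", stat, p,
            )
    return report


def _category_strata(
    de: set[str], universe: set[str], assignments: pd.DataFrame
) -> StratifiedTables | None:
    """Per-category 2×2 tables of (annotated in category) × (DE status)."""
    tables, labels = [], []
    for category in GO_CATEGORIES:
        annotated = set(
            assignments.loc[assignments["category"] == category, "gene"]
        ) & universe
        t = build_contingency(de, universe, annotated)
        # skip strata with a zero margin: they contribute no variance
        if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0 or t.n <= 1:
            continue
        tables.append(t)
        labels.append(category)
    if not tables:
        return None
    return StratifiedTables(tables=tables, labels=labels)
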