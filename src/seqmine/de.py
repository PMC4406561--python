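"""Consensus differential-expression calling.

Per-method gene lists are thresholded on p- or q-values (Benjamini–Hochberg
adjusted), then voted into a consensus list of genes supported by at least
``min_support`` methods (default 3). A pooled exact binomial test is
provided as plumbing so the pipeline can run without external DE tables,
and a data-suitability check guards methods that assume most genes are
similarly expressed across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CountMatrix
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    SchemaError,
    ValidationError,
)


@dataclass
class DEResult:
    """One method's differential-expression table (gene, pvalue[, qvalue, log2fc])."""

    method_label: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("pvalue", "qvalue"):
            if col in self.table.columns:
                vals = self.table[col].dropna().to_numpy(dtype=float)
                if ((vals < 0) | (vals > 1)).any():
                    raise ValidationError(
                        f"{self.method_label}: {col} outside [0, 1]"
                    )


@dataclass
class ConsensusList:
    """Voted consensus membership with per-gene support counts."""

    table: pd.DataFrame  # columns: gene, support, methods
    min_support: int
    criterion: str
    threshold: float

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene"])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j with p_(j) >= p_(i) of p_(j)·n/rank(j), clipped to 1
    and mapped back to input order. Output is >= the input elementwise and
    preserves its ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_de(
    result: DEResult, criterion: str = "p_value", threshold: float = 0.05
) -> set[str]:
    """Genes whose p- (or q-) value is at or below the cut-off (inclusive)."""
    if not 0 < threshold <= 1:
        raise ConfigurationError("threshold must be in (0, 1]")
    col = {"p_value": "pvalue", "q_value": "qvalue"}.get(criterion)
    if col is None:
        raise ConfigurationError(f"unknown criterion {criterion!r}")
    table = result.table
    if col not in table.columns or table[col].isna().all():
        if col == "qvalue" and "pvalue" in table.columns:
            table = table.assign(qvalue=bh_adjust(table["pvalue"].to_numpy()))
        else:
            raise SchemaError(
                f"{result.method_label}: no {col} column and nothing to adjust"
            )
    mask = table[col].astype(float) <= threshold
    return set(table.loc[mask, "gene"].astype(str))


def consensus_vote(
    lists: Mapping[str, set[str]], min_support: int = 3
) -> ConsensusList:
    """Vote a consensus list: genes present in >= ``min_support`` method lists.

    With min_support equal to the number of lists this is the set
    intersection; with 1 it is the union. Output is sorted by support
    (descending) then gene id.
    """
    if min_support < 1:
        raise ConfigurationError("min_support must be >= 1")
    if len(lists) < min_support:
        raise ConfigurationError(
            f"min_support={min_support} but only {len(lists)} lists supplied"
        )
    support: dict[str, list[str]] = {}
    for label in sorted(lists):
        for gene in lists[label]:
            support.setdefault(gene, []).append(label)
    rows = [
        {"gene": g, "support": len(methods), "methods": ",".join(sorted(methods))}
        for g, methods in support.items()
        if len(methods) >= min_support
    ]
    table = pd.DataFrame(rows, columns=["gene", "support", "methods"])
    if len(table):
        table = table.sort_values(
            ["support", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return ConsensusList(
        table=table, min_support=min_support, criterion="vote", threshold=np.nan
    )


def check_similar_expression_assumption(
    counts: CountMatrix,
    condition_a: Sequence[str],
    condition_b: Sequence[str],
    fc_threshold: float = 2.0,
    max_fraction: float = 0.5,
) -> tuple[bool, dict]:
    """Check that most genes are similarly expressed between two conditions.

    Computes per-gene |log2 ratio| of depth-normalized condition means
    (pseudo-count 1 on raw counts); the check passes iff the fraction of
    genes with |log2 ratio| > ``fc_threshold`` is strictly below
    ``max_fraction``. Methods whose normalization assumes comparable
    expression across the majority of genes should be skipped when this
    fails.
    """
    for cols in (condition_a, condition_b):
        if len(cols) == 0:
            raise DegenerateInputError("condition with no replicates")
        if (counts.counts[list(cols)].to_numpy().sum()) == 0:
            raise DegenerateInputError("all-zero condition")

    def _norm_mean(cols: Sequence[str]) -> pd.Series:
        libs = counts.library_size[list(cols)].astype(float)
        return (counts.counts[list(cols)].astype(float) + 1.0).div(libs, axis=1).mean(axis=1)

    ratio = np.log2(_norm_mean(condition_a) / _norm_mean(condition_b))
    frac = float((ratio.abs() > fc_threshold).mean())
    passes = frac < max_fraction
    diagnostics = {
        "fraction_high_fc": frac,
        "median_abs_log2_ratio": float(ratio.abs().median()),
        "fc_threshold": fc_threshold,
        "max_fraction": max_fraction,
    }
    return passes, diagnostics


def builtin_de_test(
    counts: CountMatrix,
    condition_a: Sequence[str],
    condition_b: Sequence[str],
    method_label: str = "builtin-binomial",
) -> DEResult:
    """Pooled two-library exact binomial test (pipeline plumbing).

    Counts and library sizes are summed within each condition. For a gene
    with x₁ of library N₁ and x₂ of N₂, the p-value is the two-sided exact
    binomial test of x₁ successes in x₁+x₂ trials with success probability
    N₁/(N₁+N₂). Genes with x₁+x₂=0 get p=1 and a flag. BH q-values are
    attached. This is a Poisson-sampling approximation: it does not model
    biological overdispersion across replicates.
    """
    x1 = counts.counts[list(condition_a)].sum(axis=1).astype(int)
    x2 = counts.counts[list(condition_b)].sum(axis=1).astype(int)
    n1 = float(counts.library_size[list(condition_a)].sum())
    n2 = float(counts.library_size[list(condition_b)].sum())
    if n1 <= 0 or n2 <= 0:
        raise DegenerateInputError("zero pooled library size")
    prob = n1 / (n1 + n2)
    pvals = np.ones(len(x1))
    flagged = np.zeros(len(x1), dtype=bool)
    for i, (a, b) in enumerate(zip(x1.to_numpy(), x2.to_numpy())):
        total = a + b
        if total == 0:
            flagged[i] = True
            continue
        pvals[i] = stats.binomtest(int(a), n=int(total), p=prob).pvalue
    lfc = np.log2(((x1 + 0.5) / n1) / ((x2 + 0.5) / n2))
    table = pd.DataFrame(
        {
            "gene": counts.counts.index.astype(str),
            "pvalue": pvals,
            "qvalue": bh_adjust(pvals),
            "log2fc": lfc.to_numpy(),
            "flagged": flagged,
        }
    ).reset_index(drop=True)
    return DEResult(method_label=method_label, table=table)
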