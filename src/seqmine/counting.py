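"""Unique-mapper filtering, mapping statistics, and expression quantification.

Reads are partitioned into uniquely mapped, multi-mapped, unmapped, and
filtered (QC flag or below a mapping-quality threshold); only uniquely
mapped reads are counted toward gene expression. Gene counts are turned
into depth-normalized values and RPKM (reads per kilobase of exon model
per million mapped reads).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    EmptyAnnotationError,
    EmptyInputError,
    GroupingError,
    ValidationError,
)
from .formats_io import AlignmentRecord, AnnotationIndex

IsoformRule = Literal["total_to_each_isoform", "discard_ambiguous", "proportional"]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching the published tables' formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MappingStats:
    """Per-sample read classification tallies.

    Invariant: ``n_reads = n_unique + n_multi + n_failed + n_filtered``;
    the mapped percentage is ``100·(n_unique+n_multi)/n_reads`` rounded
    half-up to two decimals.
    """

    sample_id: str
    n_reads: int
    n_unique: int
    n_multi: int
    n_failed: int
    n_filtered: int

    def __post_init__(self) -> None:
        parts = (self.n_unique, self.n_multi, self.n_failed, self.n_filtered)
        if any(v < 0 for v in parts) or self.n_reads < 0:
            raise ValidationError("negative tally")
        if sum(parts) != self.n_reads:
            raise ValidationError(
                f"{self.sample_id}: tallies {parts} do not sum to n_reads={self.n_reads}"
            )

    @property
    def pct_mapped(self) -> float:
        if self.n_reads == 0:
            return 0.0
        frac = Decimal(100) * Decimal(self.n_unique + self.n_multi) / Decimal(self.n_reads)
        return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    def as_row(self) -> dict:
        """One row in the published mapping-statistics column order."""
        return {
            "sample": self.sample_id,
            "n_reads": self.n_reads,
            "n_unique": self.n_unique,
            "n_multi": self.n_multi,
            "n_failed": self.n_failed,
            "n_filtered": self.n_filtered,
            "pct_mapped": self.pct_mapped,
        }


def load_reference_mapping_stats() -> pd.DataFrame:
    """Published mapping-statistics tallies for six bulk RNA-seq datasets.

    Used to validate the percentage arithmetic and the conservation
    identity against independently printed values.
    """
    ref = importlib.resources.files("seqmine.data") / "mapping_stats_reference.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def classify_and_summarize(
    alignments: Iterable[AlignmentRecord],
    sample_id: str,
    mapq_threshold: int = 0,
) -> tuple[list[AlignmentRecord], MappingStats]:
    """Partition reads by mapping multiplicity and emit only unique mappers.

    A read is *filtered* if any of its records is QC-failed or its best
    mapping quality falls below ``mapq_threshold``; *failed* if unmapped;
    *multi* if it has >1 reported placement; *unique* otherwise. Only the
    unique reads' single placements are returned for counting.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        by_read.setdefault(rec.read_id, []).append(rec)
    if not by_read:
        raise EmptyInputError("no alignment records supplied")

    unique: list[AlignmentRecord] = []
    n_unique = n_multi = n_failed = n_filtered = 0
    for read_id in sorted(by_read):
        recs = by_read[read_id]
        mapped = [r for r in recs if r.mapped]
        if any(r.qc_fail for r in recs) or (
            mapped and max(r.mapping_quality for r in mapped) < mapq_threshold
        ):
            n_filtered += 1
        elif not mapped:
            n_failed += 1
        elif max(r.hit_count for r in mapped) > 1 or len(mapped) > 1:
            n_multi += 1
        else:
            n_unique += 1
            unique.append(mapped[0])
    stats = MappingStats(
        sample_id=sample_id,
        n_reads=len(by_read),
        n_unique=n_unique,
        n_multi=n_multi,
        n_failed=n_failed,
        n_filtered=n_filtered,
    )
    return unique, stats


@dataclass
class GeneCounts:
    """Counts for one sample: per-gene, per-transcript, and discard tallies."""

    sample_id: str
    gene_counts: pd.Series
    transcript_counts: pd.Series
    n_ambiguous_gene: int = 0
    n_no_feature: int = 0
    library_size: int = 0


def count_genes(
    unique_alignments: Sequence[AlignmentRecord],
    annotation: AnnotationIndex,
    rule: IsoformRule = "total_to_each_isoform",
    sample_id: str = "sample",
) -> GeneCounts:
    """Count uniquely mapped reads per gene and per isoform.

    A read overlapping exons of exactly one gene adds 1 to that gene.
    Reads touching exons of more than one gene are discarded from all
    counts and tallied as ambiguous. At the transcript level a read
    compatible with n isoforms adds 1 to each (``total_to_each_isoform``),
    is dropped when n > 1 (``discard_ambiguous``), or adds 1/n to each
    (``proportional``). Gene-level counts are identical across rules.
    """
    if len(annotation) == 0:
        raise EmptyAnnotationError("annotation contains no genes")
    gene_ids = annotation.gene_ids()
    tx_index = [
        (g, t)
        for g in gene_ids
        for t in sorted(annotation.genes[g].transcripts)
    ]
    gene_counts = pd.Series(0, index=pd.Index(gene_ids, name="gene"), dtype=float)
    tx_counts = pd.Series(
        0.0, index=pd.MultiIndex.from_tuples(tx_index, names=["gene", "transcript"])
    )
    n_ambiguous = n_no_feature = 0
    for rec in unique_alignments:
        hits = annotation.overlapping(rec.reference or "", rec.start, rec.end)
        if not hits:
            n_no_feature += 1
            continue
        genes_hit = sorted({g for g, _ in hits})
        if len(genes_hit) > 1:
            n_ambiguous += 1
            continue
        gene = genes_hit[0]
        gene_counts[gene] += 1
        isoforms = sorted({t for g, t in hits})
        if rule == "total_to_each_isoform":
            for t in isoforms:
                tx_counts[(gene, t)] += 1
        elif rule == "discard_ambiguous":
            if len(isoforms) == 1:
                tx_counts[(gene, isoforms[0])] += 1
        elif rule == "proportional":
            share = 1.0 / len(isoforms)
            for t in isoforms:
                tx_counts[(gene, t)] += share
        else:  # pragma: no cover - guarded by type
            raise ValueError(f"unknown rule {rule!r}")
    return GeneCounts(
        sample_id=sample_id,
        gene_counts=gene_counts.astype(int),
        transcript_counts=tx_counts,
        n_ambiguous_gene=n_ambiguous,
        n_no_feature=n_no_feature,
        library_size=len(unique_alignments),
    )


@dataclass
class CountMatrix:
    """Raw read counts, genes × sample/replicate columns.

    ``library_size`` holds the number of uniquely mapped reads per column
    (the depth denominator); it is at least the column sum of assigned
    counts because ambiguous and intergenic reads stay in the library.
    """

    counts: pd.DataFrame
    library_size: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts")
        missing = [c for c in self.counts.columns if c not in self.library_size.index]
        if missing:
            raise ValidationError(f"no library size for column(s) {missing}")

    @classmethod
    def from_gene_counts(cls, per_sample: Sequence[GeneCounts]) -> "CountMatrix":
        cols = {gc.sample_id: gc.gene_counts for gc in per_sample}
        libs = pd.Series({gc.sample_id: gc.library_size for gc in per_sample})
        return cls(counts=pd.DataFrame(cols), library_size=libs)


@dataclass
class ExpressionMatrix:
    """Real-valued expression, same axes as the count matrix it came from."""

    values: pd.DataFrame
    units: Literal["depth_normalized", "rpkm"]


def compute_rpkm(counts: CountMatrix, annotation: AnnotationIndex) -> ExpressionMatrix:
    """RPKM per gene and column: count · 10⁹ / (union exon length · library size)."""
    if (counts.library_size[counts.counts.columns] <= 0).any():
        raise DegenerateInputError("zero library size")
    lengths = pd.Series(
        {g: annotation.genes[g].union_exon_length for g in counts.counts.index}
    )
    if (lengths <= 0).any():
        raise DegenerateInputError("gene with zero exon-model length")
    libs = counts.library_size[counts.counts.columns].astype(float)
    vals = counts.counts.astype(float).mul(1e9).div(lengths, axis=0).div(libs, axis=1)
    return ExpressionMatrix(values=vals, units="rpkm")


def normalize_and_average(
    counts: CountMatrix, replicate_groups: Mapping[str, Sequence[str]]
) -> ExpressionMatrix:
    """Depth-normalize each replicate, then average replicates per sample.

    The per-replicate value is count divided by the number of uniquely
    mapped reads in that replicate; the per-sample value is the arithmetic
    mean of its replicates.
    """
    out = {}
    for sample, reps in replicate_groups.items():
        if len(reps) == 0:
            raise GroupingError(f"sample {sample!r} has no replicates")
        missing = [r for r in reps if r not in counts.counts.columns]
        if missing:
            raise GroupingError(f"sample {sample!r}: unknown replicate(s) {missing}")
        libs = counts.library_size[list(reps)].astype(float)
        if (libs <= 0).any():
            raise DegenerateInputError(f"sample {sample!r}: zero library size")
        norm = counts.counts[list(reps)].astype(float).div(libs, axis=1)
        out[sample] = norm.mean(axis=1)
    return ExpressionMatrix(values=pd.DataFrame(out), units="depth_normalized")


def mapping_stats_frame(stats: Iterable[MappingStats]) -> pd.DataFrame:
    """Mapping statistics in the published column order, one row per sample."""
    return pd.DataFrame([s.as_row() for s in stats])
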