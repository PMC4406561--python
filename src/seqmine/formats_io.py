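"""Readers and writers for the external formats the pipeline touches.

SAM alignments, GTF/GFF exon annotations, TSV result tables (differential
expression, GO assignments), plain-text transcription-factor lists, and
regulatory-network edge lists. All genomic intervals are stored 0-based
half-open internally; SAM and GTF keep their native 1-based conventions at
the file boundary, which is the single conversion point.
"""

from __future__ import annotations

import os
import re
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .errors import (
    EmptyAnnotationError,
    FormatError,
    SchemaError,
    ValidationError,
)

GO_CATEGORIES = ("biological_process", "molecular_function", "cellular_component")

# CIGAR ops that consume the reference
_REF_CONSUMING = set("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class AlignmentRecord:
    """One reported placement of a read.

    ``start``/``end`` are 0-based half-open; unmapped records carry no
    coordinates (``reference`` is None). ``hit_count`` is the number of
    reported placements of the read across the whole file.
    """

    read_id: str
    reference: str | None
    start: int
    end: int
    mapped: bool
    mapping_quality: int
    hit_count: int = 1
    qc_fail: bool = False

    def __post_init__(self) -> None:
        if self.mapped and self.end <= self.start:
            raise ValidationError(
                f"read {self.read_id}: empty interval [{self.start},{self.end})"
            )
        if self.hit_count < 1:
            raise ValidationError(f"read {self.read_id}: hit_count < 1")


@dataclass
class GeneModel:
    """A gene with its transcripts as ordered exon interval lists (0-based half-open)."""

    gene_id: str
    strand: str = "."
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    reference: str | None = None

    @property
    def union_exon_length(self) -> int:
        """Length of the union of all exon intervals across transcripts.

        This is the "exon model" length used as the RPKM denominator.
        """
        return _union_length(
            [iv for exons in self.transcripts.values() for iv in exons]
        )

    def transcript_length(self, transcript_id: str) -> int:
        return _union_length(self.transcripts[transcript_id])


@dataclass(frozen=True)
class GoAssignment:
    gene_id: str
    term_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in GO_CATEGORIES:
            raise ValidationError(
                f"unknown GO category {self.category!r}; expected one of {GO_CATEGORIES}"
            )


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    ivs = sorted(intervals)
    total = 0
    cur_start: int | None = None
    cur_end = 0
    for s, e in ivs:
        if cur_start is None or s > cur_end:
            if cur_start is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_start is not None:
        total += cur_end - cur_start
    return total


class AnnotationIndex:
    """Exon interval index over a set of :class:`GeneModel`.

    Maps (reference, interval) queries to the overlapping exons with their
    owning (gene, transcript) pair. Queries are deterministic: results are
    returned sorted.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for gene in self.genes.values():
            tree = self._trees.setdefault(gene.reference or "", IntervalTree())
            for tid, exons in gene.transcripts.items():
                for s, e in exons:
                    tree.addi(s, e, (gene.gene_id, tid))

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def overlapping(self, reference: str, start: int, end: int) -> list[tuple[str, str]]:
        """(gene_id, transcript_id) pairs whose exons overlap [start, end)."""
        tree = self._trees.get(reference)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})


# ---------------------------------------------------------------------------
# SAM


def _cigar_reference_span(cigar: str, read_id: str, lineno: int) -> int:
    if cigar == "*":
        return 0
    span = 0
    consumed = 0
    for m in _CIGAR_RE.finditer(cigar):
        consumed += m.end() - m.start()
        if m.group(2) in _REF_CONSUMING:
            span += int(m.group(1))
    if consumed != len(cigar):
        raise FormatError(f"line {lineno}: bad CIGAR {cigar!r} for read {read_id}")
    return span


def read_sam(path: str | os.PathLike) -> list[AlignmentRecord]:
    """Parse a SAM text file into alignment records.

    The header is optional. Flag 0x4 marks a record unmapped, 0x200 marks it
    QC-failed. ``hit_count`` comes from the NH tag when present; for reads
    without NH it is inferred from the number of mapped alignment lines the
    read has in the file (so the result is independent of line order).
    """
    references: set[str] = set()
    have_header = False
    records: list[AlignmentRecord] = []
    nh_seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    have_header = True
                    for f in line.split("\t")[1:]:
                        if f.startswith("SN:"):
                            references.add(f[3:])
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(
                    f"line {lineno}: expected 11 mandatory SAM columns, got {len(fields)}"
                )
            qname, flag_s, rname, pos_s, mapq_s = fields[:5]
            cigar = fields[5]
            try:
                flag = int(flag_s)
                pos = int(pos_s)
                mapq = int(mapq_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer field ({exc})") from None
            mapped = not (flag & 0x4)
            qc_fail = bool(flag & 0x200)
            if mapped:
                if have_header and rname not in references:
                    raise ValidationError(
                        f"line {lineno}: unknown reference sequence {rname!r}"
                    )
                start = pos - 1  # SAM is 1-based
                span = _cigar_reference_span(cigar, qname, lineno) or 1
                end = start + span
                reference: str | None = rname
            else:
                reference, start, end = None, 0, 0
            nh = None
            for tag in fields[11:]:
                if tag.startswith("NH:i:"):
                    nh = int(tag[5:])
                    break
            if nh is not None:
                nh_seen[qname] = nh
            records.append(
                AlignmentRecord(
                    read_id=qname,
                    reference=reference,
                    start=start,
                    end=end if mapped else 0,
                    mapped=mapped,
                    mapping_quality=mapq,
                    hit_count=1,
                    qc_fail=qc_fail,
                )
            )
    # resolve hit counts: NH tag wins, otherwise mapped-line multiplicity
    multiplicity = Counter(r.read_id for r in records if r.mapped)
    for rec in records:
        if rec.read_id in nh_seen:
            rec.hit_count = nh_seen[rec.read_id]
        else:
            rec.hit_count = max(1, multiplicity.get(rec.read_id, 0))
    return records


def write_sam(
    records: Sequence[AlignmentRecord],
    path: str | os.PathLike,
    reference_lengths: dict[str, int] | None = None,
) -> None:
    """Write records back to SAM (coordinates converted to 1-based)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        if reference_lengths:
            for name, length in sorted(reference_lengths.items()):
                fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in records:
            flag = (0 if rec.mapped else 0x4) | (0x200 if rec.qc_fail else 0)
            if rec.mapped:
                rname = rec.reference
                pos = rec.start + 1
                cigar = f"{rec.end - rec.start}M"
            else:
                rname, pos, cigar = "*", 0, "*"
            fields = [
                rec.read_id, str(flag), str(rname), str(pos),
                str(rec.mapping_quality), cigar, "*", "0", "0", "*", "*",
                f"NH:i:{rec.hit_count}",
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GTF / GFF


def read_gtf(
    path: str | os.PathLike, feature_type: str = "exon"
) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from a GTF/GFF file.

    Only features of ``feature_type`` are used (matched case-insensitively,
    since annotation sources disagree on "exon" vs "Exon"); everything else
    is ignored. GTF 1-based inclusive coordinates are converted to 0-based
    half-open.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    wanted = feature_type.lower()
    n_features = 0
    for feat in db.all_features():
        if feat.featuretype.lower() != wanted:
            continue
        n_features += 1
        try:
            gene_id = feat.attributes["gene_id"][0]
        except KeyError:
            raise ValidationError(
                f"{feature_type} feature at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks a gene_id attribute"
            ) from None
        tid = feat.attributes.get("transcript_id", [gene_id])[0]
        gene = genes.setdefault(
            gene_id, GeneModel(gene_id=gene_id, strand=feat.strand or ".",
                               reference=feat.seqid)
        )
        gene.transcripts.setdefault(tid, []).append((feat.start - 1, feat.end))
    if not genes:
        raise EmptyAnnotationError(
            f"no {feature_type!r} features with gene models parsed from {path}"
        )
    for gene in genes.values():
        for exons in gene.transcripts.values():
            exons.sort()
    return AnnotationIndex(genes.values())


def write_gtf(index: AnnotationIndex, path: str | os.PathLike) -> None:
    """Write the exon features of an index back to GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene_id in index.gene_ids():
            gene = index.genes[gene_id]
            for tid in sorted(gene.transcripts):
                for s, e in gene.transcripts[tid]:
                    attrs = f'gene_id "{gene_id}"; transcript_id "{tid}";'
                    fh.write(
                        "\t".join(
                            [
                                gene.reference or "chr1", "seqmine", "exon",
                                str(s + 1), str(e), ".", gene.strand, ".", attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# TSV tables

DE_SCHEMA = {"required": ["gene", "pvalue"], "optional": ["qvalue", "log2fc"]}
GO_SCHEMA = {"required": ["gene", "term", "category"], "optional": []}


def read_table(path: str | os.PathLike, schema: dict) -> pd.DataFrame:
    """Read a headered TSV and enforce a column schema.

    Extra columns are preserved as opaque strings.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return df


def read_de_table(path: str | os.PathLike, method_label: str | None = None):
    """Read a differential-expression result table into a DEResult."""
    from .de import DEResult  # local import to avoid a cycle

    df = read_table(path, DE_SCHEMA)
    label = method_label or os.path.splitext(os.path.basename(str(path)))[0]
    return DEResult(method_label=label, table=df)


def read_go_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene→GO-term assignments; validates the three GO namespaces."""
    df = read_table(path, GO_SCHEMA)
    bad = set(df["category"]) - set(GO_CATEGORIES)
    if bad:
        raise ValidationError(f"{path}: unknown GO categories: {sorted(bad)}")
    return df


def read_tf_list(path: str | os.PathLike) -> list[str]:
    """Read a transcription-factor gene list, one id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# Edge lists

EDGE_COLUMNS = ["tf_id", "gene_id", "module_id"]


def write_edge_list(network, path: str | os.PathLike) -> None:
    """Write a regulatory network as a TSV edge list.

    Rows are sorted (module asc, tf asc, gene asc) so output is
    deterministic and round-trips losslessly.
    """
    rows = sorted(network.edges, key=lambda e: (e[2], e[0], e[1]))
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for tf, gene, module in rows:
            fh.write(f"{tf}\t{gene}\t{module}\n")


def read_edge_list(path: str | os.PathLike) -> set[tuple[str, str, int]]:
    df = read_table(path, {"required": EDGE_COLUMNS, "optional": []})
    return {
        (str(r.tf_id), str(r.gene_id), int(r.module_id))
        for r in df.itertuples()
    }
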