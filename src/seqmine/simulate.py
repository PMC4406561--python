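"""Seeded generators for every toy input the pipeline consumes.

Annotations with shared-exon isoforms, SAM alignments with exact
classification tallies, negative-binomial count matrices with planted
differential expression, GO assignments with a planted enriched term, and
expression matrices with planted regulatory modules. Every generator is a
pure function of its spec: the same seed yields identical bytes, and
ground truth is returned alongside the data so tests never peek at
generator internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import CountMatrix
from .formats_io import (
    AlignmentRecord,
    AnnotationIndex,
    GeneModel,
    GO_CATEGORIES,
    write_gtf,
    write_sam,
)
from .gnet import RegulatoryTree, TreeNode

READ_LENGTH = 50


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study.

    Rates are exact partitions of ``n_reads`` (category tallies are
    deterministic, not sampled). Negative-binomial counts use the
    mean/dispersion parameterization with variance mu + phi·mu²; the
    default dispersion is near-Poisson, matching the sampling model of
    the built-in pooled binomial test the count fixtures exercise.
    """

    seed: int = 0
    n_genes: int = 40
    n_isoform_genes: int = 5
    n_reads: int = 1000
    multi_rate: float = 0.1
    unmapped_rate: float = 0.05
    qcfail_rate: float = 0.01
    n_conditions: int = 2
    replicates: int = 3
    de_fraction: float = 0.3
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.001
    enrichment_odds: float = 20.0
    n_decoy_terms: int = 12
    n_modules: int = 2
    tf_per_module: int = 1
    noise_sd: float = 0.5
    leaf_separation: float = 3.0

    def __post_init__(self) -> None:
        if self.multi_rate + self.unmapped_rate + self.qcfail_rate > 1:
            raise ValueError("rates sum above 1")


# ---------------------------------------------------------------------------
# annotation

_GENE_SPAN = 2500
_EXON = 300


def gen_annotation(
    spec: FixtureSpec, out_path: str | Path | None = None
) -> tuple[AnnotationIndex, dict]:
    """Toy genome annotation: ``n_genes`` genes on 1–2 chromosomes.

    Every gene has a two-exon transcript; the first ``n_isoform_genes``
    genes carry a second isoform sharing exon 1 and adding a third exon,
    to exercise the isoform counting rules.
    """
    genes = []
    truth_lengths = {}
    per_chrom = 38  # keeps each chromosome under 100 kb
    for i in range(spec.n_genes):
        gid = f"G{i + 1:04d}"
        chrom = f"chr{i // per_chrom + 1}"
        g0 = (i % per_chrom) * _GENE_SPAN
        exon1 = (g0, g0 + _EXON)
        exon2 = (g0 + 600, g0 + 600 + _EXON)
        transcripts = {f"{gid}.t1": [exon1, exon2]}
        if i < spec.n_isoform_genes:
            exon3 = (g0 + 1200, g0 + 1200 + _EXON)
            transcripts[f"{gid}.t2"] = [exon1, exon3]
        genes.append(
            GeneModel(gene_id=gid, strand="+", transcripts=transcripts, reference=chrom)
        )
        truth_lengths[gid] = _EXON * len(
            {iv for exons in transcripts.values() for iv in exons}
        )
    index = AnnotationIndex(genes)
    if out_path is not None:
        write_gtf(index, out_path)
    truth = {"union_exon_length": truth_lengths, "shared_exon_genes": [
        f"G{i + 1:04d}" for i in range(spec.n_isoform_genes)
    ]}
    return index, truth


# ---------------------------------------------------------------------------
# alignments


def gen_alignments(
    spec: FixtureSpec,
    annotation: AnnotationIndex,
    per_gene_counts: pd.Series | None = None,
    sample_id: str = "sample",
    out_path: str | Path | None = None,
) -> tuple[list[AlignmentRecord], dict]:
    """SAM alignments with exact, deterministic category tallies.

    Uniquely mapped reads are placed inside exons with known per-gene
    counts (uniform over genes unless ``per_gene_counts`` is given);
    multi-mappers appear as two placements with NH:i:2; unmapped and
    QC-failed reads follow the spec rates applied to ``n_reads``.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = annotation.gene_ids()
    if per_gene_counts is None:
        n_multi = int(round(spec.n_reads * spec.multi_rate))
        n_unmapped = int(round(spec.n_reads * spec.unmapped_rate))
        n_qcfail = int(round(spec.n_reads * spec.qcfail_rate))
        n_unique = spec.n_reads - n_multi - n_unmapped - n_qcfail
        assignments = [gene_ids[i % len(gene_ids)] for i in range(n_unique)]
        per_gene = pd.Series(0, index=gene_ids)
        for g in assignments:
            per_gene[g] += 1
    else:
        per_gene = per_gene_counts.astype(int)
        n_unique = int(per_gene.sum())
        n_multi = int(round(n_unique * spec.multi_rate))
        n_unmapped = int(round(n_unique * spec.unmapped_rate))
        n_qcfail = int(round(n_unique * spec.qcfail_rate))
        assignments = [g for g in per_gene.index for _ in range(int(per_gene[g]))]
    n_reads = n_unique + n_multi + n_unmapped + n_qcfail

    def _place(gene_id: str) -> tuple[str, int, int]:
        gene = annotation.genes[gene_id]
        exons = sorted({iv for exons in gene.transcripts.values() for iv in exons})
        s, e = exons[rng.integers(len(exons))]
        start = int(s + rng.integers(0, e - s - READ_LENGTH + 1))
        return gene.reference or "chr1", start, start + READ_LENGTH

    records: list[AlignmentRecord] = []
    for i, gid in enumerate(assignments):
        ref, s, e = _place(gid)
        records.append(
            AlignmentRecord(f"u{i:06d}", ref, s, e, True, 50, hit_count=1)
        )
    for i in range(n_multi):
        g1, g2 = rng.choice(len(gene_ids), size=2, replace=False)
        for gid in (gene_ids[g1], gene_ids[g2]):
            ref, s, e = _place(gid)
            records.append(
                AlignmentRecord(f"m{i:06d}", ref, s, e, True, 3, hit_count=2)
            )
    for i in range(n_unmapped):
        records.append(
            AlignmentRecord(f"f{i:06d}", None, 0, 0, False, 0, hit_count=1)
        )
    for i in range(n_qcfail):
        gid = gene_ids[int(rng.integers(len(gene_ids)))]
        ref, s, e = _place(gid)
        records.append(
            AlignmentRecord(f"q{i:06d}", ref, s, e, True, 50, hit_count=1, qc_fail=True)
        )
    if out_path is not None:
        ref_lengths = {}
        for g in annotation.genes.values():
            end = max(e for exons in g.transcripts.values() for _, e in exons)
            ref_lengths[g.reference or "chr1"] = max(
                ref_lengths.get(g.reference or "chr1", 0), end + 100
            )
        write_sam(records, out_path, ref_lengths)
    truth = {
        "tallies": {
            "n_reads": n_reads,
            "n_unique": n_unique,
            "n_multi": n_multi,
            "n_failed": n_unmapped,
            "n_filtered": n_qcfail,
        },
        "per_gene": per_gene,
        "sample_id": sample_id,
    }
    return records, truth


# ---------------------------------------------------------------------------
# counts with planted differential expression


def gen_counts(spec: FixtureSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts for two conditions with planted DE genes.

    Gene means are log-normal; ``de_fraction`` of genes are shifted by
    ``de_log2fc`` (alternating up/down) in condition 2. Library sizes are
    the column sums. Truth labels (gene, is_de, true_log2fc) come back
    with the matrix.
    """
    if spec.n_conditions != 2:
        raise ValueError("DE count fixtures are defined for two conditions")
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    base_mean = rng.lognormal(mean=math.log(30.0), sigma=0.8, size=spec.n_genes)
    n_de = int(round(spec.de_fraction * spec.n_genes))
    de_idx = rng.choice(spec.n_genes, size=n_de, replace=False)
    lfc = np.zeros(spec.n_genes)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    lfc[de_idx] = spec.de_log2fc * signs

    def _draw(mean: np.ndarray) -> np.ndarray:
        if spec.nb_dispersion > 0:
            r = 1.0 / spec.nb_dispersion
            p = r / (r + mean)
            return rng.negative_binomial(r, p)
        return rng.poisson(mean)

    cols = {}
    for cond in (1, 2):
        mean = base_mean * (2.0 ** lfc if cond == 2 else 1.0)
        for rep in range(1, spec.replicates + 1):
            cols[f"cond{cond}_rep{rep}"] = _draw(mean)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    matrix = CountMatrix(counts=counts, library_size=counts.sum(axis=0))
    truth = pd.DataFrame(
        {"gene": gene_ids, "is_de": lfc != 0, "true_log2fc": lfc}
    ).set_index("gene")
    return matrix, truth


# ---------------------------------------------------------------------------
# GO assignments with a planted enriched term

PLANTED_TERM = "GO:9999999"


def gen_go(
    spec: FixtureSpec, de_genes: set[str], all_genes: list[str]
) -> tuple[pd.DataFrame, str]:
    """GO assignments with one term overrepresented among the DE genes.

    The planted term (biological_process) includes each DE gene with odds
    ``enrichment_odds`` relative to a 10% background rate; with infinite
    odds it equals the DE set exactly. Decoy terms are assigned uniformly
    and cycle through the three GO namespaces.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    p0 = 0.10
    if math.isinf(spec.enrichment_odds):
        planted = set(de_genes)
    else:
        odds1 = spec.enrichment_odds * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        planted = set()
        for g in sorted(all_genes):
            p = p1 if g in de_genes else p0
            if rng.random() < p:
                planted.add(g)
    for g in sorted(planted):
        rows.append({"gene": g, "term": PLANTED_TERM, "category": "biological_process"})
    for t in range(spec.n_decoy_terms):
        term = f"GO:{t + 1:07d}"
        category = GO_CATEGORIES[t % len(GO_CATEGORIES)]
        for g in sorted(all_genes):
            if rng.random() < 0.12:
                rows.append({"gene": g, "term": term, "category": category})
    return pd.DataFrame(rows, columns=["gene", "term", "category"]), PLANTED_TERM


# ---------------------------------------------------------------------------
# expression with planted regulatory modules


def gen_regulatory(
    spec: FixtureSpec,
) -> tuple[pd.DataFrame, list[str], pd.Series, list[RegulatoryTree]]:
    """Expression matrix with planted TF-driven regulatory modules.

    Each module's per-condition mean is defined by a depth <= 2 threshold
    tree over its TFs (split at the TF's median; adjacent leaf means
    ``leaf_separation`` apart); member profiles add Gaussian noise with sd
    ``noise_sd``. TF profiles are standard normal per condition, redrawn
    if their median split duplicates an earlier module's partition of the
    conditions. Returns (expression incl. TF rows, tf ids, member truth
    assignment, truth trees).
    """
    rng = np.random.default_rng(spec.seed + 2)
    n_cond = spec.n_conditions * spec.replicates
    conditions = [f"c{j + 1:02d}" for j in range(n_cond)]
    sep = spec.leaf_separation

    tf_ids: list[str] = []
    tf_profiles: list[np.ndarray] = []
    partitions: list[frozenset[int]] = []
    trees: list[RegulatoryTree] = []
    module_means: list[np.ndarray] = []
    for m in range(spec.n_modules):
        # primary TF: redraw until its median split is new
        for _ in range(50):
            prof = rng.normal(0.0, 1.0, n_cond)
            thr = _median_midpoint(prof)
            part = frozenset(np.flatnonzero(prof < thr).tolist())
            comp = frozenset(set(range(n_cond)) - part)
            if part not in partitions and comp not in partitions and 0 < len(part) < n_cond:
                break
        partitions.append(part)
        tf1 = f"TF{len(tf_ids) + 1:02d}"
        tf_ids.append(tf1)
        tf_profiles.append(prof)
        mean = np.where(prof < thr, -sep / 2.0, sep / 2.0).astype(float)
        root = TreeNode(
            tf=tf1,
            threshold=thr,
            left=TreeNode(mean=-sep / 2.0, variance=max(spec.noise_sd**2, 1e-6)),
            right=TreeNode(mean=sep / 2.0, variance=max(spec.noise_sd**2, 1e-6)),
        )
        used = [tf1]
        if spec.tf_per_module >= 2:
            prof2 = rng.normal(0.0, 1.0, n_cond)
            thr2 = _median_midpoint(prof2)
            tf2 = f"TF{len(tf_ids) + 1:02d}"
            tf_ids.append(tf2)
            tf_profiles.append(prof2)
            # second split shifts the high branch further up
            high = (prof >= thr) & (prof2 >= thr2)
            mean = mean + np.where(high, sep / 2.0, 0.0)
            root.right = TreeNode(
                tf=tf2,
                threshold=thr2,
                left=TreeNode(mean=sep / 2.0, variance=max(spec.noise_sd**2, 1e-6)),
                right=TreeNode(mean=sep, variance=max(spec.noise_sd**2, 1e-6)),
            )
            used.append(tf2)
        trees.append(RegulatoryTree(root=root, used_tfs=used))
        module_means.append(mean)

    n_members = spec.n_genes
    sizes = [n_members // spec.n_modules] * spec.n_modules
    for i in range(n_members - sum(sizes)):
        sizes[i] += 1
    rows = {tf: prof for tf, prof in zip(tf_ids, tf_profiles)}
    labels = {}
    g = 0
    for m, size in enumerate(sizes):
        for _ in range(size):
            gid = f"M{g + 1:04d}"
            rows[gid] = module_means[m] + rng.normal(0.0, spec.noise_sd, n_cond)
            labels[gid] = m
            g += 1
    expr = pd.DataFrame(rows, index=pd.Index(conditions, name="condition")).T
    truth = pd.Series(labels, name="module_id")
    return expr, tf_ids, truth, trees


def _median_midpoint(values: np.ndarray) -> float:
    """Threshold between the two middle order statistics."""
    s = np.sort(values)
    mid = len(s) // 2
    return float(0.5 * (s[mid - 1] + s[mid]))


# ---------------------------------------------------------------------------
# whole-study fixture


def gen_de_tables(
    spec: FixtureSpec, truth: pd.DataFrame, n_methods: int = 5
) -> dict[str, pd.DataFrame]:
    """Per-method DE result tables consistent with the planted truth.

    Planted DE genes get small p-values, null genes uniform ones, with
    independent per-method noise so the method lists overlap but disagree,
    exercising the consensus vote.
    """
    rng = np.random.default_rng(spec.seed + 3)
    labels = [f"method{i + 1}" for i in range(n_methods)]
    out = {}
    for label in labels:
        p = np.where(
            truth["is_de"].to_numpy(),
            rng.uniform(0.0, 0.03, len(truth)),
            rng.uniform(0.0, 1.0, len(truth)),
        )
        # each method misses ~10% of true DE genes
        miss = rng.random(len(truth)) < 0.1
        p = np.where(truth["is_de"].to_numpy() & miss, rng.uniform(0.1, 1.0, len(truth)), p)
        out[label] = pd.DataFrame(
            {
                "gene": truth.index,
                "pvalue": p,
                "qvalue": np.minimum(p * 2, 1.0),
                "log2fc": truth["true_log2fc"].to_numpy(),
            }
        )
    return out


def simulate_study(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write a complete toy study: annotation, per-replicate SAM files,
    method DE tables, GO assignments, TF list, ground truth, and a
    ready-to-run pipeline config.

    Planted per-gene counts drive the read placement, so counting the
    alignments reproduces the count matrix the DE truth was planted in.
    """
    import json

    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation, ann_truth = gen_annotation(spec, out / "annotation.gtf")
    matrix, de_truth = gen_counts(spec)

    samples: dict[str, dict[str, str]] = {}
    for col_idx, col in enumerate(matrix.counts.columns):
        cond = col.split("_")[0]
        sam_path = out / f"{col}.sam"
        rep_spec = replace(spec, seed=spec.seed + 10 + col_idx)
        gen_alignments(
            rep_spec, annotation, per_gene_counts=matrix.counts[col],
            sample_id=col, out_path=sam_path,
        )
        samples.setdefault(cond, {})[col] = sam_path.name

    de_genes = set(de_truth.index[de_truth["is_de"]])
    go_table, planted_term = gen_go(spec, de_genes, list(matrix.counts.index))
    go_table.to_csv(out / "go_assignments.tsv", sep="\t", index=False)

    de_tables = gen_de_tables(spec, de_truth)
    for label, table in de_tables.items():
        table.to_csv(out / f"de_{label}.tsv", sep="\t", index=False)

    tfs = sorted(de_genes)[: max(2, len(de_genes) // 3)]
    (out / "tf_list.txt").write_text("".join(f"{t}\n" for t in tfs))

    config = {
        "stage": "networks",
        "annotation": "annotation.gtf",
        "samples": samples,
        "de_tables": {label: f"de_{label}.tsv" for label in de_tables},
        "go_table": "go_assignments.tsv",
        "tf_list": "tf_list.txt",
        "output_dir": "results",
        "seed": spec.seed,
        "de": {"criterion": "p_value", "threshold": 0.05, "min_support": 3},
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    truth = {
        "de_genes": sorted(de_genes),
        "planted_term": planted_term,
        "tf_list": tfs,
        "union_exon_length": ann_truth["union_exon_length"],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {"dir": out, "truth": truth, "counts": matrix, "de_truth": de_truth}
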