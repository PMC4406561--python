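"""Read classification, counting rules, and expression normalization."""

import numpy as np
import pandas as pd
import pytest

from seqmine.counting import (
    CountMatrix,
    MappingStats,
    classify_and_summarize,
    compute_rpkm,
    count_genes,
    load_reference_mapping_stats,
    normalize_and_average,
)
from seqmine.errors import (
    DegenerateInputError,
    EmptyAnnotationError,
    EmptyInputError,
    GroupingError,
    ValidationError,
)
from seqmine.formats_io import AlignmentRecord, AnnotationIndex, GeneModel


def _read(rid, start=0, end=None, mapped=True, hits=1, qc=False, mapq=50, ref="chr1"):
    end = start + 50 if end is None else end
    return AlignmentRecord(rid, ref if mapped else None, start if mapped else 0,
                           end if mapped else 0, mapped, mapq, hits, qc)


class TestMappingStats:
    def test_published_mouse_row_percentage(self):
        s = MappingStats("Mutant, Control", 22053527, 14120075, 2577992, 5330066, 25394)
        assert s.pct_mapped == 75.72

    def test_single_mapped_read(self):
        s = MappingStats("s", 1, 1, 0, 0, 0)
        assert s.pct_mapped == 100.00

    def test_tallies_must_conserve(self):
        with pytest.raises(ValidationError):
            MappingStats("s", 10, 5, 2, 1, 1)

    def test_reference_table_loads(self):
        ref = load_reference_mapping_stats()
        assert len(ref) == 61
        assert set(ref["dataset"]).issuperset({"mouse_set1", "human_set6"})


class TestClassify:
    def test_ten_read_fixture(self):
        recs = [_read(f"u{i}", start=i * 100) for i in range(7)]
        for i in range(2):
            recs += [_read(f"m{i}", start=i * 100, hits=2),
                     _read(f"m{i}", start=5000 + i * 100, hits=2)]
        recs.append(_read("f0", mapped=False))
        unique, stats = classify_and_summarize(recs, "s")
        assert (stats.n_reads, stats.n_unique, stats.n_multi,
                stats.n_failed, stats.n_filtered) == (10, 7, 2, 1, 0)
        assert stats.pct_mapped == 90.00
        assert {r.read_id for r in unique} == {f"u{i}" for i in range(7)}

    def test_qc_fail_and_mapq_threshold_filter(self):
        recs = [_read("a"), _read("b", qc=True), _read("c", mapq=3)]
        _, stats = classify_and_summarize(recs, "s", mapq_threshold=10)
        assert (stats.n_unique, stats.n_filtered) == (1, 2)

    def test_empty_stream_raises(self):
        with pytest.raises(EmptyInputError):
            classify_and_summarize([], "s")


@pytest.fixture()
def shared_exon_gene():
    """One gene, two isoforms sharing exon [0,300); t1 adds [600,900)."""
    g = GeneModel(
        "G", "+",
        {"t1": [(0, 300), (600, 900)], "t2": [(0, 300), (1200, 1500)]},
        "chr1",
    )
    return AnnotationIndex([g])


class TestCountGenes:
    @pytest.mark.parametrize(
        "rule,expected",
        [
            ("total_to_each_isoform", (5.0, 5.0)),
            ("discard_ambiguous", (0.0, 0.0)),
            ("proportional", (2.5, 2.5)),
        ],
    )
    def test_isoform_rules_on_shared_exon(self, shared_exon_gene, rule, expected):
        reads = [_read(f"r{i}", start=10 * i, end=10 * i + 50) for i in range(5)]
        gc = count_genes(reads, shared_exon_gene, rule=rule)
        assert gc.gene_counts["G"] == 5  # gene level identical across rules
        assert (gc.transcript_counts[("G", "t1")],
                gc.transcript_counts[("G", "t2")]) == expected

    def test_isoform_specific_read_counts_one_transcript(self, shared_exon_gene):
        reads = [_read("r", start=700, end=750)]  # only t1's exon
        gc = count_genes(reads, shared_exon_gene, rule="discard_ambiguous")
        assert gc.transcript_counts[("G", "t1")] == 1
        assert gc.transcript_counts[("G", "t2")] == 0

    def test_read_spanning_two_genes_is_ambiguous(self):
        idx = AnnotationIndex([
            GeneModel("G1", "+", {"t1": [(0, 100)]}, "chr1"),
            GeneModel("G2", "+", {"t1": [(80, 200)]}, "chr1"),
        ])
        gc = count_genes([_read("r", start=70, end=120)], idx)
        assert gc.gene_counts.sum() == 0
        assert gc.n_ambiguous_gene == 1

    def test_intergenic_read_tallied_as_no_feature(self, shared_exon_gene):
        gc = count_genes([_read("r", start=400, end=450)], shared_exon_gene)
        assert gc.gene_counts.sum() == 0 and gc.n_no_feature == 1

    def test_counting_is_permutation_invariant(self, toy_annotation):
        index, _ = toy_annotation
        rng = np.random.default_rng(3)
        reads = []
        for i in range(60):
            gid = index.gene_ids()[int(rng.integers(len(index)))]
            exon = index.genes[gid].transcripts[f"{gid}.t1"][0]
            reads.append(_read(f"r{i}", start=exon[0] + 5, end=exon[0] + 55,
                               ref=index.genes[gid].reference))
        a = count_genes(reads, index).gene_counts
        shuffled = list(reads)
        rng.shuffle(shuffled)
        b = count_genes(shuffled, index).gene_counts
        assert a.equals(b)

    def test_empty_annotation_raises(self):
        with pytest.raises(EmptyAnnotationError):
            count_genes([], AnnotationIndex([]))


def _matrix(counts: dict, libs: dict) -> CountMatrix:
    return CountMatrix(counts=pd.DataFrame(counts), library_size=pd.Series(libs))


class TestExpression:
    def test_rpkm_closed_form(self, shared_exon_gene):
        cm = _matrix({"s1": {"G": 500}}, {"s1": 10_000_000})
        # union exon length of G is 900; use a 2000 bp override gene instead
        idx = AnnotationIndex([GeneModel("G", "+", {"t1": [(0, 2000)]}, "chr1")])
        rpkm = compute_rpkm(cm, idx)
        assert rpkm.values.loc["G", "s1"] == pytest.approx(25.0)

    def test_rpkm_zero_count_is_zero(self):
        idx = AnnotationIndex([GeneModel("G", "+", {"t1": [(0, 100)]}, "chr1")])
        cm = _matrix({"s1": {"G": 0}}, {"s1": 1000})
        assert compute_rpkm(cm, idx).values.loc["G", "s1"] == 0.0

    def test_rpkm_matches_brute_force_formula(self, toy_annotation):
        index, truth = toy_annotation
        rng = np.random.default_rng(5)
        genes = index.gene_ids()
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(len(genes), 3)),
            index=genes, columns=["a", "b", "c"],
        )
        libs = pd.Series({"a": 10000, "b": 20000, "c": 15000})
        rpkm = compute_rpkm(CountMatrix(counts, libs), index)
        for g in genes:
            for s in counts.columns:
                expected = counts.loc[g, s] * 1e9 / (
                    truth["union_exon_length"][g] * libs[s]
                )
                assert rpkm.values.loc[g, s] == pytest.approx(expected)

    def test_rpkm_scale_invariance(self, toy_annotation):
        index, _ = toy_annotation
        genes = index.gene_ids()
        counts = pd.DataFrame({"s": np.arange(1, len(genes) + 1)}, index=genes)
        a = compute_rpkm(CountMatrix(counts, pd.Series({"s": 1000})), index)
        b = compute_rpkm(CountMatrix(counts * 2, pd.Series({"s": 2000})), index)
        assert np.allclose(a.values, b.values)

    def test_rpkm_zero_library_raises(self):
        idx = AnnotationIndex([GeneModel("G", "+", {"t1": [(0, 100)]}, "chr1")])
        with pytest.raises(DegenerateInputError):
            compute_rpkm(_matrix({"s1": {"G": 1}}, {"s1": 0}), idx)

    def test_normalize_and_average_examples(self):
        cm = _matrix({"r1": {"g": 10}, "r2": {"g": 20}},
                     {"r1": 10**6, "r2": 2 * 10**6})
        em = normalize_and_average(cm, {"sample": ["r1", "r2"]})
        assert em.values.loc["g", "sample"] == pytest.approx(1e-5)

    def test_normalize_matches_mean_of_ratios(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(10, 3)),
            index=[f"g{i}" for i in range(10)], columns=["r1", "r2", "r3"],
        )
        libs = pd.Series({"r1": 900, "r2": 1100, "r3": 1000})
        em = normalize_and_average(CountMatrix(counts, libs), {"s": ["r1", "r2", "r3"]})
        brute = counts.div(libs, axis=1).mean(axis=1)
        assert np.allclose(em.values["s"], brute)

    def test_empty_replicate_group_raises(self):
        cm = _matrix({"r1": {"g": 1}}, {"r1": 10})
        with pytest.raises(GroupingError):
            normalize_and_average(cm, {"s": []})
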