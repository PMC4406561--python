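"""Orchestration of the five-stage mining protocol.

Stages are ordered counts → de → functions → networks; selecting a stage
implies every earlier one. Each stage persists its outputs (TSV) before
the next starts, and the final markdown report only contains numbers
recomputable from those intermediates. Optional downstream stages that
cannot run (no transcription factors, empty consensus) are logged and
skipped rather than failing the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counting import (
    CountMatrix,
    classify_and_summarize,
    compute_rpkm,
    count_genes,
    mapping_stats_frame,
    normalize_and_average,
)
from .de import (
    builtin_de_test,
    check_similar_expression_assumption,
    consensus_vote,
    select_de,
)
from .enrichment import rank_terms
from .errors import ConfigurationError, NoTFError, SeqmineError
from .formats_io import (
    read_de_table,
    read_go_table,
    read_gtf,
    read_sam,
    read_tf_list,
    write_edge_list,
)
from .gnet import GnetConfig, export_network, fit, require_tfs

logger = logging.getLogger(__name__)

STAGES = ["counts", "de", "functions", "networks"]

_TABLE_HEADER = [
    "sample",
    "# reads",
    "# reads mapped to unique sites",
    "# reads mapped to multiple sites",
    "# reads failed to map",
    "# filtered reads",
    "percentage of reads mapped to genome",
]

_KNOWN_KEYS = {
    "stage", "annotation", "samples", "de_tables", "go_table", "tf_list",
    "output_dir", "seed", "de", "enrichment", "gnet", "mapq_threshold",
    "isoform_rule", "reuse",
}
_KNOWN_DE = {"criterion", "threshold", "min_support", "assumption_fc", "assumption_fraction"}
_KNOWN_ENRICH = {"alternative", "top_n", "gate"}
_KNOWN_GNET = {"n_clusters", "max_depth", "max_iter", "min_module_size", "rel_tol"}


@dataclass
class PipelineConfig:
    stage: str = "networks"
    annotation: str | None = None
    samples: dict[str, dict[str, str]] = field(default_factory=dict)
    de_tables: dict[str, str] = field(default_factory=dict)
    go_table: str | None = None
    tf_list: str | None = None
    output_dir: str = "results"
    seed: int = 0
    mapq_threshold: int = 0
    isoform_rule: str = "total_to_each_isoform"
    de: dict[str, Any] = field(default_factory=dict)
    enrichment: dict[str, Any] = field(default_factory=dict)
    gnet: dict[str, Any] = field(default_factory=dict)
    base_dir: Path = Path(".")

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.base_dir / p

    @property
    def stages(self) -> list[str]:
        return STAGES[: STAGES.index(self.stage) + 1]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Defaults: threshold 0.05 on p-values, consensus of at least 3 lists,
    top 10 enriched terms. Unknown keys are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    for section, known in (("de", _KNOWN_DE), ("enrichment", _KNOWN_ENRICH), ("gnet", _KNOWN_GNET)):
        extra = set(raw.get(section) or {}) - known
        if extra:
            raise ConfigurationError(
                f"unknown {section} config key(s): {', '.join(sorted(extra))}"
            )
    stage = raw.get("stage", "networks")
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; expected one of {STAGES}")
    de = {"criterion": "p_value", "threshold": 0.05, "min_support": 3,
          "assumption_fc": 2.0, "assumption_fraction": 0.5}
    de.update(raw.get("de") or {})
    if not 0 < float(de["threshold"]) <= 1:
        raise ConfigurationError(
            "invalid de.threshold: the value should be between 0 and 1"
        )
    if de["criterion"] not in ("p_value", "q_value"):
        raise ConfigurationError(f"unknown de.criterion {de['criterion']!r}")
    enrichment = {"alternative": "two-sided", "top_n": 10, "gate": True}
    enrichment.update(raw.get("enrichment") or {})
    gnet = dict(raw.get("gnet") or {})
    return PipelineConfig(
        stage=stage,
        annotation=raw.get("annotation"),
        samples=raw.get("samples") or {},
        de_tables=raw.get("de_tables") or {},
        go_table=raw.get("go_table"),
        tf_list=raw.get("tf_list"),
        output_dir=raw.get("output_dir", "results"),
        seed=int(raw.get("seed", 0)),
        mapq_threshold=int(raw.get("mapq_threshold", 0)),
        isoform_rule=raw.get("isoform_rule", "total_to_each_isoform"),
        de=de,
        enrichment=enrichment,
        gnet=gnet,
        base_dir=path.parent,
    )


@dataclass
class RunReport:
    """Per-stage summaries plus provenance; rendered to markdown."""

    sections: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def render(self) -> str:
        lines = ["# Pipeline run report", ""]
        for stage in STAGES:
            if stage in self.sections:
                lines += [f"## {stage}", "", self.sections[stage], ""]
        lines += ["## provenance", ""]
        for k in sorted(self.provenance):
            lines.append(f"- {k}: {self.provenance[k]}")
        lines.append("")
        return "\n".join(lines)


def run(config: PipelineConfig) -> RunReport:
    """Execute the selected stage and all implied predecessors."""
    out = config.resolve(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.provenance = {
        "version": __version__,
        "seed": config.seed,
        "stage": config.stage,
        "started": datetime.now(timezone.utc).isoformat(),
    }

    if config.annotation is None or not config.samples:
        raise ConfigurationError("counts stage requires 'annotation' and 'samples'")
    annotation = read_gtf(config.resolve(config.annotation))

    # ---- counts ------------------------------------------------------
    stats_list = []
    gene_counts = []
    groups: dict[str, list[str]] = {}
    for cond in sorted(config.samples):
        for rep in sorted(config.samples[cond]):
            records = read_sam(config.resolve(config.samples[cond][rep]))
            unique, stats = classify_and_summarize(
                records, sample_id=rep, mapq_threshold=config.mapq_threshold
            )
            stats_list.append(stats)
            gene_counts.append(
                count_genes(unique, annotation, rule=config.isoform_rule, sample_id=rep)
            )
            groups.setdefault(cond, []).append(rep)
    stats_df = mapping_stats_frame(stats_list)
    published = stats_df.copy()
    published.columns = _TABLE_HEADER
    published.to_csv(out / "mapping_stats.tsv", sep="\t", index=False)
    matrix = CountMatrix.from_gene_counts(gene_counts)
    matrix.counts.to_csv(out / "counts.tsv", sep="\t")
    matrix.library_size.rename("library_size").to_csv(out / "library_sizes.tsv", sep="\t")
    rpkm = compute_rpkm(matrix, annotation)
    rpkm.values.to_csv(out / "rpkm.tsv", sep="\t", float_format="%.6g")
    norm = normalize_and_average(matrix, groups)
    norm.values.to_csv(out / "normalized_means.tsv", sep="\t", float_format="%.6g")
    report.sections["counts"] = (
        f"{len(stats_list)} replicate(s), {len(matrix.counts)} genes.\n\n"
        + stats_df.to_string(index=False)
    )
    if config.stage == "counts":
        _finish(report, out)
        return report

    # ---- de ----------------------------------------------------------
    conditions = sorted(groups)
    assumption_note = ""
    if len(conditions) >= 2:
        passes, diag = check_similar_expression_assumption(
            matrix, groups[conditions[0]], groups[conditions[1]],
            fc_threshold=config.de["assumption_fc"],
            max_fraction=config.de["assumption_fraction"],
        )
        assumption_note = (
            f"similar-expression assumption: {'passes' if passes else 'VIOLATED'} "
            f"(fraction |log2FC|>{config.de['assumption_fc']}: {diag['fraction_high_fc']:.3f})"
        )
        logger.info(assumption_note)
    lists: dict[str, set[str]] = {}
    if config.de_tables:
        for label in sorted(config.de_tables):
            result = read_de_table(config.resolve(config.de_tables[label]), label)
            lists[label] = select_de(
                result, config.de["criterion"], config.de["threshold"]
            )
    else:
        result = builtin_de_test(matrix, groups[conditions[0]], groups[conditions[1]])
        result.table.drop(columns=["flagged"]).to_csv(
            out / "de_builtin.tsv", sep="\t", index=False
        )
        lists[result.method_label] = select_de(
            result, config.de["criterion"], config.de["threshold"]
        )
    min_support = int(config.de["min_support"])
    if min_support > len(lists):
        logger.warning(
            "min_support=%d exceeds %d list(s); reducing", min_support, len(lists)
        )
        min_support = len(lists)
    consensus = consensus_vote(lists, min_support=min_support)
    consensus.table.to_csv(out / "consensus.tsv", sep="\t", index=False)
    per_method = ", ".join(f"{k}: {len(v)}" for k, v in sorted(lists.items()))
    report.sections["de"] = (
        f"DE genes per method — {per_method}.\n"
        f"Consensus (>= {min_support} of {len(lists)} lists): "
        f"{len(consensus.table)} genes.\n{assumption_note}"
    )
    if config.stage == "de":
        _finish(report, out)
        return report

    # ---- functions ---------------------------------------------------
    de_genes = consensus.genes
    background = set(matrix.counts.index.astype(str))
    if config.go_table is None:
        raise ConfigurationError("functions stage requires 'go_table'")
    if not de_genes:
        report.sections["functions"] = "skipped: empty consensus DE list"
        logger.warning("functions stage skipped: no DE genes")
    else:
        assignments = read_go_table(config.resolve(config.go_table))
        enr = rank_terms(
            de_genes, background, assignments,
            gate=bool(config.enrichment["gate"]),
            alternative=config.enrichment["alternative"],
        )
        section_lines = []
        top_n = int(config.enrichment["top_n"])
        for category, df in enr.results.items():
            df.to_csv(out / f"enrichment_{category}.tsv", sep="\t", index=False)
            df.head(top_n).to_csv(
                out / f"enrichment_{category}_top{top_n}.tsv", sep="\t", index=False
            )
            section_lines.append(f"{category}: {len(df)} terms tested")
        if enr.cmh_p_value is not None:
            section_lines.append(
                f"CMH pre-check: statistic={enr.cmh_statistic:.4f} "
                f"p={enr.cmh_p_value:.4g} (advisory)"
            )
        report.sections["functions"] = "\n".join(section_lines)
    if config.stage == "functions":
        _finish(report, out)
        return report

    # ---- networks ----------------------------------------------------
    if config.tf_list is None:
        raise ConfigurationError("networks stage requires 'tf_list'")
    tf_list = read_tf_list(config.resolve(config.tf_list))
    try:
        usable_tfs = require_tfs(de_genes, tf_list)
    except NoTFError:
        report.sections["networks"] = "skipped: no transcription factors"
        logger.warning("networks stage skipped: no TFs among DE genes")
        _finish(report, out)
        return report
    log_expr = np.log2(rpkm.values + 1.0)
    tf_rows = sorted(usable_tfs & set(log_expr.index))
    member_rows = sorted((de_genes - usable_tfs) & set(log_expr.index))
    if len(member_rows) < 2 or not tf_rows:
        report.sections["networks"] = (
            "skipped: not enough measured DE genes or TFs for module learning"
        )
        _finish(report, out)
        return report
    gcfg = GnetConfig(seed=config.seed, **config.gnet)
    result = fit(log_expr.loc[member_rows], log_expr.loc[tf_rows], gcfg)
    result.assignment.to_csv(out / "modules.tsv", sep="\t")
    scores = pd.DataFrame(
        [
            {
                "module_id": m.module_id,
                "n_genes": len(m.members),
                "n_tfs": len(m.tree.used_tfs),
                "tfs": ",".join(m.tree.used_tfs),
                "correlation_score": round(m.correlation_score, 6),
                "log_likelihood": round(m.log_likelihood, 6),
            }
            for m in result.modules
        ]
    )
    scores.to_csv(out / "module_scores.tsv", sep="\t", index=False)
    with open(out / "trees.txt", "w") as fh:
        for m in result.modules:
            fh.write(f"module {m.module_id} ({len(m.members)} genes)\n")
            fh.write(m.tree.render() + "\n\n")
    network = export_network(result.modules, top_n=10)
    write_edge_list(network, out / "edges.tsv")
    report.sections["networks"] = (
        f"{len(result.modules)} modules, {result.n_iter} iteration(s), "
        f"converged={result.converged}.\n"
        f"Network: {len(network.tf_nodes)} TFs, {len(network.gene_nodes)} genes, "
        f"{network.n_edges} edges."
    )
    _finish(report, out)
    return report


def _finish(report: RunReport, out: Path) -> None:
    report.provenance["finished"] = datetime.now(timezone.utc).isoformat()
    (out / "report.md").write_text(report.render())
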