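"""End-to-end pipeline: counts (or FASTQ) -> QC -> LFC -> metrics -> ROC."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import io as dio
from .evaluation import GoldStandard, evaluate_screen
from .metrics import screen_metrics
from .quantify import CountTable, count_pairs, qc_report

log = logging.getLogger("duoscreen")


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run; serialized beside outputs."""

    library: str
    out_dir: str
    counts: str | None = None
    sample_sheet: str | None = None
    fastq_r1: str | None = None
    fastq_r2: str | None = None
    anchor1: str | None = None
    anchor2: str | None = None
    gold_standard: str | None = None
    dependency_scores: str | None = None
    design: str | None = None
    reference_sample: str | None = None
    pseudocount: float = 0.5
    pseudocount_mode: str = "on_zero"
    replicate_agg: str = "mean"
    roc_unit: str = "guide_pairs"
    error_tolerance: float = 0.1
    max_mismatches: int = 1
    ts_genes: tuple[str, ...] | None = ("TP53", "NF2")
    seed: int = 0
    percentile_convention: str = "nearest-rank"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all tables plus a metrics report.

    Stages: count (if FASTQ given) -> qc -> normalize -> lfc -> gene-pair
    aggregation -> screen metrics -> ROC.  Raises with the stage name on any
    stage error; returns the structured report also written to report.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            report["stages"][name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", name, report["stages"][name])
            return result

        return deco

    library = stage("read_library")(lambda: dio.read_guide_library(config.library, config.design))

    if config.fastq_r1:
        if not (config.anchor1 and config.anchor2 and config.fastq_r2):
            raise RuntimeError("pipeline stage 'count' failed: FASTQ input needs r2 and both anchors")

        def _count() -> CountTable:
            table = count_pairs(
                dio.read_fastq(config.fastq_r1),
                dio.read_fastq(config.fastq_r2),
                library,
                config.anchor1,
                config.anchor2,
                error_tolerance=config.error_tolerance,
                max_mismatches=config.max_mismatches,
                sample_id="sample1",
            )
            dio.write_count_table(table, out / "counts.tsv", library)
            return table

        table = stage("count")(_count)
    else:
        if not config.counts:
            raise RuntimeError("pipeline stage 'input' failed: need counts or FASTQ input")
        table = stage("read_counts")(
            lambda: dio.read_count_table(config.counts, config.sample_sheet)
        )
    report["n_combinations"] = int(len(table.counts))
    report["samples"] = list(table.sample_ids)

    qc = stage("qc")(lambda: qc_report(table))
    report["qc"] = qc.to_records()

    def _metrics():
        return screen_metrics(
            table,
            library,
            replicate_agg=config.replicate_agg,
            pseudocount=config.pseudocount,
            ts_genes=config.ts_genes,
        )

    metrics, lfc, gp = stage("metrics")(_metrics)
    dio.write_lfc_table(lfc, out / "lfc.tsv")
    dio.write_gene_pair_table(gp, out / "gene_pair_lfc.tsv")
    report["effect_size_range"] = {
        "guides": metrics.effect_size_range_guides,
        "genes": metrics.effect_size_range_genes,
    }
    report["class_lfc"] = {
        cls: {"n": int(row["n"]), "mean": float(row["mean"]), "median": float(row["median"])}
        for cls, row in metrics.class_lfc.iterrows()
    }
    if metrics.replicate_correlations is not None:
        report["replicate_correlations"] = metrics.replicate_correlations

    def _roc():
        if config.gold_standard:
            gold = dio.read_gold_standard(config.gold_standard)
        else:
            gold = GoldStandard.default(library.genes())
        return evaluate_screen(lfc, gold, unit=config.roc_unit)

    ev = stage("roc")(_roc)
    report["roc"] = {"auc_ce": ev.auc_ce, "auc_ts": ev.auc_ts, "unit": ev.unit, "flags": ev.flags}

    cfg = asdict(config)
    cfg["ts_genes"] = list(config.ts_genes) if config.ts_genes else None
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
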