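"""Normalization, log2 fold changes, gene-pair aggregation and screen metrics.

The analysis math of a dual-cassette dropout screen:

* counts are normalized per sample to sequencing depth and then to the median
  of the NHT-NHT (double-control) combinations, anchoring the neutral
  baseline at 1;
* per-combination LFC = log2(end / reference) on normalized values;
* gene-pair LFCs are medians over all constituent guide-pair LFCs;
* screen-level summaries: effect-size range (max - min LFC), per-class means
  and medians, single-guide decomposition via NHT partners, and replicate /
  cross-screen correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .library import CombinatorialLibrary
from .quantify import CountTable

REPLICATE_AGG_MODES = ("mean", "median", "pooled")


@dataclass
class NormalizedTable:
    """Depth- and NHT-NHT-normalized counts (same shape as the CountTable)."""

    values: pd.DataFrame
    samples: pd.DataFrame
    record: pd.DataFrame  # per-sample: total, nht_median, scale

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.samples.index[self.samples["role"] == role])


def normalize(
    table: CountTable,
    library: CombinatorialLibrary | None = None,
    *,
    nht_nht_ids: pd.Index | None = None,
    scale: float = 1.0,
) -> NormalizedTable:
    """Normalize each sample to its total and to its NHT-NHT median.

    value = (count / sample_total) / median_over_NHT-NHT(count / sample_total)
    then multiplied by ``scale``.  After normalization the median NHT-NHT
    value in every sample is exactly ``scale``.
    """
    if nht_nht_ids is None:
        if library is None:
            raise ValueError("need a library or an explicit NHT-NHT id list")
        nht_nht_ids = library.nht_nht_ids()
    if len(nht_nht_ids) == 0:
        raise ValueError("no NHT-NHT combinations in the library")
    if scale <= 0:
        raise ValueError("scale must be positive")
    counts = table.counts.astype(float)
    values = {}
    rec = []
    for sid in counts.columns:
        col = counts[sid]
        total = col.sum()
        if total == 0:
            raise ValueError(f"sample {sid!r}: total read count is zero")
        rel = col / total
        nht_median = rel.loc[nht_nht_ids].median()
        if nht_median == 0:
            raise ValueError(f"sample {sid!r}: NHT-NHT median is zero; cannot normalize")
        values[sid] = rel / nht_median * scale
        rec.append({"sample_id": sid, "total": float(total), "nht_median": float(nht_median), "scale": scale})
    return NormalizedTable(
        pd.DataFrame(values, index=counts.index),
        table.samples.copy(),
        pd.DataFrame(rec).set_index("sample_id"),
    )


def _lfc_one(
    end: pd.Series, reference: pd.Series, pseudocount: float, pseudocount_mode: str
) -> pd.Series:
    if pseudocount_mode not in ("on_zero", "always"):
        raise ValueError(f"unknown pseudocount_mode {pseudocount_mode!r}")
    e = end.astype(float).copy()
    r = reference.astype(float).copy()
    if pseudocount_mode == "always":
        e += pseudocount
        r += pseudocount
    else:
        hit = (e == 0) | (r == 0)
        if hit.any() and pseudocount <= 0:
            raise ValueError("zero values present; a positive pseudocount is required")
        e[hit] += pseudocount
        r[hit] += pseudocount
    return np.log2(e / r)


@dataclass
class LFCTable:
    """Per-combination log2 fold changes with pair-class annotation."""

    frame: pd.DataFrame  # index combo_id; columns lfc, pair_class, gene_a, gene_b, class_a, class_b
    provenance: dict = field(default_factory=dict)

    @property
    def lfc(self) -> pd.Series:
        return self.frame["lfc"]


def guide_lfc(
    norm: NormalizedTable,
    end_samples: list[str] | str,
    reference_sample: str,
    *,
    pseudocount: float = 0.5,
    pseudocount_mode: str = "on_zero",
    replicate_agg: str = "mean",
    library: CombinatorialLibrary | None = None,
    screen_id: str | None = None,
) -> LFCTable:
    """Guide-pair LFC = log2(end / reference) on normalized values.

    With several end replicates, per-replicate LFCs are computed and combined
    by ``replicate_agg`` ("mean" or "median"; pooling of raw counts is done
    upstream with :meth:`CountTable.pooled`).  The pseudocount is applied per
    comparison, by default only where a zero is present.
    """
    if isinstance(end_samples, str):
        end_samples = [end_samples]
    missing = [s for s in [*end_samples, reference_sample] if s not in norm.values.columns]
    if missing:
        raise ValueError(f"samples not in table: {missing}")
    if replicate_agg not in ("mean", "median"):
        raise ValueError("replicate_agg must be 'mean' or 'median' here; pool counts upstream for 'pooled'")
    ref = norm.values[reference_sample]
    per_rep = pd.DataFrame(
        {s: _lfc_one(norm.values[s], ref, pseudocount, pseudocount_mode) for s in end_samples}
    )
    combined = per_rep.mean(axis=1) if replicate_agg == "mean" else per_rep.median(axis=1)
    frame = combined.to_frame("lfc")
    if library is not None:
        if not frame.index.equals(library.combo_ids):
            extra = frame.index.symmetric_difference(library.combo_ids)
            if len(extra):
                raise ValueError(f"combination universes differ; symmetric difference: {list(extra[:10])}")
        for col in ("pair_class", "guide_a", "guide_b", "gene_a", "gene_b", "class_a", "class_b"):
            frame[col] = library.combos[col]
    return LFCTable(
        frame,
        provenance={
            "reference_sample": reference_sample,
            "end_samples": list(end_samples),
            "replicate_agg": replicate_agg,
            "pseudocount": pseudocount,
            "pseudocount_mode": pseudocount_mode,
            "screen_id": screen_id,
        },
    )


def screen_lfc(
    table: CountTable,
    library: CombinatorialLibrary,
    *,
    reference_sample: str | None = None,
    end_samples: list[str] | None = None,
    replicate_agg: str = "mean",
    pseudocount: float = 0.5,
    pseudocount_mode: str = "on_zero",
    screen_id: str | None = None,
) -> LFCTable:
    """End-to-end per-screen LFC: normalize then compare end vs reference.

    Sample roles are read from the sample sheet when not given explicitly.
    ``replicate_agg``: "mean" / "median" combine per-replicate LFCs;
    "pooled" sums raw replicate counts before normalization.
    """
    if replicate_agg not in REPLICATE_AGG_MODES:
        raise ValueError(f"replicate_agg must be one of {REPLICATE_AGG_MODES}")
    if reference_sample is None:
        refs = table.samples_with_role("library_reference")
        if len(refs) != 1:
            raise ValueError(f"need exactly one library_reference sample, found {refs}")
        reference_sample = refs[0]
    if end_samples is None:
        end_samples = table.samples_with_role("screen_end")
        if not end_samples:
            raise ValueError("no screen_end samples in table")
    if replicate_agg == "pooled" and len(end_samples) > 1:
        pooled = table.pooled(end_samples, "pooled_end")
        ref_tab = CountTable(
            table.counts[[reference_sample]], table.samples.loc[[reference_sample]]
        )
        table = CountTable.merge([ref_tab, pooled])
        end_samples = ["pooled_end"]
        agg = "mean"
    else:
        agg = "mean" if replicate_agg == "pooled" else replicate_agg
    norm = normalize(table, library)
    return guide_lfc(
        norm,
        end_samples,
        reference_sample,
        pseudocount=pseudocount,
        pseudocount_mode=pseudocount_mode,
        replicate_agg=agg,
        library=library,
        screen_id=screen_id,
    )


@dataclass
class GenePairTable:
    """Median-aggregated LFC per ordered (gene_a, gene_b) pair."""

    frame: pd.DataFrame  # index (gene_a, gene_b); columns lfc, n_guide_pairs, pair_class

    @property
    def lfc(self) -> pd.Series:
        return self.frame["lfc"]


def gene_pair_lfc(lfc: LFCTable, library: CombinatorialLibrary | None = None) -> GenePairTable:
    """Median over all guide-pair LFCs of each ordered gene pair.

    NHT guides collapse to the single pseudo-gene "NHT", so NHT-gene pairs
    aggregate across all NHT partners.
    """
    frame = lfc.frame
    if "gene_a" not in frame.columns:
        if library is None:
            raise ValueError("LFC table lacks gene annotation; pass the library")
        frame = frame.join(library.combos[["gene_a", "gene_b", "pair_class"]])
    grouped = frame.groupby(["gene_a", "gene_b"], sort=True)
    out = grouped.agg(lfc=("lfc", "median"), n_guide_pairs=("lfc", "size"),
                      pair_class=("pair_class", "first"))
    return GenePairTable(out)


def effect_size_range(values) -> float:
    """max - min over a vector of LFCs (the screen's effect-size range)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    if not np.isfinite(v).all():
        raise ValueError("non-finite LFC values")
    return float(v.max() - v.min())


def class_summary(values, classes) -> pd.DataFrame:
    """Per-class n / mean / median of a value vector with class labels."""
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float), "cls": list(classes)})
    out = frame.groupby("cls")["value"].agg(n="size", mean="mean", median="median")
    out["n"] = out["n"].astype(int)
    return out


def target_class_lfc(
    lfc: LFCTable,
    *,
    ts_genes: tuple[str, ...] | None = ("TP53", "NF2"),
) -> pd.DataFrame:
    """Mean/median LFC of single-target guide pairs per targeted class.

    Uses NHT-CE and NHT-TS pairs (one targeting guide, one control), the
    cleanest readout of per-class separation.  TS summaries are restricted to
    the genes with a proliferation phenotype (default TP53 and NF2); pass
    ``ts_genes=None`` to keep all TS genes.  The NHT-NHT baseline is included
    as class "NHT".
    """
    frame = lfc.frame
    masks = {
        "CE": frame["pair_class"] == "NHT-CE",
        "TS": frame["pair_class"] == "NHT-TS",
        "NHT": frame["pair_class"] == "NHT-NHT",
    }
    if ts_genes is not None:
        targeted = frame["gene_a"].where(frame["class_a"] != "NHT", frame["gene_b"])
        masks["TS"] = masks["TS"] & targeted.isin(ts_genes)
    rows = []
    for cls, m in masks.items():
        vals = frame.loc[m, "lfc"]
        if len(vals) == 0:
            continue
        rows.append({"cls": cls, "n": len(vals), "mean": vals.mean(), "median": vals.median()})
    return pd.DataFrame(rows).set_index("cls")


def single_guide_lfc(lfc: LFCTable, position: int, *, gene_level: bool = False) -> pd.DataFrame:
    """Per-guide LFC from NHT-partner pairs at one position.

    For each non-NHT guide at ``position``, the median LFC over all of its
    combinations whose partner (the other position) is an NHT control.
    ``gene_level`` further aggregates these per gene by median.
    """
    if position not in (1, 2):
        raise ValueError("position must be 1 or 2")
    frame = lfc.frame
    g_col, cls_col, gene_col = ("guide_a", "class_a", "gene_a") if position == 1 else ("guide_b", "class_b", "gene_b")
    partner_cls = "class_b" if position == 1 else "class_a"
    if g_col not in frame.columns:
        raise ValueError("LFC table lacks guide annotation; build it with a library")
    mask = (frame[cls_col] != "NHT") & (frame[partner_cls] == "NHT")
    sub = frame.loc[mask]
    per_guide = sub.groupby([g_col, gene_col])["lfc"].agg(lfc="median", n="size").reset_index()
    per_guide = per_guide.rename(columns={g_col: "guide_id", gene_col: "gene"}).set_index("guide_id")
    if not gene_level:
        return per_guide
    gene = per_guide.groupby("gene")["lfc"].agg(lfc="median", n="size")
    return gene


def _lfc_frame(lfc: LFCTable, library: CombinatorialLibrary | None) -> pd.DataFrame:
    frame = lfc.frame
    if "guide_a" not in frame.columns:
        if library is None:
            raise ValueError("pass a library for guide annotation")
        frame = frame.join(library.combos)
    return frame


@dataclass
class Correlation:
    r: float | None
    method: str
    n: int
    n_dropped: int
    slope: float | None = None
    intercept: float | None = None

    @property
    def defined(self) -> bool:
        return self.r is not None


def correlate(x, y, method: str = "pearson") -> Correlation:
    """Pearson or Spearman correlation, dropping non-finite pairs.

    Also reports the least-squares slope/intercept (the regression line drawn
    in cross-screen comparisons).  Zero variance in either vector yields an
    undefined (flagged) result instead of an exception.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return Correlation(None, method, int(x.size), n_dropped)
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    else:
        r = float(stats.spearmanr(x, y).statistic)
    slope, intercept = np.polyfit(x, y, 1)
    return Correlation(r, method, int(x.size), n_dropped, float(slope), float(intercept))


def replicate_correlations(
    table: CountTable,
    library: CombinatorialLibrary,
    *,
    pseudocount: float = 0.5,
) -> dict[str, float | None]:
    """Replicate QC: r on guide counts, gene counts, and guide LFCs."""
    ends = table.samples_with_role("screen_end")
    if len(ends) < 2:
        raise ValueError("need >= 2 end replicates")
    a, b = ends[:2]
    out: dict[str, float | None] = {}
    out["guide_counts"] = correlate(table.counts[a], table.counts[b]).r
    gene_counts = table.counts.join(library.combos[["gene_a", "gene_b"]]).groupby(
        ["gene_a", "gene_b"]
    )[[a, b]].sum()
    out["gene_counts"] = correlate(gene_counts[a], gene_counts[b]).r
    norm = normalize(table, library)
    ref = table.samples_with_role("library_reference")[0]
    la = guide_lfc(norm, a, ref, pseudocount=pseudocount).lfc
    lb = guide_lfc(norm, b, ref, pseudocount=pseudocount).lfc
    out["guide_lfc"] = correlate(la, lb).r
    return out


@dataclass
class ScreenMetrics:
    """Headline metrics of one screen."""

    effect_size_range_guides: float
    effect_size_range_genes: float
    class_lfc: pd.DataFrame
    pair_class_summary: pd.DataFrame
    replicate_correlations: dict[str, float | None] | None = None


def screen_metrics(
    table: CountTable,
    library: CombinatorialLibrary,
    *,
    replicate_agg: str = "mean",
    pseudocount: float = 0.5,
    ts_genes: tuple[str, ...] | None = ("TP53", "NF2"),
) -> tuple[ScreenMetrics, LFCTable, GenePairTable]:
    """Full metric sweep for one screen's count table."""
    lfc = screen_lfc(table, library, replicate_agg=replicate_agg, pseudocount=pseudocount)
    gp = gene_pair_lfc(lfc)
    metrics = ScreenMetrics(
        effect_size_range_guides=effect_size_range(lfc.lfc),
        effect_size_range_genes=effect_size_range(gp.lfc),
        class_lfc=target_class_lfc(lfc, ts_genes=ts_genes),
        pair_class_summary=class_summary(lfc.lfc, lfc.frame["pair_class"]),
        replicate_correlations=(
            replicate_correlations(table, library, pseudocount=pseudocount)
            if len(table.samples_with_role("screen_end")) >= 2
            else None
        ),
    )
    return metrics, lfc, gp
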