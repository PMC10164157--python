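"""Gold standards and ROC evaluation of screen performance.

A screen is benchmarked by how well its LFCs separate guides targeting
known-essential (CE) or known-enriching tumor-suppressor (TS) genes from
guides targeting non-essential negatives.  Positive gene sets default to the
genes with conserved strong Chronos dependency scores in RPE1 lines (CE:
strong negative; TS: strong positive), or are derived from a user-supplied
dependency-score table with two cuts.  AUC is the Mann-Whitney probability
that a positive record outranks a negative one (ties counted 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .library import CombinatorialLibrary
from .metrics import Correlation, GenePairTable, LFCTable, correlate, single_guide_lfc

DEFAULT_CE_POSITIVE = frozenset({"CCT4", "EIF3B", "XPO1", "IARS", "EFTUD2", "NARS"})
DEFAULT_TS_POSITIVE = frozenset({"ARNT", "AHR", "KIRREL", "TP53", "NF2"})

ROC_UNITS = ("guide_pairs", "all_pairs", "nht_single")


@dataclass(frozen=True)
class GoldStandard:
    """Disjoint positive CE / positive TS / negative gene sets."""

    ce_positive: frozenset[str]
    ts_positive: frozenset[str]
    negatives: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        sets = (self.ce_positive, self.ts_positive, self.negatives)
        if sum(map(len, sets)) != len(self.ce_positive | self.ts_positive | self.negatives):
            raise ValueError("gold-standard gene sets must be pairwise disjoint")
        if "NHT" in self.ce_positive | self.ts_positive | self.negatives:
            raise ValueError("NHT is a control pseudo-gene and cannot be gold-labeled")

    @classmethod
    def default(cls, library_genes) -> "GoldStandard":
        """The RPE1 default sets; negatives = the library's remaining genes.

        For synthetic libraries (gene names CEnn / TSnn) the analogous split
        is used: the first 6 CE and first 5 TS genes are positives.
        """
        genes = set(library_genes) - {"NHT"}
        if genes & (DEFAULT_CE_POSITIVE | DEFAULT_TS_POSITIVE):
            ce = DEFAULT_CE_POSITIVE & genes
            ts = DEFAULT_TS_POSITIVE & genes
            source = "RPE1 DepMap defaults"
        elif all(g[:2] in ("CE", "TS") for g in genes):
            ce = {g for g in genes if g.startswith("CE") and int(g[2:]) <= 6}
            ts = {g for g in genes if g.startswith("TS") and int(g[2:]) <= 5}
            source = "synthetic defaults"
        else:
            raise ValueError(
                "library genes match neither the RPE1 defaults nor synthetic naming; "
                "supply an explicit gold standard"
            )
        neg = genes - ce - ts
        return cls(frozenset(ce), frozenset(ts), frozenset(neg), source=source)


def gold_standard_from_scores(
    dep_scores: dict[str, float] | pd.Series,
    ce_cut: float,
    ts_cut: float,
    *,
    source: str = "dependency scores",
) -> GoldStandard:
    """Threshold a gene -> dependency-score map into a gold standard.

    Genes with score <= ce_cut (strong negative dependency) are CE positives;
    score >= ts_cut are TS positives; the rest are negatives.  NHT is never
    classified.
    """
    if ce_cut >= ts_cut:
        raise ValueError(f"overlapping cuts: ce_cut ({ce_cut}) must be < ts_cut ({ts_cut})")
    scores = pd.Series(dep_scores, dtype=float)
    scores = scores[scores.index != "NHT"]
    ce = frozenset(scores.index[scores <= ce_cut])
    ts = frozenset(scores.index[scores >= ts_cut])
    neg = frozenset(scores.index) - ce - ts
    return GoldStandard(ce, ts, frozenset(neg), source=source)


@dataclass
class RocResult:
    """ROC curve and area; ``degenerate`` flags all-tied score sets."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_positive: int
    n_negative: int
    orientation: str
    degenerate: bool = False


def roc_auc(scores, labels, orientation: str = "high_is_positive") -> RocResult:
    """ROC curve + AUC with Mann-Whitney tie handling (ties count 1/2).

    ``labels`` are truthy for positives.  ``orientation`` says which score
    direction indicates a positive: "low_is_positive" for depletion readouts
    (CE genes), "high_is_positive" for enrichment (TS genes).
    """
    if orientation not in ("low_is_positive", "high_is_positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray([bool(l) for l in labels])
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative record")
    oriented = -s if orientation == "low_is_positive" else s
    if np.ptp(oriented) == 0:
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        return RocResult(fpr, tpr, np.array([np.inf, oriented[0]]), 0.5,
                         n_pos, n_neg, orientation, degenerate=True)
    fpr, tpr, thr = roc_curve(y, oriented)
    auc = float(roc_auc_score(y, oriented))
    return RocResult(fpr, tpr, thr, auc, n_pos, n_neg, orientation)


@dataclass
class ScreenEvaluation:
    auc_ce: float | None
    auc_ts: float | None
    roc_ce: RocResult | None
    roc_ts: RocResult | None
    unit: str
    flags: list[str] = field(default_factory=list)


def _pair_records(
    frame: pd.DataFrame, positives: frozenset[str], negatives: frozenset[str], unit: str
) -> tuple[pd.Series, np.ndarray]:
    """Score/label records for one ROC, at the configured record unit."""
    in_pos_a = frame["gene_a"].isin(positives)
    in_pos_b = frame["gene_b"].isin(positives)
    in_neg_a = frame["gene_a"].isin(negatives)
    in_neg_b = frame["gene_b"].isin(negatives)
    is_nht_a = frame["class_a"] == "NHT"
    is_nht_b = frame["class_b"] == "NHT"
    pos_any = in_pos_a | in_pos_b
    if unit == "all_pairs":
        pos_mask = pos_any
        neg_mask = (in_neg_a | in_neg_b) & ~pos_any
    else:  # guide_pairs: the partner must be NHT or a negative-set gene
        neutral_a = is_nht_a | in_neg_a
        neutral_b = is_nht_b | in_neg_b
        pos_mask = (in_pos_a & neutral_b) | (in_pos_b & neutral_a)
        neg_mask = ((in_neg_a & neutral_b) | (in_neg_b & neutral_a)) & ~pos_any
    keep = pos_mask | neg_mask
    return frame.loc[keep, "lfc"], pos_mask[keep].to_numpy()


def evaluate_screen(
    lfc: LFCTable,
    gold: GoldStandard,
    *,
    unit: str = "guide_pairs",
    library: CombinatorialLibrary | None = None,
) -> ScreenEvaluation:
    """AUC of CE recovery (depletion) and TS recovery (enrichment).

    Record units: "guide_pairs" (default) = guide-pair LFCs where one guide
    targets a gold-labeled gene and the partner is NHT or a negative-set
    gene; "all_pairs" = any pair involving a gold-labeled gene;
    "nht_single" = per-guide NHT-partner single-guide LFCs from both
    positions.
    """
    if unit not in ROC_UNITS:
        raise ValueError(f"unit must be one of {ROC_UNITS}")
    flags: list[str] = []
    if unit == "nht_single":
        recs = []
        for pos in (1, 2):
            try:
                per_guide = single_guide_lfc(lfc, pos)
            except ValueError:
                continue
            recs.append(per_guide)
        if not recs:
            raise ValueError("no NHT-partner records available")
        rec = pd.concat(recs)
        results = {}
        for cls, positives, orientation in (
            ("ce", gold.ce_positive, "low_is_positive"),
            ("ts", gold.ts_positive, "high_is_positive"),
        ):
            mask = rec["gene"].isin(positives | gold.negatives)
            sub = rec.loc[mask]
            labels = sub["gene"].isin(positives).to_numpy()
            results[cls] = _safe_roc(sub["lfc"], labels, orientation, flags, cls)
    else:
        frame = lfc.frame
        if "gene_a" not in frame.columns:
            if library is None:
                raise ValueError("LFC table lacks gene annotation; pass the library")
            frame = frame.join(library.combos)
        results = {}
        for cls, positives, orientation in (
            ("ce", gold.ce_positive, "low_is_positive"),
            ("ts", gold.ts_positive, "high_is_positive"),
        ):
            scores, labels = _pair_records(frame, positives, gold.negatives, unit)
            results[cls] = _safe_roc(scores, labels, orientation, flags, cls)
    return ScreenEvaluation(
        auc_ce=results["ce"].auc if results["ce"] else None,
        auc_ts=results["ts"].auc if results["ts"] else None,
        roc_ce=results["ce"],
        roc_ts=results["ts"],
        unit=unit,
        flags=flags,
    )


def _safe_roc(scores, labels, orientation, flags, cls) -> RocResult | None:
    labels = np.asarray(labels, dtype=bool)
    if len(scores) == 0 or labels.sum() == 0 or (~labels).sum() == 0:
        flags.append(f"no records for class {cls}")
        return None
    return roc_auc(scores, labels, orientation)


@dataclass
class ScreenComparison:
    r_pearson: float | None
    r_spearman: float | None
    slope: float | None
    intercept: float | None
    n: int
    only_in_a: int
    only_in_b: int


def compare_screens(
    a: LFCTable | GenePairTable | pd.Series,
    b: LFCTable | GenePairTable | pd.Series,
) -> ScreenComparison:
    """Concordance of two screens over their shared combinations / gene pairs."""
    sa = a.lfc if not isinstance(a, pd.Series) else a
    sb = b.lfc if not isinstance(b, pd.Series) else b
    shared = sa.index.intersection(sb.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared keys, found {len(shared)}")
    pear: Correlation = correlate(sa.loc[shared], sb.loc[shared], "pearson")
    spear: Correlation = correlate(sa.loc[shared], sb.loc[shared], "spearman")
    return ScreenComparison(
        r_pearson=pear.r,
        r_spearman=spear.r,
        slope=pear.slope,
        intercept=pear.intercept,
        n=pear.n,
        only_in_a=len(sa.index.difference(sb.index)),
        only_in_b=len(sb.index.difference(sa.index)),
    )
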