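"""Paired-read quantification of guide combinations and library-uniformity QC.

The original pipelines for screens of this kind chain an adapter trimmer with
a local aligner.  Because the library spacers are short, fixed-length and
fully known, this module instead uses anchored extraction (best occurrence of
the constant region upstream of each spacer, bounded edit distance) followed
by exact / bounded-Hamming matching against the per-position spacer index.
The behaviour is deterministic and every failure is tallied.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import edlib
import numpy as np
import pandas as pd

from .library import CombinatorialLibrary

_READ_RE = re.compile(r"^[ACGTN]*$")

#: sentinel returned by match_spacer when >= 2 guides tie at the best distance
AMBIGUOUS = "__ambiguous__"

UNASSIGNED_CATEGORIES = ("no_anchor", "no_match", "ambiguous", "not_in_library")

SAMPLE_ROLES = ("library_reference", "screen_end")


@dataclass
class CountTable:
    """Integer (or, for noiseless simulations, real) counts per combination.

    ``counts``: DataFrame indexed by combo_id, one column per sample_id.
    ``samples``: DataFrame indexed by sample_id with columns role, replicate.
    ``unassigned``: DataFrame indexed by sample_id with one column per
    unassigned-read category.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unassigned: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.unassigned is None:
            self.unassigned = pd.DataFrame(
                0, index=self.counts.columns, columns=list(UNASSIGNED_CATEGORIES)
            )
        bad = set(self.samples.index) ^ set(self.counts.columns)
        if bad:
            raise ValueError(f"sample sheet / count columns mismatch: {sorted(bad)}")
        for role in self.samples["role"]:
            if role not in SAMPLE_ROLES:
                raise ValueError(f"unknown sample role {role!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.samples.index[self.samples["role"] == role])

    def pooled(self, sample_ids: list[str], new_id: str, role: str = "screen_end") -> "CountTable":
        """Sum raw counts of several samples into a single pooled sample."""
        pooled = self.counts[sample_ids].sum(axis=1).to_frame(new_id)
        samples = pd.DataFrame({"role": [role], "replicate": [0]}, index=pd.Index([new_id], name="sample_id"))
        return CountTable(pooled, samples)

    @classmethod
    def single_sample(
        cls,
        counts: pd.Series,
        sample_id: str,
        role: str = "screen_end",
        replicate: int = 1,
        unassigned: dict[str, int] | None = None,
    ) -> "CountTable":
        frame = counts.to_frame(sample_id)
        samples = pd.DataFrame(
            {"role": [role], "replicate": [replicate]},
            index=pd.Index([sample_id], name="sample_id"),
        )
        table = cls(frame, samples)
        if unassigned:
            for k, v in unassigned.items():
                table.unassigned.loc[sample_id, k] = v
        return table

    @staticmethod
    def merge(tables: list["CountTable"]) -> "CountTable":
        counts = pd.concat([t.counts for t in tables], axis=1)
        samples = pd.concat([t.samples for t in tables], axis=0)
        merged = CountTable(counts, samples)
        merged.unassigned = pd.concat([t.unassigned for t in tables], axis=0)
        return merged


def _check_dna(seq: str, what: str) -> None:
    if not _READ_RE.match(seq):
        raise ValueError(f"{what} contains non-DNA characters: {seq!r}")


def locate_spacer(
    read: str, anchor: str, spacer_len: int, error_tolerance: float = 0.1
) -> str | None:
    """Extract the spacer following the best occurrence of a constant anchor.

    The anchor is located by infix (semi-global) alignment; an occurrence
    qualifies if its edit distance is <= floor(error_tolerance * len(anchor)).
    Returns the ``spacer_len`` bases immediately after the anchor, or None if
    no qualifying occurrence exists or the read is too short after it
    (untrimmed reads are discarded).
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    if not 0 <= error_tolerance < 0.5:
        raise ValueError("error_tolerance must be in [0, 0.5)")
    _check_dna(read, "read")
    _check_dna(anchor, "anchor")
    max_ed = math.floor(error_tolerance * len(anchor))
    res = edlib.align(anchor, read, mode="HW", task="locations", k=max_ed)
    if res["editDistance"] < 0:
        return None
    end = res["locations"][0][1]  # leftmost best occurrence, inclusive end
    spacer = read[end + 1 : end + 1 + spacer_len]
    if len(spacer) < spacer_len:
        return None
    return spacer


class SpacerIndex:
    """Exact + bounded-Hamming lookup over one position's spacers."""

    def __init__(self, spacer_to_guide: dict[str, str]):
        if not spacer_to_guide:
            raise ValueError("empty spacer index")
        lengths = {len(s) for s in spacer_to_guide}
        if len(lengths) != 1:
            raise ValueError(f"index spacers have mixed lengths {sorted(lengths)}")
        self.spacer_len = lengths.pop()
        self._exact = dict(spacer_to_guide)
        self._ids = list(spacer_to_guide.values())
        self._mat = np.frombuffer(
            "".join(spacer_to_guide).encode(), dtype=np.uint8
        ).reshape(len(spacer_to_guide), self.spacer_len)

    def lookup(self, spacer: str, max_mismatches: int = 1) -> str | None:
        """guide_id, None (no match) or AMBIGUOUS (tie at best distance)."""
        if len(spacer) != self.spacer_len:
            return None
        hit = self._exact.get(spacer)
        if hit is not None:
            return hit
        if max_mismatches == 0:
            return None
        q = np.frombuffer(spacer.encode(), dtype=np.uint8)
        dists = (self._mat != q).sum(axis=1)
        best = int(dists.min())
        if best > max_mismatches:
            return None
        winners = np.flatnonzero(dists == best)
        if len(winners) > 1:
            return AMBIGUOUS
        return self._ids[int(winners[0])]


def match_spacer(
    spacer: str, index: dict[str, str] | SpacerIndex, max_mismatches: int = 1
) -> str | None:
    """Match an extracted spacer against a position's library spacers.

    Exact match wins immediately; otherwise the unique guide within Hamming
    distance <= max_mismatches; AMBIGUOUS on a tie at the minimal qualifying
    distance; None (no_match) otherwise, including length mismatches.
    """
    if not isinstance(index, SpacerIndex):
        index = SpacerIndex(index)
    return index.lookup(spacer, max_mismatches)


def count_pairs(
    reads_pos1: Iterable[str],
    reads_pos2: Iterable[str],
    library: CombinatorialLibrary,
    anchor1: str,
    anchor2: str,
    *,
    error_tolerance: float = 0.1,
    max_mismatches: int = 1,
    sample_id: str = "sample",
    role: str = "screen_end",
    replicate: int = 1,
) -> CountTable:
    """Assign synchronized read pairs to library combinations.

    A pair is assigned iff both mates yield unambiguous guide matches and the
    (guide_a, guide_b) combination exists in the library.  Failed pairs are
    tallied once, under the strongest failing category in the order
    no_anchor < no_match < ambiguous < not_in_library (mate 1 breaking ties).
    """
    idx1 = SpacerIndex(library.spacer_index(1))
    idx2 = SpacerIndex(library.spacer_index(2))
    pairs = library.pair_set()
    counts: dict[tuple[str, str], int] = {}
    tallies = dict.fromkeys(UNASSIGNED_CATEGORIES, 0)

    def mate_status(read: str, anchor: str, idx: SpacerIndex) -> tuple[int, str | None]:
        spacer = locate_spacer(read, anchor, idx.spacer_len, error_tolerance)
        if spacer is None:
            return 0, None  # no_anchor
        gid = idx.lookup(spacer, max_mismatches)
        if gid is None:
            return 1, None  # no_match
        if gid == AMBIGUOUS:
            return 2, None  # ambiguous
        return 3, gid

    it1: Iterator[str] = iter(reads_pos1)
    it2: Iterator[str] = iter(reads_pos2)
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            break
        if r1 is None or r2 is None:
            raise ValueError("unsynchronized read streams: one mate file is truncated")
        s1, g1 = mate_status(r1, anchor1, idx1)
        s2, g2 = mate_status(r2, anchor2, idx2)
        worst = min(s1, s2)
        if worst < 3:
            tallies[UNASSIGNED_CATEGORIES[worst]] += 1
        elif (g1, g2) not in pairs:
            tallies["not_in_library"] += 1
        else:
            counts[(g1, g2)] = counts.get((g1, g2), 0) + 1

    vec = pd.Series(0, index=library.combo_ids, dtype=np.int64)
    if counts:
        key = pd.Series(
            counts.values(),
            index=[f"{a}__{b}" for a, b in counts.keys()],
        )
        vec.loc[key.index] = key.values
    return CountTable.single_sample(
        vec, sample_id, role=role, replicate=replicate, unassigned=tallies
    )


def nearest_rank_percentile(values: np.ndarray, p: float) -> float:
    """Nearest-rank percentile: the ceil(p*n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty vector")
    k = max(1, math.ceil(p * n))
    return float(v[k - 1])


def skew_ratio(counts: Iterable[float]) -> float | None:
    """Library skew P90/P10 (nearest-rank percentiles); None when P10 = 0.

    A skew below 2.5 is the conventional uniformity criterion for pooled
    CRISPR libraries.
    """
    v = np.asarray(list(counts), dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    if (v < 0).any():
        raise ValueError("negative counts")
    p10 = nearest_rank_percentile(v, 0.10)
    p90 = nearest_rank_percentile(v, 0.90)
    if p10 == 0:
        return None
    return p90 / p10


def lorenz_curve(counts: Iterable[float]) -> tuple[np.ndarray, np.ndarray]:
    """Lorenz curve of a count vector: cumulative read share vs combination share.

    Counts are sorted ascending; the curve starts at (0, 0) and ends at (1, 1).
    """
    v = np.sort(np.asarray(list(counts), dtype=float))
    if v.size == 0:
        raise ValueError("empty vector")
    if (v < 0).any():
        raise ValueError("negative counts")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no Lorenz curve")
    x = np.concatenate([[0.0], np.arange(1, v.size + 1) / v.size])
    y = np.concatenate([[0.0], np.cumsum(v) / total])
    return x, y


def lorenz_area(counts: Iterable[float]) -> float:
    """Area under the Lorenz curve (0.5 = perfectly uniform library)."""
    x, y = lorenz_curve(counts)
    return float(np.trapezoid(y, x))


@dataclass
class QcReport:
    """Per-sample library-uniformity QC."""

    per_sample: pd.DataFrame  # columns: skew, skew_defined, lorenz_area, n_zero, n_total
    lorenz: dict[str, tuple[np.ndarray, np.ndarray]]
    percentile_convention: str = "nearest-rank"

    def to_records(self) -> dict:
        out = {"percentile_convention": self.percentile_convention, "samples": {}}
        for sid, row in self.per_sample.iterrows():
            out["samples"][sid] = {
                "skew": None if not row["skew_defined"] else float(row["skew"]),
                "lorenz_area": float(row["lorenz_area"]),
                "n_zero": int(row["n_zero"]),
                "n_total": int(row["n_total"]),
            }
        return out


def qc_report(table: CountTable) -> QcReport:
    rows = []
    curves = {}
    for sid in table.sample_ids:
        v = table.counts[sid].to_numpy(dtype=float)
        skew = skew_ratio(v)
        curves[sid] = lorenz_curve(v)
        rows.append(
            {
                "sample_id": sid,
                "skew": np.nan if skew is None else skew,
                "skew_defined": skew is not None,
                "lorenz_area": lorenz_area(v),
                "n_zero": int((v == 0).sum()),
                "n_total": v.size,
            }
        )
    frame = pd.DataFrame(rows).set_index("sample_id")
    return QcReport(frame, curves)
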