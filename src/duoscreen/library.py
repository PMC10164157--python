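"""Guide libraries for dual-cassette combinatorial CRISPR screens.

A combinatorial library is the cross product of two ordered guide lists, one
per expression cassette (position 1 = h7SK cassette or first hybrid guide,
position 2 = hU6 cassette or second guide).  Guides target core-essential
(CE) genes, tumor-suppressor (TS) genes, or nothing (NHT, non-human-targeting
controls), and every guide pair carries a derived pair class
(CE-CE, TS-TS, CE-TS, NHT-CE, NHT-TS, NHT-NHT).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

NUCLEASES = ("SpCas9", "AsCas12a")

#: spacer length enforced per nuclease
SPACER_LEN = {"SpCas9": 20, "AsCas12a": 23}

GENE_CLASSES = ("CE", "TS", "NHT")

PAIR_CLASSES = ("CE-CE", "TS-TS", "CE-TS", "NHT-CE", "NHT-TS", "NHT-NHT")

_DNA_RE = re.compile(r"^[ACGT]+$")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class GuideRecord:
    """One gRNA: identifier, nuclease, spacer and target annotation.

    ``rank`` is the design rank of the guide for its gene (1 = best);
    ``pam_context`` is the 4-nt upstream PAM for AsCas12a guides, when known.
    """

    guide_id: str
    nuclease: str
    spacer: str
    gene: str
    gene_class: str
    rank: int | None = None
    pam_context: str | None = None

    def __post_init__(self) -> None:
        if self.nuclease not in NUCLEASES:
            raise ValueError(f"unknown nuclease {self.nuclease!r} for guide {self.guide_id}")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene_class {self.gene_class!r} for guide {self.guide_id}")
        if not _DNA_RE.match(self.spacer):
            raise ValueError(f"guide {self.guide_id}: spacer is not plain DNA: {self.spacer!r}")
        want = SPACER_LEN[self.nuclease]
        if len(self.spacer) != want:
            raise ValueError(
                f"guide {self.guide_id}: {self.nuclease} spacer must be {want} nt, "
                f"got {len(self.spacer)}"
            )
        if (self.gene == "NHT") != (self.gene_class == "NHT"):
            raise ValueError(
                f"guide {self.guide_id}: gene == 'NHT' must hold exactly for gene_class NHT"
            )
        if self.pam_context is not None and not _DNA_RE.match(self.pam_context):
            raise ValueError(f"guide {self.guide_id}: bad pam_context {self.pam_context!r}")


@dataclass(frozen=True)
class LibraryDesign:
    """A named dual-cassette vector design.

    ``processing_penalty_defaults`` are the per-position activity multipliers
    in [0, 1] used by the simulator; hybrid-transcript (CHyMErA-type) designs
    carry penalties < 1 because guide release requires Cas12a RNA processing.
    ``dual_gene_arrays`` marks designs whose cassettes carry two guides
    against the same gene (arrayed dual-gRNAs).
    """

    name: str
    cassette1_nuclease: str
    cassette2_nuclease: str
    dual_gene_arrays: bool = False
    hybrid_transcript: bool = False
    processing_penalty_defaults: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        for nuc in (self.cassette1_nuclease, self.cassette2_nuclease):
            if nuc not in NUCLEASES:
                raise ValueError(f"design {self.name}: unknown nuclease {nuc!r}")
        for p in self.processing_penalty_defaults:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"design {self.name}: processing penalty {p} outside [0, 1]")

    @property
    def spacer_lengths(self) -> tuple[int, int]:
        return (SPACER_LEN[self.cassette1_nuclease], SPACER_LEN[self.cassette2_nuclease])


#: the six screen designs compared in this package
DESIGNS: dict[str, LibraryDesign] = {
    d.name: d
    for d in (
        LibraryDesign("SpCas9", "SpCas9", "SpCas9",
                      processing_penalty_defaults=(1.0, 1.0)),
        LibraryDesign("enAsCas12a", "AsCas12a", "AsCas12a",
                      processing_penalty_defaults=(0.9, 0.9)),
        LibraryDesign("CHyMErA", "SpCas9", "AsCas12a", hybrid_transcript=True,
                      processing_penalty_defaults=(0.25, 0.6)),
        LibraryDesign("enAsCas12a_dual", "AsCas12a", "AsCas12a", dual_gene_arrays=True,
                      processing_penalty_defaults=(0.75, 0.75)),
        LibraryDesign("CHyMErA_v2", "SpCas9", "AsCas12a", hybrid_transcript=True,
                      dual_gene_arrays=True,
                      processing_penalty_defaults=(0.42, 0.95)),
        LibraryDesign("multiSPAS", "SpCas9", "AsCas12a",
                      processing_penalty_defaults=(1.0, 0.9)),
    )
}


def get_design(name: str) -> LibraryDesign:
    try:
        return DESIGNS[name]
    except KeyError:
        raise ValueError(f"unknown design {name!r}; known: {sorted(DESIGNS)}") from None


def classify_pair(class_a: str, class_b: str) -> str:
    """Pair class of two gene classes; symmetric in the unordered pair."""
    for c in (class_a, class_b):
        if c not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {c!r}")
    a, b = sorted((class_a, class_b), key=GENE_CLASSES.index)
    if a == b:
        return f"{a}-{b}"
    if a == "NHT" or b == "NHT":
        target = a if b == "NHT" else b
        return f"NHT-{target}"
    return "CE-TS"


def pam_filter(
    guides: list[GuideRecord], pattern: str, *, with_counts: bool = False
) -> list[GuideRecord] | tuple[list[GuideRecord], dict[str, int]]:
    """Subset guides whose ``pam_context`` matches an IUPAC pattern.

    Guides lacking a ``pam_context`` are excluded (and counted when
    ``with_counts``).  Matching is position-wise over the IUPAC alphabet,
    e.g. pattern ``"TTTV"`` retains TTTA/TTTC/TTTG but not TTTT.
    """
    for code in pattern:
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} in pattern {pattern!r}")
    kept: list[GuideRecord] = []
    n_missing = 0
    n_unmatched = 0
    for g in guides:
        if g.pam_context is None:
            n_missing += 1
            continue
        ctx = g.pam_context
        if len(ctx) == len(pattern) and all(b in IUPAC[c] for b, c in zip(ctx, pattern)):
            kept.append(g)
        else:
            n_unmatched += 1
    if with_counts:
        return kept, {"no_pam_context": n_missing, "unmatched": n_unmatched}
    return kept


@dataclass(frozen=True)
class Combination:
    """An ordered guide pair (position 1, position 2) with its pair class."""

    combo_id: str
    guide_a: GuideRecord
    guide_b: GuideRecord
    pair_class: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pair_class", classify_pair(self.guide_a.gene_class, self.guide_b.gene_class)
        )


def combo_id(guide_a_id: str, guide_b_id: str) -> str:
    return f"{guide_a_id}__{guide_b_id}"


@dataclass
class CombinatorialLibrary:
    """Full cross product of two per-position guide lists for one design.

    ``combos`` is a DataFrame indexed by combo_id with columns
    guide_a, guide_b, gene_a, gene_b, class_a, class_b, pair_class.
    """

    design: LibraryDesign
    guides_pos1: list[GuideRecord]
    guides_pos2: list[GuideRecord]
    combos: pd.DataFrame

    @property
    def n_combinations(self) -> int:
        return len(self.combos)

    @property
    def combo_ids(self) -> pd.Index:
        return self.combos.index

    def class_counts(self) -> pd.Series:
        return self.combos["pair_class"].value_counts()

    def spacer_index(self, position: int) -> dict[str, str]:
        """spacer -> guide_id map for one position (1 or 2)."""
        guides = self.guides_pos1 if position == 1 else self.guides_pos2
        return {g.spacer: g.guide_id for g in guides}

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.combos["guide_a"], self.combos["guide_b"]))

    def genes(self, gene_class: str | None = None) -> list[str]:
        """Distinct non-NHT target genes, optionally restricted to a class."""
        out: list[str] = []
        for g in [*self.guides_pos1, *self.guides_pos2]:
            if g.gene == "NHT":
                continue
            if gene_class is not None and g.gene_class != gene_class:
                continue
            if g.gene not in out:
                out.append(g.gene)
        return out

    def nht_nht_ids(self) -> pd.Index:
        return self.combos.index[self.combos["pair_class"] == "NHT-NHT"]


def _check_position(guides: list[GuideRecord], nuclease: str, position: int) -> None:
    if not guides:
        raise ValueError(f"position {position}: empty guide list")
    seen: dict[str, str] = {}
    dups: list[str] = []
    for g in guides:
        if g.nuclease != nuclease:
            raise ValueError(
                f"position {position}: guide {g.guide_id} is {g.nuclease}, "
                f"design cassette expects {nuclease}"
            )
        if g.spacer in seen:
            dups.append(f"{seen[g.spacer]}/{g.guide_id}")
        else:
            seen[g.spacer] = g.guide_id
    if dups:
        raise ValueError(f"position {position}: duplicate spacers between guides {', '.join(dups)}")
    ids = [g.guide_id for g in guides]
    if len(set(ids)) != len(ids):
        raise ValueError(f"position {position}: guide_ids not unique")


def build_library(
    guides_pos1: list[GuideRecord],
    guides_pos2: list[GuideRecord],
    design: LibraryDesign | str,
) -> CombinatorialLibrary:
    """Build the full cross-product library |pos1| x |pos2|.

    Raises on duplicate spacers within a position or on spacers whose length
    does not match the cassette nuclease (the GuideRecord constructor enforces
    the per-nuclease length; here cassette/nuclease consistency is enforced).
    """
    if isinstance(design, str):
        design = get_design(design)
    _check_position(guides_pos1, design.cassette1_nuclease, 1)
    _check_position(guides_pos2, design.cassette2_nuclease, 2)

    a = pd.DataFrame(
        {
            "guide_a": [g.guide_id for g in guides_pos1],
            "gene_a": [g.gene for g in guides_pos1],
            "class_a": [g.gene_class for g in guides_pos1],
        }
    )
    b = pd.DataFrame(
        {
            "guide_b": [g.guide_id for g in guides_pos2],
            "gene_b": [g.gene for g in guides_pos2],
            "class_b": [g.gene_class for g in guides_pos2],
        }
    )
    combos = a.merge(b, how="cross")
    combos.index = pd.Index(
        [combo_id(x, y) for x, y in zip(combos["guide_a"], combos["guide_b"])],
        name="combo_id",
    )
    if combos.index.has_duplicates:
        raise ValueError("combo_ids not unique; check guide_id uniqueness across positions")
    pair_lut = {
        (ca, cb): classify_pair(ca, cb) for ca in GENE_CLASSES for cb in GENE_CLASSES
    }
    combos["pair_class"] = [
        pair_lut[(ca, cb)] for ca, cb in zip(combos["class_a"], combos["class_b"])
    ]
    return CombinatorialLibrary(design, list(guides_pos1), list(guides_pos2), combos)


def dual_rank_pairs(ranks: list[int]) -> list[tuple[int, int]]:
    """Rank pairing for arrayed dual-gRNA designs: (1,4) and (2,3)."""
    if sorted(ranks) != [1, 2, 3, 4]:
        raise ValueError("dual-array pairing is defined for ranks 1..4")
    return [(1, 4), (2, 3)]
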