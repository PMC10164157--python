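import itertools

import pytest

from duoscreen.library import SPACER_LEN, GuideRecord, build_library, get_design

_BASES = "ACGT"


def spacer(i: int, length: int) -> str:
    """Deterministic unique spacer: base-4 expansion of i padded to length."""
    digits = []
    while i:
        digits.append(_BASES[i % 4])
        i //= 4
    return "".join(digits).ljust(length, "A")[::-1]


_counter = itertools.count(1)


def mk_guide(gene, gene_class, nuclease="SpCas9", guide_id=None, rank=None, pam=None, idx=None):
    i = next(_counter) if idx is None else idx
    return GuideRecord(
        guide_id=guide_id or f"g{i:04d}",
        nuclease=nuclease,
        spacer=spacer(i, SPACER_LEN[nuclease]),
        gene=gene,
        gene_class=gene_class,
        rank=rank,
        pam_context=pam,
    )


def tiny_guides(n_ce=1, n_ts=1, n_nht=1, nuclease="SpCas9", prefix="p"):
    guides = []
    for i in range(n_ce):
        guides.append(mk_guide(f"CE{i+1:02d}", "CE", nuclease, guide_id=f"{prefix}_ce{i+1}"))
    for i in range(n_ts):
        guides.append(mk_guide(f"TS{i+1:02d}", "TS", nuclease, guide_id=f"{prefix}_ts{i+1}"))
    for i in range(n_nht):
        guides.append(mk_guide("NHT", "NHT", nuclease, guide_id=f"{prefix}_nht{i+1}"))
    return guides


@pytest.fixture
def tiny_library():
    """2 CE + 1 TS + 2 NHT guides per position, SpCas9 design (5x5 = 25)."""
    g1 = tiny_guides(n_ce=2, n_ts=1, n_nht=2, prefix="a")
    g2 = tiny_guides(n_ce=2, n_ts=1, n_nht=2, prefix="b")
    return build_library(g1, g2, get_design("SpCas9"))
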