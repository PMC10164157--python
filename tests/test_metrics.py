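"""Normalization, LFC math, aggregation and screen summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duoscreen.library import build_library
from duoscreen.metrics import (
    class_summary,
    correlate,
    effect_size_range,
    gene_pair_lfc,
    guide_lfc,
    normalize,
    screen_lfc,
    single_guide_lfc,
)
from duoscreen.quantify import CountTable

from conftest import tiny_guides


def make_table(values: dict[str, list], combo_ids, roles=None) -> CountTable:
    counts = pd.DataFrame(values, index=pd.Index(combo_ids, name="combo_id"))
    roles = roles or {s: ("library_reference" if s == "ref" else "screen_end") for s in values}
    samples = pd.DataFrame(
        {
            "role": [roles[s] for s in values],
            "replicate": list(range(len(values))),
        },
        index=pd.Index(list(values), name="sample_id"),
    )
    return CountTable(counts, samples)


@pytest.fixture
def lib4():
    """2x2 library: one CE guide + one NHT guide per position."""
    return build_library(
        tiny_guides(n_ce=1, n_ts=0, n_nht=1, prefix="a"),
        tiny_guides(n_ce=1, n_ts=0, n_nht=1, prefix="b"),
        "SpCas9",
    )


class TestNormalize:
    def test_hand_example(self, lib4):
        # A=CE-CE:10, B=NHT-CE:30, N1/N2 ... only NHT-NHT combo is a_nht1__b_nht1
        ids = ["a_ce1__b_ce1", "a_ce1__b_nht1", "a_nht1__b_ce1", "a_nht1__b_nht1"]
        table = make_table({"s": [10, 30, 20, 40]}, ids, roles={"s": "screen_end"})
        # totals-normalized: (.1, .3, .2, .4); NHT-NHT median = .4
        norm = normalize(table, lib4)
        assert np.allclose(norm.values["s"], [0.25, 0.75, 0.5, 1.0])

    def test_two_nht_combos_hand_arithmetic(self):
        lib = build_library(
            tiny_guides(n_ce=1, n_ts=0, n_nht=1, prefix="a"),
            tiny_guides(n_ce=1, n_ts=0, n_nht=2, prefix="b"),
        "SpCas9",
        )
        ids = list(lib.combo_ids)
        # (A, B, N1, N2) = (10, 30, 20, 40) with NHT-NHT = {a_nht1__b_nht1, a_nht1__b_nht2}
        vals = {
            "a_ce1__b_ce1": 10, "a_ce1__b_nht1": 30, "a_ce1__b_nht2": 0,
            "a_nht1__b_ce1": 0, "a_nht1__b_nht1": 20, "a_nht1__b_nht2": 40,
        }
        table = make_table({"s": [vals[i] for i in ids]}, ids, roles={"s": "screen_end"})
        norm = normalize(table, lib)
        got = norm.values["s"]
        # rel = count/100; NHT-NHT median = (0.2 + 0.4)/2 = 0.3
        assert got["a_ce1__b_ce1"] == pytest.approx(1 / 3)
        assert got["a_ce1__b_nht1"] == pytest.approx(1.0)
        assert got["a_nht1__b_nht1"] == pytest.approx(2 / 3)
        assert got["a_nht1__b_nht2"] == pytest.approx(4 / 3)

    def test_constant_nht_normalizes_to_one(self, lib4):
        ids = list(lib4.combo_ids)
        table = make_table({"s": [5, 17, 99, 12]}, ids, roles={"s": "screen_end"})
        norm = normalize(table, lib4)
        assert norm.values.loc[lib4.nht_nht_ids(), "s"].median() == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None)
    @given(counts=st.lists(st.integers(1, 500), min_size=4, max_size=4), k=st.integers(2, 9))
    def test_scale_invariance_and_nht_median_one(self, counts, k):
        lib4 = build_library(
            tiny_guides(n_ce=1, n_ts=0, n_nht=1, prefix="a"),
            tiny_guides(n_ce=1, n_ts=0, n_nht=1, prefix="b"),
            "SpCas9",
        )
        ids = list(lib4.combo_ids)
        t1 = make_table({"s": counts}, ids, roles={"s": "screen_end"})
        t2 = make_table({"s": [k * c for c in counts]}, ids, roles={"s": "screen_end"})
        n1 = normalize(t1, lib4)
        n2 = normalize(t2, lib4)
        assert np.allclose(n1.values, n2.values)
        assert n1.values.loc[lib4.nht_nht_ids(), "s"].median() == pytest.approx(1.0)

    def test_idempotent_on_own_output(self, lib4):
        ids = list(lib4.combo_ids)
        table = make_table({"s": [12, 7, 31, 4]}, ids, roles={"s": "screen_end"})
        norm = normalize(table, lib4)
        renorm_counts = CountTable(norm.values, table.samples)
        renorm = normalize(renorm_counts, lib4)
        assert np.allclose(renorm.values, norm.values)

    def test_zero_total_rejected(self, lib4):
        table = make_table({"s": [0, 0, 0, 0]}, list(lib4.combo_ids), roles={"s": "screen_end"})
        with pytest.raises(ValueError, match="total read count is zero"):
            normalize(table, lib4)

    def test_zero_nht_median_names_sample(self, lib4):
        table = make_table({"bad": [5, 5, 5, 0]}, list(lib4.combo_ids), roles={"bad": "screen_end"})
        with pytest.raises(ValueError, match="bad"):
            normalize(table, lib4)


class TestGuideLfc:
    def _norm(self, lib, values):
        table = make_table(values, list(lib.combo_ids))
        return normalize(table, lib)

    def test_self_comparison_is_zero(self, lib4):
        norm = self._norm(lib4, {"ref": [10, 20, 30, 40], "end": [10, 20, 30, 40]})
        lfc = guide_lfc(norm, "end", "ref")
        assert np.allclose(lfc.lfc, 0.0)

    def test_log2_ratio(self):
        assert float(np.log2((8.0) / (2.0))) == 2.0  # sanity of frozen expectation
        lib = build_library(
            tiny_guides(n_ce=1, n_ts=0, n_nht=1, prefix="a"),
            tiny_guides(n_ce=1, n_ts=0, n_nht=1, prefix="b"),
            "SpCas9",
        )
        # equal NHT-NHT counts keep normalization factors identical across samples
        norm = self._norm(lib, {"ref": [2, 5, 5, 10], "end": [8, 5, 5, 10]})
        lfc = guide_lfc(norm, "end", "ref", pseudocount=0)
        assert lfc.lfc["a_ce1__b_ce1"] == pytest.approx(2.0)

    def test_pseudocount_on_zero(self, lib4):
        norm_vals = pd.DataFrame(
            {"ref": [1.0, 1, 1, 1], "end": [0.0, 1, 1, 1]},
            index=lib4.combo_ids,
        )
        from duoscreen.metrics import _lfc_one

        out = _lfc_one(norm_vals["end"], norm_vals["ref"], 0.5, "on_zero")
        assert out.iloc[0] == pytest.approx(np.log2(0.5 / 1.5), abs=5e-4)  # -1.585
        assert np.allclose(out.iloc[1:], 0)  # untouched where no zero

    def test_replicate_mean_vs_median(self, lib4):
        norm = self._norm(lib4, {"ref": [4, 4, 4, 4], "r1": [4, 4, 4, 4], "r2": [16, 4, 4, 4]})
        mean_lfc = guide_lfc(norm, ["r1", "r2"], "ref", replicate_agg="mean").lfc
        med_lfc = guide_lfc(norm, ["r1", "r2"], "ref", replicate_agg="median").lfc
        # per-replicate LFCs for the first combo are 0 and 2 (before NHT refit)
        assert mean_lfc.iloc[0] == pytest.approx(med_lfc.iloc[0])

    def test_unknown_sample_rejected(self, lib4):
        norm = self._norm(lib4, {"ref": [1, 1, 1, 1], "end": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="not in table"):
            guide_lfc(norm, "nope", "ref")


class TestGenePairAggregation:
    def test_odd_median(self):
        frame = pd.DataFrame(
            {
                "lfc": [-1.0, -2.0, -3.0],
                "gene_a": "CE01",
                "gene_b": "CE02",
                "pair_class": "CE-CE",
            },
            index=["c1", "c2", "c3"],
        )
        from duoscreen.metrics import LFCTable

        gp = gene_pair_lfc(LFCTable(frame))
        assert gp.frame.loc[("CE01", "CE02"), "lfc"] == -2.0
        assert gp.frame.loc[("CE01", "CE02"), "n_guide_pairs"] == 3

    def test_sixteen_values_median(self):
        frame = pd.DataFrame(
            {
                "lfc": list(range(1, 17)),
                "gene_a": "CE01",
                "gene_b": "TS01",
                "pair_class": "CE-TS",
            },
            index=[f"c{i}" for i in range(16)],
        )
        from duoscreen.metrics import LFCTable

        gp = gene_pair_lfc(LFCTable(frame))
        assert gp.frame.loc[("CE01", "TS01"), "lfc"] == 8.5

    def test_permutation_invariance(self):
        from duoscreen.metrics import LFCTable

        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                "lfc": rng.normal(size=12),
                "gene_a": ["CE01"] * 6 + ["TS01"] * 6,
                "gene_b": "NHT",
                "pair_class": ["NHT-CE"] * 6 + ["NHT-TS"] * 6,
            },
            index=[f"c{i}" for i in range(12)],
        )
        gp1 = gene_pair_lfc(LFCTable(frame))
        gp2 = gene_pair_lfc(LFCTable(frame.sample(frac=1, random_state=7)))
        pd.testing.assert_frame_equal(gp1.frame, gp2.frame)

    def test_single_guide_identity(self, lib4):
        table = make_table({"ref": [4, 4, 4, 4], "end": [1, 4, 4, 4]}, list(lib4.combo_ids))
        lfc = screen_lfc(table, lib4)
        gp = gene_pair_lfc(lfc)
        assert gp.frame.loc[("CE01", "CE01"), "lfc"] == pytest.approx(lfc.lfc["a_ce1__b_ce1"])


class TestEffectSizeRange:
    def test_examples(self):
        assert effect_size_range([-4, 0, 3]) == 7.0
        assert effect_size_range([2.5] * 5) == 0.0

    @settings(max_examples=30, deadline=None)
    @given(
        values=st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        c=st.floats(-10, 10),
        a=st.floats(0.1, 10),
    )
    def test_shift_invariance_scale_equivariance(self, values, c, a):
        v = np.array(values)
        assert effect_size_range(v + c) == pytest.approx(effect_size_range(v), abs=1e-9)
        assert effect_size_range(a * v) == pytest.approx(a * effect_size_range(v), rel=1e-9, abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            effect_size_range([1.0, np.nan])


class TestClassSummary:
    def test_hand_example(self):
        out = class_summary([1, 2, 6], ["x", "x", "x"])
        assert out.loc["x", "mean"] == 3.0
        assert out.loc["x", "median"] == 2.0
        assert out.loc["x", "n"] == 3

    def test_constant_class(self):
        out = class_summary([-4.29] * 8, ["CE"] * 8)
        assert out.loc["CE", "mean"] == pytest.approx(-4.29)


class TestSingleGuideLfc:
    def _lfc_table(self, lib, lfc_map):
        from duoscreen.metrics import LFCTable

        frame = lib.combos.copy()
        frame["lfc"] = [lfc_map.get(i, 0.0) for i in frame.index]
        return LFCTable(frame)

    def test_constant_partner_lfc(self, lib4):
        lfc = self._lfc_table(lib4, {"a_ce1__b_nht1": -2.0})
        out = single_guide_lfc(lfc, 1)
        assert out.loc["a_ce1", "lfc"] == -2.0

    def test_nht_guides_excluded(self, lib4):
        out = single_guide_lfc(self._lfc_table(lib4, {}), 1)
        assert "a_nht1" not in out.index

    def test_even_count_median(self):
        lib = build_library(
            tiny_guides(n_ce=1, n_ts=0, n_nht=4, prefix="a"),
            tiny_guides(n_ce=1, n_ts=0, n_nht=4, prefix="b"),
            "SpCas9",
        )
        vals = {"a_ce1__b_nht1": -1.0, "a_ce1__b_nht2": -3.0,
                "a_ce1__b_nht3": 0.0, "a_ce1__b_nht4": -2.0}
        out = single_guide_lfc(self._lfc_table(lib, vals), 1)
        assert out.loc["a_ce1", "lfc"] == -1.5
        assert out.loc["a_ce1", "n"] == 4


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        out = correlate(x, 2 * x + 1)
        assert out.r == pytest.approx(1.0)
        assert out.slope == pytest.approx(2.0)
        assert out.intercept == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.arange(5.0)
        assert correlate(x, -x).r == pytest.approx(-1.0)

    def test_spearman_hand_example(self):
        out = correlate([1, 2, 3, 4], [1, 3, 2, 4], method="spearman")
        assert out.r == pytest.approx(0.8)

    def test_zero_variance_flagged(self):
        out = correlate([1, 2, 3], [5, 5, 5])
        assert out.r is None and not out.defined

    def test_non_finite_pairs_dropped(self):
        out = correlate([1, 2, 3, np.nan], [2, 4, 6, 1])
        assert out.n == 3 and out.n_dropped == 1
        assert out.r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            correlate([1, 2], [3, 4])
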