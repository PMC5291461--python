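"""β arithmetic, QC filtering, differential/sequential calling and
subcategory summaries, with brute-force oracles for the aggregate outputs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senemeth import methylome as me
from senemeth.array_io import BetaMatrix, ProbeAnnotation
from senemeth.errors import ValidationError


def _bm(beta: dict, detp: dict | None = None) -> BetaMatrix:
    beta_df = pd.DataFrame(beta).T
    detp_df = (pd.DataFrame(detp).T if detp is not None
               else pd.DataFrame(0.01, index=beta_df.index, columns=beta_df.columns))
    return BetaMatrix(beta=beta_df, detection_p=detp_df)


class TestBetaFromIntensities:
    def test_formula_examples(self):
        assert me.beta_from_intensities(400, 500) == pytest.approx(0.4)
        assert me.beta_from_intensities(0, 12345) == 0.0
        assert me.beta_from_intensities(900, 0) == pytest.approx(0.9)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError):
            me.beta_from_intensities(-1, 10)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0, max_value=1e9),
           st.floats(min_value=0, max_value=1e9))
    def test_beta_always_in_unit_interval(self, m, u):
        b = me.beta_from_intensities(m, u)
        assert 0.0 <= b < 1.0


class TestFilterProbes:
    def test_any_sample_failure_removes_probe(self):
        bm = _bm({"p1": {"a": 0.5, "b": 0.5}, "p2": {"a": 0.5, "b": 0.5}},
                 {"p1": {"a": 0.01, "b": 0.06}, "p2": {"a": 0.01, "b": 0.05}})
        out = me.filter_probes(bm)
        assert list(out.probe_ids) == ["p2"]  # p=0.05 exactly is retained

    def test_missing_beta_removes_probe(self):
        bm = _bm({"p1": {"a": np.nan, "b": 0.5}, "p2": {"a": 0.2, "b": 0.5}})
        assert list(me.filter_probes(bm).probe_ids) == ["p2"]

    def test_survivor_count_matches_planted_failures(self, study):
        filtered = me.filter_probes(study.beta)
        detp = study.beta.detection_p
        k = int((detp > 0.05).any(axis=1).sum())
        assert len(filtered.probe_ids) == len(study.beta.probe_ids) - k


class TestCallDifferential:
    @pytest.mark.parametrize("b0,b1,expected", [
        (0.5, 0.8, "hyper"),   # above threshold
        (0.5, 0.7, "hyper"),   # boundary inclusive
        (0.5, 0.31, "none"),   # below magnitude
        (0.5, 0.3, "hypo"),    # boundary inclusive, negative side
    ])
    def test_thresholds(self, b0, b1, expected):
        bm = _bm({"p": {"c": b0, "t": b1}})
        calls = me.call_differential(bm, "t", "c")
        assert calls.loc["p", "call"] == expected

    def test_antisymmetry_under_contrast_swap(self, study):
        filtered = me.filter_probes(study.beta)
        fwd = me.call_differential(filtered, "PDL85", "PDL36")
        rev = me.call_differential(filtered, "PDL36", "PDL85")
        assert np.allclose(fwd["delta_beta"], -rev["delta_beta"])
        assert (fwd["call"] == "hyper").sum() == (rev["call"] == "hypo").sum()
        assert (fwd["call"] == "hypo").sum() == (rev["call"] == "hyper").sum()

    def test_partition_conserved(self, result):
        calls = result.meth_calls
        assert len(calls) == len(result.filtered_beta.probe_ids)
        assert calls["call"].isin(["hyper", "hypo", "none"]).all()


class TestSequential:
    def test_monotone_and_dipping_series(self):
        bm = _bm({"mono": {"a": 0.2, "b": 0.3, "c": 0.5, "d": 0.6},
                  "dip": {"a": 0.2, "b": 0.5, "c": 0.4, "d": 0.6}})
        calls = me.call_differential(bm, "d", "a")
        flags = me.classify_sequential(bm, calls, ["a", "b", "c", "d"])
        assert flags["mono"] is True or flags["mono"] == True  # noqa: E712
        assert flags["dip"] == False  # noqa: E712

    def test_uncalled_probes_flagged_na(self):
        bm = _bm({"flat": {"a": 0.5, "b": 0.5, "c": 0.5}})
        calls = me.call_differential(bm, "c", "a")
        flags = me.classify_sequential(bm, calls, ["a", "b", "c"])
        assert pd.isna(flags["flat"])

    def test_needs_three_passages(self):
        bm = _bm({"p": {"a": 0.1, "b": 0.4}})
        calls = me.call_differential(bm, "b", "a")
        with pytest.raises(ValidationError):
            me.classify_sequential(bm, calls, ["a", "b"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_comparison_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, labels = 200, ["s0", "s1", "s2", "s3"]
        beta = rng.random((n, 4))
        beta[: n // 3] = np.sort(beta[: n // 3], axis=1)        # monotone up
        beta[n // 3: 2 * n // 3] = np.sort(
            beta[n // 3: 2 * n // 3], axis=1)[:, ::-1]          # monotone down
        bm = BetaMatrix(
            beta=pd.DataFrame(beta, index=[f"p{i}" for i in range(n)], columns=labels),
            detection_p=pd.DataFrame(0.01, index=[f"p{i}" for i in range(n)],
                                     columns=labels))
        calls = me.call_differential(bm, "s3", "s0")
        flags = me.classify_sequential(bm, calls, labels)
        for pid in calls.index:
            series = bm.beta.loc[pid].to_numpy()
            call = calls.loc[pid, "call"]
            if call == "hyper":
                expected = all(series[i + 1] >= series[i] for i in range(3))
            elif call == "hypo":
                expected = all(series[i + 1] <= series[i] for i in range(3))
            else:
                assert pd.isna(flags[pid])
                continue
            assert bool(flags[pid]) == expected


class TestSubcategorySummary:
    def _toy(self):
        contexts = ["Island"] * 10 + ["OpenSea"] * 5
        probes = pd.DataFrame({
            "chrom": "chr1", "pos": range(15), "strand": "+",
            "cpg_context": contexts,
        }, index=pd.Index([f"p{i}" for i in range(15)], name="probe_id"))
        gf = pd.DataFrame({"probe_id": ["p0", "p0"], "gene": ["G1", "G2"],
                           "feature": ["TSS200", "Body"]})
        ann = ProbeAnnotation(probes=probes, gene_features=gf)
        calls = pd.DataFrame({
            "delta_beta": [0.3] * 4 + [-0.3] + [0.0] * 10,
            "call": ["hyper"] * 4 + ["hypo"] + ["none"] * 10,
        }, index=probes.index)
        return ann, calls

    def test_direct_counts_and_ratio(self):
        ann, calls = self._toy()
        out = me.summarize_subcategories(calls, ann)["cpg_context"]
        assert out.loc["Island", "hyper_rate"] == pytest.approx(0.4)
        assert out.loc["Island", "hypo_rate"] == pytest.approx(0.1)
        assert out.loc["Island", "ratio"] == pytest.approx(4.0)
        # context axis counts each probe exactly once
        assert out["total"].sum() == len(calls)

    def test_multi_gene_probe_counts_once_per_feature(self):
        ann, calls = self._toy()
        out = me.summarize_subcategories(calls, ann)["gene_feature"]
        assert out.loc["TSS200", "hyper"] == 1
        assert out.loc["Body", "hyper"] == 1
        assert out.loc["Intergenic", "total"] == 14

    def test_no_calls_gives_missing_ratios(self):
        ann, calls = self._toy()
        calls["call"] = "none"
        out = me.summarize_subcategories(calls, ann)["cpg_context"]
        assert out["ratio"].isna().all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_group_by_oracle(self, seed, study, result):
        del seed  # the fixture already randomises context/feature placement
        out = me.summarize_subcategories(result.meth_calls, study.annotation)
        calls = result.meth_calls
        ann = study.annotation
        for ctx in ["Island", "OpenSea", "N_Shore"]:
            members = ann.probes.index[ann.probes["cpg_context"] == ctx]
            members = members.intersection(calls.index)
            expected_hyper = int((calls.loc[members, "call"] == "hyper").sum())
            assert out["cpg_context"].loc[ctx, "hyper"] == expected_hyper
            assert out["cpg_context"].loc[ctx, "total"] == len(members)


class TestScatterStats:
    def test_perfect_positive_and_negative(self):
        a = pd.Series([0.1, 0.4, 0.8], index=list("xyz"))
        assert me.beta_scatter_stats(a, a) == pytest.approx(1.0)
        assert me.beta_scatter_stats(a, 1 - a) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        a = pd.Series(rng.random(50))
        b = pd.Series(rng.random(50))
        n = len(a)
        num = (n * (a * b).sum() - a.sum() * b.sum())
        den = np.sqrt(n * (a ** 2).sum() - a.sum() ** 2) * \
            np.sqrt(n * (b ** 2).sum() - b.sum() ** 2)
        assert me.beta_scatter_stats(a, b) == pytest.approx((num / den) ** 2)

    def test_constant_vector_rejected(self):
        a = pd.Series([0.5, 0.5, 0.5])
        with pytest.raises(ValidationError):
            me.beta_scatter_stats(a, pd.Series([0.1, 0.2, 0.3]))
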