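"""Nearest-TSS mapping, joint methylation-expression calls, distance
histograms and functional-group cross-tabulation against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from senemeth import integration as ig


def _probes(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions},
                        index=pd.Index([f"p{i}" for i in range(len(positions))],
                                       name="probe_id"))


def _genes(tss_list, chrom="chr1", ids=None):
    ids = ids or [f"NM_{i:03d}" for i in range(len(tss_list))]
    return pd.DataFrame({"gene_id": ids, "chrom": chrom, "tss": tss_list})


class TestNearestTss:
    def test_maps_to_closest_within_window(self):
        mapped = ig.map_probes_to_nearest_tss(_probes([1000]), _genes([5000, 12000]))
        assert mapped.loc["p0", "gene_id"] == "NM_000"
        assert mapped.loc["p0", "distance"] == 4000

    def test_beyond_window_unmapped(self):
        mapped = ig.map_probes_to_nearest_tss(_probes([20000]), _genes([11000]))
        assert len(mapped) == 0

    def test_exact_window_boundary_is_mapped(self):
        mapped = ig.map_probes_to_nearest_tss(_probes([8000]), _genes([0]))
        assert mapped.loc["p0", "distance"] == 8000

    def test_tie_breaks_to_smallest_gene_id(self):
        genes = _genes([1000, 3000], ids=["NM_ZZZ", "NM_AAA"])
        mapped = ig.map_probes_to_nearest_tss(_probes([2000]), genes)
        assert mapped.loc["p0", "gene_id"] == "NM_AAA"

    def test_invariant_to_gene_row_order(self):
        rng = np.random.default_rng(0)
        genes = _genes(list(rng.integers(0, 100000, size=50)))
        probes = _probes(list(rng.integers(0, 100000, size=200)))
        a = ig.map_probes_to_nearest_tss(probes, genes)
        b = ig.map_probes_to_nearest_tss(probes, genes.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_probes, n_genes, window = 100, 40, 8000
        # coarse grid forces frequent exact distance ties
        probes = _probes(list(rng.integers(0, 60000, size=n_probes) // 500 * 500))
        genes = _genes(list(rng.integers(0, 60000, size=n_genes) // 500 * 500))
        mapped = ig.map_probes_to_nearest_tss(probes, genes, window=window)
        for pid, pos in probes["pos"].items():
            dists = (genes["tss"] - pos).abs()
            best = dists.min()
            if best > window:
                assert pid not in mapped.index
                continue
            candidates = genes.loc[dists == best, "gene_id"]
            assert mapped.loc[pid, "distance"] == best
            assert mapped.loc[pid, "gene_id"] == candidates.min()

    def test_isoforms_compete_independently(self):
        genes = pd.DataFrame({
            "gene_id": ["NM_1", "NM_1"], "chrom": "chr1", "tss": [1000, 9000]})
        mapped = ig.map_probes_to_nearest_tss(_probes([8500]), genes)
        assert mapped.loc["p0", "tss"] == 9000


class TestJointCall:
    def _pairs(self):
        mapped = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3"], "tss": [0, 0, 0],
            "distance": [100, 200, 300], "signed_distance": [100, -200, 300],
        }, index=pd.Index(["p1", "p2", "p3"], name="probe_id"))
        calls = pd.DataFrame({
            "delta_beta": [0.3, 0.3, -0.25],
            "call": ["hyper", "hyper", "hypo"],
        }, index=pd.Index(["p1", "p2", "p3"], name="probe_id"))
        fc = pd.DataFrame({"fc": [0.4, 1.0]}, index=pd.Index(["g1", "g2"],
                                                             name="gene_id"))
        return mapped, calls, fc

    def test_joint_call_classification(self):
        mapped, calls, fc = self._pairs()
        pairs = ig.joint_call(mapped, calls, fc)
        assert pairs.loc["p1", "joint_call"] == "hyper_down"
        assert pairs.loc["p2", "joint_call"] == "none"     # expression unchanged
        assert pairs.loc["p3", "joint_call"] == "none"     # no expression data
        assert np.isnan(pairs.loc["p3", "fc"])

    def test_counts_conserved(self, result, study):
        c = ig.conservation_check(result.pairs, result.mapped,
                                  len(study.annotation.probes))
        assert c["mapped"] + c["unmapped"] == c["input_probes"]
        assert c["hyper_down"] + c["hypo_up"] + c["joint_none"] == len(result.pairs)
        assert (result.pairs["distance"] <= 8000).all()

    def test_planted_concordant_pairs_recovered(self, noise_free_study):
        """Probes planted drifting near genes planted oppositely regulated are
        exactly the flagged pairs on a noise-free study."""
        from senemeth.pipeline import analyze
        res = analyze(noise_free_study)
        truth = noise_free_study.truth
        pairs = res.pairs
        sym2acc = dict(zip(noise_free_study.genes["symbol"],
                           noise_free_study.genes["gene_id"]))
        expected = set()
        for pid, row in pairs.iterrows():
            pcls = truth.probe_class.get(pid)
            acc = row["gene_id"]
            gcls = truth.gene_expr_class.get(acc, "null")
            if pcls == "hyper_drift" and gcls == "down":
                expected.add((pid, "hyper_down"))
            elif pcls == "hypo_drift" and gcls == "up":
                expected.add((pid, "hypo_up"))
        flagged = {(pid, row["joint_call"])
                   for pid, row in pairs.iterrows() if row["joint_call"] != "none"}
        assert flagged == expected
        del sym2acc


class TestDistanceDistribution:
    def _promoters(self):
        return pd.DataFrame({"promoter_class": ["CGI", "nonCGI"]},
                            index=pd.Index(["g1", "g2"], name="gene_id"))

    def test_within_1kb_count(self):
        pairs = pd.DataFrame({"gene_id": ["g1", "g1", "g1"],
                              "distance": [100, 900, 1100]})
        out = ig.distance_distribution(pairs, self._promoters())
        assert out["within_1kb"]["CGI"] == 2

    def test_single_class_leaves_other_empty(self):
        pairs = pd.DataFrame({"gene_id": ["g1"] * 5,
                              "distance": [10, 20, 30, 40, 50]})
        out = ig.distance_distribution(pairs, self._promoters())
        assert out["histogram"]["nonCGI"].sum() == 0
        assert out["histogram"]["CGI"].sum() == 5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_binning_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = ["g1", "g2"]
        pairs = pd.DataFrame({
            "gene_id": rng.choice(genes, size=100),
            "distance": rng.integers(0, 8000, size=100),
        })
        out = ig.distance_distribution(pairs, self._promoters(), bin_width=250)
        hist = out["histogram"]
        for cls, gene in (("CGI", "g1"), ("nonCGI", "g2")):
            d = pairs.loc[pairs["gene_id"] == gene, "distance"]
            for i, label in enumerate(hist.index):
                lo, hi = i * 250, (i + 1) * 250
                assert hist.loc[label, cls] == ((d >= lo) & (d < hi)).sum()
        assert hist.to_numpy().sum() == 100


class TestFunctionalGroups:
    def test_single_group_ratio_one(self):
        mapping = pd.Series({f"g{i}": "immune response" for i in range(10)})
        out = ig.functional_group_ratios(
            mapping, {("TSS200", "hypo"): {f"g{i}" for i in range(10)}})
        row = out[(out["subcategory"] == "TSS200") & (out["group"] == "immune response")]
        assert row["fraction"].item() == 1.0

    def test_empty_set_yields_no_rows(self):
        out = ig.functional_group_ratios(pd.Series(dtype=object),
                                         {("Body", "hyper"): set()})
        assert out.empty

    def test_unmapped_genes_count_as_others(self):
        mapping = pd.Series({"g1": "transport"})
        out = ig.functional_group_ratios(mapping, {("Body", "hyper"): {"g1", "g2"}})
        assert set(out["group"]) == {"transport", "others"}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cross_tabulation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = ["immune response", "transport", "transcription"]
        genes = [f"g{i}" for i in range(50)]
        mapping = pd.Series({g: groups[rng.integers(0, 3)] for g in genes[:40]})
        gene_sets = {("TSS1500", "hyper"): set(rng.choice(genes, size=25, replace=False))}
        out = ig.functional_group_ratios(mapping, gene_sets)
        chosen = gene_sets[("TSS1500", "hyper")]
        for grp in groups + ["others"]:
            expected = sum(1 for g in chosen if mapping.get(g, "others") == grp)
            rows = out[out["group"] == grp]
            got = int(rows["count"].item()) if len(rows) else 0
            assert got == expected
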