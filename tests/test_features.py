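"""Weighted methylation levels, site-feature assignment, TE context."""

import numpy as np
import pandas as pd
import pytest

from gbmeth.features import (
    assign_sites_to_features, weighted_methylation,
    feature_methylation_table, classify_te_location, element_summary,
)
from gbmeth.calling import call_methylation
from conftest import make_sites, make_features


def brute_force_assign(sites, features):
    """O(N*M) reference: every containing interval, 1-based positions vs
    0-based half-open features."""
    out = []
    for si, s in sites.reset_index(drop=True).iterrows():
        for _, f in features.iterrows():
            if f["chrom"] == s["chrom"] and \
                    f["start"] <= s["pos"] - 1 < f["end"]:
                out.append((si, f["id"]))
    return set(out)


class TestWeightedLevel:
    def test_read_weighted_not_site_averaged(self):
        assert weighted_methylation(
            make_sites([("c", 1, "+", "CpG", 3, 7),
                        ("c", 2, "+", "CpG", 7, 3)])) == 0.5
        assert weighted_methylation(
            make_sites([("c", 1, "+", "CpG", 0, 8)])) == 0.0
        # {1/1, 0/9}: site-average would give 0.5; W weights by reads
        assert weighted_methylation(
            make_sites([("c", 1, "+", "CpG", 1, 0),
                        ("c", 2, "+", "CpG", 0, 9)])) == pytest.approx(0.1)

    def test_empty_is_missing_not_zero(self):
        assert np.isnan(weighted_methylation(make_sites([])))

    def test_associativity_under_partition(self):
        rng = np.random.default_rng(31)
        sites = make_sites([
            ("c", i, "+", "CpG", int(rng.integers(0, 20)),
             int(rng.integers(0, 20)))
            for i in range(1, 101)
        ])
        sites = sites[sites["depth"] > 0]
        w_all = weighted_methylation(sites)
        cut = len(sites) // 3
        a, b = sites.iloc[:cut], sites.iloc[cut:]
        combined = (a["count_meth"].sum() + b["count_meth"].sum()) / (
            a["depth"].sum() + b["depth"].sum())
        assert w_all == pytest.approx(combined)
        assert 0.0 <= w_all <= 1.0


class TestAssignment:
    feats = make_features([
        ("c", 0, 100, "+", "gene", "g1", None),
        ("c", 0, 40, "+", "exon", "g1.e1", "g1"),
        ("c", 40, 60, "+", "intron", "g1.i1", "g1"),
        ("c", 60, 100, "+", "exon", "g1.e2", "g1"),
    ])

    def test_nesting(self):
        sites = make_sites([("c", 10, "+", "CpG", 1, 1)])  # in exon 1
        out = assign_sites_to_features(sites, self.feats)
        assert set(out["feature_id"]) == {"g1", "g1.e1"}

    def test_between_genes_is_intergenic(self):
        sites = make_sites([("c", 500, "+", "CpG", 1, 1)])
        out = assign_sites_to_features(sites, self.feats)
        assert set(out["feature_id"]) == {"intergenic"}

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(32)
        rows = []
        for i in range(60):
            s = int(rng.integers(0, 2000))
            rows.append(("c", s, s + int(rng.integers(10, 300)), "+",
                         rng.choice(["gene", "exon", "DNA_TE"]),
                         f"f{i}", None))
        feats = make_features(rows)
        sites = make_sites([
            ("c", int(p), "+", "CpG", 1, 1)
            for p in rng.integers(1, 2300, size=200)
        ])
        got = assign_sites_to_features(sites, feats)
        got = set(zip(got["site_index"],
                      got["feature_id"])) - {(i, "intergenic")
                                             for i in range(len(sites))}
        assert got == brute_force_assign(sites, feats)


class TestFeatureTable:
    def _sites_in(self, n, start):
        return [("c", start + i, "+", "CpG", 1, 1) for i in range(n)]

    def test_min_cpg_keep_needs_eleven(self):
        feats = make_features([
            ("c", 0, 100, "+", "gene", "g10", None),
            ("c", 200, 300, "+", "gene", "g11", None),
        ])
        sites = make_sites(self._sites_in(10, 1) + self._sites_in(11, 201))
        tab = feature_methylation_table(sites, feats, min_cpg_sites=10)
        assert set(tab["feature_id"]) == {"g11"}
        tab0 = feature_methylation_table(sites, feats, min_cpg_sites=0)
        assert set(tab0["feature_id"]) == {"g10", "g11"}

    def test_w_identity_per_feature(self):
        feats = make_features([("c", 0, 50, "+", "gene", "g1", None)])
        sites = make_sites([("c", 1, "+", "CpG", 3, 7),
                            ("c", 2, "+", "CpG", 1, 9)])
        tab = feature_methylation_table(sites, feats)
        row = tab.iloc[0]
        assert row["W"] == row["total_meth_reads"] / row["total_reads"]
        assert row["W"] == pytest.approx(0.2)

    def test_non_cpg_contexts_excluded(self):
        feats = make_features([("c", 0, 50, "+", "gene", "g1", None)])
        sites = make_sites([("c", 1, "+", "CpG", 5, 5),
                            ("c", 2, "+", "CHH", 5, 5)])
        tab = feature_methylation_table(sites, feats)
        assert tab.iloc[0]["n_cpg_sites"] == 1


class TestTEContext:
    genes = make_features([("c", 50, 500, "+", "gene", "g1", None)])

    @pytest.mark.parametrize("start, end, expected", [
        (100, 200, "genic"),
        (600, 700, "intergenic"),
        (480, 520, "boundary"),
    ])
    def test_three_contexts(self, start, end, expected):
        tes = make_features([("c", start, end, ".", "DNA_TE", "t", None)])
        out = classify_te_location(tes, self.genes)
        assert out.iloc[0]["te_context"] == expected

    def test_matches_overlap_oracle(self):
        rng = np.random.default_rng(33)
        genes = make_features([
            ("c", s, s + 300, "+", "gene", f"g{i}", None)
            for i, s in enumerate(range(0, 5000, 500))
        ])
        tes = make_features([
            ("c", int(s), int(s) + int(rng.integers(20, 400)), ".",
             "DNA_TE", f"t{i}", None)
            for i, s in enumerate(rng.integers(0, 5200, size=300))
        ])
        got = classify_te_location(tes, genes)
        for _, te in tes.iterrows():
            overlaps = genes[(genes["start"] < te["end"])
                             & (genes["end"] > te["start"])]
            if len(overlaps) == 0:
                want = "intergenic"
            elif ((overlaps["start"] <= te["start"])
                  & (overlaps["end"] >= te["end"])).any():
                want = "genic"
            else:
                want = "boundary"
            assert got.set_index("te_id").loc[te["id"], "te_context"] == want


class TestElementSummary:
    def test_conservation_and_recovery(self, small_world):
        calls = call_methylation(small_world["sites"], 0.01)
        summ = element_summary(calls, small_world["features"])
        classes = summ["classes"].set_index("element")
        # overall is a depth-weighted mixture of gene and intergenic
        assert classes.loc["intergenic", "W"] < classes.loc["gene", "W"]
        lo = min(classes.loc["gene", "W"], classes.loc["intergenic", "W"])
        hi = max(classes.loc["gene", "W"], classes.loc["intergenic", "W"])
        assert lo <= classes.loc["overall", "W"] <= hi
        # genic CpG methylated fraction tracks simulated truth
        cfg = small_world["cfg"]
        expected = cfg.frac_methylated_genes * cfg.meth_level_high
        assert classes.loc["gene", "frac_methylated"] == pytest.approx(
            expected, abs=0.08)

    def test_no_tes_no_crash(self):
        feats = make_features([("c", 0, 100, "+", "gene", "g1", None)])
        sites = make_sites([("c", i, "+", "CpG", 5, 5)
                            for i in range(1, 20)])
        calls = call_methylation(sites, 0.01)
        summ = element_summary(calls, feats)
        assert len(summ["te_context"]) == 0
        assert "overall" in set(summ["classes"]["element"])
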