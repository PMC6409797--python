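"""Synthetic-data generator: determinism, ground truth, calibration."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from gbmeth.simulate import (
    SimulationConfig, gen_annotation, gen_methylome, gen_lambda_control,
    gen_expression, gen_sequences_from_mixture,
)
from gbmeth.cpgoe import composition, cpg_oe
from gbmeth.features import feature_methylation_table


def _hash_frame(df):
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
    ).hexdigest()


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_methylated_genes=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(depth_mean=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(expression_cv_ratio=0.0)


class TestAnnotation:
    def test_zero_genes_all_intergenic(self):
        cfg = SimulationConfig(n_genes=0, genome_length=5000, n_tes=0)
        genome, feats = gen_annotation(cfg)
        assert set(feats["kind"]) == {"intergenic"}
        assert len(genome["chr1"]) == 5000

    def test_genes_disjoint_and_deterministic(self):
        cfg = SimulationConfig(n_genes=10, genome_length=100_000, seed=1)
        _, f1 = gen_annotation(cfg)
        _, f2 = gen_annotation(cfg)
        assert _hash_frame(f1) == _hash_frame(f2)
        genes = f1[f1["kind"] == "gene"].sort_values("start")
        assert len(genes) == 10
        assert (genes["start"].to_numpy()[1:]
                >= genes["end"].to_numpy()[:-1]).all()

    def test_every_gene_has_exon_and_intron(self):
        cfg = SimulationConfig(n_genes=15, genome_length=100_000, seed=2)
        _, feats = gen_annotation(cfg)
        for gid in feats.loc[feats["kind"] == "gene", "id"]:
            kinds = set(feats.loc[feats["parent"] == gid, "kind"])
            assert {"exon", "intron"} <= kinds

    def test_boundary_tes_overlap_gene_and_intergenic(self):
        cfg = SimulationConfig(n_genes=20, genome_length=150_000, seed=3,
                               n_tes=30)
        _, feats = gen_annotation(cfg)
        genes = feats[feats["kind"] == "gene"]
        tes = feats[feats["kind"].isin(["DNA_TE", "RNA_TE"])]
        n_boundary = 0
        for te in tes.itertuples(index=False):
            overlaps = genes[(genes["start"] < te.end)
                             & (genes["end"] > te.start)]
            contained = ((overlaps["start"] <= te.start)
                         & (overlaps["end"] >= te.end)).any()
            if len(overlaps) and not contained:
                n_boundary += 1
        assert n_boundary > 0

    def test_infeasible_packing_is_explicit(self):
        with pytest.raises(ValueError, match="cannot pack"):
            gen_annotation(SimulationConfig(n_genes=50,
                                            genome_length=10_000))


class TestMethylome:
    def test_zero_error_all_unmethylated_reports_zero(self):
        cfg = SimulationConfig(n_genes=5, genome_length=20_000, seed=4,
                               conversion_failure=0.0,
                               frac_methylated_genes=0.0,
                               intergenic_site_meth=0.0, n_tes=0)
        genome, feats = gen_annotation(cfg)
        sites, truth = gen_methylome(genome, feats, cfg)
        assert (sites["count_meth"] == 0).all()
        assert not truth["sites"]["true_methylated"].any()

    def test_conversion_failure_rate_recovered(self):
        cfg = SimulationConfig(n_genes=5, genome_length=40_000, seed=5,
                               conversion_failure=0.01,
                               frac_methylated_genes=0.0,
                               intergenic_site_meth=0.0, n_tes=0)
        genome, feats = gen_annotation(cfg)
        sites, _ = gen_methylome(genome, feats, cfg)
        frac = sites["count_meth"].sum() / sites["depth"].sum()
        n = sites["depth"].sum()
        mc = 3 * np.sqrt(0.01 * 0.99 / n)
        assert frac == pytest.approx(0.01, abs=mc)

    def test_observed_gene_level_unbiased_at_high_depth(self):
        cfg = SimulationConfig(n_genes=30, genome_length=60_000, seed=6,
                               depth_mean=200.0, depth_dispersion=50.0,
                               frac_methylated_genes=1.0, n_tes=0)
        genome, feats = gen_annotation(cfg)
        sites, truth = gen_methylome(genome, feats, cfg,
                                     contexts=("CpG",))
        genes = feats[feats["kind"] == "gene"]
        tab = feature_methylation_table(sites, genes)
        merged = tab.merge(truth["genes"], left_on="feature_id",
                           right_on="gene_id")
        # individual genes scatter by binomial site sampling, but the
        # average observed W is unbiased for the true level
        assert abs((merged["W"] - merged["true_W"]).mean()) < 0.03
        # and at depth 200 the read-sampling noise itself is small
        assert np.abs(merged["W"] - merged["true_W"]).mean() < 0.08

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=5, genome_length=20_000, seed=7)
        genome, feats = gen_annotation(cfg)
        s1, _ = gen_methylome(genome, feats, cfg)
        s2, _ = gen_methylome(genome, feats, cfg)
        assert _hash_frame(s1) == _hash_frame(s2)


class TestLambdaControl:
    def test_zero_failure_all_zero(self):
        tab = gen_lambda_control(100, 20, 0.0, seed=1)
        assert (tab["count_meth"] == 0).all()

    def test_conversion_rate_ninety_nine_percent(self):
        # 1e6 read observations at 1% failure: ~99% converted
        tab = gen_lambda_control(50_000, 20, 0.01, seed=2)
        total = tab["depth"].sum()
        assert total == 1_000_000
        converted = tab["count_unmeth"].sum() / total
        assert converted == pytest.approx(0.99, abs=3e-4)

    def test_deterministic(self):
        t1 = gen_lambda_control(100, 15, 0.01, seed=3)
        t2 = gen_lambda_control(100, 15, 0.01, seed=3)
        assert _hash_frame(t1) == _hash_frame(t2)

    def test_needs_sites(self):
        with pytest.raises(ValueError):
            gen_lambda_control(0, 10, 0.01)


class TestExpression:
    def _truth(self, n, frac, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "is_methylated_gene": rng.random(n) < frac,
        })

    def test_mean_ratio_separates_classes(self):
        cfg = SimulationConfig(expression_mean_ratio=4.0)
        truth = self._truth(2000, 0.45, 1)
        m = gen_expression(truth, cfg, seed=2)
        med = m.fpkm.median(axis=1)
        is_meth = truth["is_methylated_gene"].to_numpy()
        assert med[is_meth].median() > med[~is_meth].median()

    def test_cv_ratio_stabilizes_methylated(self):
        cfg = SimulationConfig(expression_cv_ratio=0.5)
        truth = self._truth(2000, 0.45, 3)
        m = gen_expression(truth, cfg, seed=4)
        sd = np.log2(m.fpkm).std(axis=1, ddof=1)
        is_meth = truth["is_methylated_gene"].to_numpy()
        assert sd[is_meth].median() < sd[~is_meth].median()

    def test_null_config_classes_indistinguishable(self):
        from gbmeth.expression import wilcoxon_ranksum

        cfg = SimulationConfig(expression_mean_ratio=1.0,
                               expression_cv_ratio=1.0)
        rng = np.random.default_rng(5)
        pvals = []
        for s in range(20):
            truth = self._truth(100, 0.5, 100 + s)
            m = gen_expression(truth, cfg, seed=int(rng.integers(2 ** 31)))
            med = m.fpkm.median(axis=1)
            is_meth = truth["is_methylated_gene"].to_numpy()
            _, p = wilcoxon_ranksum(med[is_meth], med[~is_meth])
            pvals.append(p)
        # p-values behave like a uniform sample under the null
        assert 0.05 < np.mean(pvals) < 0.95
        assert min(pvals) < 0.5 < max(pvals)

    def test_coupling_shifts_groups(self):
        cfg = SimulationConfig()
        truth = self._truth(500, 0.5, 6)
        dw = pd.Series(np.linspace(-0.5, 0.5, 500),
                       index=truth["gene_id"].to_numpy())
        m = gen_expression(truth, cfg, delta_w=dw, coupling=4.0, seed=7)
        la = np.log2(m.fpkm[[c for c in m.fpkm if c.startswith("A")]]
                     .mean(axis=1))
        lb = np.log2(m.fpkm[[c for c in m.fpkm if c.startswith("B")]]
                     .mean(axis=1))
        r = np.corrcoef(la - lb, dw.to_numpy())[0, 1]
        assert r > 0.5


class TestMixtureSequences:
    def test_realized_oe_within_tolerance_of_target(self):
        seqs = gen_sequences_from_mixture([0.35, 0.65], [0.10, 0.19],
                                          n=30, length=1000, seed=8)
        assert len(seqs) == 30
        for seq in seqs.values():
            oe = cpg_oe(composition(seq))
            assert 0.0 < oe  # targets truncated positive
        # sample mean tracks the mixture mean loosely at n=30
        oes = [cpg_oe(composition(s)) for s in seqs.values()]
        assert abs(np.mean(oes) - 0.5) < 0.12

    def test_single_component_mean_recovered(self):
        seqs = gen_sequences_from_mixture([0.35], [0.10], n=60,
                                          length=1000, seed=9)
        oes = np.array([cpg_oe(composition(s)) for s in seqs.values()])
        assert np.mean(oes) == pytest.approx(0.35, abs=0.05)

    def test_unit_target_no_depletion(self):
        seqs = gen_sequences_from_mixture([1.0], [0.001], n=10,
                                          length=1000, seed=10)
        oes = [cpg_oe(composition(s)) for s in seqs.values()]
        assert np.mean(oes) == pytest.approx(1.0, abs=0.04)

    def test_every_sequence_hits_its_target_band(self):
        from gbmeth.simulate import _build_sequence

        rng = np.random.default_rng(14)
        for target in (0.2, 0.35, 0.65, 0.9, 1.1):
            for _ in range(4):
                s = _build_sequence(rng, 1000, 0.4, target, 0.03)
                assert abs(cpg_oe(composition(s)) - target) <= 0.03 + 1e-9

    def test_zero_or_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            gen_sequences_from_mixture([0.0], [0.1], n=5, length=1000,
                                       seed=11)

    def test_short_length_rejected(self):
        with pytest.raises(ValueError):
            gen_sequences_from_mixture([0.5], [0.1], n=5, length=100,
                                       seed=12)

    def test_deterministic(self):
        a = gen_sequences_from_mixture([0.5], [0.1], n=3, length=600,
                                       seed=13)
        b = gen_sequences_from_mixture([0.5], [0.1], n=3, length=600,
                                       seed=13)
        assert a == b
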