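"""End-to-end orchestration: simulate → call → aggregate → correlate.

Plain files plus a JSON manifest; no workflow engine.  Every stage reads
only its declared inputs and writes into the run directory, and the full
configuration (including the seed) is serialized next to the outputs so
a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import meth_io, calling, features, expression, cpgoe, simulate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All thresholds and simulation parameters of one pipeline run.

    Defaults are the analysis defaults used throughout the package:
    FDR threshold q = 0.01, retained depth band [5, 30], genes kept only
    with more than 10 covered CpG sites, top 5% |ΔW| for the differential
    correlation, 1000-bp genome fragments for O/E scans.
    """

    outdir: str = "gbmeth_run"
    seed: int = 0
    # simulation
    n_genes: int = 500
    genome_length: int = 900_000
    coupling: float = 2.0
    delta_w_sd: float = 0.15
    n_mixture_genes: int = 300
    mixture_means: tuple = (0.35, 0.65)
    mixture_sds: tuple = (0.10, 0.19)
    # analysis thresholds
    q_threshold: float = 0.01
    min_depth: int = 5
    max_depth: int = 30
    min_cpg: int = 10
    top_fraction: float = 0.05
    fragment: int = 1000
    window: int = 60
    max_mismatch: int = 10
    min_aln_length: int = 180
    mixture_k: int = 2

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("mixture_means", "mixture_sds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    sim = simulate.SimulationConfig(
        n_genes=cfg.n_genes, genome_length=cfg.genome_length, seed=cfg.seed,
    )
    rng = np.random.default_rng(cfg.seed)
    genome, feats = simulate.gen_annotation(sim, rng=rng)
    sites_a, truth_a = simulate.gen_methylome(genome, feats, sim, rng=rng)
    shift = pd.Series(
        rng.normal(0.0, cfg.delta_w_sd, cfg.n_genes),
        index=truth_a["genes"]["gene_id"].to_numpy(),
    )
    sites_b, truth_b = simulate.gen_methylome(
        genome, feats, sim, rng=rng,
        gene_states=pd.Series(
            truth_a["genes"]["is_methylated_gene"].to_numpy(),
            index=truth_a["genes"]["gene_id"].to_numpy(),
        ),
        site_fraction_shift=shift,
    )
    control = simulate.gen_lambda_control(
        20_000, 20, sim.conversion_failure, seed=int(rng.integers(2 ** 31)),
    )
    delta_w = pd.Series(
        truth_a["genes"]["true_W"].to_numpy()
        - truth_b["genes"]["true_W"].to_numpy(),
        index=truth_a["genes"]["gene_id"].to_numpy(),
    )
    expr = simulate.gen_expression(
        truth_a["genes"], sim, groups=("A", "B"), n_replicates=10,
        delta_w=delta_w, coupling=cfg.coupling,
        seed=int(rng.integers(2 ** 31)),
    )
    mix_seqs = simulate.gen_sequences_from_mixture(
        cfg.mixture_means, cfg.mixture_sds, cfg.n_mixture_genes,
        length=1000, seed=int(rng.integers(2 ** 31)),
    )
    meth_io.write_coverage(sites_a, out / "popA.cov.tsv")
    meth_io.write_coverage(sites_b, out / "popB.cov.tsv")
    meth_io.write_coverage(control, out / "lambda.cov.tsv")
    meth_io.write_gff3(feats, out / "annotation.gff3")
    meth_io.write_fasta(genome, out / "genome.fa")
    meth_io.write_fasta(mix_seqs, out / "mixture_genes.fa")
    meth_io.write_expression(expr, out / "expression.tsv")
    truth_a["genes"].to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    return {"n_sites_popA": len(sites_a), "n_sites_popB": len(sites_b),
            "n_genes": cfg.n_genes, "n_control_sites": len(control)}


def _stage_call(cfg: RunConfig, out: Path) -> dict:
    control = meth_io.read_coverage(out / "lambda.cov.tsv")
    cc = calling.estimate_conversion_error(control)
    report = {"error_rate": cc.error_rate,
              "conversion_rate": cc.conversion_rate}
    for pop in ("popA", "popB"):
        sites = meth_io.read_coverage(out / f"{pop}.cov.tsv")
        calls = calling.call_methylation(
            sites, cc.error_rate, q_threshold=cfg.q_threshold,
            min_depth=cfg.min_depth, max_depth=cfg.max_depth,
        )
        calls.to_csv(out / f"{pop}.calls.tsv", sep="\t", index=False)
        summ = calls.attrs["context_summary"]
        report[pop] = {
            "n_retained": len(calls),
            "frac_methylated_by_context": dict(zip(
                summ["context"], summ["frac_methylated"].round(6))),
        }
    return report


def _stage_featmeth(cfg: RunConfig, out: Path) -> dict:
    feats = meth_io.read_features(out / "annotation.gff3")
    genes = feats[feats["kind"] == "gene"]
    report = {}
    for pop in ("popA", "popB"):
        calls = pd.read_csv(out / f"{pop}.calls.tsv", sep="\t")
        tab = features.feature_methylation_table(
            calls, genes, min_cpg_sites=cfg.min_cpg,
        )
        tab.to_csv(out / f"{pop}.gene_meth.tsv", sep="\t", index=False)
        report[pop] = {"n_genes_kept": len(tab),
                       "median_W": float(tab["W"].median())}
    return report


def _stage_elements(cfg: RunConfig, out: Path) -> dict:
    feats = meth_io.read_features(out / "annotation.gff3")
    calls = pd.read_csv(out / "popA.calls.tsv", sep="\t")
    summ = features.element_summary(calls, feats)
    summ["classes"].to_csv(out / "element_classes.tsv", sep="\t",
                           index=False)
    summ["te_context"].to_csv(out / "te_context.tsv", sep="\t", index=False)
    return {"classes": summ["classes"].set_index("element")
            ["frac_methylated"].round(4).to_dict()}


def _stage_diff(cfg: RunConfig, out: Path) -> dict:
    expr = meth_io.read_expression(out / "expression.tsv")
    meth_a = pd.read_csv(out / "popA.gene_meth.tsv", sep="\t")
    meth_b = pd.read_csv(out / "popB.gene_meth.tsv", sep="\t")
    tab, rho, p = expression.differential_table(
        meth_a, meth_b,
        expression.group_mean_fpkm(expr, "A"),
        expression.group_mean_fpkm(expr, "B"),
        top_fraction=cfg.top_fraction, min_cpg=cfg.min_cpg,
    )
    tab.to_csv(out / "differential.tsv", sep="\t", index=False)
    return {"n_genes": len(tab), "n_flagged": int(tab["passed_top5"].sum()),
            "spearman_rho": rho, "spearman_p": p}


def _stage_stability(cfg: RunConfig, out: Path) -> dict:
    expr = meth_io.read_expression(out / "expression.tsv")
    meth_a = pd.read_csv(out / "popA.gene_meth.tsv", sep="\t")
    tab = expression.expression_stability(
        expr, expr.samples_in("A"), meth_a,
    )
    tab.to_csv(out / "stability.tsv", sep="\t", index=False)
    cls = expression.methylation_classes(tab["W"])
    med = {c: float(tab.loc[cls == c, "sd_log2_fpkm"].median())
           for c in np.unique(cls)}
    return {"n_genes": len(tab), "median_sd_by_class": med}


def _stage_cpgoe(cfg: RunConfig, out: Path) -> dict:
    seqs = meth_io.read_fasta(out / "mixture_genes.fa")
    tab = cpgoe.gene_set_cpgoe(seqs)
    tab.to_csv(out / "gene_cpgoe.tsv", sep="\t", index=False)
    genome = meth_io.read_fasta(out / "genome.fa")
    frags = cpgoe.genome_fragment_scan(genome, fragment=cfg.fragment)
    frags.to_csv(out / "fragment_cpgoe.tsv", sep="\t", index=False)
    return {"n_gene_values": len(tab), "n_fragments": len(frags),
            "mean_gene_gpc_oe": float(tab["gpc_oe"].mean())}


def _stage_mixture(cfg: RunConfig, out: Path) -> dict:
    tab = pd.read_csv(out / "gene_cpgoe.tsv", sep="\t")
    fit = cpgoe.fit_normal_mixture(
        tab["cpg_oe"].to_numpy(), k=cfg.mixture_k, seed=cfg.seed,
    )
    result = {"weights": fit.weights.tolist(), "means": fit.means.tolist(),
              "sds": fit.sds.tolist(), "log_likelihood": fit.log_likelihood,
              "converged": fit.converged}
    with open(out / "mixture_fit.json", "w") as fh:
        json.dump(result, fh, indent=1)
    return result


_STAGES = [
    ("simulate", _stage_simulate),
    ("call", _stage_call),
    ("featmeth", _stage_featmeth),
    ("elements", _stage_elements),
    ("diff", _stage_diff),
    ("stability", _stage_stability),
    ("cpgoe", _stage_cpgoe),
    ("mixture", _stage_mixture),
]


def run_pipeline(cfg: RunConfig, stages=None) -> dict:
    """Execute the pipeline stages in dependency order.

    ``stages`` restricts execution to a subset (upstream artifacts must
    then already exist in the run directory).  Returns the machine-
    readable run report, which is also written to ``report.json``.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump({"schema_version": CONFIG_SCHEMA_VERSION, **asdict(cfg)},
                  fh, indent=1)
    wanted = set(stages) if stages is not None else None
    report = {"schema_version": CONFIG_SCHEMA_VERSION, "seed": cfg.seed,
              "stages": {}}
    for name, fn in _STAGES:
        if wanted is not None and name not in wanted:
            continue
        logger.info("stage %s", name)
        try:
            report["stages"][name] = fn(cfg, out)
        except FileNotFoundError as exc:
            raise RuntimeError(
                f"stage {name!r} failed: missing upstream artifact "
                f"{exc.filename}"
            ) from exc
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
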