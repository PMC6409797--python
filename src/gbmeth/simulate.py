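"""Synthetic WGBS, annotation, expression and sequence data with known
ground truth.

The generator emulates the statistical structure the downstream analyses
assume, not the sequencing process itself (no reads, no mapping bias):

- a genome with non-overlapping multi-exon genes, transposable elements
  in intergenic, boundary and genic placements, and intergenic spacers;
- a bimodal gene methylome: a fraction of genes is "methylated", meaning
  a high proportion of their CpG sites carry methylation, the rest carry
  essentially none; intergenic CpG sites are sparsely methylated;
- bisulfite read counts: each cytosine gets a read depth from a
  truncated negative binomial, and the methylated read count is binomial
  with success probability 1 − ε for truly methylated sites and ε for
  unmethylated ones, where ε is the bisulfite conversion-failure rate;
- an unmethylated λDNA spike-in for estimating ε;
- expression where methylated genes have a higher mean FPKM and a lower
  coefficient of variation, with an optional between-population shift
  coupled to between-population methylation differences;
- gene sequences whose CpG O/E is drawn from a chosen normal mixture,
  holding base composition fixed so that only CpG placement varies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meth_io import ExpressionMatrix
from .cpgoe import sample_mixture

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "gen_annotation",
    "gen_methylome",
    "gen_lambda_control",
    "gen_expression",
    "gen_sequences_from_mixture",
]

_C, _G, _A, _T = ord("C"), ord("G"), ord("A"), ord("T")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study.

    Defaults mimic an invertebrate gene-body methylome: a clearly bimodal
    gene population (≈45% methylated so that roughly a third of genic
    CpGs are methylated at a within-gene site fraction of 0.8), sparse
    intergenic methylation (5% of sites), a negative-binomial read depth
    with mean 15 (so the [5, 30] retention band keeps most sites), and a
    99% bisulfite conversion rate (ε = 0.01).
    """

    n_genes: int = 200
    genome_length: int = 300_000
    frac_methylated_genes: float = 0.45
    meth_level_high: float = 0.8
    meth_level_low: float = 0.0
    intergenic_site_meth: float = 0.05
    depth_mean: float = 15.0
    depth_dispersion: float = 5.0
    conversion_failure: float = 0.01
    expression_mean_ratio: float = 4.0
    expression_cv_ratio: float = 0.5
    base_fpkm_mean: float = 10.0
    base_fpkm_cv: float = 0.8
    gene_level_sd_log2: float = 1.0
    gc_content: float = 0.33
    n_tes: int = 30
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_methylated_genes", "meth_level_high",
                     "meth_level_low", "intergenic_site_meth",
                     "conversion_failure", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.expression_mean_ratio <= 0 or self.expression_cv_ratio <= 0:
            raise ValueError("expression ratios must be positive")
        if self.n_genes < 0 or self.genome_length < 0:
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# annotation

_MIN_EXON, _MAX_EXON = 150, 400
_MIN_INTRON, _MAX_INTRON = 100, 400
_MIN_GAP = 100
_MIN_TE, _MAX_TE = 60, 150


def _random_sequence(rng, length, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array([_A, _C, _G, _T], dtype=np.uint8),
                      size=length, p=p)


def gen_annotation(cfg: SimulationConfig, rng=None):
    """Simulate a genome sequence and its feature annotation.

    Genes are packed left to right with random intergenic gaps; each gene
    has 2–4 exons separated by introns, so every gene carries at least
    one intron.  TEs (alternating DNA/RNA class) are placed in the three
    genomic contexts: fully intergenic, spanning a gene boundary, and
    fully genic.  Raises when the genome is too short to hold the
    requested genes.

    Returns (genome, features): genome is {"chr1": sequence string},
    features a DataFrame in internal 0-based half-open coordinates.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    seq = _random_sequence(rng, cfg.genome_length, cfg.gc_content)
    genome = {"chr1": bytes(seq).decode("ascii")}
    if cfg.n_genes == 0:
        feats = pd.DataFrame(
            [("chr1", 0, cfg.genome_length, ".", "intergenic",
              "intergenic_1", None)] if cfg.genome_length else [],
            columns=["chrom", "start", "end", "strand", "kind", "id",
                     "parent"],
        )
        return genome, feats

    # draw gene structures first, then check packing feasibility
    structures = []
    for _ in range(cfg.n_genes):
        n_exons = int(rng.integers(2, 5))
        exons = rng.integers(_MIN_EXON, _MAX_EXON + 1, size=n_exons)
        introns = rng.integers(_MIN_INTRON, _MAX_INTRON + 1,
                               size=n_exons - 1)
        structures.append((exons, introns))
    spans = np.array([e.sum() + i.sum() for e, i in structures])
    slack = cfg.genome_length - spans.sum() - _MIN_GAP * (cfg.n_genes + 1)
    if slack < 0:
        raise ValueError(
            f"cannot pack {cfg.n_genes} genes (total span {spans.sum()} bp "
            f"+ minimal gaps) into a {cfg.genome_length} bp genome"
        )
    extra = rng.multinomial(int(slack), np.full(cfg.n_genes + 1,
                                                1.0 / (cfg.n_genes + 1)))
    gaps = _MIN_GAP + extra

    rows = []
    cursor = 0
    gene_bounds = []
    for gi, (exons, introns) in enumerate(structures):
        cursor += int(gaps[gi])
        gid = f"g{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        gstart = cursor
        pos = gstart
        parts = []
        for k, elen in enumerate(exons):
            parts.append((pos, pos + int(elen), "exon",
                          f"{gid}.e{k + 1}"))
            pos += int(elen)
            if k < len(introns):
                parts.append((pos, pos + int(introns[k]), "intron",
                              f"{gid}.i{k + 1}"))
                pos += int(introns[k])
        rows.append(("chr1", gstart, pos, strand, "gene", gid, None))
        for s, e, kind, pid in parts:
            rows.append(("chr1", s, e, strand, kind, pid, gid))
        gene_bounds.append((gstart, pos))
        cursor = pos

    # TEs: cycle contexts intergenic -> boundary -> genic
    te_rows = []
    contexts = ["intergenic", "boundary", "genic"]
    for ti in range(cfg.n_tes):
        kind = "DNA_TE" if ti % 2 == 0 else "RNA_TE"
        ctx = contexts[ti % 3]
        tlen = int(rng.integers(_MIN_TE, _MAX_TE + 1))
        gi = int(rng.integers(0, cfg.n_genes))
        gstart, gend = gene_bounds[gi]
        if ctx == "genic":
            if gend - gstart <= tlen + 2:
                continue
            s = int(rng.integers(gstart + 1, gend - tlen - 1))
        elif ctx == "boundary":
            # straddle the gene start: begins in the upstream gap
            half = max(1, tlen // 2)
            s = gstart - half
            if s < 0:
                continue
        else:
            gap_end = gstart - 1
            gap_start = gene_bounds[gi - 1][1] + 1 if gi > 0 else 0
            if gap_end - gap_start <= tlen:
                continue
            s = int(rng.integers(gap_start, gap_end - tlen))
        te_rows.append(("chr1", s, s + tlen, ".", kind,
                        f"te{ti + 1:03d}", None))
    rows.extend(te_rows)

    # remaining space labelled intergenic
    prev = 0
    n_inter = 0
    for gstart, gend in gene_bounds:
        if gstart > prev:
            n_inter += 1
            rows.append(("chr1", prev, gstart, ".", "intergenic",
                         f"intergenic_{n_inter}", None))
        prev = gend
    if cfg.genome_length > prev:
        n_inter += 1
        rows.append(("chr1", prev, cfg.genome_length, ".", "intergenic",
                     f"intergenic_{n_inter}", None))

    feats = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "kind", "id",
                       "parent"],
    )
    return genome, feats


# ---------------------------------------------------------------------------
# methylome

def _truncated_nb(rng, mean, dispersion, size):
    """Negative binomial with given mean and dispersion, truncated to >= 1."""
    p = dispersion / (dispersion + mean)
    out = rng.negative_binomial(dispersion, p, size=size)
    bad = out < 1
    while bad.any():
        out[bad] = rng.negative_binomial(dispersion, p, size=int(bad.sum()))
        bad = out < 1
    return out


def _cytosine_sites(seq_bytes: np.ndarray):
    """Positions (0-based), strands and contexts of all cytosines on both
    strands.  Context is the two downstream bases in reading direction;
    cytosines too close to the contig edge to have two downstream bases
    are skipped."""
    n = len(seq_bytes)
    pos_list, strand_list, ctx_list = [], [], []
    # plus strand: C at i, context seq[i+1], seq[i+2]
    ci = np.flatnonzero(seq_bytes[: n - 2] == _C)
    nxt1 = seq_bytes[ci + 1]
    nxt2 = seq_bytes[ci + 2]
    ctx = np.where(nxt1 == _G, "CpG", np.where(nxt2 == _G, "CHG", "CHH"))
    pos_list.append(ci)
    strand_list.append(np.full(len(ci), "+"))
    ctx_list.append(ctx)
    # minus strand: C is a G on the plus strand at i; downstream on the
    # minus strand are the complements of seq[i-1], seq[i-2]
    gi = np.flatnonzero(seq_bytes[2:] == _G) + 2
    prv1 = seq_bytes[gi - 1]
    prv2 = seq_bytes[gi - 2]
    ctx_m = np.where(prv1 == _C, "CpG", np.where(prv2 == _C, "CHG", "CHH"))
    pos_list.append(gi)
    strand_list.append(np.full(len(gi), "-"))
    ctx_list.append(ctx_m)
    pos = np.concatenate(pos_list)
    order = np.argsort(pos, kind="stable")
    return (pos[order], np.concatenate(strand_list)[order],
            np.concatenate(ctx_list)[order])


def gen_methylome(genome: dict, features: pd.DataFrame,
                  cfg: SimulationConfig, rng=None,
                  contexts=("CpG", "CHG", "CHH"),
                  gene_states: pd.Series | None = None,
                  site_fraction_shift: pd.Series | None = None):
    """Simulate a site table of bisulfite read counts with ground truth.

    Every cytosine on both strands is emitted (restrict with
    ``contexts``).  Each gene is first assigned a true methylation class
    (Bernoulli(frac_methylated_genes), or supplied via ``gene_states``),
    giving a per-gene fraction of truly methylated CpG sites
    (``meth_level_high`` or ``meth_level_low``, optionally perturbed
    per-gene by ``site_fraction_shift``, e.g. to create a second
    population with shifted levels).  Intergenic CpG sites are methylated
    with probability ``intergenic_site_meth``; CHG/CHH sites are always
    truly unmethylated and appear methylated only through conversion
    failure.

    Returns (sites, truth) where truth has keys "sites" (per-site true
    state) and "genes" (per-gene class, true site fraction, and the true
    weighted level f(1−ε) + (1−f)ε implied by it).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    eps = cfg.conversion_failure
    frames = []
    truth_site_frames = []

    genes = features[features["kind"] == "gene"].sort_values("start")
    gene_ids = genes["id"].to_numpy()
    if gene_states is None:
        states = rng.random(len(gene_ids)) < cfg.frac_methylated_genes
        gene_states = pd.Series(states, index=gene_ids)
    else:
        gene_states = gene_states.reindex(gene_ids)
    frac = np.where(gene_states.to_numpy(), cfg.meth_level_high,
                    cfg.meth_level_low).astype(float)
    if site_fraction_shift is not None:
        frac = np.clip(
            frac + site_fraction_shift.reindex(gene_ids).fillna(0.0)
            .to_numpy(), 0.0, 1.0,
        )
    gene_truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_methylated_gene": gene_states.to_numpy(),
        "true_site_fraction": frac,
        "true_W": frac * (1 - eps) + (1 - frac) * eps,
    })

    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pos0, strand, ctx = _cytosine_sites(arr)
        keep = np.isin(ctx, contexts)
        pos0, strand, ctx = pos0[keep], strand[keep], ctx[keep]

        g = genes[genes["chrom"] == chrom]
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        gidx_sorted = np.argsort(gs, kind="stable")
        gs_s, ge_s = gs[gidx_sorted], ge[gidx_sorted]
        j = np.searchsorted(gs_s, pos0, side="right") - 1
        in_gene = (j >= 0) & (pos0 < ge_s[np.clip(j, 0, max(0, len(ge_s) - 1))]
                              if len(ge_s) else False)
        # map back to per-gene site fraction
        site_frac = np.full(len(pos0), cfg.intergenic_site_meth)
        if len(gs_s):
            gene_row = np.flatnonzero(
                np.isin(genes["chrom"].to_numpy(), [chrom]))
            frac_sorted = frac[gene_row][gidx_sorted] if len(gene_row) else frac
            site_frac[in_gene] = frac_sorted[j[in_gene]]

        is_cpg = ctx == "CpG"
        true_state = np.zeros(len(pos0), dtype=bool)
        true_state[is_cpg] = rng.random(int(is_cpg.sum())) < site_frac[is_cpg]

        depth = _truncated_nb(rng, cfg.depth_mean, cfg.depth_dispersion,
                              len(pos0))
        p_read = np.where(true_state, 1.0 - eps, eps)
        m = rng.binomial(depth, p_read)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos0 + 1,
            "strand": strand,
            "context": ctx,
            "count_meth": m,
            "count_unmeth": depth - m,
            "depth": depth,
        }))
        truth_site_frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos0 + 1,
            "strand": strand,
            "true_methylated": true_state,
        }))

    sites = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    truth = {
        "sites": pd.concat(truth_site_frames, ignore_index=True)
        if truth_site_frames else pd.DataFrame(),
        "genes": gene_truth,
    }
    return sites, truth


def gen_lambda_control(n_sites: int, depth, conversion_failure: float,
                       seed=None) -> pd.DataFrame:
    """An unmethylated spike-in control site table.

    All sites are truly unmethylated; the observed methylated read count
    at each site is Binomial(depth, conversion_failure).  ``depth`` may
    be a scalar or a per-site array.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    d = np.broadcast_to(np.asarray(depth, dtype=np.int64), n_sites).copy()
    m = rng.binomial(d, conversion_failure)
    return pd.DataFrame({
        "chrom": "lambda",
        "pos": np.arange(1, n_sites + 1),
        "strand": "+",
        "context": "CpG",
        "count_meth": m,
        "count_unmeth": d - m,
        "depth": d,
    })


# ---------------------------------------------------------------------------
# expression

def _lognormal_params(mean, cv):
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def gen_expression(gene_truth: pd.DataFrame, cfg: SimulationConfig,
                   groups=("A", "B"), n_replicates: int = 10,
                   delta_w: pd.Series | None = None,
                   coupling: float = 0.0, seed=None) -> ExpressionMatrix:
    """Simulate a gene x sample FPKM matrix.

    Per-gene FPKM is log-normal.  Methylated genes get a mean multiplied
    by ``expression_mean_ratio`` and a coefficient of variation
    multiplied by ``expression_cv_ratio`` relative to unmethylated genes;
    gene-to-gene baseline variation is ``gene_level_sd_log2`` in log2
    units.  When ``delta_w`` (per-gene methylation difference, first
    group minus second) and ``coupling`` are given, the first group's
    log2 mean is shifted by +coupling·ΔW/2 and the second's by
    −coupling·ΔW/2, creating a methylation–expression coupling between
    the groups; additional groups get no shift.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    gene_ids = gene_truth["gene_id"].to_numpy()
    is_meth = gene_truth["is_methylated_gene"].to_numpy()
    n = len(gene_ids)

    mean = np.where(is_meth,
                    cfg.base_fpkm_mean * cfg.expression_mean_ratio,
                    cfg.base_fpkm_mean).astype(float)
    cv = np.where(is_meth, cfg.base_fpkm_cv * cfg.expression_cv_ratio,
                  cfg.base_fpkm_cv).astype(float)
    sigma_ln = np.sqrt(np.log1p(cv * cv))
    mu_ln = np.log(mean) - sigma_ln ** 2 / 2.0
    # stable gene-to-gene baseline offset, shared across samples
    gene_offset = rng.normal(0.0, cfg.gene_level_sd_log2 * math.log(2), n)

    shift = np.zeros((len(groups), n))
    if delta_w is not None and coupling != 0.0:
        dw = delta_w.reindex(gene_ids).fillna(0.0).to_numpy()
        shift[0] = +coupling * dw / 2.0 * math.log(2)
        if len(groups) > 1:
            shift[1] = -coupling * dw / 2.0 * math.log(2)

    data = {}
    group_map = {}
    for gi, group in enumerate(groups):
        for r in range(1, n_replicates + 1):
            sample = f"{group}_r{r}"
            noise = rng.normal(0.0, sigma_ln)
            data[sample] = np.exp(mu_ln + gene_offset + shift[gi] + noise)
            group_map[sample] = group
    fpkm = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionMatrix(fpkm=fpkm, groups=group_map)


# ---------------------------------------------------------------------------
# sequences with a target CpG O/E

def _count_cg(arr: np.ndarray) -> int:
    return int(np.count_nonzero((arr[:-1] == _C) & (arr[1:] == _G)))


def _markov_cpg_sequence(rng, length, gc, target):
    """A sequence whose C→G transition rate is tuned so the expected
    CpG O/E equals ``target`` while every other transition keeps the
    background base frequencies — in particular G→C, so GpC O/E stays
    near 1 and the realized base counts stay near the requested
    composition."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array([_A, _C, _G, _T], dtype=np.uint8)
    p_a, p_c, p_g, p_t = p
    # C row: only the C->G rate is tuned; the freed (or borrowed) mass
    # goes to A/T so that C->C keeps its background rate.  Non-C rows are
    # solved from stationarity (p M = p) so the chain's base composition
    # stays at p — this keeps the GpC O/E control unbiased at 1.
    pg_after_c = np.clip(target * p_g, 0.0, 0.95)
    delta = p_g - pg_after_c
    from_c = np.array([
        p_a + delta * p_a / (p_a + p_t),
        p_c,
        pg_after_c,
        p_t + delta * p_t / (p_a + p_t),
    ])
    from_bg = (p - p_c * from_c) / (1.0 - p_c)
    if (from_c < 0).any() or (from_bg < 0).any():
        raise ValueError(
            f"CpG O/E target {target} infeasible at GC content {gc}"
        )
    cum_bg = np.cumsum(from_bg)
    cum_c = np.cumsum(from_c)
    u = rng.random(length)
    arr = np.empty(length, dtype=np.uint8)
    arr[0] = bases[np.searchsorted(cum_bg, u[0])]
    for i in range(1, length):
        cum = cum_c if arr[i - 1] == _C else cum_bg
        arr[i] = bases[np.searchsorted(cum, u[i])]
    return arr


def _build_sequence(rng, length, gc, target, tol):
    """A random sequence whose CpG O/E lies within ``tol`` of ``target``.

    A Markov draw lands near the target in expectation; residual
    deviation is removed by swap moves on base placement (composition-
    preserving), so the repair leaves the GpC control unbiased."""
    if target <= 0:
        raise ValueError(f"unattainable CpG O/E target {target}")
    arr = _markov_cpg_sequence(rng, length, gc, target)
    n_c = int(np.count_nonzero(arr == _C))
    n_g = int(np.count_nonzero(arr == _G))
    if n_c == 0 or n_g == 0:
        raise ValueError("degenerate composition: no C or no G")
    per_count = target * n_c * n_g / length
    k_target = int(round(per_count))
    k_tol = tol * n_c * n_g / length
    k_lo = max(0, int(math.ceil(per_count - k_tol)))
    k_hi = int(math.floor(per_count + k_tol))
    if k_hi < k_lo or k_lo > min(n_c, n_g):
        raise ValueError(
            f"CpG O/E target {target} (±{tol}) is unattainable for "
            f"{n_c} C / {n_g} G in {length} bp"
        )
    k_target = min(max(k_target, k_lo), k_hi)

    for _ in range(50 * length):
        k = _count_cg(arr)
        if k_lo <= k <= k_hi:
            return bytes(arr).decode("ascii")
        if k > k_hi:
            # break a CpG: swap the G of a random CG pair elsewhere
            cg_pos = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
            i = int(rng.choice(cg_pos)) + 1
        else:
            # make a CpG: swap a random non-G base following a C with a G
            c_pos = np.flatnonzero(arr[:-1] == _C)
            c_pos = c_pos[arr[c_pos + 1] != _G]
            if len(c_pos) == 0:
                raise ValueError(
                    f"cannot raise CpG count toward target {target}"
                )
            i = int(rng.choice(c_pos)) + 1
        j = int(rng.integers(0, length))
        arr[i], arr[j] = arr[j], arr[i]
        k_new = _count_cg(arr)
        if abs(k_new - k_target) > abs(k - k_target):
            arr[i], arr[j] = arr[j], arr[i]  # revert
    raise RuntimeError(
        f"sequence construction did not converge for target {target}"
    )  # pragma: no cover


def gen_sequences_from_mixture(means, sds, n: int, length: int = 1000,
                               seed=None, weights=None, gc: float = 0.5,
                               tol: float = 0.03) -> dict:
    """Gene sequences whose CpG O/E follows a given normal mixture.

    A target O/E is drawn per gene from the mixture (truncated to > 0),
    then a sequence of fixed base composition is built whose realized
    CpG O/E is within ``tol`` of the target.  Base counts are held fixed
    and only placement varies, so GpC O/E stays near 1 and the CpG
    depletion is not confounded with GC content.

    Returns {gene_id: sequence}.
    """
    if length < 500:
        raise ValueError("length must be >= 500")
    if np.asarray(means, dtype=float).min() <= 0:
        raise ValueError("component means must be positive")
    rng = np.random.default_rng(seed)
    targets = sample_mixture(means, sds, n, weights=weights,
                             seed=rng.integers(2 ** 31))
    out = {}
    for i, t in enumerate(targets):
        out[f"sim{i + 1:05d}"] = _build_sequence(rng, length, gc, float(t),
                                                 tol)
    return out
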