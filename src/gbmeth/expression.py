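"""Methylation–expression analyses.

Three questions, mirroring the classic gene-body-methylation observations
in invertebrates:

1. Do methylated genes have higher expression?  Genes are binned by
   weighted methylation level W into low [0, 0.2], medium (0.2, 0.7] and
   high (0.7, 1] classes and FPKM distributions are compared pairwise by
   Wilcoxon rank-sum tests.
2. Does differential methylation between populations track differential
   expression?  Per-gene ΔW (population A minus B) is correlated
   (Spearman) with log2 fold change of mean FPKM over the genes in the
   top 5% of |ΔW|, after requiring at least 11 covered CpG sites.
3. Are methylated genes more stably expressed?  Per-gene SD of
   log2(FPKM) across individuals is compared against methylation level.
"""

from __future__ import annotations

import itertools
import logging
import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "group_mean_fpkm",
    "log2_fold_change",
    "methylation_classes",
    "pairwise_wilcoxon",
    "spearman",
    "differential_table",
    "expression_stability",
]

DEFAULT_PSEUDOCOUNT = 0.01
CLASS_LABELS = ("low", "medium", "high")


def group_mean_fpkm(matrix, group) -> pd.Series:
    """Per-gene arithmetic mean FPKM over the samples of one group."""
    samples = matrix.samples_in(group)
    return matrix.fpkm[samples].mean(axis=1)


def log2_fold_change(mean_a, mean_b, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log2((meanA + c) / (meanB + c)) with pseudocount c.

    Accepts scalars or aligned vectors.  With c = 0 a zero mean on either
    side is undefined and raises.
    """
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("FPKM means must be non-negative")
    if pseudocount == 0 and ((a == 0) | (b == 0)).any():
        raise ValueError(
            "zero mean FPKM with pseudocount 0: fold change undefined"
        )
    out = np.log2(a + pseudocount) - np.log2(b + pseudocount)
    return out if out.ndim else float(out)


def methylation_classes(w) -> np.ndarray:
    """Bin W into low [0, 0.2], medium (0.2, 0.7], high (0.7, 1].

    The published bin edges overlap at 0.2 and 0.7; boundary values are
    assigned to the lower class.
    """
    arr = np.asarray(w, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("W must lie in [0, 1]")
    out = np.where(arr <= 0.2, "low", np.where(arr <= 0.7, "medium", "high"))
    return out if out.ndim else str(out)


def _rankdata(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _exact_wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of group assignments.

    p = 2 * min(P(U <= u), P(U >= u)) capped at 1, over the permutation
    distribution of the Mann–Whitney U statistic of the pooled sample
    (ties handled exactly by enumeration).
    """
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = _rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for comb in itertools.combinations(range(n + m), n):
        us.append(ranks[list(comb)].sum())
    us = np.asarray(us) - n * (n + 1) / 2
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_ranksum(x, y, exact_max_n: int = 8):
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact by enumeration when both groups have at most ``exact_max_n``
    observations; otherwise the normal approximation with tie correction
    and continuity correction.  Returns (U statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        ranks = _rankdata(np.concatenate([x, y]))
        u = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2
        return float(u), _exact_wilcoxon_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pairwise_wilcoxon(values_by_class: dict) -> pd.DataFrame:
    """All pairwise rank-sum tests between expression classes.

    ``values_by_class`` maps a class label to its per-gene values.
    Classes with fewer than 2 genes are skipped with a warning.
    Returns a DataFrame with columns class_a, class_b, n_a, n_b, u, p.
    """
    usable = {k: np.asarray(v, dtype=float)
              for k, v in values_by_class.items() if len(v) >= 2}
    skipped = set(values_by_class) - set(usable)
    if skipped:
        logger.warning("classes skipped (fewer than 2 genes): %s",
                       sorted(skipped))
    if len(usable) < 2:
        raise ValueError("need at least 2 non-empty classes")
    rows = []
    for a, b in itertools.combinations(usable, 2):
        u, p = wilcoxon_ranksum(usable[a], usable[b])
        rows.append((a, b, len(usable[a]), len(usable[b]), u, p))
    return pd.DataFrame(rows, columns=["class_a", "class_b", "n_a", "n_b",
                                       "u", "p"])


@lru_cache(maxsize=4)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman(x, y, exact_max_n: int = 9):
    """Spearman rank correlation with average ranks for ties.

    The p-value is exact by full permutation enumeration for
    n <= ``exact_max_n`` (two-sided: P(|rho_perm| >= |rho_obs|)), and the
    usual t-approximation for larger n.  Returns (rho, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rx = _rankdata(x)
    ry = _rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = _perm_matrix(n)
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        rhos = (ry_c[perms] @ rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def differential_table(meth_a: pd.DataFrame, meth_b: pd.DataFrame,
                       mean_fpkm_a: pd.Series, mean_fpkm_b: pd.Series,
                       top_fraction: float = 0.05, min_cpg: int = 10,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Differential methylation vs differential expression between two
    populations.

    ``meth_a``/``meth_b`` are per-gene methylation tables (feature_id, W,
    n_cpg_sites) for populations A and B; ``mean_fpkm_a``/``mean_fpkm_b``
    are per-gene replicate-mean FPKM Series.  Genes need more than
    ``min_cpg`` covered CpG sites in both populations.  ΔW = W_A − W_B.
    The top ``top_fraction`` of genes by |ΔW| (⌈f·n⌉ genes, ties at the
    cutoff all kept) are flagged, and Spearman's correlation between
    log2FC and ΔW is computed over the flagged genes.

    Returns (table, rho, p); the table has columns gene_id, delta_w,
    log2fc, passed_top5.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    a = meth_a.set_index("feature_id")
    b = meth_b.set_index("feature_id")
    genes = a.index.intersection(b.index)
    genes = genes[(a.loc[genes, "n_cpg_sites"] > min_cpg)
                  & (b.loc[genes, "n_cpg_sites"] > min_cpg)]
    genes = genes.intersection(mean_fpkm_a.index).intersection(
        mean_fpkm_b.index)
    n = len(genes)
    if n == 0:
        raise ValueError("no genes survive the CpG-count filter")
    delta_w = (a.loc[genes, "W"] - b.loc[genes, "W"]).to_numpy()
    log2fc = log2_fold_change(
        mean_fpkm_a.loc[genes].to_numpy(), mean_fpkm_b.loc[genes].to_numpy(),
        pseudocount,
    )
    n_top = math.ceil(top_fraction * n)
    abs_dw = np.abs(delta_w)
    cutoff = np.sort(abs_dw)[::-1][n_top - 1]
    passed = abs_dw >= cutoff
    if passed.sum() > n_top:
        logger.info("top-%g%% cutoff ties: flagged %d genes (> %d)",
                    100 * top_fraction, int(passed.sum()), n_top)
    tab = pd.DataFrame({
        "gene_id": genes,
        "delta_w": delta_w,
        "log2fc": log2fc,
        "passed_top5": passed,
    })
    flagged = tab[tab["passed_top5"]]
    if len(flagged) < 10:
        logger.warning("only %d genes flagged; correlation is unstable",
                       len(flagged))
    if len(flagged) >= 3 and np.ptp(flagged["delta_w"]) > 0 \
            and np.ptp(flagged["log2fc"]) > 0:
        rho, p = spearman(flagged["log2fc"], flagged["delta_w"])
    else:
        rho, p = float("nan"), float("nan")
    return tab, rho, p


def expression_stability(matrix, individuals, meth_table: pd.DataFrame,
                         require_expressed_in_all: bool = True,
                         pseudocount: float = DEFAULT_PSEUDOCOUNT
                         ) -> pd.DataFrame:
    """Per-gene SD of log2(FPKM) across individuals vs methylation level.

    With ``require_expressed_in_all`` (default) only genes with FPKM > 0
    in every listed individual enter, and log2 is taken on raw FPKM; in
    the permissive mode genes expressed in at least one individual enter
    and a pseudocount keeps log2 finite.  Sample SD (n−1 denominator).

    Returns a DataFrame with columns gene_id, sd_log2_fpkm, mean_log2_fpkm,
    plus the W (and frac_sites_called, if available) of ``meth_table``.
    """
    individuals = list(individuals)
    if len(individuals) < 2:
        raise ValueError("need at least 2 individuals")
    sub = matrix.fpkm[individuals]
    if require_expressed_in_all:
        sub = sub[(sub > 0).all(axis=1)]
        logm = np.log2(sub)
    else:
        sub = sub[(sub > 0).any(axis=1)]
        logm = np.log2(sub + pseudocount)
    out = pd.DataFrame({
        "gene_id": logm.index,
        "sd_log2_fpkm": logm.std(axis=1, ddof=1).to_numpy(),
        "mean_log2_fpkm": logm.mean(axis=1).to_numpy(),
    })
    keep = ["feature_id", "W"]
    if "frac_sites_called" in meth_table.columns:
        keep.append("frac_sites_called")
    out = out.merge(meth_table[keep], left_on="gene_id",
                    right_on="feature_id").drop(columns="feature_id")
    return out
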