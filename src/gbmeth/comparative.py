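"""Cross-species analyses: ortholog pairing, alignment filtering, and
CpG O/E / evolutionary-rate correlations.

Orthologs between two gene sets are inferred by reciprocal best hits
(RBH): a pair (a, b) is kept only when b is a's unique top-scoring hit
and a is b's unique top-scoring hit.  Codon alignments are cleaned with
a sliding-window identity filter before rate estimation: a codon is kept
when it lies in at least one frame-aligned 60-bp window with at most 10
non-identical positions (SNPs and gaps both count), and only filtered
alignments longer than 180 bp are retained.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "reciprocal_best_hits",
    "filter_codon_alignment",
    "ortholog_correlations",
    "pearson_with_ci",
]


def _unique_best(hits: pd.DataFrame) -> dict:
    """query -> subject for queries with a unique top-scoring hit."""
    best = {}
    for query, grp in hits.groupby("query"):
        scores = grp["score"].to_numpy()
        if not np.isfinite(scores).all():
            raise ValueError(f"non-finite score for query {query!r}")
        top = scores.max()
        winners = grp.loc[scores == top, "subject"].unique()
        if len(winners) == 1:
            best[query] = winners[0]
    return best


def reciprocal_best_hits(hits_ab: pd.DataFrame,
                         hits_ba: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal-best-hit ortholog pairs from two directed hit tables.

    Each table needs columns query, subject, score (higher is better).
    A tie for a query's best hit disqualifies that query.  The result is
    symmetric in the two inputs.

    Returns a DataFrame with columns gene_a, gene_b.
    """
    best_ab = _unique_best(hits_ab)
    best_ba = _unique_best(hits_ba)
    pairs = sorted(
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    )
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


def filter_codon_alignment(seq_a: str, seq_b: str, window: int = 60,
                           max_mismatch: int = 10, min_length: int = 180):
    """Window-identity filter on a pairwise codon alignment.

    The two aligned sequences must have equal length divisible by 3.
    Windows of ``window`` bp slide in 3-bp (codon) steps; a window passes
    when it contains at most ``max_mismatch`` non-identical positions.
    A codon is kept iff it lies fully inside at least one passing window;
    kept codons are concatenated in order.  The filtered alignment is
    retained only when strictly longer than ``min_length`` bp.

    Returns (filtered_a, filtered_b), or None when the result is too
    short.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    if len(seq_a) % 3 != 0:
        raise ValueError("alignment length is not a multiple of 3")
    if window % 3 != 0:
        raise ValueError("window must be a whole number of codons")
    a = np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)
    mismatch = (a != b).astype(np.int64)
    n_codons = len(a) // 3
    w_codons = window // 3
    keep = np.zeros(n_codons, dtype=bool)
    if n_codons >= w_codons:
        cum = np.concatenate([[0], np.cumsum(mismatch)])
        # window starting at codon i covers bases [3i, 3i+window)
        n_windows = n_codons - w_codons + 1
        starts = 3 * np.arange(n_windows)
        counts = cum[starts + window] - cum[starts]
        passing = counts <= max_mismatch
        for i in np.flatnonzero(passing):
            keep[i : i + w_codons] = True
    idx = np.repeat(keep, 3)
    fa = bytes(a[idx]).decode("ascii")
    fb = bytes(b[idx]).decode("ascii")
    if len(fa) <= min_length:
        return None
    return fa, fb


def pearson_with_ci(x, y, alpha: float = 0.05):
    """Pearson r with a Fisher-z confidence interval.

    Returns (r, p, ci_low, ci_high).  Degenerate at |r| = 1, where the
    interval collapses to the point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0 - 1e-15 or n <= 3:
        return float(r), float(p), float(r), float(r)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return (float(r), float(p), math.tanh(z - crit * se),
            math.tanh(z + crit * se))


def ortholog_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Correlation report over an ortholog table.

    ``records`` needs columns cpg_oe_a and cpg_oe_b and may carry dn, ds,
    dn_ds.  Reports Pearson r with 95% Fisher-z CI for the cross-species
    CpG O/E correlation, and for each available rate column against the
    per-gene mean CpG O/E of the two species.  Rows with missing values
    are dropped pairwise.
    """
    rows = []

    def _add(label, x, y):
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < 3:
            logger.warning("%s: fewer than 3 complete pairs; skipped", label)
            return
        r, p, lo, hi = pearson_with_ci(x[mask], y[mask])
        rows.append((label, int(mask.sum()), r, lo, hi, p))

    oe_a = records["cpg_oe_a"].to_numpy(dtype=float)
    oe_b = records["cpg_oe_b"].to_numpy(dtype=float)
    _add("cpg_oe_a_vs_cpg_oe_b", oe_a, oe_b)
    mean_oe = (oe_a + oe_b) / 2.0
    for col in ("dn", "ds", "dn_ds"):
        if col in records.columns:
            _add(f"{col}_vs_mean_cpg_oe",
                 records[col].to_numpy(dtype=float), mean_oe)
    if not rows:
        raise ValueError("no computable correlations in ortholog table")
    return pd.DataFrame(
        rows, columns=["comparison", "n", "r", "ci_low", "ci_high", "p"]
    )
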