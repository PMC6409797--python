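"""Per-cytosine methylation calling.

Bisulfite treatment converts unmethylated cytosines to uracil (read as T)
while methylated cytosines stay C.  Conversion is imperfect: an
unmethylated phage λDNA spike-in, which carries no methylation, estimates
the per-read failure rate ε — the probability that an unmethylated C is
nevertheless read as methylated.  Given ε, a site with m methylated reads
out of n is tested against Binomial(n, ε) with a one-sided upper-tail
p-value, p-values are converted to false discovery rates genome-wide by
the Benjamini–Hochberg step-up procedure, and sites with q below the
threshold (default 0.01) are called methylated.

Sites are depth-filtered before testing: depth below 5 gives unreliable
proportions, and depth above 30 flags collapsed repeats or mapping
artifacts, so the default retained band is [5, 30] inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ConversionControl",
    "estimate_conversion_error",
    "filter_by_depth",
    "binomial_pvalue",
    "bh_fdr",
    "call_methylation",
]


@dataclass(frozen=True)
class ConversionControl:
    """Bisulfite conversion-failure rate estimated from a spike-in control.

    ``error_rate`` is ε, the per-read probability that an unmethylated
    cytosine reads as methylated; the conversion rate is 1 − ε.
    """

    error_rate: float
    n_read_observations: int

    @property
    def conversion_rate(self) -> float:
        return 1.0 - self.error_rate


def estimate_conversion_error(control: pd.DataFrame) -> ConversionControl:
    """Pooled ε over control sites: total methylated reads / total reads."""
    if len(control) == 0:
        raise ValueError("empty conversion control table")
    total = int(control["depth"].sum())
    if total == 0:
        raise ValueError("conversion control has zero total read depth")
    eps = float(control["count_meth"].sum()) / total
    if total < 1000:
        logger.warning(
            "conversion error estimated from only %d read observations; "
            "low confidence", total,
        )
    logger.info(
        "conversion control: eps=%.5f (conversion rate %.2f%%) from %d reads",
        eps, 100.0 * (1.0 - eps), total,
    )
    return ConversionControl(error_rate=eps, n_read_observations=total)


def filter_by_depth(sites: pd.DataFrame, min_depth: int = 5,
                    max_depth: float = 30) -> pd.DataFrame:
    """Retain sites with min_depth <= depth <= max_depth (both inclusive)."""
    if min_depth > max_depth:
        raise ValueError(
            f"min_depth ({min_depth}) exceeds max_depth ({max_depth})"
        )
    keep = (sites["depth"] >= min_depth) & (sites["depth"] <= max_depth)
    return sites[keep]


def binomial_pvalue(count_meth, depth, error_rate: float):
    """One-sided upper-tail P(X >= m) for X ~ Binomial(n, ε).

    Accepts scalars or arrays.  m = 0 gives p = 1 exactly.  With ε = 0
    any m > 0 gives p = 0, which is flagged in the log since it forces
    the smallest possible q-values.
    """
    m = np.asarray(count_meth)
    n = np.asarray(depth)
    if (m < 0).any() or (m > n).any():
        raise ValueError("need 0 <= count_meth <= depth")
    if np.asarray(n).min() < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error rate must be in [0, 1]")
    if error_rate == 0.0 and (m > 0).any():
        logger.warning(
            "error rate is exactly 0; sites with any methylated read get p=0"
        )
    # sf(m-1) = P(X >= m); exact 1.0 at m=0
    p = binom.sf(m - 1, n, error_rate)
    return p if p.ndim else float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved.

    q_(i) = min over j >= i of p_(j) * N / j on the sorted p-values,
    capped at 1; ties share the rank of the step-up minimum.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to BH")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def call_methylation(sites: pd.DataFrame, error_rate: float,
                     q_threshold: float = 0.01, min_depth: int = 5,
                     max_depth: float = 30,
                     per_context: bool = False) -> pd.DataFrame:
    """Depth-filter, test, and call methylation for a site table.

    The BH procedure runs jointly over all retained sites — all contexts
    and chromosomes in one family — matching a single genome-wide
    correction; ``per_context=True`` instead corrects within each cytosine
    context separately.

    Returns the retained sites with added columns ``p_value``, ``q_value``
    and ``is_methylated`` (q < q_threshold).  Per-context methylated
    fractions are attached as ``result.attrs["context_summary"]``.
    """
    if isinstance(error_rate, ConversionControl):
        error_rate = error_rate.error_rate
    retained = filter_by_depth(sites, min_depth, max_depth).copy()
    logger.info("depth filter [%s, %s]: retained %d of %d sites",
                min_depth, max_depth, len(retained), len(sites))
    if len(retained) == 0:
        retained["p_value"] = np.array([], dtype=float)
        retained["q_value"] = np.array([], dtype=float)
        retained["is_methylated"] = np.array([], dtype=bool)
        retained.attrs["context_summary"] = pd.DataFrame(
            columns=["context", "n_sites", "n_methylated", "frac_methylated"]
        )
        return retained
    p = binomial_pvalue(
        retained["count_meth"].to_numpy(), retained["depth"].to_numpy(),
        error_rate,
    )
    retained["p_value"] = p
    if per_context:
        q = np.empty_like(p)
        for ctx, idx in retained.groupby("context").indices.items():
            q[idx] = bh_fdr(p[idx])
        retained["q_value"] = q
    else:
        retained["q_value"] = bh_fdr(p)
    retained["is_methylated"] = retained["q_value"] < q_threshold

    summary = (
        retained.groupby("context", observed=True)
        .agg(n_sites=("is_methylated", "size"),
             n_methylated=("is_methylated", "sum"))
        .reset_index()
    )
    summary["frac_methylated"] = summary["n_methylated"] / summary["n_sites"]
    retained.attrs["context_summary"] = summary
    for row in summary.itertuples(index=False):
        logger.info("context %s: %d/%d sites methylated (%.2f%%)",
                    row.context, row.n_methylated, row.n_sites,
                    100.0 * row.frac_methylated)
    return retained
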