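"""CpG observed/expected ratios and normal-mixture decomposition.

CpG O/E compares the observed number of CpG dinucleotides in a sequence
with the number expected from its C and G content alone:

    CpG O/E = (L * #CpG) / (#C * #G)

Methylated cytosines deaminate to thymine at an elevated rate, so regions
with a history of CpG methylation are depleted of CpG dinucleotides and
show O/E well below 1.  GpC O/E, computed with the same formula on GC
dinucleotides, is unaffected by CpG-specific deamination and serves as a
negative control.  Across a gene set, the O/E distribution is typically a
mixture of a depleted (historically methylated) and a non-depleted mode;
``fit_normal_mixture`` decomposes it into Gaussian components by
expectation-maximisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceComposition",
    "KDEResult",
    "MixtureFit",
    "composition",
    "cpg_oe",
    "gpc_oe",
    "genome_fragment_scan",
    "kde",
    "fit_normal_mixture",
    "gene_set_cpgoe",
    "STEGODYPHUS_MIXTURES",
]

# Published CpG O/E mixture components for protein-coding genes of the two
# social Stegodyphus spider species (equal-weight convention for sampling).
# Each entry: (means, standard deviations), components sorted by mean.
STEGODYPHUS_MIXTURES = {
    "dumicola": ((0.35, 0.65), (0.10, 0.19)),
    "mimosarum": ((0.34, 0.71, 1.04), (0.11, 0.24, 0.02)),
}


@dataclass(frozen=True)
class SequenceComposition:
    """Base and dinucleotide counts of one nucleotide sequence.

    Positions with non-ACGT symbols are excluded from base counts, and a
    dinucleotide is only counted when both of its bases are valid.
    ``length`` is the full sequence length L used in the O/E formula.
    """

    length: int
    n_cpg: int
    n_gpc: int
    n_c: int
    n_g: int


@dataclass(frozen=True)
class KDEResult:
    """Gaussian kernel density estimate on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


@dataclass(frozen=True)
class MixtureFit:
    """A k-component univariate normal mixture fitted by EM.

    Components are sorted by ascending mean.  ``weights`` sum to one.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_observations: int = 0

    def bic(self) -> float:
        """Bayesian information criterion (lower is better)."""
        n_params = 3 * self.k - 1
        return n_params * math.log(self.n_observations) - 2.0 * self.log_likelihood

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        comp = np.exp(-0.5 * ((x - self.means) / self.sds) ** 2) / (
            self.sds * math.sqrt(2.0 * math.pi)
        )
        return (comp * self.weights).sum(axis=-1)


_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def composition(seq: str) -> SequenceComposition:
    """Count C, G, CpG and GpC in ``seq``, case-insensitively.

    Overlapping dinucleotides are counted (every position pair i, i+1),
    and any pair touching a non-ACGT base is skipped.
    """
    arr = _encode(seq)
    valid = np.isin(arr, _VALID)
    c = arr == ord("C")
    g = arr == ord("G")
    n_c = int(np.count_nonzero(c & valid))
    n_g = int(np.count_nonzero(g & valid))
    if arr.size >= 2:
        pair_ok = valid[:-1] & valid[1:]
        n_cpg = int(np.count_nonzero(c[:-1] & g[1:] & pair_ok))
        n_gpc = int(np.count_nonzero(g[:-1] & c[1:] & pair_ok))
    else:
        n_cpg = n_gpc = 0
    return SequenceComposition(
        length=arr.size, n_cpg=n_cpg, n_gpc=n_gpc, n_c=n_c, n_g=n_g
    )


def cpg_oe(comp: SequenceComposition) -> float:
    """(L * #CpG) / (#C * #G); NaN when the sequence has no C or no G."""
    if comp.n_c == 0 or comp.n_g == 0:
        logger.debug("CpG O/E undefined: n_C=%d n_G=%d", comp.n_c, comp.n_g)
        return float("nan")
    return comp.length * comp.n_cpg / (comp.n_c * comp.n_g)


def gpc_oe(comp: SequenceComposition) -> float:
    """(L * #GpC) / (#C * #G); NaN when the sequence has no C or no G."""
    if comp.n_c == 0 or comp.n_g == 0:
        return float("nan")
    return comp.length * comp.n_gpc / (comp.n_c * comp.n_g)


def genome_fragment_scan(genome, fragment: int = 1000):
    """Per-fragment CpG O/E and GpC O/E over non-overlapping tiles.

    Parameters
    ----------
    genome
        Mapping of contig name to sequence string.
    fragment
        Tile length in bp (>= 100).  Tiling starts at position 0 of each
        contig; a trailing fragment shorter than ``fragment`` is dropped so
        that L is constant across fragments.

    Returns
    -------
    pandas.DataFrame with columns chrom, start, end, cpg_oe, gpc_oe.
    Fragments with no C or no G carry NaN.
    """
    import pandas as pd

    if fragment < 100:
        raise ValueError(f"fragment length must be >= 100, got {fragment}")
    rows = []
    for chrom in genome:
        seq = genome[chrom]
        n_frag = len(seq) // fragment
        for i in range(n_frag):
            start = i * fragment
            comp = composition(seq[start : start + fragment])
            rows.append(
                (chrom, start, start + fragment, cpg_oe(comp), gpc_oe(comp))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cpg_oe", "gpc_oe"]
    )


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    a = min(sd, iqr / 1.34) if iqr > 0 else sd
    if a == 0:
        raise ValueError("cannot choose a bandwidth for constant data")
    return 0.9 * a * n ** (-1 / 5)


def kde(values, bandwidth: float | None = None, drop_zeros: bool = True,
        grid_size: int = 512) -> KDEResult:
    """Gaussian kernel density estimate with Silverman's rule of thumb.

    Zero values are removed by default before estimation: in gene-level
    CpG O/E data a zero almost always reflects a sequence too short to
    contain any CpG, not genuine total depletion.
    """
    from scipy.stats import gaussian_kde

    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if drop_zeros:
        x = x[x != 0.0]
    if x.size < 2:
        raise ValueError("need at least 2 finite values for a KDE")
    h = float(bandwidth) if bandwidth is not None else _silverman_bandwidth(x)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    est = gaussian_kde(x, bw_method=h / x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    return KDEResult(grid=grid, density=est(grid), bandwidth=h)


def _em_run(x, pi, mu, sigma, sigma_floor, tol, max_iter):
    """One EM run; returns (pi, mu, sigma, loglik, n_iter, converged)."""
    n = x.size
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step in log space
        log_comp = (
            -0.5 * ((x[:, None] - mu) / sigma) ** 2
            - np.log(sigma)
            - 0.5 * math.log(2.0 * math.pi)
            + np.log(pi)
        )
        log_norm = logsumexp(log_comp, axis=1)
        loglik = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        pi = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sigma = np.maximum(np.sqrt(var), sigma_floor)
        if loglik - prev < -1e-9 * max(1.0, abs(prev)):
            raise RuntimeError("EM log-likelihood decreased")  # pragma: no cover
        if abs(loglik - prev) < tol * max(1.0, abs(loglik)):
            converged = True
            break
        prev = loglik
    return pi, mu, sigma, loglik, it, converged


def fit_normal_mixture(values, k: int, n_starts: int = 10, tol: float = 1e-8,
                       max_iter: int = 2000, seed=None,
                       drop_zeros: bool = True) -> MixtureFit:
    """Fit a k-component univariate normal mixture by EM.

    The best of ``n_starts`` initialisations (k-quantile means, the first
    unjittered and the rest jittered) is kept by final log-likelihood.
    Component standard deviations are floored at 1e-4 of the sample SD so
    a component cannot collapse onto a single observation.  Zeros are
    removed by default for the same reason as in :func:`kde`.

    Returns a :class:`MixtureFit` with components sorted by mean.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if drop_zeros:
        x = x[x != 0.0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} values to fit k={k}")
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot fit a mixture to constant data")
    sigma_floor = 1e-4 * sd
    rng = np.random.default_rng(seed)
    quant = np.quantile(x, (np.arange(k) + 0.5) / k)

    best = None
    n_failed = 0
    for s in range(n_starts):
        mu0 = quant.copy()
        if s > 0:
            mu0 = mu0 + rng.normal(0.0, 0.25 * sd, size=k)
        sigma0 = np.full(k, sd)
        pi0 = np.full(k, 1.0 / k)
        try:
            out = _em_run(x, pi0, mu0, sigma0, sigma_floor, tol, max_iter)
        except (RuntimeError, FloatingPointError):  # pragma: no cover
            n_failed += 1
            continue
        if best is None or out[3] > best[3]:
            best = out
    if best is None:  # pragma: no cover
        raise RuntimeError("all EM starts failed")
    pi, mu, sigma, loglik, n_iter, converged = best
    order = np.argsort(mu)
    return MixtureFit(
        k=k,
        weights=pi[order],
        means=mu[order],
        sds=sigma[order],
        log_likelihood=loglik,
        n_iterations=n_iter,
        converged=converged,
        n_observations=x.size,
    )


def gene_set_cpgoe(sequences, exclude=None):
    """Per-gene CpG O/E (and GpC O/E) table for a set of gene sequences.

    Parameters
    ----------
    sequences
        Mapping of gene id to nucleotide sequence.
    exclude
        Optional collection of gene ids to drop, e.g. genes located in
        repetitive regions whose O/E reflects repeat dynamics rather than
        methylation history.

    Returns
    -------
    pandas.DataFrame with columns gene_id, length, n_cpg, cpg_oe, gpc_oe,
    is_zero (flagging zero O/E values that KDE/mixture steps will drop).
    """
    import pandas as pd

    if not sequences:
        raise ValueError("empty sequence set")
    excl = set(exclude) if exclude is not None else set()
    rows = []
    for gid, seq in sequences.items():
        if gid in excl:
            continue
        comp = composition(seq)
        oe = cpg_oe(comp)
        rows.append(
            (gid, comp.length, comp.n_cpg, oe, gpc_oe(comp), oe == 0.0)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "length", "n_cpg", "cpg_oe", "gpc_oe", "is_zero"],
    )


def sample_mixture(means, sds, n, weights=None, seed=None,
                   truncate_positive: bool = True) -> np.ndarray:
    """Draw ``n`` values from a normal mixture, optionally truncated to > 0.

    Used both by the sequence simulator and by parameter-recovery checks
    against the published Stegodyphus component parameters.  Negative (and
    zero) draws are redrawn when ``truncate_positive`` is set, since an
    O/E ratio cannot be negative.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    k = means.size
    if weights is None:
        weights = np.full(k, 1.0 / k)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    comp = rng.choice(k, size=n, p=weights)
    x = rng.normal(means[comp], sds[comp])
    if truncate_positive:
        bad = x <= 0
        while bad.any():
            comp_bad = rng.choice(k, size=int(bad.sum()), p=weights)
            x[bad] = rng.normal(means[comp_bad], sds[comp_bad])
            bad = x <= 0
    return x
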