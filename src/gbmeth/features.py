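"""Aggregation of site-level methylation into genomic features.

The overall methylation level of a feature is the weighted methylation
level W = Σ mᵢ / Σ (mᵢ + uᵢ) over the feature's covered CpG sites, i.e.
each site contributes in proportion to its read depth rather than each
site counting equally.  W is computed from raw counts for all retained
sites; the binomial calls feed only the fraction of sites called
methylated.

Gene bodies span exons plus introns; a transposable element is "genic"
when fully contained in a gene span (including introns), "intergenic"
when it overlaps no gene, and "boundary" otherwise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "assign_sites_to_features",
    "weighted_methylation",
    "feature_methylation_table",
    "classify_te_location",
    "element_summary",
]

TE_KINDS = ("DNA_TE", "RNA_TE", "unclassified_repeat")


def _intervals_nonoverlapping(starts: np.ndarray, ends: np.ndarray) -> bool:
    order = np.argsort(starts, kind="stable")
    return bool((starts[order][1:] >= ends[order][:-1]).all())


def _assign_chrom(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                  idx: np.ndarray):
    """(site_index, feature_index) pairs for one chromosome.

    Non-overlapping feature sets use a searchsorted fast path; nested or
    overlapping sets fall back to an interval tree.
    """
    if len(starts) == 0 or len(pos) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    if _intervals_nonoverlapping(starts, ends):
        order = np.argsort(starts, kind="stable")
        s, e, fi = starts[order], ends[order], idx[order]
        j = np.searchsorted(s, pos, side="right") - 1
        ok = (j >= 0) & (pos < e[np.clip(j, 0, len(e) - 1)])
        return np.flatnonzero(ok), fi[j[ok]]
    from intervaltree import IntervalTree

    tree = IntervalTree()
    for s, e, fi in zip(starts, ends, idx):
        tree.addi(int(s), int(e), int(fi))
    site_idx, feat_idx = [], []
    for i, p in enumerate(pos):
        for iv in tree.at(int(p)):
            site_idx.append(i)
            feat_idx.append(iv.data)
    return np.asarray(site_idx, dtype=np.int64), np.asarray(feat_idx,
                                                            dtype=np.int64)


def assign_sites_to_features(sites: pd.DataFrame,
                             features: pd.DataFrame) -> pd.DataFrame:
    """Map each site to every feature interval containing it.

    Site positions are 1-based; features are 0-based half-open, so a site
    at position p lies in [start, end) iff start <= p-1 < end.  A site may
    land in several nested features (a gene and one of its exons).  Sites
    outside every gene are additionally reported with feature id
    ``"intergenic"``.

    Returns a long DataFrame with columns site_index (positional index
    into ``sites``), feature_id, kind.
    """
    pos0_all = sites["pos"].to_numpy() - 1
    chrom_s = sites["chrom"].to_numpy()
    out_site, out_feat = [], []
    feat_ids = features["id"].to_numpy()
    feat_kinds = features["kind"].to_numpy()
    for chrom in pd.unique(chrom_s):
        in_chrom = np.flatnonzero(chrom_s == chrom)
        fmask = (features["chrom"] == chrom).to_numpy()
        fidx = np.flatnonzero(fmask)
        si, fi = _assign_chrom(
            pos0_all[in_chrom],
            features["start"].to_numpy()[fidx],
            features["end"].to_numpy()[fidx],
            fidx,
        )
        out_site.append(in_chrom[si])
        out_feat.append(fi)
        # intergenic = complement of gene spans
        gmask = fmask & (features["kind"] == "gene").to_numpy()
        gidx = np.flatnonzero(gmask)
        gsi, _ = _assign_chrom(
            pos0_all[in_chrom],
            features["start"].to_numpy()[gidx],
            features["end"].to_numpy()[gidx],
            gidx,
        )
        inter = np.setdiff1d(np.arange(len(in_chrom)), gsi)
        out_site.append(in_chrom[inter])
        out_feat.append(np.full(len(inter), -1, dtype=np.int64))
    site_index = np.concatenate(out_site) if out_site else np.empty(0, int)
    feat_index = np.concatenate(out_feat) if out_feat else np.empty(0, int)
    is_inter = feat_index < 0
    return pd.DataFrame({
        "site_index": site_index,
        "feature_id": np.where(is_inter, "intergenic", feat_ids[feat_index]),
        "kind": np.where(is_inter, "intergenic", feat_kinds[feat_index]),
    })


def weighted_methylation(sites: pd.DataFrame) -> float:
    """W = Σ count_meth / Σ depth over a site list; NaN when empty."""
    total = sites["depth"].sum()
    if len(sites) == 0 or total == 0:
        return float("nan")
    return float(sites["count_meth"].sum() / total)


def feature_methylation_table(sites: pd.DataFrame, features: pd.DataFrame,
                              min_cpg_sites: int = 0,
                              cpg_only: bool = True) -> pd.DataFrame:
    """Per-feature weighted methylation levels.

    Only CpG-context sites contribute by default (animal methylation is
    essentially CpG-restricted).  Features with no more than
    ``min_cpg_sites`` covered CpG sites are dropped — with the default
    gene filter of 10, a gene needs at least 11 covered sites to be kept.

    When ``sites`` carries an ``is_methylated`` column (from
    :func:`gbmeth.calling.call_methylation`) the fraction of sites called
    methylated is reported alongside W.

    Returns a DataFrame with columns feature_id, kind, W, n_cpg_sites,
    total_meth_reads, total_reads and (when calls are present)
    frac_sites_called.
    """
    use = sites[sites["context"] == "CpG"] if cpg_only else sites
    use = use.reset_index(drop=True)
    assign = assign_sites_to_features(use, features)
    assign = assign[assign["feature_id"] != "intergenic"]
    have_calls = "is_methylated" in use.columns
    joined = assign.merge(
        use[["count_meth", "depth"] + (["is_methylated"] if have_calls else [])],
        left_on="site_index", right_index=True,
    )
    agg = {
        "n_cpg_sites": ("site_index", "size"),
        "total_meth_reads": ("count_meth", "sum"),
        "total_reads": ("depth", "sum"),
    }
    if have_calls:
        agg["n_sites_called"] = ("is_methylated", "sum")
    tab = (
        joined.groupby(["feature_id", "kind"], observed=True)
        .agg(**agg)
        .reset_index()
    )
    tab["W"] = tab["total_meth_reads"] / tab["total_reads"]
    if have_calls:
        tab["frac_sites_called"] = tab["n_sites_called"] / tab["n_cpg_sites"]
        tab = tab.drop(columns="n_sites_called")
    if min_cpg_sites > 0:
        n0 = len(tab)
        tab = tab[tab["n_cpg_sites"] > min_cpg_sites]
        logger.info("CpG-count filter (> %d sites): kept %d of %d features",
                    min_cpg_sites, len(tab), n0)
    cols = ["feature_id", "kind", "W", "n_cpg_sites", "total_meth_reads",
            "total_reads"]
    if have_calls:
        cols.append("frac_sites_called")
    return tab[cols].reset_index(drop=True)


def classify_te_location(tes: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Classify each TE as genic, intergenic, or boundary.

    genic: contained in some gene span (a TE nested in an intron counts);
    intergenic: overlaps no gene; boundary: partial overlap.
    """
    out = []
    for chrom, grp in tes.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        for row in grp.itertuples(index=False):
            overlap = (gs < row.end) & (ge > row.start)
            if not overlap.any():
                ctx = "intergenic"
            elif ((gs[overlap] <= row.start) & (ge[overlap] >= row.end)).any():
                ctx = "genic"
            else:
                ctx = "boundary"
            out.append((row.id, row.kind, ctx))
    return pd.DataFrame(out, columns=["te_id", "kind", "te_context"])


def element_summary(calls: pd.DataFrame, features: pd.DataFrame) -> dict:
    """Per-element-class CpG methylation summary.

    ``calls`` is a called site table (needs ``is_methylated``).  Produces

    - ``classes``: for overall / gene / exon / intron / intergenic and each
      annotated repeat class: number of covered CpG sites, fraction called
      methylated, and class-level weighted methylation level;
    - ``te_context``: per-TE weighted levels grouped by genomic context
      (genic / boundary / intergenic) with class medians.
    """
    cpg = calls[calls["context"] == "CpG"].reset_index(drop=True)
    assign = assign_sites_to_features(cpg, features)
    joined = assign.merge(
        cpg[["count_meth", "depth", "is_methylated"]],
        left_on="site_index", right_index=True,
    )

    def _summ(df, label):
        n = len(df)
        return {
            "element": label,
            "n_cpg_sites": n,
            "frac_methylated": float(df["is_methylated"].mean()) if n else np.nan,
            "W": float(df["count_meth"].sum() / df["depth"].sum())
            if n and df["depth"].sum() else np.nan,
        }

    rows = [_summ(cpg, "overall")]
    for kind in ("gene", "exon", "intron", "intergenic") + TE_KINDS:
        sub = joined[joined["kind"] == kind]
        if kind in TE_KINDS and len(sub) == 0 and \
                not (features["kind"] == kind).any():
            continue
        # a site may sit in several same-kind features; count it once
        rows.append(_summ(sub.drop_duplicates("site_index"), kind))
    classes = pd.DataFrame(rows)

    tes = features[features["kind"].isin(TE_KINDS)]
    genes = features[features["kind"] == "gene"]
    if len(tes):
        ctx = classify_te_location(tes, genes)
        per_te = feature_methylation_table(cpg, tes, min_cpg_sites=0)
        per_te = per_te.merge(ctx.drop(columns="kind"),
                              left_on="feature_id", right_on="te_id")
        med = (
            per_te.groupby(["kind", "te_context"], observed=True)
            .agg(n_tes=("W", "size"), median_W=("W", "median"))
            .reset_index()
        )
    else:
        per_te = pd.DataFrame(columns=["feature_id", "kind", "W",
                                       "te_context"])
        med = pd.DataFrame(columns=["kind", "te_context", "n_tes",
                                    "median_W"])
    return {"classes": classes, "te_context": med, "per_te": per_te}
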