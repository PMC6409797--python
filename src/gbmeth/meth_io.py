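"""Readers and writers for the formats the pipeline touches.

All genomic intervals are held internally as 0-based half-open [start, end)
regardless of the on-disk dialect; conversion happens only at the I/O
boundary.  Bismark-style coverage files are 1-based inclusive, GFF3 is
1-based inclusive, BED is already 0-based half-open.

The coverage dialect is the extended 8-column Bismark coverage file:

    chrom  start  end  percent_methylation  count_meth  count_unmeth  strand  context

i.e. the standard 6 columns plus strand ({+,-}) and cytosine context
({CpG, CHG, CHH}).  The percent column is advisory only; methylated and
unmethylated read counts are the source of truth.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_coverage",
    "write_coverage",
    "read_features",
    "write_gff3",
    "read_expression",
    "write_expression",
    "read_fasta",
    "write_fasta",
]

COVERAGE_COLUMNS = [
    "chrom", "start", "end", "percent", "count_meth", "count_unmeth",
    "strand", "context",
]
CONTEXTS = ("CpG", "CHG", "CHH")
FEATURE_KINDS = (
    "gene", "exon", "intron", "DNA_TE", "RNA_TE", "unclassified_repeat",
    "intergenic",
)

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "count_meth",
                "count_unmeth", "depth"]


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# coverage files

def read_coverage(path) -> pd.DataFrame:
    """Read an extended Bismark coverage file into a site table.

    Returns a DataFrame with columns chrom, pos (1-based), strand, context,
    count_meth, count_unmeth, depth.  The percent column is discarded (it
    is recomputable); a mismatch between it and the counts is warned about
    but not fatal.
    """
    with _open_text(path) as fh:
        try:
            df = pd.read_csv(
                fh, sep="\t", header=None, names=COVERAGE_COLUMNS,
                dtype={"chrom": str, "strand": str, "context": str},
            )
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=SITE_COLUMNS)
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"malformed coverage file {path}: {exc}") from exc
    if df.shape[1] != 8 or df["context"].isna().any():
        raise ValueError(
            f"{path}: expected the extended 8-column Bismark coverage dialect "
            "(chrom, start, end, percent, count_meth, count_unmeth, strand, "
            "context); found a line with fewer fields"
        )
    for col in ("start", "end", "count_meth", "count_unmeth"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna().idxmax() + 1
            raise ValueError(
                f"{path}: malformed {col!r} field at line {bad}"
            ) from exc
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        line = int(np.flatnonzero(bad_ctx.to_numpy())[0]) + 1
        raise ValueError(
            f"{path}: unknown context {df['context'][bad_ctx].iloc[0]!r} "
            f"at line {line}"
        )
    depth = df["count_meth"] + df["count_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        expect = 100.0 * df["count_meth"] / depth
    mismatch = depth.gt(0) & (expect - df["percent"]).abs().gt(0.51)
    if mismatch.any():
        logger.warning(
            "%s: percent column disagrees with counts on %d lines; "
            "counts are used", path, int(mismatch.sum()),
        )
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["start"].astype(np.int64),
        "strand": df["strand"],
        "context": df["context"],
        "count_meth": df["count_meth"],
        "count_unmeth": df["count_unmeth"],
        "depth": depth.astype(np.int64),
    })
    return out


def write_coverage(sites: pd.DataFrame, path) -> None:
    """Write a site table back to the extended 8-column coverage dialect."""
    depth = sites["count_meth"] + sites["count_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(depth > 0, 100.0 * sites["count_meth"] / depth, 0.0)
    out = pd.DataFrame({
        "chrom": sites["chrom"],
        "start": sites["pos"],
        "end": sites["pos"],
        "percent": percent,
        "count_meth": sites["count_meth"],
        "count_unmeth": sites["count_unmeth"],
        "strand": sites["strand"],
        "context": sites["context"],
    })
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False,
                   float_format="%.6g")


# ---------------------------------------------------------------------------
# feature annotations

_GFF3_TYPE_MAP = {
    "gene": "gene",
    "exon": "exon",
    "intron": "intron",
    "DNA_TE": "DNA_TE",
    "RNA_TE": "RNA_TE",
    "unclassified_repeat": "unclassified_repeat",
    "transposable_element": "DNA_TE",
    "repeat_region": "unclassified_repeat",
    "intergenic": "intergenic",
    "intergenic_region": "intergenic",
}


def _parse_gff3_attributes(text: str) -> dict:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_features(path, dialect: str = "gff3",
                  default_kind: str = "gene",
                  derive_introns: bool = True) -> pd.DataFrame:
    """Read a GFF3 or BED annotation into the internal feature table.

    Coordinates are normalized to 0-based half-open.  When a gene has exon
    records but no intron records, introns are derived as the gaps between
    consecutive exons.  Overlapping exons within one gene are an error.

    Returns a DataFrame with columns chrom, start, end, strand, kind, id,
    parent.
    """
    dialect = dialect.lower()
    if dialect == "gff3":
        rows = []
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ValueError(
                        f"{path}: line {ln}: expected 9 GFF3 fields, "
                        f"got {len(fields)}"
                    )
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
                kind = _GFF3_TYPE_MAP.get(ftype)
                if kind is None:
                    logger.debug("%s: line %d: skipping type %r", path, ln, ftype)
                    continue
                a = _parse_gff3_attributes(attrs)
                rows.append((
                    chrom, int(start) - 1, int(end), strand, kind,
                    a.get("ID", f"{kind}_{ln}"), a.get("Parent"),
                ))
        feats = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "kind", "id",
                           "parent"],
        )
    elif dialect == "bed":
        rows = []
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}: line {ln}: BED needs >= 3 fields"
                    )
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"{default_kind}_{ln}"
                strand = fields[5] if len(fields) > 5 else "."
                rows.append((chrom, start, end, strand, default_kind, name,
                             None))
        feats = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "kind", "id",
                           "parent"],
        )
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    if len(feats) and (feats["start"] >= feats["end"]).any():
        bad = feats[feats["start"] >= feats["end"]].iloc[0]
        raise ValueError(f"{path}: empty or inverted interval {bad['id']}")
    if derive_introns and len(feats):
        feats = _derive_introns(feats, source=str(path))
    return feats.reset_index(drop=True)


def _derive_introns(feats: pd.DataFrame, source: str = "") -> pd.DataFrame:
    exons = feats[feats["kind"] == "exon"]
    have_introns = set(feats.loc[feats["kind"] == "intron", "parent"].dropna())
    new_rows = []
    for gene_id, grp in exons.groupby("parent"):
        if gene_id is None:
            continue
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(
                f"{source}: overlapping exons within gene {gene_id!r}"
            )
        if gene_id in have_introns:
            continue
        for i, (a, b) in enumerate(zip(ends[:-1], starts[1:]), start=1):
            if b > a:
                new_rows.append((
                    grp["chrom"].iloc[0], a, b, grp["strand"].iloc[0],
                    "intron", f"{gene_id}.intron{i}", gene_id,
                ))
    if new_rows:
        feats = pd.concat(
            [feats, pd.DataFrame(new_rows, columns=feats.columns)],
            ignore_index=True,
        )
    return feats


def write_gff3(feats: pd.DataFrame, path) -> None:
    """Write the internal feature table as GFF3 (1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for row in feats.itertuples(index=False):
            attrs = f"ID={row.id}"
            if row.parent is not None and not (
                isinstance(row.parent, float) and np.isnan(row.parent)
            ):
                attrs += f";Parent={row.parent}"
            fh.write(
                f"{row.chrom}\tgbmeth\t{row.kind}\t{row.start + 1}\t{row.end}"
                f"\t.\t{row.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# expression

@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM matrix with a group label per sample.

    ``fpkm`` is indexed by gene id with one column per sample; ``groups``
    maps sample id to its group label (e.g. population or
    population x temperature combination).
    """

    fpkm: pd.DataFrame
    groups: dict

    def __post_init__(self):
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = set(self.fpkm.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")

    def samples_in(self, group) -> list:
        out = [s for s in self.fpkm.columns if self.groups[s] == group]
        if not out:
            raise KeyError(f"unknown or empty group {group!r}")
        return out


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x sample FPKM TSV.

    The first column holds gene ids.  Sample headers encode the group as
    ``group|sample``; a header without ``|`` becomes its own group.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    groups = {}
    rename = {}
    for col in df.columns:
        group, sep, sample = col.partition("|")
        if sep:
            rename[col] = sample
            groups[sample] = group
        else:
            groups[col] = col
    df = df.rename(columns=rename)
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample id after group parsing")
    return ExpressionMatrix(fpkm=df, groups=groups)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.fpkm.copy()
    df.columns = [f"{matrix.groups[s]}|{s}" for s in df.columns]
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    from Bio import SeqIO

    out = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"{path}: duplicate FASTA header {rec.id!r}")
            seq = str(rec.seq)
            if not seq:
                logger.warning("%s: empty sequence for %s", path, rec.id)
            out[rec.id] = seq
    return out


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
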