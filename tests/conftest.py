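import numpy as np
import pandas as pd
import pytest

from gbmeth.simulate import SimulationConfig, gen_annotation, gen_methylome


def make_sites(rows):
    """Site table from (chrom, pos, strand, context, m, u) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "count_meth",
                       "count_unmeth"],
    )
    df["depth"] = df["count_meth"] + df["count_unmeth"]
    return df


def make_features(rows):
    """Feature table from (chrom, start, end, strand, kind, id, parent)."""
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "kind", "id",
                       "parent"],
    )


@pytest.fixture(scope="session")
def small_world():
    """A small simulated genome, annotation and methylome shared by
    read-only tests."""
    cfg = SimulationConfig(n_genes=40, genome_length=80_000, seed=11)
    genome, feats = gen_annotation(cfg)
    sites, truth = gen_methylome(genome, feats, cfg)
    return {"cfg": cfg, "genome": genome, "features": feats,
            "sites": sites, "truth": truth}
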