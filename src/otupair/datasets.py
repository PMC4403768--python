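"""Bundled example data.

``load_chicken_top_otus`` rebuilds a two-column (pooled cecal, pooled
fecal) dataset from a published summary table of the most abundant OTUs
in paired chicken cecal and fecal communities.  The table lists each
OTU's percentage of its site's total reads; the loader adds synthetic
low-abundance filler OTUs so each column sums to 100%, which makes the
bundled percentages reproducible through :func:`top_abundance_table`.
"""

from __future__ import annotations

import importlib.resources as resources

import numpy as np
import pandas as pd

from .tables_io import Dataset, OtuTable, SampleRecord

__all__ = ["load_chicken_top_otus"]

N_FILLER = 100  # synthetic rows absorbing the unlisted remainder mass


def load_chicken_top_otus() -> Dataset:
    """Pooled cecal/fecal abundances of the dominant chicken gut OTUs.

    Returns a :class:`Dataset` with two samples (``pooled_cecal``,
    ``pooled_fecal``) whose columns each sum to 100, the listed OTUs at
    their published site percentages, ``FILLER_*`` OTUs sharing the
    remaining mass evenly, and taxonomy (closest isolate, % similarity)
    for the listed OTUs.
    """
    ref = resources.files("otupair.data") / "chicken_top_otus.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"otu_id": str})
    cecal = df["pct_cecal"].to_numpy(dtype=float)
    fecal = df["pct_fecal"].to_numpy(dtype=float)
    rem_c = 100.0 - cecal.sum()
    rem_f = 100.0 - fecal.sum()
    if rem_c < 0 or rem_f < 0:
        raise ValueError("bundled table percentages exceed 100")
    otu_ids = df["otu_id"].tolist() + [f"FILLER_{k + 1:03d}"
                                       for k in range(N_FILLER)]
    counts = np.column_stack([
        np.concatenate([cecal, np.full(N_FILLER, rem_c / N_FILLER)]),
        np.concatenate([fecal, np.full(N_FILLER, rem_f / N_FILLER)]),
    ])
    table = OtuTable(counts, otu_ids=otu_ids,
                     sample_ids=["pooled_cecal", "pooled_fecal"])
    samples = [SampleRecord("pooled_cecal", "POOL", "cecal", "all"),
               SampleRecord("pooled_fecal", "POOL", "fecal", "all")]
    taxonomy = {r.otu_id: (r.isolate, float(r.similarity))
                for r in df.itertuples()}
    return Dataset(table=table, samples=samples, taxonomy=taxonomy)
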