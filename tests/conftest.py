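import numpy as np
import pytest

import otupair as op


@pytest.fixture(scope="session")
def small_paired():
    """A small generated paired dataset with its ground truth."""
    cfg = op.GeneratorConfig(n_birds=12, n_otus=120, seed=42,
                             low_depth_bird_fraction=0.0)
    return op.generate_paired_dataset(cfg)


@pytest.fixture(scope="session")
def filtered_averaged(small_paired):
    """The small dataset after the full filter chain plus rarefaction mean."""
    dataset, _ = small_paired
    table = op.filter_rare_otus(dataset.table)
    dataset = op.enforce_pairing(
        op.filter_low_depth_samples(dataset.with_table(table)).dataset)
    averaged = op.rarefy_mean(dataset.table,
                              op.RarefactionConfig(repetitions=25, seed=7))
    return dataset, dataset.with_table(averaged)


def toy_dataset(counts, otu_ids, records):
    table = op.OtuTable(np.asarray(counts, dtype=float), otu_ids=otu_ids,
                        sample_ids=[r[0] for r in records])
    samples = [op.SampleRecord(*r) for r in records]
    return op.Dataset(table=table, samples=samples)
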