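"""The preprocessing chain: rare-OTU filter, depth filter, pairing
filter, then multiple rarefaction with count averaging.

OTUs with <10 reads or seen in <5 samples are dropped; samples under
1000 reads are dropped together with their pair mate so every remaining
bird has both a cecal and a fecal sample; finally every sample is
subsampled to a common depth 100 times and the counts averaged.
"""

import otupair as op

dataset, _ = op.generate_paired_dataset(op.GeneratorConfig(
    n_birds=20, n_otus=200, seed=42, low_depth_bird_fraction=0.1))

table = op.filter_rare_otus(dataset.table)   # remove-if-either rule
print(f"OTU filter: {dataset.table.shape[0]} -> {table.shape[0]} OTUs")

res = op.filter_low_depth_samples(dataset.with_table(table))
print(f"depth filter dropped: {res.dropped_sample_ids}")

paired = op.enforce_pairing(res.dataset)
print(f"pairing filter: {res.dataset.table.shape[1]} -> "
      f"{paired.table.shape[1]} samples ({len(paired.birds())} birds, "
      f"mates of dropped samples removed too)")

averaged = op.rarefy_mean(paired.table,
                          op.RarefactionConfig(repetitions=100, seed=7))
depths = averaged.sample_depths()
print(f"after 100x rarefaction-averaging every sample holds exactly "
      f"{depths.iloc[0]:.0f} reads (fractional counts allowed)")
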