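# otupair

Paired-site comparison of 16S microbiota OTU tables.

When the same animal is sampled at two gut sites — the motivating case
is chicken cecal content vs cloacal (fecal) swabs, where fecal sampling
is non-lethal and repeatable but the cecum is the biologically relevant
fermentation site — the question is how faithfully one site's community
reflects the other's.  `otupair` implements the full comparison
pipeline: study-design filtering of OTU count tables, depth
normalisation by multiple rarefaction with count averaging, alpha
diversity with Monte-Carlo permutation inference, beta diversity
(eight classical metrics plus weighted/unweighted UniFrac, PCoA, UPGMA,
jackknifed cluster support) with PERMANOVA/ADONIS, a shared/exclusive
OTU partition with sequence-mass accounting, and an
abundance-stratified analysis of how inter-site correlation decays from
the rare biosphere to the dominant OTUs.  A synthetic-community
generator with known ground truth makes every stage testable without
sequence data.

## The statistics at the core

* **Rarefaction averaging.** Each sample is subsampled without
  replacement (multivariate hypergeometric) to a common depth *d*, 100
  times, and the counts averaged; every column of the averaged table
  sums to *d* exactly.
* **Alpha diversity.** Observed species, F1/F2, bias-corrected Chao1
  `S_obs + F1(F1−1)/(2(F2+1))`, Shannon `H = −Σ p_i log₂ p_i`, Simpson
  evenness `(1/Σp_i²)/S_obs`, equitability `H/log₂ S_obs`, Strong's
  dominance `D_w = max_i (b_i/N − i/S_obs)`, Faith's PD.  Sites are
  compared with a permutation test on `|mean_cecal − mean_fecal|`
  (p floored at 1/permutations).
* **UniFrac.** Unweighted: unique branch length over branch length
  leading to any observed OTU.  Weighted (normalised):
  `Σ l_b |p_b^X − p_b^Y| / Σ l_b (p_b^X + p_b^Y)` over branches *b* of
  a rooted OTU phylogeny.
* **ADONIS (one-factor PERMANOVA).**
  `F = (SS_between/(a−1)) / (SS_within/(n−a))` with
  `SS_total = Σ_{i<j} d²_ij/n`, `R² = SS_between/SS_total`, inference by
  label permutation (optionally within trial strata).
* **Venn partition.** An OTU is site-exclusive iff detected in one
  site's samples only; the three-way split is reported as % of OTUs and
  % of all reads.
* **Correlation curve.** One point per (bird, OTU) present in both of a
  bird's samples; Pearson r recomputed above rising minimum-abundance
  thresholds traces the decay of inter-site agreement with abundance.

## Worked example

```python
import otupair as op

# synthetic paired communities: 40 birds, 3 trials, 400 OTUs
dataset, truth = op.generate_paired_dataset(op.GeneratorConfig(seed=42))

# filter -> pair -> rarefy
table = op.filter_rare_otus(dataset.table)          # <10 reads or <5 samples
dataset = op.enforce_pairing(
    op.filter_low_depth_samples(dataset.with_table(table)).dataset)
averaged = op.rarefy_mean(dataset.table,
                          op.RarefactionConfig(repetitions=100, seed=1))

part = op.partition_by_site(dataset)
print(f"shared: {part.pct_otus[0]:.2f}% of OTUs, "
      f"{part.pct_sequences[0]:.2f}% of reads")

points = op.collect_paired_points(dataset.with_table(averaged))
curve = op.correlation_vs_threshold(points, site_axis="cecal_min",
                                    thresholds=[0, 1, 5, 10])
print("r by min abundance:",
      [f"{r:.2f}" for r in curve.r_values], curve.n_points)
```

prints

```
shared: 89.17% of OTUs, 99.26% of reads
r by min abundance: ['0.44', '0.38', '0.13', '-0.14'] [8352, 590, 62, 23]
```

i.e. the two sites share almost all OTUs and nearly all reads, and the
abundance of an OTU in one site tracks the other site well only while
the OTU is rare: above 10% of a community the correlation is gone, so
fecal proportions cannot stand in for cecal proportions even though
presence/absence agrees.  The `examples/` directory has one short
script per capability (simulation, filtering/rarefaction, alpha, beta +
UniFrac + ADONIS, Venn partition, correlation curves, left/right cecal
pairs).

A thin CLI wraps the same library:

```bash
otupair simulate --birds 40 --otus 400 --seed 1 --outdir sim/
otupair run --table sim/otu_table.tsv --metadata sim/metadata.tsv \
            --tree sim/tree.nwk --taxonomy sim/taxonomy.tsv \
            --outdir run/ --seed 1 --permutations 10000
otupair report --rundir run/
```

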