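# Methods

`otupair` analyses paired-site 16S OTU count tables — the canonical case
being cecal content vs cloacal (fecal) swabs from the same birds — and
ships a synthetic-community generator so the whole pipeline is testable
without sequence data.  This note documents the statistical procedures,
the defaults and why they were chosen, what the generator does and does
not emulate, and the numerical conventions.

## Preprocessing

The pipeline order is fixed: rare-OTU filter → sample-depth filter →
pairing filter → multiple rarefaction.

**Rare-OTU filter.** An OTU is removed when its total count is below 10
reads *or* it occurs in fewer than 5 samples (both strict inequalities:
10 reads in 5 samples is retained).  The legacy phrasing of this rule is
ambiguous between OR and AND semantics; OR removal is the default
because it is the stricter and more common reading, and `mode="and"`
gives the literal conjunctive reading.  Note the chain as a whole is not
mathematically idempotent: removing a shallow sample can push an OTU's
occupancy below 5, so a second pass may remove more OTUs.  Each filter
is idempotent on its own output, and the chain is a fixpoint whenever
the depth filter removed nothing.

**Depth and pairing filters.** Samples under 1000 reads (strict) are
dropped, and then every bird missing one member of its two-site pair is
removed entirely, so the design stays strictly paired: sample count is
always twice the bird count downstream.

**Rarefaction.** Each retained sample is subsampled without replacement
(multivariate hypergeometric) to a common depth — by default the minimum
retained sample depth, the only depth feasible for every sample — and
the procedure is repeated 100 times with the integer tables averaged.
The averaged table is fractional; its column sums equal the depth
exactly.  One seeded generator is consumed sequentially across
repetitions, so a single repetition reproduces `rarefy_once` with the
same seed and the whole procedure is bit-reproducible.  Diversity
statistics are computed on the averaged table; estimators that need
integer counts (singletons/doubletons, Chao1) are instead computed on
each single rarefaction draw and averaged (`alpha_per_rarefaction`),
since a singleton is undefined on averaged counts.

## Alpha diversity

Indices per sample: observed species (count above a detection threshold,
default 0), F1/F2 singleton/doubleton counts, bias-corrected Chao1
`S_obs + F1(F1-1)/(2(F2+1))`, Shannon entropy (log base 2 by default,
matching the legacy toolchain; configurable), Simpson evenness
`(1/Σp²)/S_obs`, equitability `H/log(S_obs)` (defined as 1 when
S_obs = 1), Strong's dominance `max_i (b_i/N − i/S_obs)` over abundance
ranks, and Faith's PD (branch length of the minimal rooted subtree
spanning the observed OTUs).

**Site comparison.** The statistic is the absolute difference of site
means; the null is `permutations` (default 1e5) random relabelings of
samples across sites, p = (# permuted ≥ observed)/permutations, with
the convention that a count of zero is reported as "< 1/permutations"
and stored numerically as 1/permutations.  Free relabeling is the
default to match the classical nonparametric two-sample test; since the
design is paired, a sign-flip test on within-bird differences is
available (`paired=True`).  The uncorrected p-values are reported (with
an optional Bonferroni column in the pipeline output that never gates
significance).

## Beta diversity

Eight non-phylogenetic metrics with their legacy conventions spelled
out: Jaccard on presence/absence; Bray-Curtis `Σ|x−y|/Σ(x+y)`; Canberra
as the *mean* of `|x−y|/(x+y)` over coordinates with `x+y>0` (not the
raw sum — conventions differ and this one keeps the metric in [0,1]);
chord (Euclidean distance of L2-normalised vectors); Euclidean;
Manhattan; "Pearson" as `1 − r` (range [0,2], not halved); Soergel
`Σ|x−y|/Σmax(x,y)`.

**UniFrac.** Both variants are computed from a branch × OTU incidence
matrix built in one post-order pass and shared across all sample pairs
(contract-checked against per-pair recomputation in tests via
scikit-bio).  Unweighted: unique branch length over branch length
leading to at least one observed OTU.  Weighted: `Σ l_b |p_b^X − p_b^Y|`
on per-sample proportions, divided by `Σ l_b (p_b^X + p_b^Y)` in the
normalised variant (the default, bounded in [0,1]); the raw variant is
available.

**ADONIS / PERMANOVA.** `SS_total = Σ_{i<j} d²_ij / n`, within-group
analogues per group, `pseudo-F = (SS_between/(a−1))/(SS_within/(n−a))`,
`R² = SS_between/SS_total`.  The null permutes labels freely, or within
strata (e.g. trials) when given; the p-value floor convention matches
the alpha tests.  Permutations are evaluated vectorised in chunks
(`einsum` over permuted membership masks).

**PCoA.** Classical scaling: eigendecomposition of the double-centred
`−D²/2` matrix; axes with eigenvalues below 1e-10 of the spectral
magnitude are treated as zero, negative-eigenvalue axes are dropped and
their relative magnitude (`Σ|λ₋|/Σ|λ|`) reported; no Lingoes/Cailliez
correction.  On genuinely Euclidean input the embedding reproduces the
distances to 1e-6.

**UPGMA.** Hand-rolled average-linkage agglomeration (O(n³), fine for
hundreds of samples) with deterministic tie-breaking by the
lexicographically smallest leaf-label pair; output is ultrametric
Newick.

**Jackknifing.** Each replicate rarefies every sample to
`depth_fraction` (default 0.75) × the minimum depth, recomputes UniFrac
and UPGMA.  Support is defined against the majority-rule consensus of
the replicate trees: clades recurring in >50% of replicates (always
mutually compatible) form the consensus, labelled with their recurrence
fraction.  A single replicate therefore trivially yields support 1.0
everywhere.  The full-depth UPGMA tree is returned alongside for
reference.

## Venn partition and reports

An OTU is site-exclusive when it is detected (count > 0) in at least one
sample of one site and in none of the other, assessed on the raw
post-filter counts by default — rarefaction discards reads and would
artificially inflate exclusivity; a presence threshold is available for
averaged tables.  Percentages of OTUs and of read mass (denominator:
all reads in the combined table) are kept at full precision in the
result object and rounded to 2 decimals only in exported reports, so
the three-way split always sums to 100.

The top-N table ranks OTUs by their share of one site's total reads and
reports both sites' shares from the same table, so a shared OTU appears
with consistent values in the cecal-ranked and fecal-ranked tables.
Ties break by OTU id.  The package bundles a published summary table of
the dominant OTUs in paired chicken cecal/fecal communities
(`otupair.datasets.load_chicken_top_otus`); synthetic low-abundance
filler rows absorb the unlisted remainder so each pooled column sums to
100% and the printed percentages are reproducible through the ranking
code.

## Paired correlation

One point per (bird, OTU) with positive relative abundance in both of
the bird's samples, on the percent scale of the rarefaction-averaged
table.  Pearson r is the default (Spearman and log10 modes exist for
sensitivity analysis); r is reported as NaN — never an exception — when
fewer than 3 points remain or an axis is constant.  The
correlation-vs-threshold curve recomputes r after restricting to points
whose cecal (or fecal) abundance meets a rising minimum; the default
grid is {0, 0.1, 0.5, 1, 2, 5, 10, 25, 50}%.  Points pool all birds
rather than averaging per OTU (a per-OTU mode exists).  The dominance
census counts distinct birds owning at least one point above 50% per
site.

## Synthetic data generator

Per bird `b` and shared OTU `i`, with `a_i, h_i, u_bi, e_bi ~ N(0,1)`:

* cecal log-weight `x = σ_c (√(1−w²) a_i + w u_bi)`;
* fecal OTU effect `ρ a_i + √(1−ρ²) h_i` (ρ = 0.7), giving the two sites
  a shared abundance ranking plus a systematic site shift — the signal
  ADONIS detects;
* fecal bird deviation `α_s u_bi + √(1−α_s²) e_bi`, where `α_s` is the
  coupling of OTU i's abundance stratum; strata are percent bands of the
  latent population composition (bounds 0.1/0.5/2/10%) with couplings
  0.9/0.8/0.65/0.45/0.1, so agreement collapses only for the dominant
  class — this produces the decaying correlation-vs-threshold curve;
* fecal log-weight uses `σ_f > σ_c` (defaults 2.4 vs 1.6), making fecal
  communities less even and less rich at fixed depth;
* compositions mix 90% of the exponentiated weights with a 10% uniform
  floor (`rare_floor`), keeping every shared OTU above the detection
  limit that the 10-read/5-sample filter implies — a deliberate
  departure from pure log-normal tails, without which shared OTUs would
  be misclassified as exclusive at realistic depths;
* dominance: with the configured per-site probabilities (defaults 0.26
  fecal, 0.07 cecal) a bird's leading OTU is amplified to a uniform
  52–70% share, and the same OTU is noisily elevated in the partner site
  (clipped below 45%); birds not selected have their top OTU capped at
  45%, so the probability knobs mean exactly "probability a bird carries
  a >50% OTU".  Elevating the partner site keeps the pooled correlation
  positive (dominant taxa are high in both sites) while the attained
  percentage is only loosely coupled, as real dominants behave;
* exclusive OTUs: fixed global relative weights with per-bird jitter at
  a constant small fraction of each site's reads (defaults 0.27% /
  0.45% of all reads for cecal-/fecal-exclusive), so each exclusive OTU
  recurs in enough samples to survive the filters;
* integer counts are multinomial draws at a per-sample depth uniform on
  1000–6000 reads; a configurable fraction of birds (default 5%)
  receives one sub-1000-read sample to exercise the depth/pairing
  filters.

Cecal left/right pairs reuse one latent bird profile per bird plus
independent log-normal noise of scale `within_bird_noise`, making the
left/right contrast null by construction.

**What the generator does not emulate:** sequencing error, chimeras,
OTU-picking artefacts, taxonomic structure (taxonomy labels are
synthetic placeholders), compositional correlations beyond the single
dominance mechanism, and trial-level community shifts (trial labels are
assigned round-robin without a trial effect).  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to upstream bioinformatics artefacts.

## Problem sizes and reproducibility

The test-suite and acceptance-script runs use deliberately moderate
sizes chosen to exercise every code path at high statistical power:
structure recovery at the generator defaults (40 birds × 400 OTUs) and
at the surveyed scale (163 birds, three trials); exact-enumeration
cross-checks at n = 3+3 (20 relabelings); null calibration over 500
simulated datasets with 400 permutations each; and 100 left/right
replicate datasets of 12 birds × 80 OTUs with 99 permutations each.
Every random step — generation, rarefaction, permutation tests,
jackknifing — derives from named substreams of one master seed and is
bit-reproducible.

## Known limitations

* PERMANOVA p-values use the r/B convention (floored at 1/B) rather
  than (r+1)/(B+1); at the default 1e5 permutations the difference is
  negligible, and the calibration tests bound the type-I error at
  0.05 ± 0.02.
* Weighted UniFrac assumes proportions; variable residual depth after
  averaging is not re-weighted.
* The correlation analysis quantifies agreement; it deliberately does
  not fit a predictive model of cecal from fecal abundance, because the
  stratified decoupling makes such prediction unreliable exactly where
  it would matter.
* BIOM support covers only the minimal dense JSON dialect.
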