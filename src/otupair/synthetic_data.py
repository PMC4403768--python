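"""Synthetic paired cecal/fecal communities with known ground truth.

The generator emulates the statistical structure of a paired avian-gut
16S survey: a large shared core of OTUs carrying almost all reads, small
site-exclusive rare tails, a cecal site that is richer and more even than
the fecal site, occasional birds whose fecal (less often cecal) community
is dominated by a single OTU, and an inter-site abundance correlation
that decays from the rare biosphere to the dominant OTUs.

Model sketch (per bird b, shared OTU i):

* a_i ~ N(0,1) is a global OTU abundance effect, h_i an independent
  fecal-specific effect; fecal OTU effects are rho*a_i + sqrt(1-rho^2)*h_i
  so the two sites share most of their abundance ranking but differ
  systematically (this is what site-level PERMANOVA detects).
* u_bi ~ N(0,1) is the bird-level cecal deviation; the fecal deviation is
  alpha_s*u_bi + sqrt(1-alpha_s^2)*e_bi where alpha_s is the coupling of
  OTU i's abundance stratum s - high for rare strata, low for dominant
  strata, producing the decaying correlation-vs-threshold curve.
* log cecal weight x = sigma_cecal*(sqrt(1-w^2)a + w*u); fecal analogous
  with sigma_fecal > sigma_cecal so fecal communities are less even.
* Sample compositions mix 90% of the exponentiated weights with a 10%
  uniform floor so every shared OTU sits above the detection limit the
  downstream 10-read/5-sample filter implies; exclusive OTUs are injected
  at a fixed small fraction of each site's reads.  Integer counts are
  multinomial draws at a uniformly random depth per sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skbio import TreeNode

from .tables_io import Dataset, OtuTable, SampleRecord, write_otu_table

__all__ = ["GeneratorConfig", "GroundTruth", "generate_tree",
           "generate_paired_dataset", "generate_cecal_pairs",
           "write_simulated"]


def _default_coupling() -> dict[int, float]:
    # stratum k spans latent abundances between stratum_pct_bounds[k-1] and
    # stratum_pct_bounds[k]; coupling decays sharply only for the dominant
    # (>10%) class, mirroring how agreement collapses for dominant OTUs
    return {0: 0.9, 1: 0.8, 2: 0.65, 3: 0.45, 4: 0.1}


@dataclass
class GeneratorConfig:
    """Study conditions for the paired-community generator.

    Defaults mirror the surveyed design: ~88.5% shared OTUs, cecal- and
    fecal-exclusive tails of 7.4% / 4.1% of OTUs carrying ~0.27% / 0.45%
    of reads, sample depths of 1000-6000 reads (a few thousand on
    average), a fecal community both less even (larger log-normal sigma)
    and more often dominated by a single OTU (26% vs 7% of birds), and
    stratum couplings decaying from 0.9 (rare) to 0.1 (dominant).
    """

    n_birds: int = 40
    n_trials: int = 3
    n_otus: int = 400
    shared_fraction: float = 0.885
    cecal_only_fraction: float = 0.074
    fecal_only_fraction: float = 0.041
    cecal_only_read_fraction: float = 0.0027
    fecal_only_read_fraction: float = 0.0045
    exclusive_read_fraction_ceiling: float = 0.005
    depth_range: tuple[int, int] = (1000, 6000)
    lognormal_sigma_cecal: float = 1.6
    lognormal_sigma_fecal: float = 2.4
    coupling_by_stratum: dict[int, float] = field(
        default_factory=_default_coupling)
    stratum_pct_bounds: tuple = (0.1, 0.5, 2.0, 10.0)
    dominant_otu_prob_fecal: float = 0.26
    dominant_otu_prob_cecal: float = 0.07
    site_profile_correlation: float = 0.7
    within_bird_weight: float = 0.45
    rare_floor: float = 0.10
    low_depth_bird_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = (self.shared_fraction + self.cecal_only_fraction
                 + self.fecal_only_fraction)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        for name in ("cecal_only_read_fraction", "fecal_only_read_fraction"):
            if getattr(self, name) > self.exclusive_read_fraction_ceiling:
                raise ValueError(f"{name} exceeds the per-class ceiling "
                                 f"{self.exclusive_read_fraction_ceiling}")
        if not all(-1.0 <= r <= 1.0 for r in self.coupling_by_stratum.values()):
            raise ValueError("stratum couplings must lie in [-1, 1]")
        if len(self.coupling_by_stratum) != len(self.stratum_pct_bounds) + 1:
            raise ValueError("need one coupling per abundance stratum "
                             "(len(stratum_pct_bounds) + 1)")
        if self.n_birds < 1 or self.n_otus < 3:
            raise ValueError("need at least 1 bird and 3 OTUs")
        for frac, label in ((self.cecal_only_fraction, "cecal_only"),
                            (self.fecal_only_fraction, "fecal_only"),
                            (self.shared_fraction, "shared")):
            if round(frac * self.n_otus) < 1:
                raise ValueError(f"{label} class would contain < 1 OTU")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid depth_range")


@dataclass
class GroundTruth:
    """Latent state behind a generated dataset."""

    shared_ids: list[str]
    cecal_only_ids: list[str]
    fecal_only_ids: list[str]
    strata: dict[str, int]                 # shared otu -> stratum index
    dominant_events: list[dict]            # bird/site/otu/target_pct
    low_depth_samples: list[str]
    config: GeneratorConfig
    latent_cecal_log: np.ndarray | None = None   # (n_birds, n_shared)
    latent_fecal_log: np.ndarray | None = None
    bird_ids: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "shared_ids": self.shared_ids,
            "cecal_only_ids": self.cecal_only_ids,
            "fecal_only_ids": self.fecal_only_ids,
            "strata": self.strata,
            "dominant_events": self.dominant_events,
            "low_depth_samples": self.low_depth_samples,
            "bird_ids": self.bird_ids,
            "config": asdict(self.config),
        }


# ---------------------------------------------------------------------------


def generate_tree(n_otus: int, seed: int = 0,
                  ids: list[str] | None = None) -> TreeNode:
    """Random rooted bifurcating tree over ``n_otus`` leaves.

    Built by repeatedly joining two uniformly chosen lineages under a new
    ancestor; branch lengths are exponential(mean 0.1) plus a small floor
    so every branch is positive.  Deterministic given the seed.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    rng = np.random.default_rng(seed)
    if ids is None:
        ids = [f"OTU_{k + 1:04d}" for k in range(n_otus)]
    if len(ids) != n_otus:
        raise ValueError("ids length must equal n_otus")
    nodes = []
    for name in ids:
        tip = TreeNode(name=name)
        tip.length = float(rng.exponential(0.1) + 0.01)
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(0.1) + 0.01)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _class_sizes(cfg: GeneratorConfig) -> tuple[int, int, int]:
    n_c = max(1, round(cfg.cecal_only_fraction * cfg.n_otus))
    n_f = max(1, round(cfg.fecal_only_fraction * cfg.n_otus))
    n_sh = cfg.n_otus - n_c - n_f
    return n_sh, n_c, n_f


def _compose(weights_log: np.ndarray, floor: float) -> np.ndarray:
    w = np.exp(weights_log - weights_log.max())
    p = w / w.sum()
    return (1.0 - floor) * p + floor / p.size


def _cap_top(p: np.ndarray, cap: float = 0.45) -> np.ndarray:
    """Compress any runaway OTU below ``cap`` so that >50% dominance occurs
    only in the birds the dominance-probability knobs select."""
    p = p.copy()
    for _ in range(20):
        i = int(p.argmax())
        if p[i] <= cap:
            break
        others = 1.0 - p[i]
        scale = (1.0 - cap) / others
        p *= scale
        p[i] = cap
    return p / p.sum()


def _inject_dominant(p: np.ndarray, otu_idx: int, target: float) -> np.ndarray:
    p = p.copy()
    old = p[otu_idx]
    p *= (1.0 - target) / (1.0 - old)
    p[otu_idx] = target
    return p / p.sum()


def generate_paired_dataset(config: GeneratorConfig
                            ) -> tuple[Dataset, GroundTruth]:
    """Generate a paired cecal/fecal dataset plus its ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_sh, n_c, n_f = _class_sizes(cfg)
    shared_ids = [f"OTU_{k + 1:04d}" for k in range(n_sh)]
    cex_ids = [f"OTU_C{k + 1:03d}" for k in range(n_c)]
    fex_ids = [f"OTU_F{k + 1:03d}" for k in range(n_f)]

    a = rng.standard_normal(n_sh)
    h = rng.standard_normal(n_sh)
    w = cfg.within_bird_weight
    rho = cfg.site_profile_correlation
    # strata follow the latent population-level cecal composition, cut at
    # the configured percent bounds (0 = rarest band, last = dominant)
    base_pct = 100.0 * _compose(
        cfg.lognormal_sigma_cecal * np.sqrt(1 - w ** 2) * a, cfg.rare_floor)
    strata = np.searchsorted(np.asarray(cfg.stratum_pct_bounds), base_pct)
    alpha = np.array([cfg.coupling_by_stratum[int(s)] for s in strata])
    af = rho * a + np.sqrt(1 - rho ** 2) * h

    # global relative weights of the exclusive OTUs (stable across birds,
    # so each exclusive OTU recurs in enough samples to pass the filter)
    g_c = rng.lognormal(0.0, 0.5, n_c)
    g_f = rng.lognormal(0.0, 0.5, n_f)
    q_c = 2.0 * cfg.cecal_only_read_fraction   # per-cecal-sample fraction
    q_f = 2.0 * cfg.fecal_only_read_fraction

    bird_ids = [f"B{k + 1:03d}" for k in range(cfg.n_birds)]
    trials = [f"T{(k % cfg.n_trials) + 1}" for k in range(cfg.n_birds)]
    n_low = round(cfg.low_depth_bird_fraction * cfg.n_birds)
    low_birds = set(rng.choice(cfg.n_birds, size=n_low, replace=False).tolist())

    cols: dict[str, np.ndarray] = {}
    samples: list[SampleRecord] = []
    dominant_events: list[dict] = []
    low_depth_samples: list[str] = []
    lat_c = np.zeros((cfg.n_birds, n_sh))
    lat_f = np.zeros((cfg.n_birds, n_sh))

    for bi, bird in enumerate(bird_ids):
        u = rng.standard_normal(n_sh)
        e = rng.standard_normal(n_sh)
        x = cfg.lognormal_sigma_cecal * (np.sqrt(1 - w ** 2) * a + w * u)
        v = alpha * u + np.sqrt(1 - alpha ** 2) * e
        y = cfg.lognormal_sigma_fecal * (np.sqrt(1 - w ** 2) * af + w * v)
        lat_c[bi], lat_f[bi] = x, y
        pc = _cap_top(_compose(x, cfg.rare_floor))
        pf = _cap_top(_compose(y, cfg.rare_floor))
        # dominance blows up the bird's leading OTU; the same OTU is also
        # elevated (noisily, below the dominance cutoff) in the partner
        # site, so dominant points sit high on both axes - keeping the
        # pooled correlation positive - while the attained percentage
        # itself is only loosely coupled between sites
        if rng.random() < cfg.dominant_otu_prob_fecal:
            otu = int(np.argmax(pf))
            target = float(rng.uniform(0.52, 0.70))
            pf = _inject_dominant(pf, otu, target)
            partner = float(np.clip(0.15 * target * rng.lognormal(0, 0.6),
                                    0.02, 0.35))
            pc = _inject_dominant(pc, otu, partner)
            dominant_events.append({"bird_id": bird, "site": "fecal",
                                    "otu_id": shared_ids[otu],
                                    "target_pct": 100 * target})
        if rng.random() < cfg.dominant_otu_prob_cecal:
            otu = int(np.argmax(pc))
            target = float(rng.uniform(0.52, 0.70))
            pc = _inject_dominant(pc, otu, target)
            partner = float(np.clip(0.15 * target * rng.lognormal(0, 0.6),
                                    0.02, 0.35))
            pf = _inject_dominant(pf, otu, partner)
            dominant_events.append({"bird_id": bird, "site": "cecal",
                                    "otu_id": shared_ids[otu],
                                    "target_pct": 100 * target})
        # per-bird jitter on the exclusive tails
        pcex = q_c * (g_c * np.exp(0.3 * rng.standard_normal(n_c)))
        pcex /= pcex.sum() / q_c
        pfex = q_f * (g_f * np.exp(0.3 * rng.standard_normal(n_f)))
        pfex /= pfex.sum() / q_f
        p_cecal = np.concatenate([pc * (1 - q_c), pcex, np.zeros(n_f)])
        p_fecal = np.concatenate([pf * (1 - q_f), np.zeros(n_c), pfex])
        depth_c = int(rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1))
        depth_f = int(rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1))
        sid_c, sid_f = f"{bird}_cecal", f"{bird}_fecal"
        if bi in low_birds:
            if rng.random() < 0.5:
                depth_c = int(rng.integers(300, 1000))
                low_depth_samples.append(sid_c)
            else:
                depth_f = int(rng.integers(300, 1000))
                low_depth_samples.append(sid_f)
        cols[sid_c] = rng.multinomial(depth_c, p_cecal / p_cecal.sum())
        cols[sid_f] = rng.multinomial(depth_f, p_fecal / p_fecal.sum())
        samples.append(SampleRecord(sid_c, bird, "cecal", trials[bi]))
        samples.append(SampleRecord(sid_f, bird, "fecal", trials[bi]))

    otu_ids = shared_ids + cex_ids + fex_ids
    counts = np.column_stack([cols[s.sample_id] for s in samples]).astype(float)
    table = OtuTable(counts, otu_ids=otu_ids,
                     sample_ids=[s.sample_id for s in samples])
    taxonomy = _synthetic_taxonomy(rng, shared_ids, cex_ids, fex_ids)
    dataset = Dataset(table=table, samples=samples, taxonomy=taxonomy)
    truth = GroundTruth(
        shared_ids=shared_ids, cecal_only_ids=cex_ids, fecal_only_ids=fex_ids,
        strata={shared_ids[i]: int(strata[i]) for i in range(n_sh)},
        dominant_events=dominant_events,
        low_depth_samples=low_depth_samples, config=cfg,
        latent_cecal_log=lat_c, latent_fecal_log=lat_f, bird_ids=bird_ids)
    return dataset, truth


def _synthetic_taxonomy(rng, shared_ids, cex_ids, fex_ids):
    """Synthetic isolate annotations (names are placeholders, similarities
    emulate the pattern that fecal-exclusive OTUs more often match known
    type strains than cecal-exclusive ones)."""
    taxonomy = {}
    for o in shared_ids:
        taxonomy[o] = (f"Isolate sp. {o}", float(rng.uniform(80, 100)))
    for o in cex_ids:
        taxonomy[o] = (f"Uncultured sp. {o}", float(rng.uniform(78, 97)))
    for o in fex_ids:
        taxonomy[o] = (f"Type strain sp. {o}", float(rng.uniform(88, 100)))
    return taxonomy


def generate_cecal_pairs(config: GeneratorConfig,
                         within_bird_noise: float = 0.25) -> Dataset:
    """Left/right cecal samples per bird from one shared latent profile.

    Both sides of a bird share the bird's latent cecal community; each
    side adds independent log-normal noise of scale ``within_bird_noise``
    plus multinomial sampling noise, so left/right pairs are similar and
    the left-vs-right site contrast is null by construction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_sh, _, _ = _class_sizes(cfg)
    shared_ids = [f"OTU_{k + 1:04d}" for k in range(n_sh)]
    a = rng.standard_normal(n_sh)
    w = cfg.within_bird_weight
    cols: dict[str, np.ndarray] = {}
    samples: list[SampleRecord] = []
    for k in range(cfg.n_birds):
        bird = f"B{k + 1:03d}"
        u = rng.standard_normal(n_sh)
        z = cfg.lognormal_sigma_cecal * (np.sqrt(1 - w ** 2) * a + w * u)
        for side in ("ceca_left", "ceca_right"):
            zz = z + within_bird_noise * rng.standard_normal(n_sh)
            p = _compose(zz, cfg.rare_floor)
            depth = int(rng.integers(cfg.depth_range[0],
                                     cfg.depth_range[1] + 1))
            sid = f"{bird}_{side}"
            cols[sid] = rng.multinomial(depth, p)
            samples.append(SampleRecord(sid, bird, side, "pairs"))
    counts = np.column_stack([cols[s.sample_id] for s in samples]).astype(float)
    table = OtuTable(counts, otu_ids=shared_ids,
                     sample_ids=[s.sample_id for s in samples])
    return Dataset(table=table, samples=samples)


def write_simulated(outdir, dataset: Dataset, tree: TreeNode | None,
                    truth: GroundTruth | None) -> dict[str, str]:
    """Write the standard artifact files (table/metadata TSV, Newick tree,
    taxonomy TSV, ground-truth JSON); returns the paths written."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    paths["table"] = os.path.join(outdir, "otu_table.tsv")
    write_otu_table(dataset.table, paths["table"])
    paths["metadata"] = os.path.join(outdir, "metadata.tsv")
    with open(paths["metadata"], "w") as fh:
        fh.write("sample_id\tbird_id\tsite\ttrial\n")
        for s in dataset.samples:
            fh.write(f"{s.sample_id}\t{s.bird_id}\t{s.site}\t{s.trial}\n")
    if dataset.taxonomy:
        paths["taxonomy"] = os.path.join(outdir, "taxonomy.tsv")
        with open(paths["taxonomy"], "w") as fh:
            fh.write("otu_id\tisolate\tsimilarity\n")
            for otu, (iso, sim) in dataset.taxonomy.items():
                fh.write(f"{otu}\t{iso}\t{sim:.2f}\n")
    if tree is not None:
        paths["tree"] = os.path.join(outdir, "tree.nwk")
        tree.write(paths["tree"])
    if truth is not None:
        paths["truth"] = os.path.join(outdir, "ground_truth.json")
        with open(paths["truth"], "w") as fh:
            json.dump(truth.as_dict(), fh, indent=1)
    return paths
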