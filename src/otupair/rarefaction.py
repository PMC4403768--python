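"""Depth normalisation by repeated rarefaction and count averaging.

Each sample column is subsampled without replacement to a common depth
(a multivariate hypergeometric draw over its reads); repeating the draw
``repetitions`` times and averaging the integer tables yields the
fractional "100x rarefied" table the downstream diversity and correlation
stages run on.  Averaging preserves the constant column total, so every
column of the averaged table sums to exactly the rarefaction depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables_io import OtuTable

__all__ = ["RarefactionConfig", "rarefy_once", "rarefy_mean"]


@dataclass
class RarefactionConfig:
    """Rarefaction settings.

    depth
        Reads per sample after subsampling; ``None`` means the minimum
        column sum of the table being rarefied (the only depth feasible
        for every retained sample).
    repetitions
        Number of independent draws averaged (default 100).
    seed
        Master seed; one generator is consumed sequentially across
        repetitions, so repetitions are independent yet reproducible and
        a single repetition reproduces :func:`rarefy_once`.
    """

    depth: int | None = None
    repetitions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.repetitions <= 0:
            raise ValueError("repetitions must be positive")


def _resolve_depth(table: OtuTable, depth: int | None) -> int:
    depths = table.counts.sum(axis=0)
    if depth is None:
        depth = int(round(depths.min()))
    low = [s for s, d in zip(table.sample_ids, depths)
           if d < depth - 1e-9]
    if low:
        raise ValueError(
            f"samples shallower than rarefaction depth {depth}: {low}")
    return int(depth)


def rarefy_once(table: OtuTable, depth: int | None = None,
                seed: int | np.random.Generator = 0,
                with_replacement: bool = False) -> OtuTable:
    """One random subsample of every column to exactly ``depth`` reads.

    Without replacement (the default, true rarefaction) each column is a
    multivariate-hypergeometric draw from its reads; ``with_replacement``
    switches to a multinomial draw on the column's proportions.
    """
    if not table.is_integer():
        raise ValueError("rarefaction requires integer counts")
    depth = _resolve_depth(table, depth)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    counts = np.round(table.counts).astype(np.int64)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        col = counts[:, j]
        total = int(col.sum())
        if total == depth and not with_replacement:
            out[:, j] = col
        elif with_replacement:
            out[:, j] = rng.multinomial(depth, col / total)
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return OtuTable(out.astype(float), otu_ids=table.otu_ids,
                    sample_ids=table.sample_ids)


def rarefy_mean(table: OtuTable, config: RarefactionConfig) -> OtuTable:
    """Mean of ``config.repetitions`` independent rarefactions.

    Output counts are fractional; every column sums to exactly the
    rarefaction depth.  Deterministic given ``config.seed``.
    """
    depth = _resolve_depth(table, config.depth)
    # one master generator consumed sequentially: repetition k's draws
    # follow repetition k-1's, so repetitions=1 reproduces rarefy_once
    # with the same seed and all repetitions stay independent
    rng = np.random.default_rng(config.seed)
    acc = np.zeros(table.shape, dtype=float)
    for _ in range(config.repetitions):
        acc += rarefy_once(table, depth, rng).counts
    acc /= config.repetitions
    return OtuTable(acc, otu_ids=table.otu_ids, sample_ids=table.sample_ids)
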