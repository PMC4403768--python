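"""OTU tables, sample metadata, and the study-design filtering rules.

The data model is deliberately small: an :class:`OtuTable` wraps a pandas
DataFrame of non-negative counts (OTUs x samples), a :class:`SampleRecord`
carries the bird/site/trial design labels, and a :class:`Dataset` ties the
two together with optional taxonomy annotations.  Counts are stored as
floats throughout so the same container serves raw integer tables and
rarefaction-averaged (fractional) tables; readers reject fractional input
unless explicitly permitted.

Filtering follows the paired cecal/fecal study design: rare OTUs are
dropped first, then low-depth samples, then any bird left with only one
member of its sample pair is removed entirely so the design stays paired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleRecord",
    "Dataset",
    "DepthFilterResult",
    "FormatError",
    "MetadataError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "read_taxonomy",
    "filter_rare_otus",
    "filter_low_depth_samples",
    "enforce_pairing",
    "relative_abundance",
]

#: the two recognised two-level site designs
SITE_PAIRS = (("cecal", "fecal"), ("ceca_left", "ceca_right"))
VALID_SITES = frozenset(s for pair in SITE_PAIRS for s in pair)


class FormatError(ValueError):
    """Malformed OTU table or annotation file."""


class MetadataError(ValueError):
    """Sample metadata violates the paired design contract."""


@dataclass(frozen=True)
class SampleRecord:
    """Design labels for one sequenced sample."""

    sample_id: str
    bird_id: str
    site: str
    trial: str

    def __post_init__(self) -> None:
        if self.site not in VALID_SITES:
            raise MetadataError(
                f"sample {self.sample_id!r}: unknown site {self.site!r}; "
                f"expected one of {sorted(VALID_SITES)}"
            )


class OtuTable:
    """Non-negative OTU x sample count matrix with stable orderings.

    Parameters
    ----------
    counts
        DataFrame (index = OTU ids, columns = sample ids) or array-like;
        values must be finite and >= 0.
    otu_ids, sample_ids
        Required when ``counts`` is not a DataFrame.
    """

    def __init__(self, counts, otu_ids: Sequence[str] | None = None,
                 sample_ids: Sequence[str] | None = None) -> None:
        if isinstance(counts, pd.DataFrame):
            df = counts.copy()
            df.index = df.index.astype(str)
            df.columns = df.columns.astype(str)
        else:
            if otu_ids is None or sample_ids is None:
                raise ValueError("otu_ids and sample_ids required for array input")
            df = pd.DataFrame(np.asarray(counts, dtype=float),
                              index=[str(i) for i in otu_ids],
                              columns=[str(s) for s in sample_ids])
        df = df.astype(float)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        vals = df.to_numpy()
        if vals.size and not np.all(np.isfinite(vals)):
            raise FormatError("missing or non-finite cells in OTU table")
        if vals.size and vals.min() < 0:
            raise FormatError("negative counts in OTU table")
        self._df = df

    # -- accessors ---------------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as a (n_otus, n_samples) float array (a copy-safe view)."""
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    def sample_depths(self) -> pd.Series:
        """Per-sample read totals (column sums)."""
        return self._df.sum(axis=0)

    def otu_totals(self) -> pd.Series:
        return self._df.sum(axis=1)

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self._df[sample_id].to_numpy()

    def is_integer(self, tol: float = 1e-9) -> bool:
        vals = self._df.to_numpy()
        return bool(np.all(np.abs(vals - np.round(vals)) <= tol))

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self._df.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return OtuTable(self._df.loc[:, ids])

    def select_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        ids = list(otu_ids)
        missing = [o for o in ids if o not in self._df.index]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        return OtuTable(self._df.loc[ids, :])

    def __eq__(self, other) -> bool:  # count equality to 1e-9, same orders
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (self.otu_ids == other.otu_ids
                and self.sample_ids == other.sample_ids
                and np.allclose(self.counts, other.counts, atol=1e-9, rtol=0))

    def __repr__(self) -> str:
        return f"OtuTable({self.shape[0]} OTUs x {self.shape[1]} samples)"


@dataclass
class Dataset:
    """An OTU table plus the sample design records that cover it."""

    table: OtuTable
    samples: list[SampleRecord]
    taxonomy: dict[str, tuple[str, float]] | None = None

    def __post_init__(self) -> None:
        by_id = {s.sample_id: s for s in self.samples}
        if len(by_id) != len(self.samples):
            raise MetadataError("duplicate sample_id in metadata")
        table_ids = set(self.table.sample_ids)
        if set(by_id) != table_ids:
            missing = table_ids - set(by_id)
            extra = set(by_id) - table_ids
            raise MetadataError(
                f"metadata does not cover table: missing={sorted(missing)} "
                f"extra={sorted(extra)}")
        seen: dict[tuple[str, str], str] = {}
        for s in self.samples:
            key = (s.bird_id, s.site)
            if key in seen:
                raise MetadataError(
                    f"bird {s.bird_id!r} has two {s.site!r} samples "
                    f"({seen[key]!r}, {s.sample_id!r})")
            seen[key] = s.sample_id

    @property
    def sample_map(self) -> dict[str, SampleRecord]:
        return {s.sample_id: s for s in self.samples}

    def site_of(self, sample_id: str) -> str:
        return self.sample_map[sample_id].site

    def sites(self) -> list[str]:
        return sorted({s.site for s in self.samples})

    def samples_for_site(self, site: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.site == site]

    def birds(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.bird_id not in out:
                out.append(s.bird_id)
        return out

    def trials(self) -> list[str]:
        return sorted({s.trial for s in self.samples})

    def with_table(self, table: OtuTable) -> "Dataset":
        keep = set(table.sample_ids)
        return Dataset(table=table,
                       samples=[s for s in self.samples if s.sample_id in keep],
                       taxonomy=self.taxonomy)


@dataclass
class DepthFilterResult:
    """Depth-filter outcome: the surviving dataset plus what was dropped."""

    dataset: Dataset
    dropped_sample_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, format: Literal["tsv", "biom-json"] = "tsv",
                   allow_fractions: bool = False) -> OtuTable:
    """Read an OTU count table.

    ``tsv``: first column OTU ids (header cell conventionally ``#OTU ID``),
    one column per sample, numeric cells; missing cells are an error, not
    zero.  ``biom-json``: the minimal dense BIOM-JSON dialect.
    Raw tables must be integer unless ``allow_fractions`` is set.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{path}: empty OTU table") from exc
        if df.shape[1] == 0:
            raise FormatError(f"{path}: OTU table has no sample columns")
        if df.isna().any().any():
            raise FormatError(f"{path}: missing cells in OTU table")
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric cell in OTU table") from exc
    elif format == "biom-json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: invalid BIOM-JSON") from exc
        if doc.get("matrix_type") != "dense":
            raise FormatError(
                f"{path}: only the dense BIOM-JSON dialect is supported "
                f"(matrix_type={doc.get('matrix_type')!r})")
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        data = np.asarray(doc["data"], dtype=float)
        if data.shape != (len(otu_ids), len(sample_ids)):
            raise FormatError(f"{path}: BIOM data shape {data.shape} does not "
                              f"match rows/columns")
        df = pd.DataFrame(data, index=otu_ids, columns=sample_ids)
    else:
        raise ValueError(f"unknown format {format!r}")
    table = OtuTable(df)
    if not allow_fractions and not table.is_integer():
        raise FormatError(
            f"{path}: fractional counts in raw table (pass allow_fractions=True "
            f"for rarefaction-averaged tables)")
    return table


def write_otu_table(table: OtuTable, path) -> None:
    """Write a tab-delimited OTU table (first header cell ``#OTU ID``).

    Fractional counts are rendered with enough significant digits to
    round-trip through :func:`read_otu_table`.
    """
    if table.shape[1] == 0:
        raise ValueError("refusing to write a table with 0 samples")
    if table.shape[0] == 0:
        raise ValueError("refusing to write a table with 0 OTUs")
    df = table.to_dataframe()
    df.index.name = "#OTU ID"
    # %.12g keeps integers as integers and fractions to 12 significant digits
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_metadata(path) -> list[SampleRecord]:
    """Read sample metadata (TSV with sample_id, bird_id, site, trial)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "bird_id", "site", "trial"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    return [SampleRecord(r.sample_id, r.bird_id, r.site, r.trial)
            for r in df.itertuples()]


def read_taxonomy(path) -> dict[str, tuple[str, float]]:
    """Read taxonomy annotations (TSV: otu_id, isolate, similarity%)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = list(df.columns)
    if len(cols) < 3:
        raise FormatError(f"{path}: taxonomy needs otu_id, isolate, similarity")
    return {str(r[0]): (str(r[1]), float(r[2]))
            for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# filtering & pairing
# ---------------------------------------------------------------------------

def filter_rare_otus(table: OtuTable, min_total_reads: int = 10,
                     min_samples: int = 5,
                     mode: Literal["or", "and"] = "or") -> OtuTable:
    """Drop rare OTUs from a raw count table.

    An OTU fails the read rule when its total is < ``min_total_reads`` and
    the occupancy rule when it occurs in < ``min_samples`` samples; both
    thresholds are strict.  ``mode="or"`` (default) removes an OTU failing
    either rule; ``mode="and"`` removes only OTUs failing both.  The sample
    set is unchanged.
    """
    if min_total_reads < 0 or min_samples < 0:
        raise ValueError("thresholds must be non-negative")
    if mode not in ("or", "and"):
        raise ValueError(f"mode must be 'or' or 'and', got {mode!r}")
    counts = table.counts
    totals = counts.sum(axis=1)
    occupancy = (counts > 0).sum(axis=1)
    fail_reads = totals < min_total_reads
    fail_occ = occupancy < min_samples
    remove = (fail_reads | fail_occ) if mode == "or" else (fail_reads & fail_occ)
    keep = [o for o, r in zip(table.otu_ids, remove) if not r]
    return table.select_otus(keep)


def filter_low_depth_samples(dataset: Dataset,
                             min_depth: int = 1000) -> DepthFilterResult:
    """Drop samples whose post-OTU-filter depth is < ``min_depth`` (strict)."""
    if min_depth < 0:
        raise ValueError("min_depth must be non-negative")
    depths = dataset.table.sample_depths()
    dropped = [s for s in dataset.table.sample_ids if depths[s] < min_depth]
    keep = [s for s in dataset.table.sample_ids if s not in dropped]
    return DepthFilterResult(dataset=dataset.with_table(
        dataset.table.select_samples(keep)), dropped_sample_ids=dropped)


def enforce_pairing(dataset: Dataset) -> Dataset:
    """Remove every bird missing one member of its two-site sample pair.

    When a sample was rejected (e.g. by the depth filter) its mate is
    removed too, so the design stays strictly paired: after this step every
    bird contributes exactly one sample from each of the two sites.
    """
    sites = dataset.sites()
    pair = next((p for p in SITE_PAIRS if set(sites) <= set(p)), None)
    if pair is None:
        raise MetadataError(
            f"sites {sites} are not a recognised two-level pairing")
    by_bird: dict[str, set[str]] = {}
    for s in dataset.samples:
        by_bird.setdefault(s.bird_id, set()).add(s.site)
    complete = {b for b, ss in by_bird.items() if ss == set(pair)}
    keep = [s.sample_id for s in dataset.samples if s.bird_id in complete]
    return dataset.with_table(dataset.table.select_samples(keep))


def relative_abundance(table: OtuTable) -> OtuTable:
    """Convert counts to percentages: every column sums to 100."""
    depths = table.counts.sum(axis=0)
    zero = [s for s, d in zip(table.sample_ids, depths) if d == 0]
    if zero:
        raise ValueError(f"zero-depth samples cannot be normalised: {zero}")
    return OtuTable(table.to_dataframe() / depths * 100.0)


def pair_map(dataset: Dataset) -> dict[str, dict[str, str]]:
    """bird_id -> {site: sample_id} for a paired dataset."""
    out: dict[str, dict[str, str]] = {}
    for s in dataset.samples:
        out.setdefault(s.bird_id, {})[s.site] = s.sample_id
    return out
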