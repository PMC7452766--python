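"""Community data containers, readers and transforms for OTU tables.

The unit of analysis is a :class:`CommunityDataset`: a samples-by-OTUs read
count matrix joined to per-sample metadata (host plant species, sampling
location, environmental covariates, sequencing depth) and per-OTU functional
guild labels (mycorrhizal / endophytic / unclassified).

Counts are raw reads throughout; sequencing depth is handled downstream as a
model covariate, not by rarefaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

GUILDS = ("mycorrhizal", "endophytic", "unclassified")

#: Mandatory columns of a sample metadata frame, in canonical order.
SAMPLE_COLUMNS = (
    "sample_id",
    "location_id",
    "host_species",
    "individual_id",
    "elevation",
    "soil_ph",
    "soil_water",
    "active_layer_depth",
    "vegetation_cover",
    "seq_depth",
)

_NUMERIC_SAMPLE_COLUMNS = (
    "elevation",
    "soil_ph",
    "soil_water",
    "active_layer_depth",
    "vegetation_cover",
    "seq_depth",
)


class CommunityFormatError(ValueError):
    """Raised when an input file violates the community-data contracts."""


@dataclass
class OtuTable:
    """A samples x OTUs matrix of non-negative integer read counts.

    Row and column order is preserved from the source and treated as
    canonical by all downstream matrices.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CommunityFormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise CommunityFormatError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise CommunityFormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise CommunityFormatError("counts must be non-negative")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.otu_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def select_otus(self, otu_ids: list[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OtuTable(self.sample_ids, list(otu_ids), self.counts[:, idx])

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), self.otu_ids, self.counts[idx, :])


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise CommunityFormatError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


class GuildMap(dict):
    """otu_id -> guild label; unknown OTUs resolve to ``"unclassified"``."""

    def __init__(self, mapping: dict[str, str] | None = None) -> None:
        super().__init__()
        if mapping:
            for otu, guild in mapping.items():
                self[otu] = guild

    def __setitem__(self, otu: str, guild: str) -> None:
        if guild not in GUILDS:
            raise ValueError(
                f"guild for {otu!r} must be one of {GUILDS}, got {guild!r}"
            )
        super().__setitem__(str(otu), guild)

    def __missing__(self, otu: str) -> str:
        return "unclassified"

    def labels_for(self, otu_ids: list[str]) -> list[str]:
        return [self[o] for o in otu_ids]


@dataclass
class CommunityDataset:
    """OTU table + sample metadata + guild labels, sample-aligned."""

    table: OtuTable
    samples: pd.DataFrame
    guilds: GuildMap = field(default_factory=GuildMap)

    def __post_init__(self) -> None:
        validate_sample_frame(self.samples)
        frame_ids = list(self.samples["sample_id"].astype(str))
        if frame_ids != self.table.sample_ids:
            raise CommunityFormatError(
                "sample ids of OTU table and metadata frame differ "
                "(same identifiers in the same order are required)"
            )
        if not isinstance(self.guilds, GuildMap):
            self.guilds = GuildMap(dict(self.guilds))

    @property
    def n_samples(self) -> int:
        return self.table.n_samples

    @property
    def n_otus(self) -> int:
        return self.table.n_otus

    def guild_labels(self) -> list[str]:
        return self.guilds.labels_for(self.table.otu_ids)

    def select_samples(self, sample_ids: list[str]) -> "CommunityDataset":
        sub = self.samples.set_index("sample_id").loc[sample_ids].reset_index()
        # keep categorical level order of the full dataset
        for col in ("location_id", "host_species"):
            sub[col] = pd.Categorical(
                sub[col], categories=self.samples[col].cat.categories
            )
        return CommunityDataset(
            self.table.select_samples(sample_ids), sub, self.guilds
        )


def validate_sample_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a sample metadata frame in place.

    Categorical levels of ``location_id`` and ``host_species`` are recorded
    in first-appearance order; numeric covariates must be finite and
    ``seq_depth`` >= 1.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in frame.columns]
    if missing:
        raise CommunityFormatError(
            f"sample metadata is missing mandatory column(s): {', '.join(missing)}"
        )
    frame["sample_id"] = frame["sample_id"].astype(str)
    _check_unique(list(frame["sample_id"]), "sample")
    for col in ("location_id", "host_species"):
        if not isinstance(frame[col].dtype, pd.CategoricalDtype):
            frame[col] = pd.Categorical(
                frame[col].astype(str),
                categories=pd.unique(frame[col].astype(str)),
            )
    for col in _NUMERIC_SAMPLE_COLUMNS:
        try:
            frame[col] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise CommunityFormatError(
                f"column {col!r} must be numeric: {exc}"
            ) from None
        if not np.all(np.isfinite(frame[col].to_numpy(dtype=float))):
            raise CommunityFormatError(f"column {col!r} contains non-finite values")
    if (frame["seq_depth"] < 1).any():
        raise CommunityFormatError("seq_depth must be >= 1 for every sample")
    frame["seq_depth"] = frame["seq_depth"].astype(np.int64)
    return frame


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path) -> OtuTable:
    """Read an OTU table from TSV (samples as rows) or BIOM-style JSON.

    TSV layout: first column holds sample identifiers, header row holds OTU
    identifiers, cells are integer read counts.
    """
    path = Path(path)
    head = path.read_text().lstrip()[:1]
    if head == "{":
        return _read_biom_json(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    otu_ids = header[1:]
    _check_unique(otu_ids, "OTU")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise CommunityFormatError(f"ragged or incomplete row for sample {bad!r}")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.all(np.mod(vals, 1) == 0):
            raise CommunityFormatError(
                f"non-integer count in OTU column {otu_ids[j]!r}"
            )
        if (vals < 0).any():
            raise CommunityFormatError(
                f"negative count in OTU column {otu_ids[j]!r}"
            )
        counts[:, j] = vals.astype(np.int64)
    return OtuTable(sample_ids, otu_ids, counts)


def _read_biom_json(path: Path) -> OtuTable:
    # Minimal BIOM 1.0 JSON reader (dense or sparse); BIOM stores rows as
    # observations (OTUs) and columns as samples, so the matrix is transposed
    # into the samples-by-OTUs orientation used here.
    doc = json.loads(Path(path).read_text())
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(otu_ids), len(sample_ids)))
    if doc.get("matrix_type", "dense") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat = np.asarray(doc["data"], dtype=float)
    return OtuTable(sample_ids, otu_ids, mat.T)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV sample metadata file (see SAMPLE_COLUMNS)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_frame(frame)


def write_sample_metadata(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_guilds(path: str | Path) -> GuildMap:
    """Read a two-column TSV ``otu_id<TAB>guild``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["otu_id", "guild"]:
        raise CommunityFormatError(
            "guild file must have columns 'otu_id' and 'guild'"
        )
    return GuildMap(dict(zip(df["otu_id"], df["guild"])))


def write_guilds(guilds: GuildMap, path: str | Path, otu_ids=None) -> None:
    ids = list(otu_ids) if otu_ids is not None else sorted(guilds)
    pd.DataFrame({"otu_id": ids, "guild": [guilds[o] for o in ids]}).to_csv(
        path, sep="\t", index=False
    )


def read_dataset(directory: str | Path) -> CommunityDataset:
    """Read ``otu_table.tsv``, ``samples.tsv`` and ``guilds.tsv`` from a directory."""
    directory = Path(directory)
    table = read_otu_table(directory / "otu_table.tsv")
    samples = read_sample_metadata(directory / "samples.tsv")
    guilds_path = directory / "guilds.tsv"
    guilds = read_guilds(guilds_path) if guilds_path.exists() else GuildMap()
    return CommunityDataset(table, samples, guilds)


def write_dataset(ds: CommunityDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_otu_table(ds.table, directory / "otu_table.tsv")
    write_sample_metadata(ds.samples, directory / "samples.tsv")
    write_guilds(ds.guilds, directory / "guilds.tsv", otu_ids=ds.table.otu_ids)


# ---------------------------------------------------------------------------
# Filtering and transforms
# ---------------------------------------------------------------------------

def prevalence(table: OtuTable) -> np.ndarray:
    """Per-OTU fraction of samples with a non-zero count."""
    if table.n_samples == 0:
        raise ValueError("prevalence undefined for a table with zero samples")
    return (table.counts > 0).mean(axis=0)


def filter_by_prevalence(table: OtuTable, threshold: float = 0.05) -> OtuTable:
    """Drop OTUs occurring in fewer than ``threshold`` of the samples.

    OTUs exactly at the threshold are kept: only strictly rarer OTUs are
    excluded.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    keep = prevalence(table) >= threshold
    otu_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    return OtuTable(table.sample_ids, otu_ids, table.counts[:, keep])


def subset_by_guild(ds: CommunityDataset, guild: str) -> CommunityDataset:
    """Restrict the OTU set to one functional guild (``"all"`` is a no-op)."""
    if guild == "all":
        return ds
    if guild not in GUILDS:
        raise ValueError(f"unknown guild {guild!r}; expected one of {GUILDS} or 'all'")
    keep = [o for o in ds.table.otu_ids if ds.guilds[o] == guild]
    return CommunityDataset(ds.table.select_otus(keep), ds.samples, ds.guilds)


def relative_sqrt_transform(table: OtuTable) -> np.ndarray:
    """Square root of per-sample relative read counts.

    Each entry is sqrt(count / sample total), so each squared row sums to 1.
    This is the transform feeding compositional ordination.
    """
    totals = table.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-total sample(s): {', '.join(bad)}")
    return np.sqrt(table.counts / totals[:, None])


def bray_curtis(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity between rows.

    d(a, b) = sum|a_k - b_k| / sum(a_k + b_k). Two all-zero rows are defined
    to have dissimilarity 0 so the matrix stays total.
    """
    matrix = np.asarray(matrix, dtype=float)
    if np.any(matrix < 0):
        raise ValueError("Bray-Curtis requires non-negative entries")
    if matrix.shape[0] < 2:
        return np.zeros((matrix.shape[0], matrix.shape[0]))
    with np.errstate(invalid="ignore"):
        dm = squareform(pdist(matrix, metric="braycurtis"))
    return np.nan_to_num(dm, nan=0.0)
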