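"""Domain types and I/O for OTU count tables, sample metadata and taxonomy.

The central object is the :class:`OtuTable`: an integer count matrix
(samples x OTUs) carrying per-sample metadata (animal, gut region,
replicate) and, optionally, the sequence-identity level at which the OTUs
were clustered.  Counts stay integral end-to-end — rarefaction and Good's
coverage are defined on integer read counts — and are only converted to
relative abundances on explicit request.

Files are plain TSV (UTF-8): the count table has a ``sample_id`` first
column and one column per OTU; metadata has columns ``sample_id``,
``animal_id``, ``region`` and (optionally) ``replicate``; taxonomy has
``otu_id`` plus the four ranks phylum/class/order/family with the literal
sentinel ``unclassified`` allowed at any rank, provided classification is
monotone (nothing classified below an unclassified rank).  A reader for the
BIOM 1.0 JSON dialect is provided as an alternate input path.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ConsistencyError",
    "GutRegion",
    "REGION_ORDER",
    "LARGE_INTESTINE_ORDER",
    "UNCLASSIFIED",
    "RANKS",
    "SampleInfo",
    "OtuTable",
    "TaxonomyTable",
    "read_otu_table",
    "read_biom_table",
    "write_otu_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "pool_replicates",
]

UNCLASSIFIED = "unclassified"
RANKS = ("phylum", "class", "order", "family")


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad header, unparsable cells)."""


class ValidationError(ValueError):
    """Structurally parsable input that violates a domain contract."""


class ConsistencyError(ValueError):
    """Cross-file disagreement (e.g. a sample without metadata)."""


class GutRegion(str, enum.Enum):
    """The eight sampled gut compartments.

    ``group`` places each compartment in the anatomical blocks that organise
    the analysis: the terminal ileum stands apart from the large intestine;
    within the large intestine the proximal block (caecum and ventral colon)
    and the distal block (dorsal colon onwards to faeces) carry distinct
    community signatures, with the left dorsal colon intermediate between
    the two.
    """

    ILEUM = "ileum"
    CAECUM = "caecum"
    RVC = "RVC"
    LVC = "LVC"
    LDC = "LDC"
    RDC = "RDC"
    SC = "SC"
    FAECES = "faeces"

    @property
    def group(self) -> str:
        return _REGION_GROUP[self]

    @classmethod
    def parse(cls, name: "str | GutRegion") -> "GutRegion":
        if isinstance(name, cls):
            return name
        try:
            return _REGION_LOOKUP[str(name).strip().lower()]
        except KeyError:
            raise ValidationError(
                f"unknown gut region {name!r}; expected one of "
                f"{[r.value for r in cls]}"
            ) from None


_REGION_GROUP = {
    GutRegion.ILEUM: "foregut_terminal",
    GutRegion.CAECUM: "proximal_LI",
    GutRegion.RVC: "proximal_LI",
    GutRegion.LVC: "proximal_LI",
    GutRegion.LDC: "intermediate",
    GutRegion.RDC: "distal_LI",
    GutRegion.SC: "distal_LI",
    GutRegion.FAECES: "distal_LI",
}

_REGION_LOOKUP = {r.value.lower(): r for r in GutRegion}

#: Gut-passage order of all eight regions.
REGION_ORDER: tuple[GutRegion, ...] = (
    GutRegion.ILEUM,
    GutRegion.CAECUM,
    GutRegion.RVC,
    GutRegion.LVC,
    GutRegion.LDC,
    GutRegion.RDC,
    GutRegion.SC,
    GutRegion.FAECES,
)

#: Passage order of the seven large-intestine regions (for trajectories).
LARGE_INTESTINE_ORDER: tuple[GutRegion, ...] = REGION_ORDER[1:]


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sequenced sample."""

    sample_id: str
    animal_id: str
    region: GutRegion
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")


_META_COLUMNS = ["animal_id", "region", "replicate"]


class OtuTable:
    """Integer OTU count matrix with aligned per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer counts, rows indexed by sample id,
        columns by OTU id.  Exactly-integral floats are coerced.
    samples
        DataFrame indexed by sample id with columns ``animal_id``,
        ``region`` (canonical region names) and ``replicate``.  Every sample
        in ``counts`` must be present; extra metadata rows are dropped.
    clustering_identity
        Optional sequence-identity fraction of the OTU clustering
        (one of 0.90 / 0.95 / 0.97 / 0.99).
    """

    _IDENTITIES = (0.90, 0.95, 0.97, 0.99)

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        clustering_identity: float | None = None,
    ) -> None:
        counts = self._validate_counts(counts)
        samples = self._validate_samples(samples, counts.index)
        if clustering_identity is not None:
            clustering_identity = float(clustering_identity)
            if not any(
                abs(clustering_identity - x) < 1e-9 for x in self._IDENTITIES
            ):
                raise ValidationError(
                    "clustering_identity must be one of 0.90/0.95/0.97/0.99"
                )
        self.counts = counts
        self.samples = samples
        self.clustering_identity = clustering_identity

    # -- validation -----------------------------------------------------

    @staticmethod
    def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if counts.columns.duplicated().any():
            dupes = counts.columns[counts.columns.duplicated()].tolist()
            raise FormatError(f"duplicate OTU ids: {dupes}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.issubdtype(arr.dtype, np.number):
                raise ValidationError("counts must be numeric")
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise ValidationError("counts must be exactly integral")
            counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValidationError("counts must be non-negative")
        counts = counts.astype(np.int64, copy=False)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        counts.index.name = "sample_id"
        return counts

    @staticmethod
    def _validate_samples(
        samples: pd.DataFrame, sample_ids: pd.Index
    ) -> pd.DataFrame:
        samples = samples.copy()
        if samples.index.name != "sample_id" and "sample_id" in samples.columns:
            samples = samples.set_index("sample_id")
        samples.index = samples.index.astype(str)
        if samples.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        missing = [c for c in ("animal_id", "region") if c not in samples.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if "replicate" not in samples.columns:
            samples["replicate"] = 1
        absent = sample_ids.difference(samples.index)
        if len(absent):
            raise ConsistencyError(
                f"samples missing from metadata: {absent.tolist()}"
            )
        samples = samples.loc[sample_ids, _META_COLUMNS]
        samples["animal_id"] = samples["animal_id"].astype(str)
        samples["region"] = [GutRegion.parse(r).value for r in samples["region"]]
        reps = samples["replicate"].to_numpy()
        if np.any(reps != np.floor(reps)) or np.any(reps < 1):
            raise ValidationError("replicate must be an integer >= 1")
        samples["replicate"] = samples["replicate"].astype(int)
        key = samples[["animal_id", "region", "replicate"]]
        if key.duplicated().any():
            raise ValidationError(
                "(animal_id, region, replicate) must be unique across samples"
            )
        samples.index.name = "sample_id"
        return samples

    # -- basic accessors ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    @property
    def depths(self) -> pd.Series:
        """Per-sample read totals (the depth N of each sample)."""
        return self.counts.sum(axis=1)

    @property
    def regions(self) -> pd.Series:
        return self.samples["region"]

    @property
    def animals(self) -> pd.Series:
        return self.samples["animal_id"]

    def sample_info(self, sample_id: str) -> SampleInfo:
        row = self.samples.loc[sample_id]
        return SampleInfo(
            sample_id=sample_id,
            animal_id=row["animal_id"],
            region=GutRegion.parse(row["region"]),
            replicate=int(row["replicate"]),
        )

    # -- transformations ------------------------------------------------

    def replace_counts(self, counts: pd.DataFrame) -> "OtuTable":
        """New table with the same metadata and identity but new counts."""
        return OtuTable(
            counts, self.samples.loc[counts.index.astype(str)],
            self.clustering_identity,
        )

    def restrict_region(self, region: GutRegion | str) -> "OtuTable":
        region = GutRegion.parse(region)
        mask = self.samples["region"] == region.value
        if not mask.any():
            raise ValidationError(f"no samples from region {region.value!r}")
        return OtuTable(
            self.counts.loc[mask.to_numpy()],
            self.samples.loc[mask.to_numpy()],
            self.clustering_identity,
        )

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised proportions p_i = N_i / N (float)."""
        depths = self.depths
        if (depths == 0).any():
            zero = depths.index[depths == 0].tolist()
            raise ValidationError(f"zero-depth samples: {zero}")
        return self.counts.div(depths, axis=0)

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        return self.replace_counts(self.counts.loc[:, keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.samples.equals(other.samples)
            and self.clustering_identity == other.clustering_identity
        )

    def __repr__(self) -> str:  # pragma: no cover
        ident = (
            f", identity={self.clustering_identity:.2f}"
            if self.clustering_identity is not None
            else ""
        )
        return f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs{ident})"


@dataclass
class TaxonomyTable:
    """OTU id -> (phylum, class, order, family) lineage map.

    The sentinel ``unclassified`` may appear at any rank, but resolution is
    monotone: once a rank is unclassified every finer rank must be too.
    OTUs absent from the map are reported as fully unclassified.
    """

    lineages: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.lineages.empty:
            self.lineages = pd.DataFrame(columns=list(RANKS))
            self.lineages.index.name = "otu_id"
            return
        df = self.lineages.copy()
        if df.index.name != "otu_id" and "otu_id" in df.columns:
            df = df.set_index("otu_id")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise FormatError("duplicate OTU ids in taxonomy")
        missing = [r for r in RANKS if r not in df.columns]
        if missing:
            raise FormatError(f"taxonomy missing rank columns: {missing}")
        df = df[list(RANKS)].astype(str)
        # normalise the sentinel, preserve genuine names as written
        for rank in RANKS:
            low = df[rank].str.strip()
            df[rank] = low.where(low.str.lower() != UNCLASSIFIED, UNCLASSIFIED)
            df[rank] = df[rank].replace({"": UNCLASSIFIED, "nan": UNCLASSIFIED})
        for otu, row in df.iterrows():
            seen_unclassified = False
            for rank in RANKS:
                if row[rank] == UNCLASSIFIED:
                    seen_unclassified = True
                elif seen_unclassified:
                    raise ValidationError(
                        f"OTU {otu}: rank {rank!r} classified "
                        f"({row[rank]!r}) below an unclassified rank"
                    )
        df.index.name = "otu_id"
        self.lineages = df

    def lineage(self, otu_id: str) -> tuple[str, str, str, str]:
        otu_id = str(otu_id)
        if otu_id in self.lineages.index:
            row = self.lineages.loc[otu_id]
            return tuple(row[r] for r in RANKS)  # type: ignore[return-value]
        return (UNCLASSIFIED,) * 4

    def __contains__(self, otu_id: str) -> bool:
        return str(otu_id) in self.lineages.index

    def __len__(self) -> int:
        return len(self.lineages)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split("\t")
    if len(header) != len(set(header)):
        raise FormatError(f"{path}: duplicate column names in header")
    try:
        return pd.read_csv(path, sep="\t", dtype={0: str}, encoding="utf-8")
    except pd.errors.ParserError as exc:  # pragma: no cover - rare
        raise FormatError(f"{path}: {exc}") from exc


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, animal_id, region[, replicate])."""
    df = _read_tsv(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata must have a 'sample_id' column")
    return df.set_index("sample_id")


def read_otu_table(
    path: str | Path,
    metadata_path: str | Path,
    clustering_identity: float | None = None,
) -> OtuTable:
    """Read a TSV count table and its metadata into a validated OtuTable."""
    df = _read_tsv(path)
    first = df.columns[0]
    if first != "sample_id":
        raise FormatError(
            f"{path}: first column must be 'sample_id', got {first!r}"
        )
    counts = df.set_index("sample_id")
    for col in counts.columns:
        if not np.issubdtype(counts[col].dtype, np.number):
            raise ValidationError(f"{path}: non-numeric counts in OTU {col!r}")
    meta = read_sample_metadata(metadata_path)
    return OtuTable(counts, meta, clustering_identity)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write the count matrix as TSV (lossless for integer counts)."""
    table.counts.to_csv(path, sep="\t", encoding="utf-8")


def write_sample_metadata(table: OtuTable, path: str | Path) -> None:
    table.samples.to_csv(path, sep="\t", encoding="utf-8")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a 5-column taxonomy TSV (otu_id + four ranks)."""
    df = _read_tsv(path)
    if "otu_id" not in df.columns:
        raise FormatError(f"{path}: taxonomy must have an 'otu_id' column")
    return TaxonomyTable(df)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    taxonomy.lineages.to_csv(path, sep="\t", encoding="utf-8")


def read_biom_table(
    path: str | Path,
    metadata_path: str | Path | None = None,
    clustering_identity: float | None = None,
) -> OtuTable:
    """Read a BIOM 1.0 JSON table (dense or sparse) as an OtuTable.

    BIOM stores observations (OTUs) as rows and samples as columns; the
    matrix is transposed into the samples-x-OTUs orientation used here.
    Sample metadata is taken from a TSV if given, else from the BIOM
    column ``metadata`` entries (keys ``animal_id``/``region``/``replicate``).
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    mat = np.zeros((n_obs, n_samp))
    mtype = doc.get("matrix_type", "sparse")
    if mtype == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    elif mtype == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise FormatError(f"{path}: unsupported matrix_type {mtype!r}")
    counts = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    if metadata_path is not None:
        meta = read_sample_metadata(metadata_path)
    else:
        records = {}
        for col in doc["columns"]:
            md = col.get("metadata") or {}
            records[str(col["id"])] = {
                "animal_id": md.get("animal_id", ""),
                "region": md.get("region", ""),
                "replicate": md.get("replicate", 1),
            }
        meta = pd.DataFrame.from_dict(records, orient="index")
        meta.index.name = "sample_id"
    return OtuTable(counts, meta, clustering_identity)


def pool_replicates(table: OtuTable) -> OtuTable:
    """Sum replicate subsamples into one sample per (animal, region).

    Downstream analyses act on one sample per animal x region; when a table
    carries triplicate subsamples this pools their reads (count addition)
    and assigns the pooled sample the id ``"<animal>|<region>"``.
    """
    key = list(zip(table.samples["animal_id"], table.samples["region"]))
    grouped = table.counts.groupby(pd.Index(key), sort=False).sum()
    new_ids = [f"{a}|{r}" for a, r in grouped.index]
    counts = pd.DataFrame(
        grouped.to_numpy(), index=new_ids, columns=table.counts.columns
    )
    meta = pd.DataFrame(
        {
            "animal_id": [a for a, _ in grouped.index],
            "region": [r for _, r in grouped.index],
            "replicate": 1,
        },
        index=pd.Index(new_ids, name="sample_id"),
    )
    return OtuTable(counts, meta, table.clustering_identity)
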