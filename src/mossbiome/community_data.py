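"""OTU-table data model, I/O, and abundance filters/transforms.

The substrate of every downstream analysis is a non-negative integer count
matrix of OTUs (rows) by sequencing libraries (columns), carrying a
Greengenes-style semicolon-ranked taxonomy string per OTU, plus a sample
metadata table describing the sampling design (peatland system, area,
subsite, moss plant, endophyte/epiphyte/reference fraction) and continuous
covariates (pH, temperature, pore-water CH4).

Filtering follows the conventions of amplicon surveys: lineage-based
exclusion (chloroplasts, out-of-domain OTUs) and removal of entries whose
sample-wise relative abundance falls below a small threshold (default
0.01%), assessed per entry against the library size before any zeroing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYSTEMS = ("amb", "sph")
FRACTIONS = ("endophyte", "epiphyte", "reference")
SAMPLE_CLASSES = ("moss", "vascular", "sediment")
HYDROLOGY = ("submerged", "emerged", "unknown")

#: metadata columns expected by the pipeline (sample_id is the index)
METADATA_COLUMNS = [
    "system",
    "area",
    "subsite",
    "plant_label",
    "sample_class",
    "fraction",
    "plant_unit",
    "hydrology",
    "pH",
    "temperature",
    "ch4",
]


class CommunityDataError(ValueError):
    """Raised for malformed OTU tables or metadata."""


@dataclass(frozen=True)
class OtuTable:
    """Immutable OTU count table (OTUs x samples) with taxonomy strings.

    Parameters
    ----------
    otu_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers (library names).
    counts : ndarray of shape (n_otus, n_samples)
        Non-negative integer read counts.
    taxonomy : sequence of str
        Per-OTU semicolon-ranked lineage, Greengenes style
        (``k__Bacteria; p__...``).
    domain_label : str
        ``"bacteria"`` or ``"archaea"``; the domain the library was
        amplified for.
    """

    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray
    taxonomy: tuple[str, ...]
    domain_label: str = "bacteria"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise CommunityDataError("counts must be a 2-D matrix")
        if counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise CommunityDataError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                bad = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
                raise CommunityDataError(
                    "non-integer count at OTU "
                    f"{self.otu_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise CommunityDataError(
                "negative count at OTU "
                f"{self.otu_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "taxonomy", tuple(self.taxonomy))
        if len(set(self.otu_ids)) != len(self.otu_ids):
            seen: set[str] = set()
            dup = next(i for i in self.otu_ids if i in seen or seen.add(i))
            raise CommunityDataError(f"duplicate OTU id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen = set()
            dup = next(i for i in self.sample_ids if i in seen or seen.add(i))
            raise CommunityDataError(f"duplicate sample id: {dup!r}")
        if len(self.taxonomy) != len(self.otu_ids):
            raise CommunityDataError("taxonomy length != number of OTUs")
        if self.domain_label not in ("bacteria", "archaea"):
            raise CommunityDataError(
                f"domain_label must be 'bacteria' or 'archaea', got {self.domain_label!r}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Per-sample total read counts (column sums)."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by OTU id, columns = sample ids."""
        return pd.DataFrame(
            self.counts, index=list(self.otu_ids), columns=list(self.sample_ids)
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise CommunityDataError(f"unknown sample id: {sample_id!r}") from None

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        """Column subset in the given order; library sizes must stay positive."""
        idx = [self.sample_index(s) for s in sample_ids]
        sub = self.counts[:, idx]
        if (sub.sum(axis=0) == 0).any():
            empty = [sample_ids[j] for j in np.flatnonzero(sub.sum(axis=0) == 0)]
            raise CommunityDataError(f"selection leaves empty libraries: {empty}")
        return replace(self, sample_ids=tuple(sample_ids), counts=sub)

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in otu_ids]
        return replace(
            self,
            otu_ids=tuple(otu_ids),
            counts=self.counts[idx, :],
            taxonomy=tuple(self.taxonomy[i] for i in idx),
        )


@dataclass(frozen=True)
class RelAbundTable:
    """Per-sample proportions on the same axes as an :class:`OtuTable`."""

    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        colsum = vals.sum(axis=0)
        if not np.allclose(colsum, 1.0, atol=1e-9):
            bad = self.sample_ids[int(np.argmax(np.abs(colsum - 1.0)))]
            raise CommunityDataError(f"column {bad!r} does not sum to 1")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.otu_ids), columns=list(self.sample_ids)
        )


@dataclass
class RareFilterReport:
    """What :func:`filter_rare` removed."""

    entries_zeroed: int
    otus_dropped: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(
    path: str | Path, format: str = "tsv", domain_label: str = "bacteria"
) -> OtuTable:
    """Read an OTU table from TSV (canonical) or BIOM 2.x.

    The TSV dialect: first column holds OTU ids, the header row holds sample
    ids, and an optional trailing ``taxonomy`` column holds lineage strings.
    Missing taxonomy is filled with ``"Unassigned"`` (with a warning).
    """
    path = Path(path)
    if format == "biom":
        return _read_biom(path, domain_label)
    if format != "tsv":
        raise CommunityDataError(f"unknown format: {format!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment=None, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise CommunityDataError(f"duplicate OTU id: {dup!r}")
    if df.columns.str.lower().duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise CommunityDataError(f"duplicate sample id: {dup!r}")
    cols = list(df.columns)
    if cols and cols[-1].lower() == "taxonomy":
        taxonomy = tuple(df[cols[-1]].fillna("Unassigned"))
        df = df[cols[:-1]]
    else:
        logger.warning("no taxonomy column in %s; filling with 'Unassigned'", path)
        warnings.warn(f"no taxonomy column in {path}; filling with 'Unassigned'")
        taxonomy = tuple("Unassigned" for _ in range(len(df)))
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna().argmax()]
            raise CommunityDataError(
                f"non-numeric count at OTU {row!r}, sample {col!r}"
            )
        frac, whole = np.modf(vals.to_numpy(dtype=float))
        if (frac != 0).any():
            row = df.index[int(np.argmax(frac != 0))]
            raise CommunityDataError(
                f"non-integer count at OTU {row!r}, sample {col!r}"
            )
        if (whole < 0).any():
            row = df.index[int(np.argmax(whole < 0))]
            raise CommunityDataError(
                f"negative count at OTU {row!r}, sample {col!r}"
            )
        counts[:, j] = whole.astype(np.int64)
    return OtuTable(
        otu_ids=tuple(df.index.astype(str)),
        sample_ids=tuple(str(c) for c in df.columns),
        counts=counts,
        taxonomy=taxonomy,
        domain_label=domain_label,
    )


def _read_biom(path: Path, domain_label: str) -> OtuTable:
    try:
        import biom  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise CommunityDataError(
            "BIOM support requires the optional 'biom-format' package"
        ) from exc
    bt = biom.load_table(str(path))
    counts = np.asarray(bt.matrix_data.todense())
    taxonomy = []
    for oid in bt.ids(axis="observation"):
        md = bt.metadata(oid, axis="observation") or {}
        tax = md.get("taxonomy", "Unassigned")
        if isinstance(tax, (list, tuple)):
            tax = "; ".join(tax)
        taxonomy.append(tax)
    return OtuTable(
        otu_ids=tuple(bt.ids(axis="observation")),
        sample_ids=tuple(bt.ids(axis="sample")),
        counts=counts.astype(np.int64),
        taxonomy=tuple(taxonomy),
        domain_label=domain_label,
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write the canonical TSV dialect (UTF-8, LF, '.' decimals)."""
    df = table.to_dataframe()
    df["taxonomy"] = list(table.taxonomy)
    df.index.name = "otu_id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV indexed by ``sample_id``.

    Continuous covariates (pH, temperature, ch4) are coerced to float with
    missing values as NaN; design factors stay as strings.
    """
    md = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    md.index = md.index.astype(str)
    md.index.name = "sample_id"
    for col in ("pH", "temperature", "ch4"):
        if col in md.columns:
            md[col] = pd.to_numeric(md[col], errors="coerce")
    return md


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        metadata.to_csv(fh, sep="\t")


def validate_metadata(table: OtuTable, metadata: pd.DataFrame) -> None:
    """Check that every sample resolves to one metadata row and that the
    paired design constraints hold (endophyte/epiphyte libraries are moss
    samples attached to a plant unit)."""
    missing = [s for s in table.sample_ids if s not in metadata.index]
    if missing:
        raise CommunityDataError(f"samples without metadata: {missing}")
    if metadata.index.duplicated().any():
        dup = metadata.index[metadata.index.duplicated()][0]
        raise CommunityDataError(f"duplicate metadata row for sample {dup!r}")
    sub = metadata.loc[list(table.sample_ids)]
    paired = sub["fraction"].isin(["endophyte", "epiphyte"])
    bad_class = paired & (sub["sample_class"] != "moss")
    if bad_class.any():
        raise CommunityDataError(
            f"endo/epiphyte libraries must be moss samples: "
            f"{list(sub.index[bad_class])}"
        )
    bad_unit = paired & (sub["plant_unit"].isna() | (sub["plant_unit"] == ""))
    if bad_unit.any():
        raise CommunityDataError(
            f"endo/epiphyte libraries lack a plant_unit: {list(sub.index[bad_unit])}"
        )


# ---------------------------------------------------------------------------
# Filters and transforms
# ---------------------------------------------------------------------------

DEFAULT_EXCLUDE_PATTERNS = ("chloroplast",)

_DOMAIN_TOKEN = {"bacteria": "k__bacteria", "archaea": "k__archaea"}
_OPPOSITE = {"bacteria": "archaea", "archaea": "bacteria"}


def filter_taxa(
    table: OtuTable,
    exclude_patterns: Iterable[str] = DEFAULT_EXCLUDE_PATTERNS,
    expected_domain: str | None = None,
) -> OtuTable:
    """Drop OTUs by lineage: exclusion patterns (case-insensitive substring
    match on the lineage string, default chloroplasts) and OTUs whose
    kingdom-rank token contradicts the expected domain (e.g. a
    ``k__Bacteria`` OTU inside an archaeal library set).
    """
    if expected_domain is None:
        expected_domain = table.domain_label
    patterns = [p.lower() for p in exclude_patterns]
    wrong_domain = _DOMAIN_TOKEN[_OPPOSITE[expected_domain]]
    keep = []
    for i, lineage in enumerate(table.taxonomy):
        low = lineage.lower()
        if any(p in low for p in patterns):
            continue
        if wrong_domain in low:
            continue
        keep.append(i)
    if not keep:
        raise CommunityDataError("taxon filter removed every OTU")
    if len(keep) == table.n_otus:
        return table
    return table.select_otus([table.otu_ids[i] for i in keep])


def filter_rare(
    table: OtuTable,
    min_fraction: float = 1e-4,
    drop_whole_otus: bool = False,
) -> tuple[OtuTable, RareFilterReport]:
    """Remove entries below a sample-wise relative-abundance threshold.

    Each count strictly below ``min_fraction`` of its library size (library
    sizes computed before any zeroing) is set to zero; OTU rows that become
    all-zero are dropped. Entries exactly at the threshold are kept (the
    rule is a strict ``<``). With ``drop_whole_otus=True`` an OTU is instead
    dropped entirely if *every* entry is below threshold, leaving surviving
    rows untouched.
    """
    if not 0 < min_fraction < 1:
        raise CommunityDataError(f"min_fraction must be in (0,1), got {min_fraction}")
    totals = table.library_sizes()
    if (totals == 0).any():
        empty = [table.sample_ids[j] for j in np.flatnonzero(totals == 0)]
        raise CommunityDataError(f"empty libraries: {empty}")
    below = (table.counts > 0) & (table.counts < min_fraction * totals[None, :])
    if drop_whole_otus:
        drop_rows = below.all(axis=1) | (table.counts == 0).all(axis=1)
        keep_rows = ~drop_rows
        new_counts = table.counts[keep_rows]
        zeroed = 0
    else:
        new_counts = np.where(below, 0, table.counts)
        zeroed = int(below.sum())
        keep_rows = (new_counts > 0).any(axis=1)
        new_counts = new_counts[keep_rows]
    dropped = [o for o, k in zip(table.otu_ids, keep_rows) if not k]
    kept_ids = tuple(o for o, k in zip(table.otu_ids, keep_rows) if k)
    kept_tax = tuple(t for t, k in zip(table.taxonomy, keep_rows) if k)
    out = OtuTable(
        otu_ids=kept_ids,
        sample_ids=table.sample_ids,
        counts=new_counts,
        taxonomy=kept_tax,
        domain_label=table.domain_label,
    )
    return out, RareFilterReport(entries_zeroed=zeroed, otus_dropped=dropped)


def relative_abundance(table: OtuTable) -> RelAbundTable:
    """Column-wise proportions; every library must have reads."""
    totals = table.library_sizes()
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise CommunityDataError(f"zero-sum sample: {bad!r}")
    return RelAbundTable(
        otu_ids=table.otu_ids,
        sample_ids=table.sample_ids,
        values=table.counts / totals[None, :],
    )


def hellinger(table: OtuTable) -> np.ndarray:
    """Hellinger transform: sqrt of per-sample proportions.

    Returns an (OTUs x samples) float matrix whose columns have unit
    Euclidean norm; stabilizes the leverage of dominant OTUs in ordination.
    """
    totals = table.library_sizes()
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise CommunityDataError(f"zero-sum sample: {bad!r}")
    return np.sqrt(table.counts / totals[None, :])
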