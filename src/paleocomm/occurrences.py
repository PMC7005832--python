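"""Sample-by-taxon abundance tables with stratigraphic binning.

The central container is :class:`AbundanceTable`: an integer count matrix
(samples x taxa) plus per-sample metadata (time bin, locality, lithology)
and, at species rank, a taxonomy map from species to genus/family.  Tables
can be loaded from three delimited-text dialects (long, wide, and
Paleobiology Database occurrence downloads), filtered on a minimum specimen
count per sample, aggregated from species to genus rank, and partitioned by
time bin.

Name handling is deliberately conservative: names are whitespace-collapsed
and matched case-insensitively, but no synonymy resolution is attempted.
Species identified only informally ("Genus sp." / "Genus spp.") are kept as
distinct species-rank entities within their genus; identifications limited
to the family level are dropped (with a logged count) because they cannot
be placed in a genus-level analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LITHOLOGIES = ("carbonate", "clastic", "mixed", "glauconitic")

#: Default stratigraphic scheme: 16 ordered Maastrichtian-Priabonian
#: intervals.  Hyperthermal flags mark the bins coinciding with the late
#: Maastrichtian warming, the PETM, ETM-2 and the MECO.
DEFAULT_BIN_LABELS = (
    "Maastrichtian-1",
    "Maastrichtian-2",
    "Danian-1",
    "Danian-2",
    "Danian-3",
    "Selandian",
    "Thanetian-1",
    "Thanetian-2",
    "Ypresian-1",
    "Ypresian-2",
    "Ypresian-3",
    "Lutetian-1",
    "Lutetian-2",
    "Bartonian-1",
    "Bartonian-2",
    "Priabonian",
)
DEFAULT_HYPERTHERMAL_BINS = (1, 8, 9, 12)

_INFORMAL_RE = re.compile(r"^(sp|spp)\.?$", re.IGNORECASE)
_FAMILY_RE = re.compile(r"(?:idae|inae)$", re.IGNORECASE)


class ValidationError(ValueError):
    """Raised when a table or input file violates a structural invariant."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed in its declared dialect."""


def _canon(name: str) -> str:
    """Collapse internal whitespace and strip; the display form of a name."""
    return " ".join(str(name).split())


def _key(name: str) -> str:
    """Case-folded canonical form used for matching names."""
    return _canon(name).casefold()


def is_informal_epithet(species_name: str) -> bool:
    """True if the species epithet is an open-nomenclature 'sp.'/'spp.'."""
    parts = _canon(species_name).split()
    return len(parts) >= 2 and bool(_INFORMAL_RE.match(parts[-1]))


@dataclass(frozen=True)
class TimeBinScheme:
    """Ordered stratigraphic time bins, oldest first."""

    labels: tuple[str, ...] = DEFAULT_BIN_LABELS
    hyperthermal_bins: tuple[int, ...] = ()

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("time bin labels must be unique")
        for b in self.hyperthermal_bins:
            if not 0 <= b < len(self.labels):
                raise ValidationError(f"hyperthermal flag {b} outside scheme")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label) -> int:
        """Resolve a label (or an integer index) to a bin index."""
        if isinstance(label, (int, np.integer)):
            i = int(label)
            if not 0 <= i < len(self.labels):
                raise ValidationError(f"time bin index {i} outside scheme")
            return i
        try:
            return self.labels.index(str(label))
        except ValueError:
            raise ValidationError(f"unknown time bin label {label!r}") from None


def default_scheme() -> TimeBinScheme:
    return TimeBinScheme(DEFAULT_BIN_LABELS, DEFAULT_HYPERTHERMAL_BINS)


@dataclass
class AbundanceTable:
    """Sample x taxon integer abundance matrix with metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample_id with one column per taxon.
    meta
        DataFrame indexed by sample_id with columns ``time_bin`` (ordinal
        index into ``scheme``), ``locality`` and ``lithology``.
    taxonomy
        At species rank: DataFrame indexed by species name with columns
        ``genus``, ``family`` and ``is_informal``.  ``None`` at genus or
        functional rank.
    rank
        One of ``"species"``, ``"genus"`` or ``"functional"``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    taxonomy: pd.DataFrame | None = None
    rank: str = "species"
    scheme: TimeBinScheme = field(default_factory=default_scheme)

    def __post_init__(self):
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def specimen_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def validate(self) -> None:
        c = self.counts
        if not c.index.equals(self.meta.index):
            raise ValidationError("counts and meta must share the sample index")
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate taxon columns")
        arr = c.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValidationError("counts must be integers")
                self.counts = c.astype(np.int64)
                arr = self.counts.to_numpy()
            if (arr < 0).any():
                raise ValidationError("counts must be non-negative")
        if self.rank not in ("species", "genus", "functional"):
            raise ValidationError(f"unknown rank {self.rank!r}")
        nbins = len(self.scheme)
        tb = self.meta["time_bin"].to_numpy()
        if len(tb) and ((tb < 0) | (tb >= nbins)).any():
            raise ValidationError("time_bin outside scheme range")
        if self.rank == "species" and self.taxonomy is not None:
            missing = set(self.counts.columns) - set(self.taxonomy.index)
            if missing:
                raise ValidationError(f"taxa missing from taxonomy: {sorted(missing)[:5]}")

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(
            self.counts.copy(),
            self.meta.copy(),
            None if self.taxonomy is None else self.taxonomy.copy(),
            self.rank,
            self.scheme,
        )

    def drop_empty_taxa(self) -> "AbundanceTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        tax = self.taxonomy.loc[keep] if self.taxonomy is not None else None
        return AbundanceTable(self.counts[keep], self.meta, tax, self.rank, self.scheme)


# ---------------------------------------------------------------------------
# Loading


def _finish_long(rows: pd.DataFrame, scheme: TimeBinScheme) -> AbundanceTable:
    """Assemble an AbundanceTable from a normalised long DataFrame with
    columns sample_id, time_bin, locality, lithology, species, genus,
    family, count (species/genus already canonicalised)."""
    piv = rows.pivot_table(
        index="sample_id", columns="species", values="count", aggfunc="sum", fill_value=0
    ).astype(np.int64)
    meta = (
        rows.drop_duplicates("sample_id")
        .set_index("sample_id")[["time_bin", "locality", "lithology"]]
        .loc[piv.index]
    )
    tax = (
        rows.drop_duplicates("species")
        .set_index("species")[["genus", "family", "is_informal"]]
        .loc[piv.columns]
    )
    piv.columns.name = None
    return AbundanceTable(piv, meta, tax, rank="species", scheme=scheme)


def _normalise_species(genus: str, species: str) -> tuple[str, bool]:
    """Return the canonical species name and its informal flag.

    Genus-only identifications become 'Genus sp.' (informal)."""
    genus = _canon(genus)
    species = _canon(species)
    if not species or _INFORMAL_RE.match(species):
        return f"{genus} sp.", True
    if is_informal_epithet(species):
        return species, True
    if len(species.split()) == 1:  # bare epithet
        return f"{genus} {species}", False
    return species, False


def load_abundance_table(path, format: str = "long_csv",
                         scheme: TimeBinScheme | None = None) -> AbundanceTable:
    """Load a species-rank abundance table from a delimited text file.

    Supported dialects:

    ``long_csv``
        columns sample_id, time_bin, locality, lithology, species, genus,
        family, count — one row per (sample, species).
    ``wide_csv``
        columns sample_id, time_bin, locality, lithology then one column
        per taxon ("Genus species").
    ``pbdb_csv``
        Paleobiology Database occurrence download: collection_no (used as
        the sample id), accepted_name, genus, family, abund_value, plus
        time_bin/locality/lithology if present.

    Family-level identifications (no genus, name ending in -idae/-inae)
    are excluded; the number excluded is logged.  Informal species are
    flagged and, for genus-only rows, normalised to "Genus sp.".
    """
    scheme = scheme or default_scheme()
    if format == "long_csv":
        df = _read_csv(path)
        req = {"sample_id", "time_bin", "locality", "lithology", "species", "genus", "count"}
        _require_columns(df, req, path)
        if "family" not in df.columns:
            df["family"] = ""
        rows = df
    elif format == "wide_csv":
        df = _read_csv(path)
        meta_cols = ["sample_id", "time_bin", "locality", "lithology"]
        _require_columns(df, set(meta_cols), path)
        taxa_cols = [c for c in df.columns if c not in meta_cols]
        rows = df.melt(id_vars=meta_cols, value_vars=taxa_cols,
                       var_name="species", value_name="count")
        rows = rows[pd.to_numeric(rows["count"], errors="coerce").fillna(0) > 0]
        rows = rows.copy()
        rows["genus"] = [ _canon(s).split()[0] for s in rows["species"] ]
        rows["family"] = ""
    elif format == "pbdb_csv":
        df = _read_csv(path)
        _require_columns(df, {"collection_no", "accepted_name", "abund_value"}, path)
        bad = pd.to_numeric(df["abund_value"], errors="coerce").isna()
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} occurrences without numeric abundance in {path}"
            )
        rows = pd.DataFrame({
            "sample_id": df["collection_no"].astype(str),
            "time_bin": df["time_bin"] if "time_bin" in df else 0,
            "locality": df["locality"] if "locality" in df else "",
            "lithology": df["lithology"] if "lithology" in df else "mixed",
            "species": df["accepted_name"],
            "genus": df["genus"] if "genus" in df else "",
            "family": df["family"] if "family" in df else "",
            "count": df["abund_value"],
        })
    else:
        raise ValueError(f"unknown format {format!r}")

    return _rows_to_table(rows, scheme, source=str(path))


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype={"sample_id": str}, skipinitialspace=True)
    except pd.errors.ParserError as e:  # pragma: no cover - message passthrough
        raise ParseError(f"{path}: {e}") from None


def _require_columns(df: pd.DataFrame, required: set, path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")


def _rows_to_table(rows: pd.DataFrame, scheme: TimeBinScheme, source: str = "") -> AbundanceTable:
    rows = rows.copy()
    cnt = pd.to_numeric(rows["count"], errors="coerce")
    if cnt.isna().any():
        i = int(np.argmax(cnt.isna().to_numpy()))
        raise ParseError(f"{source}: non-numeric count at data row {i + 1}")
    if not np.allclose(cnt, np.round(cnt)):
        raise ValidationError(f"{source}: counts must be integers")
    if (cnt < 0).any():
        raise ValidationError(f"{source}: negative count")
    rows["count"] = cnt.astype(np.int64)

    rows["genus"] = rows["genus"].fillna("").map(_canon)
    rows["species"] = rows["species"].fillna("").map(_canon)
    rows["family"] = rows.get("family", "").fillna("").map(_canon)

    # family-level identifications: no genus and a family-form (or 'indet.') name
    name0 = rows["species"].str.split().str[0].fillna("")
    is_family = (rows["genus"] == "") & (
        name0.str.contains(_FAMILY_RE) | rows["species"].str.contains(r"\bindet\.?", case=False)
    )
    n_family = int(is_family.sum())
    if n_family:
        logger.info("excluded %d family-level identification rows", n_family)
    rows = rows[~is_family].copy()
    if (rows["genus"] == "").any():
        bad = rows.loc[rows["genus"] == "", "species"].iloc[0]
        raise ValidationError(f"{source}: record {bad!r} has no genus assignment")

    norm = [_normalise_species(g, s) for g, s in zip(rows["genus"], rows["species"])]
    rows["species"] = [n for n, _ in norm]
    rows["is_informal"] = [f for _, f in norm]
    rows["time_bin"] = [scheme.index_of(b) for b in rows["time_bin"]]

    tab = _finish_long(rows, scheme)
    tab.n_family_level_excluded = n_family
    return tab


# ---------------------------------------------------------------------------
# Writing


def write_long_csv(table: AbundanceTable, path) -> None:
    """Write the long dialect; inverse of load_abundance_table(long_csv)."""
    recs = []
    tax = table.taxonomy
    for sid in table.sample_ids:
        m = table.meta.loc[sid]
        row = table.counts.loc[sid]
        for taxon in table.taxa:
            n = int(row[taxon])
            if n == 0:
                continue
            genus = tax.loc[taxon, "genus"] if tax is not None else taxon
            family = tax.loc[taxon, "family"] if tax is not None else ""
            recs.append((sid, table.scheme.labels[int(m["time_bin"])], m["locality"],
                         m["lithology"], taxon, genus, family, n))
    pd.DataFrame(
        recs,
        columns=["sample_id", "time_bin", "locality", "lithology",
                 "species", "genus", "family", "count"],
    ).to_csv(path, index=False)


def write_wide_csv(table: AbundanceTable, path) -> None:
    out = table.meta[["time_bin", "locality", "lithology"]].copy()
    out.insert(0, "sample_id", table.counts.index)
    out["time_bin"] = [table.scheme.labels[int(b)] for b in out["time_bin"]]
    out = pd.concat([out.reset_index(drop=True),
                     table.counts.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filters and transforms


def filter_min_specimens(table: AbundanceTable, threshold: int = 50) -> AbundanceTable:
    """Retain samples with at least ``threshold`` specimens.

    The conventional cut drops samples with fewer than 50 specimens, so a
    sample of exactly 50 is kept.  Taxa left with zero total abundance are
    dropped.  Idempotent.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    keep = table.specimen_totals >= threshold
    sub = AbundanceTable(
        table.counts.loc[keep], table.meta.loc[keep], table.taxonomy,
        table.rank, table.scheme,
    )
    return sub.drop_empty_taxa()


def aggregate_to_rank(table: AbundanceTable, rank: str = "genus") -> AbundanceTable:
    """Sum congeneric species columns into genus columns.

    Informal species contribute to their genus; specimen totals are
    conserved exactly.
    """
    if rank != "genus":
        raise ValueError("only aggregation to genus rank is supported")
    if table.rank != "species":
        raise ValidationError("aggregation requires a species-rank table")
    if table.taxonomy is None:
        raise ValidationError("species table lacks a taxonomy map")
    genera = table.taxonomy.loc[table.taxa, "genus"]
    if (genera.map(_canon) == "").any():
        bad = genera.index[genera.map(_canon) == ""][0]
        raise ValidationError(f"species {bad!r} lacks a genus assignment")
    agg = table.counts.T.groupby(genera.values).sum().T
    agg = agg[sorted(agg.columns)]
    return AbundanceTable(agg, table.meta, None, "genus", table.scheme)


def split_by_bin(table: AbundanceTable) -> dict[int, AbundanceTable]:
    """Partition samples by time bin; only occupied bins appear as keys."""
    out: dict[int, AbundanceTable] = {}
    for b, idx in table.meta.groupby("time_bin").groups.items():
        sub = AbundanceTable(
            table.counts.loc[idx], table.meta.loc[idx], table.taxonomy,
            table.rank, table.scheme,
        )
        out[int(b)] = sub
    return out
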