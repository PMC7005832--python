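"""Palaeolatitudinal affinity groups.

Species are classified by the absolute palaeolatitudinal extent of their
whole known range: species confined to the tropics (|lat| <= 23.5 deg by
default) have warm-water affinity; species reaching into but not beyond
the warm-temperate zone (up to 43 deg by default) are eurythermal; species
recorded poleward of that limit are wide-ranging/cool-tolerant.  The zone
boundaries are configuration, and southern-hemisphere records are folded
to absolute latitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrences import AbundanceTable, _key


@dataclass(frozen=True)
class LatRangeRecord:
    species: str
    min_palaeolat: float
    max_palaeolat: float

    def __post_init__(self):
        if not (-90 <= self.min_palaeolat <= self.max_palaeolat <= 90):
            raise ValueError(
                f"{self.species}: invalid latitude range "
                f"[{self.min_palaeolat}, {self.max_palaeolat}]")

    @property
    def absolute_extent(self) -> float:
        """Largest absolute latitude the species reaches."""
        return max(abs(self.min_palaeolat), abs(self.max_palaeolat))


@dataclass(frozen=True)
class AffinityScheme:
    """Ordered zones by increasing boundary latitude (degrees absolute)."""

    zone_names: tuple[str, ...] = ("warm-water", "eurythermal", "wide-ranging")
    boundaries: tuple[float, ...] = (23.5, 43.0)

    def __post_init__(self):
        if len(self.boundaries) != len(self.zone_names) - 1:
            raise ValueError("need one fewer boundary than zones")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")


def classify_species(rec: LatRangeRecord, scheme: AffinityScheme | None = None) -> str:
    """Innermost zone containing the species' full absolute-latitude range."""
    scheme = scheme or AffinityScheme()
    extent = rec.absolute_extent
    for name, bound in zip(scheme.zone_names, scheme.boundaries):
        if extent <= bound:
            return name
    return scheme.zone_names[-1]


def load_lat_ranges(path) -> list[LatRangeRecord]:
    """CSV with columns species, min_palaeolat, max_palaeolat."""
    df = pd.read_csv(path, skipinitialspace=True)
    missing = {"species", "min_palaeolat", "max_palaeolat"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [LatRangeRecord(str(r.species), float(r.min_palaeolat),
                           float(r.max_palaeolat))
            for r in df.itertuples()]


def classify_all(records, scheme: AffinityScheme | None = None) -> dict[str, str]:
    scheme = scheme or AffinityScheme()
    return {rec.species: classify_species(rec, scheme) for rec in records}


def bin_affinity_composition(table: AbundanceTable, classes: dict[str, str],
                             unknown_label: str = "unknown") -> pd.DataFrame:
    """Per-bin fractions of species in each affinity class.

    Presence-based: a species counts once per bin it occurs in, regardless
    of abundance.  Unclassified species fall into ``unknown_label``;
    fractions (including unknown) sum to 1 in every occupied bin.
    """
    lookup = {_key(k): v for k, v in classes.items()}
    presence = table.counts > 0
    bins = table.meta["time_bin"].to_numpy()
    labels = sorted(set(lookup.values()) | {unknown_label})
    rows = []
    for b in sorted(set(int(x) for x in bins)):
        in_bin = presence.loc[bins == b].any(axis=0)
        taxa = [t for t in table.taxa if in_bin[t]]
        if not taxa:
            continue
        counts = {lab: 0 for lab in labels}
        for t in taxa:
            counts[lookup.get(_key(t), unknown_label)] += 1
        n = len(taxa)
        row = {"bin": b, "n_species": n}
        row.update({lab: counts[lab] / n for lab in labels})
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")
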