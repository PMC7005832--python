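"""Functional (ecospace) composition and latitudinal affinity groups.

Tallies genus abundances into modes of life (tiering x motility x
feeding) and classifies species into palaeolatitudinal affinity groups
(warm-water if confined to the tropics, eurythermal up to the 43-degree
warm-temperate limit, wide-ranging beyond), then summarises the per-bin
affinity composition of the fauna.
"""

from paleocomm import (
    AffinityScheme,
    aggregate_to_rank,
    bin_affinity_composition,
    filter_min_specimens,
    to_functional_table,
)
from paleocomm.affinity import LatRangeRecord, classify_all
from paleocomm.synthetic import preset, simulate

table, truth = simulate(preset("stable", seed=3))
genus = aggregate_to_rank(filter_min_specimens(table, 50))

func = to_functional_table(genus, truth.ecospace)
print(f"{genus.n_taxa} genera fall into {func.n_taxa} modes of life")
totals = func.counts.sum(axis=0).sort_values(ascending=False)
print("top modes of life by specimens:")
print(totals.head(5).to_string())

records = [LatRangeRecord(r.species, r.min_palaeolat, r.max_palaeolat)
           for r in truth.lat_ranges.itertuples()]
classes = classify_all(records, AffinityScheme())
comp = bin_affinity_composition(table, classes)
print("\nper-bin affinity composition (fractions of species):")
print(comp.round(3).to_string())
print("\nzones: warm-water <= 23.5 deg, eurythermal <= 43 deg, "
      "wide-ranging beyond")
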