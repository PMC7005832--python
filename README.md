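# paleocomm

Quantitative paleocommunity analysis for stratigraphically binned
sample-by-taxon abundance data, of the kind compiled from bed-level fossil
collections and literature counts (e.g. Paleobiology Database downloads).
It is aimed at paleoecologists asking whether events in a stratigraphic
series — mass extinctions, hyperthermals, facies changes — left a signal
in the diversity, composition and functional structure of benthic
communities.

The package provides, as a library with a thin CLI:

- **Data handling** — species-rank abundance tables with per-sample
  metadata (16-bin default time scheme, locality, lithology), loaders for
  long/wide/PBDB CSV dialects, the standard "≥ 50 specimens" sample
  filter, genus aggregation, and informal-species ("*Genus* sp.")
  bookkeeping.
- **Diversity** — raw richness and shareholder quorum subsampling (SQS):
  specimens are drawn without replacement until the summed true relative
  frequencies of the taxa encountered reach a quota *q* (default 0.6)
  corrected by Good's *u* = 1 − n₁/N; the richness at the stopping point,
  averaged over trials, is the coverage-standardised richness.
  Kruskal–Wallis comparisons between bins or lithology classes.
- **Turnover** — Foote boundary-crosser classification per bin (FL, bL,
  Ft, bt from range-through taxon ranges) and the proportion rates
  extinction = (N_bL + N_FL)/N, origination = (N_Ft + N_FL)/N,
  turnover = (N_bL + N_Ft + N_FL)/N, with edge-bin masking.
- **Ecospace** — genus → mode-of-life assignment (tiering × motility ×
  feeding, configurable vocabularies) and functional abundance tables.
- **Composition** — Bray–Curtis (on √-transformed relative abundances)
  and Kulczynski (presence/absence) dissimilarities, non-metric MDS
  minimising Kruskal stress-1 with per-sample stress screening, PERMANOVA
  (pseudo-F by Anderson's direct partitioning, pairwise t = √F, permutation
  and Monte-Carlo p-values), and sequential between-bin centroid
  dissimilarities in PCoA space.
- **Networks** — weighted unipartite sample networks (edge weight =
  Bray–Curtis similarity), unweighted bipartite sample–taxon networks,
  walktrap partitioning (modularity-optimal dendrogram cut), overlapping
  COPRA covers with extended modularity
  Q_E = (1/2m) Σ_c Σ_ij (A_ij − k_i k_j/2m) α_ic α_jc,
  and configuration-model (degree-preserving) null tests.
- **Affinity** — palaeolatitudinal affinity groups (warm-water ≤ 23.5°,
  eurythermal ≤ 43°, wide-ranging beyond) and per-bin composition.
- **Synthetic data** — a generator of stratigraphic community series with
  known per-bin extinction/origination, optional extinction pulse and
  composition shift, log-series dominance and species nested in genera, so
  every estimator can be validated against ground truth.

## Worked example

`examples/02_foote_turnover.py` simulates a mass-extinction scenario
(extinction pulse with probability 0.8 after bin 8, pool resampling at
bin 9) and recovers the event from the sampled abundances alone:

```
planted pulse: bin 8 with extinction probability 0.8
estimated extinction argmax: bin 8 (rate 0.79)
Edge bins are masked (NaN): their rates are truncated by the window.
```

The estimated extinction proportion peaks at the pulse bin and matches the
planted probability to within sampling error.  Continuing with the same
scenario, `examples/03_ordination_permanova.py` finds the compositional
break exactly at the planted shift:

```
largest shift: bins 8 -> 9 (t = 11.0); the scenario planted its shift at bin 9
```

and `examples/04_network_communities.py` partitions the genus-level sample
network into exactly two modules — one holding all pre-pulse samples
(bins 0–8), one all post-pulse samples (bins 9–15) — with a
configuration-model null fraction below 0.01.  The other examples cover
SQS diversity, ecospace tallying and latitudinal affinity.

An end-to-end run (simulation → filtering → diversity → turnover →
ordination → PERMANOVA → networks → affinity, with every interface table
written to disk) is one command:

```sh
paleocomm run-preset --preset mass_extinction --out scratch/run --seed 1
```

## Layout

```
src/paleocomm/     occurrences, ecospace, diversity, turnover,
                   composition, networks, affinity, synthetic, pipeline, cli
examples/          one short narrative script per capability
tests/             unit + property tests and statistical acceptance checks
docs/methods.md    models, estimators, numerical choices, limitations
```
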