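# Methods

This note documents the models and estimators implemented in `paleocomm`,
the choices made where conventions diverge, and what the synthetic-data
generator does and does not emulate.

## Data model and filtering

A dataset is a samples × taxa matrix of integer specimen counts plus
per-sample metadata: an ordinal time bin (default scheme: 16 ordered
Maastrichtian–Priabonian intervals with hyperthermal flags), a locality
and a lithology class (carbonate, clastic, mixed, glauconitic).  At
species rank a taxonomy map carries genus, family and an informal flag.

Conventions:

- Names are whitespace-collapsed and matched case-insensitively; no
  synonymy resolution is attempted.
- Open-nomenclature species ("*Genus* sp./spp.") are retained as distinct
  species-rank entities within their genus — they are countable but
  underrepresent true species variation.  Genus-only records are
  normalised to "*Genus* sp.".
- Identifications resolvable only to family level cannot enter a
  genus-level analysis and are dropped at load time with a logged count.
- The small-sample filter keeps samples with **at least** the threshold
  number of specimens (default 50; a sample of exactly 50 is kept).  The
  filter is idempotent and conserves counts on retained samples.
- Duplicate sample ids are rejected: a sample is one bed-level collection.

## Coverage-subsampled richness (SQS)

Per sample, each trial draws specimens uniformly without replacement and
accumulates the set of taxa seen; the trial stops as soon as the summed
*true* relative frequencies of the encountered taxa reach `quota × u`,
where `u = 1 − (singleton taxa)/(specimens)` is Good's coverage estimate,
and reports the number of taxa at the stop.  The estimate is the mean
over `n_trials` (default 1000; the pipeline uses 200).  Choices:

- The within-sample (specimen-draw) variant is used, because the analysis
  standardises *each sample*, not a pooled collection curve.
- Good's u corrects the quota target (effective quorum = quota × u).
  Exclusion of the single most dominant taxon from the coverage
  bookkeeping is available but off by default.
- Counts are sorted into canonical order before simulation, which makes
  the estimate exactly invariant under taxon relabelling at fixed seed.
- Samples with a single taxon carry no subsampling information and raise
  a distinct exclusion signal rather than an error.
- The mean (not median) over trials is reported.

## Foote turnover rates

Taxon ranges are the extremes of binned occurrence; taxa are assumed
present in every bin between first and last occurrence (range-through).
Per bin, taxa are classified FL (confined), bL (bottom-crosser only),
Ft (top-crosser only) or bt (both), and the rates are the proportions
extinction = (N_bL + N_FL)/N, origination = (N_Ft + N_FL)/N and turnover
= (N_bL + N_Ft + N_FL)/N, which obey turnover = extinction + origination
− N_FL/N identically.  Rates depend only on presence, never abundance.
Origination and turnover are masked (reported NaN, flag set) in the first
bin and extinction and turnover in the last, where ranges are truncated;
the category counts stay visible.  A sampled-in-bin mode (classify only
taxa actually sampled in the bin) is available for sensitivity analysis.

## Dissimilarity, ordination, PERMANOVA

- Transforms: relative abundance (rows sum to 1), square-root of relative
  abundance (deemphasises dominants; the default under Bray–Curtis), and
  presence/absence.
- Bray–Curtis d = 1 − 2Σmin(xᵢ,yᵢ)/(Σx+Σy); Kulczynski presence/absence
  d = 1 − ½(a/(a+b) + a/(a+c)).
- nMDS minimises Kruskal stress-1 by alternating monotone (isotonic)
  regression of configuration distances on dissimilarity ranks with a
  Guttman/SMACOF update.  Tied dissimilarities are pooled into single
  isotonic blocks (the primary approach to ties).  The first start is the
  metric PCoA configuration, the rest random; the best final stress wins.
  Per-sample stress is the point-wise contribution
  √(Σⱼ(dᵢⱼ−d̂ᵢⱼ)²/Σⱼdᵢⱼ²); samples above 0.3 are removed and the
  ordination refit once, with an optional single-start 0.8 pre-filter for
  species-level runs (both thresholds configurable).  This point-wise
  formula is one convention among several; it is isolated for sensitivity
  testing.
- PERMANOVA computes pseudo-F directly from the dissimilarity matrix
  (SS_T = Σᵢ<ⱼd²ᵢⱼ/N, within-group analogue, Anderson's partitioning);
  p by unrestricted label permutation with the observed labelling counted
  in numerator and denominator; pairwise t = √F for two groups (a
  semi-metric can make SS_A marginally negative; t is then clamped at 0).
  When fewer than 999 distinct relabelings exist, a Monte-Carlo p is
  added from a normal approximation to the permutation distribution of t
  — an approximation to the asymptotic-distribution Monte-Carlo p of
  PRIMER, and documented as such.
- Sequential comparisons report, for each adjacent occupied bin pair, the
  pairwise t and p plus the dissimilarity between group centroids in the
  full PCoA embedding, where axes with negative eigenvalues contribute
  with negative sign; this reproduces the raw pairwise dissimilarity
  exactly for single-sample groups.  Centroids in PCoA space were chosen
  over among-group sums of squares; both agree for Euclidean-embeddable
  matrices.

## Networks and community structure

- Unipartite: nodes are samples; an edge joins two samples sharing at
  least one taxon, weighted by their Bray–Curtis similarity computed on
  untransformed relative abundances (a √-transform flag exists; the
  transform is an ordination convention, not a network one).
- Bipartite: unweighted sample–taxon edges, one per occurrence; the
  one-mode projection joins same-class nodes sharing a bipartite
  neighbour.
- Walktrap (random-walk agglomeration, walk length 5, dendrogram cut at
  maximal weighted modularity) is delegated to igraph's reference
  implementation; connected components are handled independently and
  nodes are processed in sorted order, making results deterministic.
- Modularity is weighted Newman Q = Σ_c (w_cc/W − (s_c/2W)²); extended
  modularity for overlapping covers is the belonging-coefficient bilinear
  form Q_E = (1/2m) Σ_c Σ_ij (A_ij − kᵢkⱼ/2m) α_ic α_jc, which reduces
  exactly to Q for crisp covers.  For bipartite covers Q_E is scored on
  the unweighted sample-side projection.  The exact overlapping-modularity
  variant differs between published protocols; this one is isolated so
  alternatives can be swapped.
- COPRA: label propagation with per-node belonging coefficients capped at
  v memberships (default v = 2; labels below 1/v are discarded and the
  rest renormalised, with seeded random tie-breaks).  Updates are
  synchronous, except that on two-colourable graphs a sweep updates one
  vertex class and then the other — a fully synchronous sweep on a
  bipartite graph never converges (the sides swap label vectors), and the
  alternating scheme is the standard COPRA treatment of bipartite
  networks.  Termination is on stabilisation of per-label node counts
  (two consecutive stable sweeps) or `max_iter`.  `best_of_n` runs many
  independently seeded replicates and keeps the cover with the highest
  quality score (default: extended modularity from the sample nodes); the
  pipeline default is a few hundred runs, far below the 10⁵-run protocol
  reported for the reference analysis, and is configurable upward.
- Configuration-model null: for each replicate the topology is rewired to
  a uniform simple graph with the observed degree sequence (stub matching
  with rejection; for graphs at density ≥ 0.5, where rejection is
  hopeless and the degree sequence nearly pins the topology,
  degree-preserving double-edge swaps from the observed graph are used
  instead — for a complete graph the null correctly reduces to
  reassigning the observed weights).  Observed edge weights are then
  randomly reassigned to the new edges.  The reported fraction is the
  share of replicates whose detected score reaches the observed score;
  fractions below 1% are taken as support for real structure.

## Latitudinal affinity

Species are classified once, from their full known range folded to
absolute latitude: warm-water if the extent stays within the tropical
boundary (23.5°), eurythermal if within the warm-temperate limit (43°),
wide-ranging beyond; both boundaries and the zone list are configuration.
Per-bin composition is presence-based (each species counts once per bin)
and includes an explicit `unknown` bucket so fractions always sum to 1.

## Synthetic data generator

The generator emulates a regional, literature-augmented compilation:
~10²–10³ bed-level samples of ≥ 50 specimens across 16 ordered bins,
right-skewed abundance distributions dominated by a few taxa, and species
nested within genera so species-level turnover runs faster than
genus-level.

Dynamics: an initial pool of `n_genera` genera (default 45) with
1 + Poisson(0.8) species each evolves bin-to-bin; each species present
goes extinct after a bin with probability `extinction_prob` (default
0.15), so the per-bin Foote extinction proportion has expectation equal
to the planted probability on interior bins.  Origination draws
Poisson(o(1−o)⁻¹ · pool) new species per bin (target Foote origination
proportion `origination_prob`, default 0.15), each joining an existing
genus with probability 0.7, otherwise founding a new genus.  Each species
receives a relative-abundance weight at origination from a log-series
distribution (θ = 0.9; lognormal alternative); samples draw
Multinomial(n, weights) specimens with n lognormal between 50 and 400
(median ≈ 150), 12 samples per bin.

Events: a **pulse** raises the extinction probability for one bin
transition (default 0.8) and suppresses origination for a configurable
delay; a **composition shift** re-draws the abundance weights of the
surviving pool and, after a pulse, refills the pool to its pre-event size
by a radiation in which 90% of new species found new genera — emulating a
post-extinction recovery whose fauna is taxonomically distinct from the
pre-event one.  Truth output records the full config, true species and
genus ranges, realised per-bin rates, and the pre/post-shift module label
of every sample.

Presets (parameters fixed here, not tuned per run):

- `stable` — background dynamics only.  Sampling intensity (≈ 1800–2200
  specimens per bin against ~60–90 active species) keeps the per-bin
  detection failure of an active species at the 10⁻³–10⁻⁴ level, so
  observed range-through ranges track true ranges closely enough for
  estimator-recovery tests; this is a design requirement of the preset,
  not an accident.
- `mass_extinction` — pulse (p = 0.8) after bin 8, one-bin origination
  delay, composition shift at bin 9.  The two regimes separate into two
  genus-level walktrap modules split exactly at the shift bin.
- `hyperthermal_null` — a closed pool (no origination or extinction) with
  hyperthermal flags on bins 8, 9 and 12.  Adjacent bins are exchangeable
  by construction, so any significant sequential-PERMANOVA shift at a
  flagged bin is a false positive; background turnover would break that
  exchangeability, which is why the null preset runs dynamics-free.

What the generator does **not** emulate: sequence-stratigraphic hiatuses,
facies-dependent preservation, time-averaging differences between
lithologies (lithology labels are random), geographic structure within
bins, and realistic pool sizes — with only a few hundred species, a few
ubiquitous dominants make the bipartite co-occurrence projection nearly
complete, so projection-based extended modularity has little contrast at
this scale (real compilations with thousands of mostly rare species give
sparse projections).  Passing tests therefore validate the estimators
under idealised sampling, not robustness to preservation bias.

## Problem sizes and determinism

The test suite and the acceptance script run at deliberately compact
sizes chosen to exercise the statistics without waste: 2000 null
simulations for PERMANOVA calibration (n = 20, 199 permutations), 200
stable-preset replicates for Foote recovery, 100 dynamics-free replicates
for the sequential-PERMANOVA false-shift rate, 500 configuration-model
replicates for the null test, and best-of-50/100 COPRA runs.  Every
stochastic routine takes an explicit seed; pipeline reruns with the same
config are byte-identical.

## Known limitations

- The Monte-Carlo PERMANOVA p is a normal approximation, not PRIMER's
  asymptotic-distribution sampler; for very small groups prefer the
  exact permutation p over enumerable relabelings.
- Per-sample stress conventions differ between nMDS implementations;
  absolute per-sample values (and hence exclusion sets) may differ from
  other software even when configurations agree.
- COPRA's random tie-breaking makes single runs unstable by design;
  interpret only best-of-n results, and expect the trivial one-module
  cover on hub-dominated presence networks.
- SQS here is the within-sample variant; it is not comparable to
  multi-collection occurrence-based implementations.
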