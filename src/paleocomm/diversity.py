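"""Raw and coverage-subsampled richness.

Shareholder quorum subsampling (SQS) standardises richness across samples
of unequal size by drawing specimens without replacement until the summed
true relative frequencies of the taxa encountered reach a coverage quota
(default 0.6), corrected by Good's u — one minus the proportion of
specimens that belong to singleton taxa.  The returned value is the mean
number of taxa at the stopping point over many seeded trials.

Samples with a single taxon carry no subsampling information and are
excluded (signalled by :class:`SingleTaxonSample`, distinct from failure).
Between-group richness comparisons use the Kruskal-Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .occurrences import AbundanceTable


class SingleTaxonSample(Exception):
    """Exclusion signal: SQS is undefined for a single-taxon sample."""


@dataclass(frozen=True)
class SQSConfig:
    """Subsampling configuration.

    quota
        Coverage quorum in (0, 1]; 0.6 is the conventional choice.
    n_trials
        Subsampling trials averaged into the estimate.
    exclude_dominant
        If True, the single most abundant taxon is excluded from the
        coverage bookkeeping (its specimens still occupy draws).
    """

    quota: float = 0.6
    n_trials: int = 1000
    exclude_dominant: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.quota <= 1:
            raise ValueError("quota must be in (0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def raw_richness(counts) -> int:
    """Number of taxa with positive abundance."""
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("negative abundance")
    return int((c > 0).sum())


def goods_u(counts) -> float:
    """Good's u coverage estimate: 1 - (singleton taxa) / (total specimens)."""
    c = np.asarray(counts)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty abundance vector")
    total = c.sum()
    u = 1.0 - (c == 1).sum() / total
    return float(min(1.0, max(0.0, u)))


def sqs_richness(counts, cfg: SQSConfig | None = None) -> float:
    """Coverage-subsampled richness of one abundance vector.

    Each trial draws specimens in a random order without replacement and
    accumulates distinct taxa; the trial stops as soon as the summed true
    frequencies of the encountered taxa reach ``quota * u`` and reports the
    number of taxa seen.  Deterministic under a fixed config seed.
    """
    cfg = cfg or SQSConfig()
    c = np.asarray(counts)
    c = c[c > 0].astype(np.int64)
    c = np.sort(c)[::-1]  # canonical order: exact invariance to relabelling
    if c.size == 0:
        raise ValueError("empty abundance vector")
    if c.size == 1:
        raise SingleTaxonSample("single-taxon sample excluded from SQS")
    total = int(c.sum())
    freqs = c / total
    target_freqs = freqs.copy()
    if cfg.exclude_dominant:
        target_freqs[np.argmax(c)] = 0.0
    target = cfg.quota * goods_u(c)

    rng = np.random.default_rng(cfg.seed)
    specimens = np.repeat(np.arange(c.size), c)
    out = np.empty(cfg.n_trials)
    for t in range(cfg.n_trials):
        order = rng.permutation(specimens)
        # taxa in order of first encounter, then the stopping point of the
        # cumulative-coverage rule
        uniq, first = np.unique(order, return_index=True)
        encountered = uniq[np.argsort(first)]
        cum = np.cumsum(target_freqs[encountered])
        k = int(np.searchsorted(cum, target - 1e-12)) + 1
        out[t] = min(k, encountered.size)
    return float(out.mean())


def richness_table(tables: dict[str, AbundanceTable],
                   cfg: SQSConfig | None = None) -> pd.DataFrame:
    """Per-sample raw and subsampled richness across ranked tables.

    ``tables`` maps a rank label (e.g. "species", "genus", "functional")
    to an AbundanceTable over the same samples.  Single-taxon samples get
    NaN in the subsampled column.  Returns one row per sample with columns
    sample_id, time_bin, n_specimens, then raw_richness_<rank> and
    sqs_<rank> per supplied rank.
    """
    cfg = cfg or SQSConfig()
    first = next(iter(tables.values()))
    out = pd.DataFrame({
        "sample_id": first.sample_ids,
        "time_bin": first.meta["time_bin"].to_numpy(),
        "n_specimens": first.specimen_totals.to_numpy(),
    })
    for r, (rank, tab) in enumerate(tables.items()):
        raws, sqss = [], []
        for i, sid in enumerate(tab.sample_ids):
            vec = tab.counts.loc[sid].to_numpy()
            raws.append(raw_richness(vec))
            try:
                sub_cfg = SQSConfig(cfg.quota, cfg.n_trials, cfg.exclude_dominant,
                                    seed=cfg.seed + 100003 * r + i)
                sqss.append(sqs_richness(vec, sub_cfg))
            except SingleTaxonSample:
                sqss.append(np.nan)
        out[f"raw_richness_{rank}"] = raws
        out[f"sqs_{rank}"] = sqss
    return out


def compare_groups(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis comparison of a per-sample metric across groups.

    Returns (H, p) with tie correction.  Degenerate case of identical
    values in every group yields (0, 1).  An empty group is an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    parts = []
    for g in labels:
        part = values[groups == g]
        part = part[~np.isnan(part)]
        if part.size == 0:
            raise ValueError(f"group {g!r} is empty")
        parts.append(part)
    if np.ptp(np.concatenate(parts)) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*parts)
    return float(h), float(p)
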