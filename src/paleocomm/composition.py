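"""Compositional dissimilarity, ordination and permutation tests.

Workflow mirrors standard community-ecology practice: abundances are
converted to relative abundances (optionally square-root transformed to
deemphasise dominant taxa) or reduced to presence/absence; pairwise
dissimilarities use the Bray-Curtis coefficient for relative-abundance
data and the Kulczynski coefficient for presence/absence data; ordination
is non-metric multidimensional scaling (nMDS) minimising Kruskal stress-1;
group differences are tested with PERMANOVA, whose pairwise t = sqrt(F)
gives an absolute measure of separation between groups.

The permutation p-value counts the observed labelling in numerator and
denominator.  When the number of distinct labelings is small, a Monte
Carlo p-value from a normal approximation to the permutation distribution
of t is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .occurrences import AbundanceTable

# ---------------------------------------------------------------------------
# Transforms and coefficients


def transform(table: AbundanceTable, mode: str = "relative") -> pd.DataFrame:
    """Per-sample transform of the count matrix.

    relative          rows sum to 1
    relative_sqrt     element-wise sqrt of the relative abundances
    presence_absence  0/1 indicator
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        sid = table.counts.index[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {sid!r} has zero total abundance")
    if mode == "relative":
        mat = counts / totals[:, None]
    elif mode == "relative_sqrt":
        mat = np.sqrt(counts / totals[:, None])
    elif mode == "presence_absence":
        mat = (counts > 0).astype(float)
    else:
        raise ValueError(f"unknown transform {mode!r}")
    return pd.DataFrame(mat, index=table.counts.index, columns=table.counts.columns)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def kulczynski_pa(x, y) -> float:
    """Kulczynski presence/absence dissimilarity.

    With a shared, b only-in-x, c only-in-y:
    1 - (a/(a+b) + a/(a+c)) / 2.
    """
    x = np.asarray(x) > 0
    y = np.asarray(y) > 0
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    if a + b == 0 or a + c == 0:
        raise ValueError("empty presence set")
    return float(1.0 - 0.5 * (a / (a + b) + a / (a + c)))


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise sample dissimilarities with provenance tags."""

    ids: list
    values: np.ndarray
    method: str = "bray_curtis"
    transform: str = "relative"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any() or (v > 1 + 1e-9).any():
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids) -> "DissimilarityMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return DissimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)],
                                   self.method, self.transform)


def dissimilarity_matrix(table: AbundanceTable, method: str = "bray_curtis",
                         transform_mode: str | None = None) -> DissimilarityMatrix:
    """All pairwise dissimilarities of a table's samples.

    ``bray_curtis`` defaults to the ``relative_sqrt`` transform (dominance
    deemphasised); ``kulczynski_pa`` always works on presence/absence.
    """
    if method == "bray_curtis":
        mode = transform_mode or "relative_sqrt"
        mat = transform(table, mode).to_numpy()
        # vectorised pairwise Bray-Curtis
        mins = np.minimum(mat[:, None, :], mat[None, :, :]).sum(axis=2)
        sums = mat.sum(axis=1)
        denom = sums[:, None] + sums[None, :]
        d = 1.0 - 2.0 * mins / denom
    elif method == "kulczynski_pa":
        mode = "presence_absence"
        mat = transform(table, mode).to_numpy().astype(bool)
        a = (mat[:, None, :] & mat[None, :, :]).sum(axis=2).astype(float)
        sizes = mat.sum(axis=1).astype(float)
        d = 1.0 - 0.5 * (a / sizes[:, None] + a / sizes[None, :])
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DissimilarityMatrix(list(table.counts.index), d, method, mode)


# ---------------------------------------------------------------------------
# Principal coordinates (used for centroids and nMDS initialisation)


def pcoa_embedding(d: DissimilarityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Full principal-coordinate embedding of a dissimilarity matrix.

    Returns (coordinates, eigenvalues) over all axes, including those with
    negative eigenvalues (their coordinates are kept so that squared
    embedding distances reproduce the squared input dissimilarities when
    negative-axis contributions are subtracted).
    """
    D2 = d.values ** 2
    n = d.n
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    coords = v * np.sqrt(np.abs(w))[None, :]
    return coords, w


# ---------------------------------------------------------------------------
# nMDS


@dataclass
class OrdinationResult:
    ids: list
    coordinates: np.ndarray
    stress: float
    per_sample_stress: np.ndarray
    excluded: list = field(default_factory=list)
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates, index=self.ids,
                          columns=[f"axis{i+1}" for i in range(k)])
        df["per_sample_stress"] = self.per_sample_stress
        df.index.name = "sample_id"
        return df


def _monotone_fit(dvec: np.ndarray, diss: np.ndarray) -> np.ndarray:
    """Least-squares monotone (isotonic) disparities of configuration
    distances against dissimilarities; tied dissimilarities are pooled
    into single blocks (primary approach to ties)."""
    order = np.argsort(diss, kind="stable")
    uniq, inverse, counts_ = np.unique(diss[order], return_inverse=True,
                                       return_counts=True)
    block_means = np.zeros(len(uniq))
    np.add.at(block_means, inverse, dvec[order])
    block_means /= counts_
    fit = isotonic_regression(block_means, weights=counts_.astype(float)).x
    dhat = np.empty_like(dvec)
    dhat[order] = fit[inverse]
    return dhat


def _stress_parts(dist: np.ndarray, dhat: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    resid2 = (dist - dhat) ** 2
    denom = (dist ** 2).sum()
    stress = math.sqrt(resid2.sum() / denom) if denom > 0 else 0.0
    return stress, resid2, dist ** 2


def _nmds_single(D: np.ndarray, k: int, x0: np.ndarray, max_iter: int,
                 tol: float) -> tuple[np.ndarray, float, bool]:
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    diss = D[iu]
    X = x0.copy()
    last = np.inf
    converged = False
    for _ in range(max_iter):
        diff = X[:, None, :] - X[None, :, :]
        dist_mat = np.sqrt((diff ** 2).sum(axis=2))
        dvec = dist_mat[iu]
        dhat_vec = _monotone_fit(dvec, diss)
        stress, _, _ = _stress_parts(dvec, dhat_vec)
        if abs(last - stress) < tol:
            converged = True
            break
        last = stress
        # Guttman transform towards the disparities
        dhat = np.zeros_like(dist_mat)
        dhat[iu] = dhat_vec
        dhat += dhat.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist_mat > 1e-12, dhat / dist_mat, 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = B @ X / n
        X -= X.mean(axis=0)
        scale = np.sqrt((X ** 2).sum())
        if scale > 0:
            X /= scale
    return X, last if last < np.inf else 0.0, converged


def nmds(d: DissimilarityMatrix, k: int = 2, n_restarts: int = 8, seed: int = 0,
         max_iter: int = 300, tol: float = 1e-7,
         stress_threshold: float = 0.3,
         prefilter_threshold: float | None = None) -> OrdinationResult:
    """Non-metric MDS with random restarts and per-sample stress screening.

    The first start is the metric (principal-coordinate) configuration;
    the remaining ``n_restarts - 1`` are random.  Per-sample stress is the
    point-wise contribution sqrt(sum_j (d_ij - dhat_ij)^2 / sum_j d_ij^2).
    Samples exceeding ``prefilter_threshold`` (if given) are removed after
    a first single-start fit, then samples exceeding ``stress_threshold``
    are removed after the full fit and the ordination refit once.
    """
    if d.n < k + 2:
        raise ValueError("need at least k + 2 samples")
    rng = np.random.default_rng(seed)
    excluded: list = []
    work = d

    if prefilter_threshold is not None:
        res0 = _fit_best(work, k, 1, rng, max_iter, tol)
        bad = [s for s, v in zip(work.ids, res0.per_sample_stress)
               if v > prefilter_threshold]
        if bad and work.n - len(bad) >= k + 2:
            excluded.extend(bad)
            work = work.subset([s for s in work.ids if s not in set(bad)])

    res = _fit_best(work, k, n_restarts, rng, max_iter, tol)
    bad = [s for s, v in zip(work.ids, res.per_sample_stress)
           if v > stress_threshold]
    if bad and work.n - len(bad) >= k + 2:
        excluded.extend(bad)
        work = work.subset([s for s in work.ids if s not in set(bad)])
        res = _fit_best(work, k, n_restarts, rng, max_iter, tol)
    res.excluded = excluded
    return res


def _fit_best(d: DissimilarityMatrix, k: int, n_restarts: int, rng,
              max_iter: int, tol: float) -> OrdinationResult:
    D = d.values
    n = d.n
    coords0, _ = pcoa_embedding(d)
    starts = [coords0[:, :k]]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.standard_normal((n, k)))
    best = None
    for x0 in starts:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape[1] < k:  # degenerate PCoA with fewer positive axes
            x0 = np.hstack([x0, rng.standard_normal((n, k - x0.shape[1])) * 1e-3])
        x0 = x0 - x0.mean(axis=0)
        norm = np.sqrt((x0 ** 2).sum())
        x0 = x0 / norm if norm > 0 else rng.standard_normal((n, k))
        X, stress, conv = _nmds_single(D, k, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, conv)
    X, stress, conv = best
    iu = np.triu_indices(n, 1)
    diff = X[:, None, :] - X[None, :, :]
    dist_mat = np.sqrt((diff ** 2).sum(axis=2))
    dhat_vec = _monotone_fit(dist_mat[iu], D[iu])
    dhat = np.zeros_like(dist_mat)
    dhat[iu] = dhat_vec
    dhat += dhat.T
    resid2 = (dist_mat - dhat) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        per_sample = np.sqrt(resid2.sum(axis=1) / (dist_mat ** 2).sum(axis=1))
    per_sample = np.nan_to_num(per_sample)
    stress_final, _, _ = _stress_parts(dist_mat[iu], dhat_vec)
    return OrdinationResult(list(d.ids), X, stress_final, per_sample,
                            converged=conv)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    groups: list
    pseudo_F: float
    t: float | None
    p_perm: float
    p_mc: float | None
    n_permutations: int
    n_distinct_relabelings: float


def _ss_within(D2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    ssw = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        ssw += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ssw


def permanova(d: DissimilarityMatrix, groups, n_permutations: int = 999,
              seed: int = 0, mc_threshold: int = 999) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    The pseudo-F statistic partitions the total sum of squared
    dissimilarities directly (Anderson's approach):
    SS_T = sum_{i<j} d_ij^2 / N, SS_W analogous within groups,
    F = (SS_A / (a-1)) / (SS_W / (N-a)).  p is from unrestricted label
    permutation with the observed labelling counted.  For two groups,
    t = sqrt(F).  When fewer than ``mc_threshold`` distinct relabelings
    exist, a Monte Carlo p from a normal approximation to the permutation
    distribution of t is also reported.
    """
    labels = np.asarray(groups)
    if len(labels) != d.n:
        raise ValueError("group labels must align with samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        g = uniq[int(np.argmax(counts < 2))]
        raise ValueError(f"group {g!r} has fewer than two samples")
    N = d.n
    a = len(uniq)
    D2 = d.values ** 2
    ss_t = D2.sum() / (2 * N)
    ss_w = _ss_within(D2, labels, uniq)
    ss_a = ss_t - ss_w
    df_a, df_w = a - 1, N - a
    if ss_w <= 1e-300:
        f_obs = np.inf
    else:
        f_obs = (ss_a / df_a) / (ss_w / df_w)

    # number of distinct relabelings N! / prod(n_g!)
    log_distinct = math.lgamma(N + 1) - sum(math.lgamma(c + 1) for c in counts)
    n_distinct = math.exp(min(log_distinct, 700))
    if log_distinct < 40:  # exactly representable: report the integer
        n_distinct = float(round(n_distinct))

    rng = np.random.default_rng(seed)
    # vectorised permutation of labels via indicator matrices
    codes = np.searchsorted(uniq, labels)
    perm_f = np.empty(n_permutations)
    onehot = np.zeros((a, N))
    for b in range(n_permutations):
        perm = rng.permutation(codes)
        onehot[:] = 0.0
        onehot[perm, np.arange(N)] = 1.0
        within = np.einsum("gi,ij,gj->g", onehot, D2, onehot) / (2 * counts)
        ssw_p = within.sum()
        ssa_p = ss_t - ssw_p
        perm_f[b] = np.inf if ssw_p <= 1e-300 else (ssa_p / df_a) / (ssw_p / df_w)

    p_perm = (1 + int((perm_f >= f_obs - 1e-12).sum())) / (n_permutations + 1)
    if a != 2:
        t = None
    elif np.isfinite(f_obs):
        t = math.sqrt(max(f_obs, 0.0))  # negative pseudo-F (semi-metric) -> 0
    else:
        t = np.inf

    p_mc = None
    if n_distinct < mc_threshold:
        with np.errstate(invalid="ignore"):
            perm_t = np.sqrt(np.clip(perm_f[np.isfinite(perm_f)], 0, None))
        mu, sd = perm_t.mean(), perm_t.std(ddof=1)
        t_obs = math.sqrt(max(f_obs, 0.0)) if np.isfinite(f_obs) else np.inf
        if sd > 0 and np.isfinite(t_obs):
            from scipy.stats import norm
            p_mc = float(norm.sf((t_obs - mu) / sd))
        else:
            p_mc = 0.0 if t_obs > mu else 1.0
    return PermanovaResult(list(uniq), float(f_obs), t, float(p_perm), p_mc,
                           n_permutations, n_distinct)


# ---------------------------------------------------------------------------
# Sequential between-bin comparisons


def centroid_dissimilarity(d: DissimilarityMatrix, idx_a, idx_b) -> float:
    """Dissimilarity between two group centroids in PCoA space.

    All axes are retained; negative-eigenvalue axes contribute with
    negative sign to the squared centroid distance, so for single-sample
    groups the value reproduces the original pairwise dissimilarity.
    """
    coords, eig = pcoa_embedding(d)
    ca = coords[idx_a].mean(axis=0)
    cb = coords[idx_b].mean(axis=0)
    delta2 = (ca - cb) ** 2
    sq = delta2[eig > 0].sum() - delta2[eig < 0].sum()
    return float(math.copysign(math.sqrt(abs(sq)), sq)) if sq < 0 else float(math.sqrt(sq))


def sequential_centroid_dissimilarity(d: DissimilarityMatrix, bins,
                                      n_permutations: int = 999, seed: int = 0,
                                      alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise PERMANOVA t and centroid dissimilarity for adjacent bins.

    ``bins`` maps each sample id in ``d`` to an ordered bin label.  For
    every adjacent pair of occupied bins, the pairwise PERMANOVA t and
    permutation p (Monte Carlo p when available) and the PCoA centroid
    dissimilarity are reported; pairs whose p exceeds ``alpha`` are
    flagged insignificant.
    """
    bins = dict(bins) if not isinstance(bins, dict) else bins
    missing = [s for s in d.ids if s not in bins]
    if missing:
        raise ValueError(f"samples without bin assignment: {missing[:5]}")
    labels = np.array([bins[s] for s in d.ids])
    occupied = sorted(set(labels))
    rows = []
    for prev, cur in zip(occupied[:-1], occupied[1:]):
        idx = np.flatnonzero((labels == prev) | (labels == cur))
        if (labels == prev).sum() < 2 or (labels == cur).sum() < 2:
            continue
        sub = d.subset([d.ids[i] for i in idx])
        sub_labels = labels[idx]
        res = permanova(sub, sub_labels, n_permutations=n_permutations,
                        seed=seed + int(np.asarray(cur == np.array(occupied)).argmax()))
        cd = centroid_dissimilarity(sub, np.flatnonzero(sub_labels == prev),
                                    np.flatnonzero(sub_labels == cur))
        p_eff = res.p_mc if res.p_mc is not None else res.p_perm
        rows.append({
            "bin_prev": prev, "bin": cur, "t": res.t, "p_perm": res.p_perm,
            "p_mc": res.p_mc, "p": p_eff,
            "centroid_dissimilarity": cd,
            "significant": p_eff <= alpha,
            "n_permutations": res.n_permutations,
        })
    return pd.DataFrame(rows)
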