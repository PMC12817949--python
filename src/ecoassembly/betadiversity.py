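"""Pairwise community dissimilarity and permutation tests of group separation.

Bray-Curtis distances quantify compositional turnover between samples;
ANOSIM and PERMANOVA (one-way) test whether the grouping explains that
turnover, with p-values from label permutations. The root Jensen-Shannon
divergence (rJSD) is the dissimilarity used by the dissimilarity-overlap
curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .core_io import CommunityTable, DistanceMatrix, SampleMetadata

__all__ = [
    "GroupTestResult",
    "bray_curtis_matrix",
    "rjsd",
    "anosim",
    "permanova",
]


@dataclass
class GroupTestResult:
    """Outcome of a permutation test of between-group separation."""

    statistic_name: str  # "ANOSIM R" or "pseudo-F"
    statistic: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    r_squared: float | None = None  # PERMANOVA only

    def to_dict(self) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "group_sizes": self.group_sizes,
        }
        if self.r_squared is not None:
            d["r_squared"] = self.r_squared
        return d


def bray_curtis_matrix(table: CommunityTable) -> DistanceMatrix:
    """Bray-Curtis distance between every pair of samples.

    BC(x, y) = sum_i |x_i - y_i| / sum_i (x_i + y_i); works on counts or
    proportions. A sample with zero total abundance is an error.
    """
    values = table.values
    if np.any(values.sum(axis=0) == 0):
        j = int(np.argmax(values.sum(axis=0) == 0))
        raise ValueError(f"sample {table.sample_ids[j]!r} has zero total abundance")
    dm = squareform(pdist(values.T, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, dm, metric="braycurtis")


def rjsd(x: np.ndarray, y: np.ndarray) -> float:
    """Root Jensen-Shannon divergence between two probability vectors.

    rJSD = sqrt(0.5 KL(x||m) + 0.5 KL(y||m)) with m = (x+y)/2, natural
    logarithm, and the convention 0 log 0 = 0. Ranges over [0, sqrt(ln 2)].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("probability vectors must be non-negative")
    m = 0.5 * (x + y)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_x = np.where(x > 0, x * np.log(x / m), 0.0)
        kl_y = np.where(y > 0, y * np.log(y / m), 0.0)
    jsd = 0.5 * kl_x.sum() + 0.5 * kl_y.sum()
    return float(np.sqrt(max(jsd, 0.0)))


def _check_groups(dm: DistanceMatrix, meta: SampleMetadata) -> np.ndarray:
    labels = meta.labels_for(dm.ids)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("at least two groups are required")
    if np.any(counts < 2):
        g = uniq[np.argmax(counts < 2)]
        raise ValueError(f"group {g!r} has fewer than 2 samples")
    return labels


def _anosim_r(ranks: np.ndarray, within: np.ndarray, m: int) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    dm: DistanceMatrix, meta: SampleMetadata, n_perm: int = 999, seed: int = 0
) -> GroupTestResult:
    """ANOSIM test: R = (mean between-group rank - mean within-group rank)/(M/2).

    Distances are mid-ranked over all M = n(n-1)/2 pairs; the p-value is the
    (1 + #{permuted R >= observed R}) / (1 + n_perm) one-sided estimate under
    random relabelling of samples.
    """
    labels = _check_groups(dm, meta)
    n = len(dm.ids)
    condensed = squareform(dm.values, checks=False)
    ranks = rankdata(condensed)  # mid-ranks for ties
    m = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)

    within = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, within, m)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, w, m) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    sizes = {str(g): int((labels == g).sum()) for g in np.unique(labels)}
    return GroupTestResult("ANOSIM R", r_obs, p, n_perm, sizes)


def _permanova_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Return (pseudo-F, R^2) from squared distances and group labels."""
    n = len(labels)
    groups, inverse = np.unique(labels, return_inverse=True)
    a = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(inverse == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_within == 0:
        return np.inf, 1.0 if ss_total > 0 else 0.0
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def permanova(
    dm: DistanceMatrix, meta: SampleMetadata, n_perm: int = 999, seed: int = 0
) -> GroupTestResult:
    """One-way PERMANOVA (Adonis) on a distance matrix.

    pseudo-F = ((SS_total - SS_within)/(a-1)) / (SS_within/(n-a)) with
    SS_total = (1/n) sum_{i<j} d_ij^2 and within-group sums analogous.
    The permutation p-value shuffles group labels over samples. When
    SS_within = 0 the statistic is reported as +inf; the p-value is still
    defined from the permutation ordering.
    """
    labels = _check_groups(dm, meta)
    n = len(dm.ids)
    d2 = dm.values**2
    f_obs, r2 = _permanova_stats(d2, labels)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_stats(d2, rng.permutation(labels))
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    sizes = {str(g): int((labels == g).sum()) for g in np.unique(labels)}
    return GroupTestResult("pseudo-F", f_obs, p, n_perm, sizes, r_squared=r2)
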