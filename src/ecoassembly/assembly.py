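"""Null-model partitioning of community assembly processes.

The framework classifies every unordered pair of communities into one of
five assembly processes by comparing observed turnover against null
expectations:

* phylogenetic turnover: beta mean nearest taxon distance (betaMNTD) is
  standardised against a tip-shuffling null to give betaNTI; betaNTI > 2
  indicates heterogeneous selection, betaNTI < -2 homogeneous selection;
* taxonomic turnover: for the remaining pairs (|betaNTI| <= 2), the
  Bray-Curtis-based Raup-Crick metric (RCbray) places the observed
  Bray-Curtis within a null distribution of probabilistically re-assembled
  communities; RCbray > 0.95 indicates dispersal limitation, RCbray < -0.95
  homogenizing dispersal, and |RCbray| <= 0.95 drift.

Dispersal limitation, homogenizing dispersal and drift are treated as
stochastic processes; the two selection regimes as deterministic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core_io import CommunityTable, DistanceMatrix, SampleMetadata

__all__ = [
    "NullModelConfig",
    "AssemblyPartition",
    "PROCESS_LABELS",
    "patristic_matrix",
    "bmntd",
    "bnti",
    "raup_crick_bray",
    "partition_processes",
    "group_bnti_summary",
]

PROCESS_LABELS = (
    "heterogeneous selection",
    "homogeneous selection",
    "dispersal limitation",
    "homogenizing dispersal",
    "drift",
)


@dataclass
class NullModelConfig:
    """Settings shared by the betaNTI and Raup-Crick null models.

    Thresholds are symmetric about zero: a pair is classified as selection
    when |betaNTI| exceeds ``bnti_threshold`` and as dispersal when |RCbray|
    exceeds ``rc_threshold``.
    """

    n_randomizations: int = 999
    abundance_weighted: bool = True
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    seed: int = 0
    tie_tolerance: float = 1e-10
    exhaustive: bool = False  # enumerate all tip permutations (tiny tables only)

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class AssemblyPartition:
    """Per-pair process labels and the fractions of the five processes."""

    pairs: pd.DataFrame  # columns: sample_i, sample_j, bnti, rc, process
    fractions: dict[str, float]
    n_degenerate: int = 0

    @property
    def n_classified(self) -> int:
        return len(self.pairs) - self.n_degenerate

    @property
    def stochastic_fraction(self) -> float:
        return sum(
            self.fractions[p]
            for p in ("dispersal limitation", "homogenizing dispersal", "drift")
        )

    @property
    def deterministic_fraction(self) -> float:
        return sum(
            self.fractions[p]
            for p in ("heterogeneous selection", "homogeneous selection")
        )

    def modal_process(self) -> str:
        return max(PROCESS_LABELS, key=lambda p: self.fractions[p])

    def to_dict(self) -> dict:
        return {
            "fractions": self.fractions,
            "n_pairs": len(self.pairs),
            "n_degenerate": self.n_degenerate,
            "stochastic_fraction": self.stochastic_fraction,
            "deterministic_fraction": self.deterministic_fraction,
        }


# ---------------------------------------------------------------------------
# Phylogenetic turnover


def patristic_matrix(tree: dendropy.Tree, taxon_ids: list[str]) -> np.ndarray:
    """Patristic (branch-length) distance matrix over the given taxa.

    Every taxon must map to exactly one tree tip; an absent taxon is a
    hard error naming it.
    """
    pdm = tree.phylogenetic_distance_matrix()
    tip_by_label = {t.label: t for t in tree.taxon_namespace}
    for taxon in taxon_ids:
        if taxon not in tip_by_label:
            raise KeyError(f"taxon {taxon!r} is not a tip of the tree")
    n = len(taxon_ids)
    dist = np.zeros((n, n))
    for i in range(n):
        ti = tip_by_label[taxon_ids[i]]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(ti, tip_by_label[taxon_ids[j]])
            dist[i, j] = dist[j, i] = d
    return dist


def _weights_matrix(table: CommunityTable, abundance_weighted: bool) -> np.ndarray:
    """Per-sample taxon weights: relative abundances over present taxa, or
    1/richness in presence-absence mode. Zero for absent taxa."""
    counts = table.values.astype(float)
    present = counts > 0
    if np.any(present.sum(axis=0) == 0):
        j = int(np.argmax(present.sum(axis=0) == 0))
        raise ValueError(f"sample {table.sample_ids[j]!r} is empty")
    if abundance_weighted:
        return counts / counts.sum(axis=0)
    return present / present.sum(axis=0)


def _bmntd_square(weights: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs given taxon weights (taxa x samples)
    and a taxon x taxon distance matrix.

    For each sample k, M[:, k holds min_{i' present in k} d(i, i') for every
    taxon i; since the diagonal of `dist` is zero, a taxon shared by both
    samples contributes distance 0. betaMNTD(j,k) =
    0.5 * (sum_i w_ij M_ik + sum_i w_ik M_ij).
    """
    present = weights > 0
    n_samples = weights.shape[1]
    m = np.empty_like(weights)
    for k in range(n_samples):
        m[:, k] = dist[:, present[:, k]].min(axis=1)
    half = weights.T @ m  # (j, k) -> sum_i w_ij * M_ik
    out = 0.5 * (half + half.T)
    np.fill_diagonal(out, 0.0)
    return out


def bmntd(
    table: CommunityTable,
    tree: dendropy.Tree,
    abundance_weighted: bool = True,
    _dist: np.ndarray | None = None,
) -> DistanceMatrix:
    """Beta mean nearest taxon distance between every pair of samples.

    Abundance-weighted by default: each taxon's distance to its nearest
    relative in the other community is weighted by its within-sample
    relative abundance (over taxa present in that sample).
    """
    dist = patristic_matrix(tree, table.taxon_ids) if _dist is None else _dist
    weights = _weights_matrix(table, abundance_weighted)
    return DistanceMatrix(
        table.sample_ids, _bmntd_square(weights, dist), metric="bMNTD"
    )


def bnti(
    table: CommunityTable,
    tree: dendropy.Tree,
    config: NullModelConfig | None = None,
    _dist: np.ndarray | None = None,
) -> DistanceMatrix:
    """Beta nearest taxon index: standardised effect size of betaMNTD.

    The null model shuffles taxon labels across the tree tips (equivalently,
    permutes the rows of the taxon weight matrix against the patristic
    matrix) over all taxa in the table; betaNTI = (observed - null mean) /
    null sd per pair. Pairs whose null sd is below 1e-12 are degenerate and
    reported as NaN. With ``config.exhaustive`` the null enumerates every
    taxon permutation instead of sampling (tiny tables only).
    """
    config = config or NullModelConfig()
    dist = patristic_matrix(tree, table.taxon_ids) if _dist is None else _dist
    weights = _weights_matrix(table, config.abundance_weighted)
    n_taxa = weights.shape[0]
    obs = _bmntd_square(weights, dist)

    if config.exhaustive:
        if n_taxa > 8:
            raise ValueError("exhaustive null is limited to <= 8 taxa")
        perms = [np.array(p) for p in itertools.permutations(range(n_taxa))]
    else:
        rng = np.random.default_rng(config.seed)
        perms = [rng.permutation(n_taxa) for _ in range(config.n_randomizations)]

    nulls = np.empty((len(perms), *obs.shape))
    for r, perm in enumerate(perms):
        nulls[r] = _bmntd_square(weights[np.argsort(perm)], dist)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 1e-12, (obs - mean) / sd, np.nan)
    np.fill_diagonal(z, 0.0)
    z = 0.5 * (z + z.T)  # exact symmetry against fp noise
    return DistanceMatrix(table.sample_ids, z, metric="bNTI")


# ---------------------------------------------------------------------------
# Taxonomic turnover (Raup-Crick on Bray-Curtis)


def _null_communities(
    rng: np.random.Generator,
    n_draws: int,
    richness: int,
    total: int,
    occ_weights: np.ndarray,
    ab_weights: np.ndarray,
) -> np.ndarray:
    """Draw `n_draws` null communities preserving richness and total reads.

    Taxa are chosen without replacement with probability proportional to
    their occurrence frequency (Gumbel top-k); each chosen taxon receives
    one individual and the remaining reads are distributed multinomially
    with probability proportional to regional relative abundance over the
    chosen taxa.
    """
    n_taxa = len(occ_weights)
    with np.errstate(divide="ignore"):
        log_w = np.log(occ_weights)
    keys = log_w + rng.gumbel(size=(n_draws, n_taxa))
    chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    compact = np.ones((n_draws, richness))
    extra = total - richness
    if extra > 0:
        probs = ab_weights[chosen].astype(float)
        probs /= probs.sum(axis=1, keepdims=True)
        compact += rng.multinomial(extra, probs)
    counts = np.zeros((n_draws, n_taxa))
    rows = np.repeat(np.arange(n_draws), richness)
    counts[rows, chosen.ravel()] = compact.ravel()
    return counts


def raup_crick_bray(
    table: CommunityTable, config: NullModelConfig | None = None
) -> DistanceMatrix:
    """Bray-Curtis-based Raup-Crick deviation for every sample pair.

    For each unordered pair both communities are probabilistically
    re-assembled ``n_randomizations`` times, preserving observed richness
    and total abundance; the observed Bray-Curtis is placed within the null
    Bray-Curtis distribution and scaled to [-1, 1]:
    RC = 2 * (#{null < obs} + 0.5 #{null ~= obs}) / n - 1.
    Ties are counted within ``config.tie_tolerance``.
    """
    config = config or NullModelConfig()
    counts = table.values.astype(float)
    n_taxa, n_samples = counts.shape
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        j = int(np.argmax(totals == 0))
        raise ValueError(f"sample {table.sample_ids[j]!r} is empty")
    if not np.allclose(counts % 1, 0):
        raise ValueError("Raup-Crick requires integer counts")

    occ = (counts > 0).sum(axis=1).astype(float)  # occurrence frequency
    ab = counts.sum(axis=1)  # regional abundance
    richness = (counts > 0).sum(axis=0)
    n_draws = config.n_randomizations

    # one independent, order-invariant seed stream per unordered pair
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_samples * (n_samples - 1) // 2)

    rc = np.zeros((n_samples, n_samples))
    pair_idx = 0
    for j in range(n_samples):
        for k in range(j + 1, n_samples):
            rng = np.random.default_rng(children[pair_idx])
            pair_idx += 1
            obs = np.abs(counts[:, j] - counts[:, k]).sum() / (
                totals[j] + totals[k]
            )
            null_j = _null_communities(
                rng, n_draws, int(richness[j]), int(totals[j]), occ, ab
            )
            null_k = _null_communities(
                rng, n_draws, int(richness[k]), int(totals[k]), occ, ab
            )
            null_bc = np.abs(null_j - null_k).sum(axis=1) / (totals[j] + totals[k])
            below = (null_bc < obs - config.tie_tolerance).sum()
            ties = (np.abs(null_bc - obs) <= config.tie_tolerance).sum()
            rc[j, k] = rc[k, j] = 2.0 * (below + 0.5 * ties) / n_draws - 1.0
    return DistanceMatrix(table.sample_ids, rc, metric="RCbray")


# ---------------------------------------------------------------------------
# Classification


def _classify_pair(b: float, rc: float, bnti_thr: float, rc_thr: float) -> str:
    if b > bnti_thr:
        return "heterogeneous selection"
    if b < -bnti_thr:
        return "homogeneous selection"
    if rc > rc_thr:
        return "dispersal limitation"
    if rc < -rc_thr:
        return "homogenizing dispersal"
    return "drift"


def partition_processes(
    bnti_dm: DistanceMatrix,
    rc_dm: DistanceMatrix,
    scope: list[tuple[str, str]] | None = None,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> AssemblyPartition:
    """Assign each sample pair to one of the five assembly processes.

    ``scope`` restricts the classification to a subset of unordered pairs
    (default: all). Pairs whose betaNTI is degenerate (NaN) are excluded
    from the fraction denominator and counted separately.
    """
    if set(bnti_dm.ids) != set(rc_dm.ids):
        raise ValueError("betaNTI and RCbray matrices cover different samples")
    if scope is None:
        scope = [(a, b) for a, b, _ in bnti_dm.pairs()]
    records = []
    n_degenerate = 0
    counts = {p: 0 for p in PROCESS_LABELS}
    for a, b in scope:
        z = bnti_dm[a, b]
        r = rc_dm[a, b]
        if math.isnan(z):
            n_degenerate += 1
            records.append((a, b, z, r, "degenerate"))
            continue
        label = _classify_pair(z, r, bnti_threshold, rc_threshold)
        counts[label] += 1
        records.append((a, b, z, r, label))
    n_classified = sum(counts.values())
    fractions = {
        p: (counts[p] / n_classified if n_classified else 0.0) for p in PROCESS_LABELS
    }
    pairs = pd.DataFrame(
        records, columns=["sample_i", "sample_j", "bnti", "rc", "process"]
    )
    return AssemblyPartition(pairs, fractions, n_degenerate)


def group_bnti_summary(
    bnti_dm: DistanceMatrix,
    meta: SampleMetadata,
    mode: str = "within",
    reference: str | None = None,
) -> dict:
    """Per-group betaNTI distributions for group comparisons.

    ``mode="within"`` collects betaNTI over within-group pairs;
    ``mode="vs_reference"`` collects each group's pairs against the
    reference group's samples. Groups with fewer than two contributing
    samples yield an empty list. Each non-reference group is compared to the
    reference (when given) with a stock Wilcoxon rank-sum test.
    """
    if mode not in ("within", "vs_reference"):
        raise ValueError(f"unknown mode: {mode!r}")
    if mode == "vs_reference" and reference is None:
        raise ValueError("vs_reference mode requires a reference group")
    labels = meta.labels_for(bnti_dm.ids)
    out: dict[str, dict] = {}
    values_by_group: dict[str, list[float]] = {}
    for g in sorted(set(labels)):
        vals: list[float] = []
        for a, b, v in bnti_dm.pairs():
            ga, gb = meta.group_of(a), meta.group_of(b)
            if mode == "within":
                take = ga == g and gb == g
            else:
                take = (ga == g and gb == reference) or (
                    gb == g and ga == reference
                )
                if g == reference:
                    take = ga == g and gb == g
            if take and not math.isnan(v):
                vals.append(v)
        if not vals:
            logging.getLogger("ecoassembly").warning(
                "group_bnti_summary: group %r contributes no pairs", g
            )
        values_by_group[g] = vals
        arr = np.array(vals)
        out[g] = {
            "values": vals,
            "n_pairs": len(vals),
            "mean": float(arr.mean()) if len(vals) else None,
            "median": float(np.median(arr)) if len(vals) else None,
        }
    if reference is not None and reference in values_by_group:
        ref_vals = values_by_group[reference]
        for g, vals in values_by_group.items():
            if g == reference or not vals or not ref_vals:
                continue
            stat, p = mannwhitneyu(vals, ref_vals, alternative="two-sided")
            out[g]["rank_test_vs_reference"] = {"U": float(stat), "p_value": float(p)}
    return out
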