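"""Niche breadth, niche overlap, and specialist/generalist classification.

Habitat niche metrics treat the samples themselves as resource states: a
taxon's usage distribution p_i is its abundance across samples normalised
to sum to one. Levins breadth B = 1/sum p^2 (inverse Simpson concentration)
and Shannon breadth H = -sum p ln p quantify how evenly a taxon spreads
over habitats; Schoener (proportional similarity) and Pianka (cosine)
indices quantify how similarly two taxa use them. Taxa are classed as
specialists (B < 1.5), generalists (B > 5), or middle, and the
community-level breadth Bcom per sample is the abundance-weighted mean
breadth of the taxa present in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core_io import CommunityTable, SampleMetadata

__all__ = [
    "NicheProfile",
    "levins_breadth",
    "shannon_breadth",
    "schoener_overlap",
    "pianka_overlap",
    "community_niche_summary",
    "classify_taxa",
]

SPECIALIST_MAX = 1.5
GENERALIST_MIN = 5.0


def _usage(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("usage vector has negative entries")
    total = p.sum()
    if total == 0:
        raise ValueError("usage vector is all zero")
    return p / total


def levins_breadth(p: np.ndarray) -> float:
    """Levins niche breadth B = 1 / sum_j p_j^2, in [1, n_states]."""
    p = _usage(p)
    return float(1.0 / np.square(p).sum())


def shannon_breadth(p: np.ndarray) -> float:
    """Shannon niche breadth H = -sum_j p_j ln p_j (0 ln 0 = 0), in [0, ln n]."""
    p = _usage(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def schoener_overlap(p: np.ndarray, q: np.ndarray) -> float:
    """Schoener overlap O = 1 - 0.5 sum_j |p_j - q_j|, symmetric, in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("usage vectors differ in length")
    p, q = _usage(p), _usage(q)
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def pianka_overlap(p: np.ndarray, q: np.ndarray) -> float:
    """Pianka overlap: cosine similarity of the two usage vectors, in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("usage vectors differ in length")
    p, q = _usage(p), _usage(q)
    denom = np.sqrt(np.square(p).sum() * np.square(q).sum())
    return float((p * q).sum() / denom)


@dataclass
class NicheProfile:
    """Per-taxon breadths and classes, per-sample Bcom, per-scope overlaps."""

    per_taxon: pd.DataFrame  # index taxon; columns levins_b, shannon_h, class
    bcom: pd.Series  # index sample; abundance-weighted community breadth
    ocom: dict[str, dict[str, float]]  # scope -> {"schoener": x, "pianka": y}
    specialist_max: float = SPECIALIST_MAX
    generalist_min: float = GENERALIST_MIN

    def class_proportions(self, taxa: list[str] | None = None) -> dict[str, float]:
        classes = self.per_taxon["class"] if taxa is None else self.per_taxon.loc[
            taxa, "class"
        ]
        frac = classes.value_counts(normalize=True)
        return {
            c: float(frac.get(c, 0.0)) for c in ("specialist", "middle", "generalist")
        }


def _classify(b: float, specialist_max: float, generalist_min: float) -> str:
    # boundaries are strict as stated: B = 1.5 and B = 5 are "middle"
    if b < specialist_max:
        return "specialist"
    if b > generalist_min:
        return "generalist"
    return "middle"


def classify_taxa(
    levins_b: pd.Series,
    specialist_max: float = SPECIALIST_MAX,
    generalist_min: float = GENERALIST_MIN,
    phylum_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify taxa as specialist / middle / generalist from Levins B.

    Returns a frame with the class per taxon and, when a taxon -> phylum
    mapping is supplied, a ``phylum`` column enabling per-phylum class
    proportions.
    """
    classes = levins_b.apply(_classify, args=(specialist_max, generalist_min))
    out = pd.DataFrame({"levins_b": levins_b, "class": classes})
    if phylum_map is not None:
        out["phylum"] = phylum_map.reindex(out.index)
    return out


def community_niche_summary(
    table: CommunityTable,
    meta: SampleMetadata | None = None,
    weighted_bcom: bool = True,
    specialist_max: float = SPECIALIST_MAX,
    generalist_min: float = GENERALIST_MIN,
) -> NicheProfile:
    """Per-taxon breadths, per-sample Bcom, and per-scope mean overlaps.

    Resource states are the individual samples. Bcom for a sample is the
    mean Levins breadth of the taxa present in it, weighted by their
    within-sample relative abundance (or unweighted when
    ``weighted_bcom=False``). Ocom for a scope (a sample group, or the
    whole table) is the mean pairwise overlap over taxon pairs that
    co-occur within the scope's samples.
    """
    if table.n_samples < 2:
        raise ValueError("niche breadth is undefined for a single sample")
    counts = table.values.astype(float)
    taxa = table.taxon_ids
    row_totals = counts.sum(axis=1)
    nonzero = row_totals > 0
    usage = np.zeros_like(counts)
    usage[nonzero] = counts[nonzero] / row_totals[nonzero, None]

    b = np.full(len(taxa), np.nan)
    h = np.full(len(taxa), np.nan)
    b[nonzero] = 1.0 / np.square(usage[nonzero]).sum(axis=1)
    nz_usage = usage[nonzero]
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(nz_usage > 0, np.log(nz_usage), 0.0)
    h[nonzero] = -(nz_usage * logs).sum(axis=1)

    per_taxon = pd.DataFrame({"levins_b": b, "shannon_h": h}, index=taxa)
    per_taxon["class"] = [
        _classify(v, specialist_max, generalist_min) if np.isfinite(v) else "absent"
        for v in b
    ]

    # per-sample community breadth
    bcom = {}
    for j, sample in enumerate(table.sample_ids):
        present = counts[:, j] > 0
        if not present.any():
            bcom[sample] = np.nan
            continue
        if weighted_bcom:
            w = counts[present, j] / counts[present, j].sum()
            bcom[sample] = float((w * b[present]).sum())
        else:
            bcom[sample] = float(b[present].mean())
    bcom = pd.Series(bcom, name="bcom")

    scopes: dict[str, list[str]] = {"global": table.sample_ids}
    if meta is not None:
        for g in meta.group_labels:
            scopes[g] = [s for s in meta.samples_in(g) if s in table.sample_ids]
    sample_index = {s: j for j, s in enumerate(table.sample_ids)}
    ocom: dict[str, dict[str, float]] = {}
    for scope, samples in scopes.items():
        cols = [sample_index[s] for s in samples]
        sub = counts[:, cols]
        present_taxa = np.flatnonzero(sub.sum(axis=1) > 0)
        sch, pia = [], []
        for a_pos in range(len(present_taxa)):
            for b_pos in range(a_pos + 1, len(present_taxa)):
                ia, ib = present_taxa[a_pos], present_taxa[b_pos]
                # pairs must co-occur somewhere within the scope
                if not np.any((sub[ia] > 0) & (sub[ib] > 0)):
                    continue
                sch.append(schoener_overlap(usage[ia], usage[ib]))
                pia.append(pianka_overlap(usage[ia], usage[ib]))
        ocom[scope] = {
            "schoener": float(np.mean(sch)) if sch else np.nan,
            "pianka": float(np.mean(pia)) if pia else np.nan,
            "n_pairs": len(sch),
        }

    return NicheProfile(per_taxon, bcom, ocom, specialist_max, generalist_min)


def compare_bcom_groups(
    profile: NicheProfile, meta: SampleMetadata, reference: str
) -> dict[str, dict[str, float]]:
    """Wilcoxon rank-sum comparison of per-sample Bcom between each group
    and a reference group (delegated to a stock routine)."""
    out = {}
    ref_vals = profile.bcom.loc[
        [s for s in meta.samples_in(reference) if s in profile.bcom.index]
    ].dropna()
    for g in meta.group_labels:
        if g == reference:
            continue
        vals = profile.bcom.loc[
            [s for s in meta.samples_in(g) if s in profile.bcom.index]
        ].dropna()
        if len(vals) == 0 or len(ref_vals) == 0:
            continue
        stat, p = mannwhitneyu(vals, ref_vals, alternative="two-sided")
        out[g] = {"U": float(stat), "p_value": float(p)}
    return out
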