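"""Dissimilarity-overlap curve (DOC) analysis.

For every pair of communities, overlap is the average shared-taxa abundance
fraction and dissimilarity is the root Jensen-Shannon divergence of the two
abundance profiles renormalised over the shared taxa. A negative slope of
the smoothed dissimilarity-overlap relationship at high overlap is the
signature of universal (host-independent) interspecific dynamics. The
negative-slope region, its change point xc, the fraction of pairs beyond it
(Fns), and a one-sided significance are estimated with a sample-level
bootstrap: whole samples are resampled and the pair cloud is rebuilt per
replicate, respecting the dependence among pairs that share a sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .betadiversity import rjsd
from .core_io import CommunityTable

__all__ = ["DOCResult", "doc_points", "doc_fit", "doc_analysis"]

RJSD_MAX = float(np.sqrt(np.log(2.0)))


@dataclass
class DOCResult:
    """Summary of a dissimilarity-overlap curve fit."""

    points: pd.DataFrame  # sample_i, sample_j, overlap, dissimilarity
    grid: np.ndarray
    fitted: np.ndarray  # LOWESS fit to the real point cloud on `grid`
    median_boot_slope: np.ndarray  # median bootstrap slope per grid point
    xc: float | None  # change point: onset of the negative-slope region
    fns: float  # fraction of real points with overlap > xc
    terminal_slope: float  # real-fit slope at the high-overlap end
    p_value: float  # fraction of bootstrap replicates with non-negative terminal slope
    n_boot: int
    span: float
    seed: int
    n_dropped_pairs: int = 0

    def to_dict(self) -> dict:
        return {
            "n_points": len(self.points),
            "n_dropped_pairs": self.n_dropped_pairs,
            "xc": self.xc,
            "fns": self.fns,
            "terminal_slope": self.terminal_slope,
            "p_value": self.p_value,
            "n_boot": self.n_boot,
            "span": self.span,
            "seed": self.seed,
        }


def doc_points(table: CommunityTable) -> tuple[pd.DataFrame, int]:
    """Compute the (overlap, dissimilarity) point for every sample pair.

    For a pair (x, y), the shared set S = {i : x_i > 0 and y_i > 0};
    overlap O = sum_{i in S} (x_i + y_i)/2, and the dissimilarity is the
    rJSD of x and y renormalised over S. Pairs sharing fewer than two taxa
    carry no divergence information and are dropped; the count of dropped
    pairs is returned alongside the points.
    """
    if table.n_samples < 3:
        raise ValueError("DOC requires at least 3 samples")
    if table.mode != "proportions":
        from .core_io import relative_abundance

        table = relative_abundance(table)
    values = table.values
    samples = table.sample_ids
    records = []
    n_dropped = 0
    n = len(samples)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = values[:, i], values[:, j]
            shared = (x > 0) & (y > 0)
            if shared.sum() < 2:
                n_dropped += 1
                continue
            overlap = 0.5 * (x[shared].sum() + y[shared].sum())
            xs = x[shared] / x[shared].sum()
            ys = y[shared] / y[shared].sum()
            records.append((samples[i], samples[j], overlap, rjsd(xs, ys)))
    points = pd.DataFrame(
        records, columns=["sample_i", "sample_j", "overlap", "dissimilarity"]
    )
    return points, n_dropped


def _lowess_on_grid(
    o: np.ndarray, d: np.ndarray, grid: np.ndarray, span: float
) -> np.ndarray:
    """LOWESS fit of d on o evaluated on `grid`; NaN outside the data range."""
    fit = lowess(d, o, frac=span, return_sorted=True)
    out = np.interp(grid, fit[:, 0], fit[:, 1])
    out[(grid < o.min()) | (grid > o.max())] = np.nan
    return out


def _terminal_slope(slopes: np.ndarray) -> float:
    """Slope at the highest-overlap grid point with data."""
    finite = np.flatnonzero(~np.isnan(slopes))
    return float(slopes[finite[-1]]) if len(finite) else np.nan


def doc_fit(
    points: pd.DataFrame,
    n_boot: int = 1000,
    span: float = 0.7,
    seed: int = 0,
    n_grid: int = 50,
    resample: str = "samples",
) -> DOCResult:
    """Fit the DOC and bootstrap its negative-slope region.

    By default the bootstrap resamples SAMPLES with replacement: pairs
    sharing a sample are dependent in community data, so pair-level
    resampling would understate uncertainty there. Each replicate keeps the
    pairs of resampled samples (with multiplicity) and refits the LOWESS
    smoother on an overlap grid. ``resample="pairs"`` switches to a plain
    pair-level bootstrap, which is the calibrated choice when the pair
    values are exchangeable (no shared-sample dependence); on such data the
    sample-level bootstrap is conservative. The change point xc is the
    smallest grid overlap above which the median bootstrap slope is
    negative everywhere; Fns is the fraction of real points with overlap >
    xc; the one-sided p-value is the fraction of replicates whose terminal
    (high-overlap) slope is non-negative.
    """
    if resample not in ("samples", "pairs"):
        raise ValueError(f"unknown resample unit: {resample!r}")
    if len(points) < 10:
        raise ValueError("DOC fit requires at least 10 points")
    o = points["overlap"].to_numpy(dtype=float)
    d = points["dissimilarity"].to_numpy(dtype=float)
    if np.ptp(o) == 0:
        raise ValueError("all overlap values identical; no curve can be fitted")

    grid = np.linspace(o.min(), o.max(), n_grid)
    fitted = _lowess_on_grid(o, d, grid, span)
    real_slope = np.gradient(fitted, grid)

    sample_ids = sorted(set(points["sample_i"]) | set(points["sample_j"]))
    by_pair = {
        (r.sample_i, r.sample_j): (r.overlap, r.dissimilarity)
        for r in points.itertuples()
    }
    rng = np.random.default_rng(seed)
    boot_slopes = np.full((n_boot, n_grid), np.nan)
    terminal = np.full(n_boot, np.nan)
    pair_lookup = {}
    for (si, sj), v in by_pair.items():
        pair_lookup[(si, sj)] = v
        pair_lookup[(sj, si)] = v
    for b in range(n_boot):
        if resample == "pairs":
            idx = rng.integers(0, len(points), size=len(points))
            ob = o[idx]
            db = d[idx]
        else:
            drawn = rng.choice(sample_ids, size=len(sample_ids), replace=True)
            # pairs over resampled positions: duplicated samples contribute
            # their pairs with multiplicity; same-sample position pairs
            # carry no information and are skipped
            sub = []
            for a_pos in range(len(drawn)):
                for b_pos in range(a_pos + 1, len(drawn)):
                    sa, sb = drawn[a_pos], drawn[b_pos]
                    if sa == sb:
                        continue
                    v = pair_lookup.get((sa, sb))
                    if v is not None:
                        sub.append(v)
            if len(sub) < 10:
                continue
            ob = np.array([p[0] for p in sub])
            db = np.array([p[1] for p in sub])
        if np.ptp(ob) == 0:
            continue
        fit_b = _lowess_on_grid(ob, db, grid, span)
        boot_slopes[b] = np.gradient(fit_b, grid)
        terminal[b] = _terminal_slope(boot_slopes[b])

    valid = ~np.isnan(terminal)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no bootstrap replicate produced a fit")
    p_value = float((terminal[valid] >= 0).sum() / n_valid)

    with np.errstate(invalid="ignore"):
        med = np.nanmedian(boot_slopes, axis=0)
    # maximal suffix of the grid where the median bootstrap slope is negative
    neg = med < 0
    xc: float | None = None
    if neg[-1]:
        start = n_grid - 1
        while start > 0 and neg[start - 1]:
            start -= 1
        xc = float(grid[start])
    fns = float((o > xc).mean()) if xc is not None else 0.0

    return DOCResult(
        points=points,
        grid=grid,
        fitted=fitted,
        median_boot_slope=med,
        xc=xc,
        fns=fns,
        terminal_slope=_terminal_slope(real_slope),
        p_value=p_value,
        n_boot=n_boot,
        span=span,
        seed=seed,
    )


def doc_analysis(
    table: CommunityTable,
    n_boot: int = 1000,
    span: float = 0.7,
    seed: int = 0,
) -> DOCResult:
    """End-to-end DOC: compute pair points from a table, then fit."""
    points, n_dropped = doc_points(table)
    result = doc_fit(points, n_boot=n_boot, span=span, seed=seed)
    result.n_dropped_pairs = n_dropped
    return result
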