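"""Retention-time validation of spectral clusters: CV and the FCR.

Replicate acquisitions of one peptide elute within a narrow LC window, so
a correct cluster has a small coefficient of variation (CV, in percent) of
its members' retention times.  The false clustering rate (FCR) compares
how often clusters that tight arise by chance: retention times of all
multi-member clusters are permuted while keeping cluster sizes fixed, and

    FCR = (1/P) * sum_p  #{i : CV_p(i) <= delta} / #{i : CV(i) <= delta}

over P permutations.  Scanning delta (the CV cutoff) and rho (the
correlation cutoff used for clustering) against a target FCR is how the
pipeline's thresholds are chosen.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import clustering as _clustering
from .signal import GridConfig, bin_spectrum, moving_average

logger = logging.getLogger(__name__)

__all__ = [
    "FcrScan",
    "cluster_cv",
    "compute_fcr",
    "scan_delta",
    "scan_rho",
    "choose_threshold",
    "choose_delta",
    "choose_rho",
]


@dataclass
class FcrScan:
    """Observed CVs and FCR values over a grid of thresholds."""

    grid: np.ndarray                  # the scanned thresholds (delta or rho)
    fcr: np.ndarray                   # FCR per grid value (NaN where undefined)
    cv_observed: np.ndarray           # per-eligible-cluster CVs (percent)
    n_eligible: int                   # clusters with >= 2 members
    n_permutations: int
    seed: int | None
    scanned: str = "delta"            # which threshold the grid refers to

    def as_mapping(self) -> dict[float, float]:
        return {float(g): float(f) for g, f in zip(self.grid, self.fcr)}


def cluster_cv(rt_values: np.ndarray) -> float:
    """Coefficient of variation of member retention times, in percent.

    100 * sample standard deviation (n-1 denominator) / mean.  Requires at
    least two values and a positive mean; singleton clusters are handled
    upstream as ineligible rather than through this function.
    """
    rt = np.asarray(rt_values, dtype=float)
    if rt.size < 2:
        raise ValueError("CV requires at least two retention times")
    mean = rt.mean()
    if mean <= 0:
        raise ValueError("retention-time mean must be positive")
    return float(100.0 * rt.std(ddof=1) / mean)


def _eligible_rts(clusters) -> list[np.ndarray]:
    """Per-cluster RT arrays for clusters of size >= 2.

    Accepts SpectralCluster objects or bare RT sequences.
    """
    out = []
    for c in clusters:
        rt = np.asarray(getattr(c, "rt_values", c), dtype=float)
        if rt.size >= 2:
            out.append(rt)
    return out


def _cvs(parts: list[np.ndarray]) -> np.ndarray:
    return np.array([cluster_cv(p) for p in parts])


def compute_fcr(
    clusters,
    delta: float,
    n_permutations: int = 100,
    seed: int | None = None,
    exhaustive: bool = False,
) -> float:
    """Permutation FCR at a single CV threshold delta.

    Retention times of all eligible (size >= 2) clusters are pooled,
    shuffled globally and dealt back into the same cluster-size template;
    singleton members' RTs never enter.  With ``exhaustive=True`` every
    permutation of the pooled RTs is enumerated instead of sampling (only
    sensible for tiny inputs).  Returns NaN when no observed cluster has
    CV <= delta.  The ratio may exceed 1; it is reported unclamped.
    """
    parts = _eligible_rts(clusters)
    if not parts:
        return float("nan")
    observed = _cvs(parts)
    denom = int(np.sum(observed <= delta))
    if denom == 0:
        logger.warning("FCR undefined at delta=%g: no observed cluster passes", delta)
        return float("nan")
    sizes = [p.size for p in parts]
    pool = np.concatenate(parts)
    bounds = np.cumsum(sizes)[:-1]

    def count_passing(perm: np.ndarray) -> int:
        return int(np.sum(_cvs(np.split(perm, bounds)) <= delta))

    if exhaustive:
        ratios = [
            count_passing(np.array(perm)) / denom
            for perm in itertools.permutations(pool)
        ]
        return float(np.mean(ratios))
    rng = np.random.default_rng(seed)
    ratios = [
        count_passing(rng.permutation(pool)) / denom for _ in range(n_permutations)
    ]
    fcr = float(np.mean(ratios))
    if fcr > 1.0:
        logger.warning("FCR %.3f exceeds 1 (reported unclamped)", fcr)
    return fcr


def choose_threshold(grid: np.ndarray, fcr: np.ndarray, target: float = 0.05) -> float:
    """Grid value whose FCR is closest to the target from below.

    Ties go to the smaller threshold; if no grid value is at or below the
    target, the value with FCR closest to the target overall is returned.
    """
    grid = np.asarray(grid, dtype=float)
    fcr = np.asarray(fcr, dtype=float)
    ok = ~np.isnan(fcr)
    if not ok.any():
        raise ValueError("FCR undefined over the whole grid")
    grid, fcr = grid[ok], fcr[ok]
    below = fcr <= target
    if below.any():
        cand = np.flatnonzero(below)
        best = cand[np.lexsort((grid[cand], -(fcr[cand])))][0]
    else:
        best = np.lexsort((grid, np.abs(fcr - target)))[0]
    return float(grid[best])


def choose_delta(scan: "FcrScan", target: float = 0.05) -> float:
    """CV cutoff from a delta scan whose FCR best approaches the target."""
    return choose_threshold(scan.grid, scan.fcr, target)


def choose_rho(scan: "FcrScan", target: float = 0.05) -> float:
    """Correlation cutoff from a rho scan whose FCR best approaches the target."""
    return choose_threshold(scan.grid, scan.fcr, target)


def scan_delta(
    clusters,
    delta_grid: np.ndarray,
    n_permutations: int = 100,
    seed: int | None = None,
) -> FcrScan:
    """FCR over a grid of CV thresholds (one shared permutation stream).

    The same P permutations are reused across the grid so that the scan is
    internally consistent (and monotone behavior is not masked by
    resampling noise).
    """
    delta_grid = np.asarray(delta_grid, dtype=float)
    parts = _eligible_rts(clusters)
    if not parts:
        return FcrScan(delta_grid, np.full(delta_grid.size, np.nan),
                       np.array([]), 0, n_permutations, seed, "delta")
    observed = _cvs(parts)
    sizes = [p.size for p in parts]
    pool = np.concatenate(parts)
    bounds = np.cumsum(sizes)[:-1]
    rng = np.random.default_rng(seed)
    permuted_cvs = np.stack(
        [_cvs(np.split(rng.permutation(pool), bounds)) for _ in range(n_permutations)]
    )
    fcr = np.empty(delta_grid.size)
    for k, delta in enumerate(delta_grid):
        denom = int(np.sum(observed <= delta))
        if denom == 0:
            fcr[k] = np.nan
        else:
            fcr[k] = float(np.mean(np.sum(permuted_cvs <= delta, axis=1) / denom))
    return FcrScan(delta_grid, fcr, observed, len(parts), n_permutations, seed, "delta")


def scan_rho(
    spectra,
    rho_grid: np.ndarray,
    delta: float = 4.4,
    n_permutations: int = 100,
    seed: int | None = None,
    grid: GridConfig | None = None,
    precursor_tol: float = 1.0,
) -> FcrScan:
    """FCR at a fixed delta while the correlation cutoff rho varies.

    The spectra are reclustered at every rho in the grid; profiles,
    precursor groups and each group's single-linkage tree are computed
    once and only the cut height changes, so the scan is cheap.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    rho_grid = np.asarray(rho_grid, dtype=float)
    gcfg = grid or GridConfig()
    binned = [bin_spectrum(s, gcfg) for s in spectra]
    profiles = {i: moving_average(b) for i, b in enumerate(binned)}
    groups = _clustering.group_by_precursor(spectra, precursor_tol)

    import itertools as _it

    trees = []
    for g in groups:
        if len(g.indices) == 1:
            trees.append((g.indices, None))
            continue
        m = len(g.indices)
        condensed = np.empty(m * (m - 1) // 2)
        for pos, (a, b) in enumerate(_it.combinations(range(m), 2)):
            condensed[pos] = 1.0 - _clustering.correlation_index(
                profiles[g.indices[a]], profiles[g.indices[b]]
            )
        np.clip(condensed, 0.0, None, out=condensed)
        trees.append((g.indices, linkage(condensed, method="single")))

    rts = np.array([s.retention_time for s in spectra])
    fcr = np.empty(rho_grid.size)
    for k, rho in enumerate(rho_grid):
        rt_sets = []
        for indices, tree in trees:
            if tree is None:
                rt_sets.append(rts[indices])
                continue
            labels = fcluster(tree, t=1.0 - rho, criterion="distance")
            for lab in np.unique(labels):
                rt_sets.append(rts[np.asarray(indices)[labels == lab]])
        fcr[k] = compute_fcr(rt_sets, delta, n_permutations, seed)
    cv_obs = np.array([])  # per-rho observed CVs differ; not stored in the scan
    return FcrScan(rho_grid, fcr, cv_obs, -1, n_permutations, seed, "rho")
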