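"""Two-stage clustering of MS/MS spectra into per-peptide spectral sets.

Stage one groups spectra by precursor m/z so that every pair inside a
group differs by at most the precursor tolerance (a diameter constraint,
enforced by complete-linkage agglomeration).  Stage two runs single-linkage
hierarchical clustering inside each group with distance 1 - r, where r is
the correlation index of the MWA profiles, cut at 1 - rho.  Each resulting
cluster gets a reference spectrum (bin-wise mean of the members'
standardized spectra), a Q score (mean member-to-reference MWA
correlation), and per-replicate spectral counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dep import CountTable
from .signal import (
    BinnedSpectrum,
    GridConfig,
    MwaProfile,
    bin_spectrum,
    correlation_index,
    moving_average,
)
from .spectra_io import RawSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "PrecursorGroup",
    "SpectralCluster",
    "group_by_precursor",
    "cluster_within_group",
    "build_reference",
    "q_score",
    "cluster_spectra",
    "count_spectra",
]


@dataclass
class PrecursorGroup:
    """Spectrum indices whose pairwise precursor m/z differences are <= tol."""

    indices: list[int]
    precursor_mz: np.ndarray

    @property
    def diameter(self) -> float:
        return float(self.precursor_mz.max() - self.precursor_mz.min())


@dataclass
class SpectralCluster:
    """A set of spectra inferred to come from one peptide."""

    cluster_id: str
    members: list[RawSpectrum]
    member_indices: list[int]
    reference: BinnedSpectrum
    q_score: float
    counts: dict[tuple[str, str], int]
    rt_values: np.ndarray

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def samples(self) -> set[str]:
        return {m.sample for m in self.members}

    @property
    def occupancy(self) -> str:
        """"shared" when members span more than one sample group, else "<sample>-only"."""
        s = self.samples
        return "shared" if len(s) > 1 else f"{next(iter(s))}-only"

    @property
    def mean_precursor_mz(self) -> float:
        return float(np.mean([m.precursor_mz for m in self.members]))


def group_by_precursor(
    spectra: list[RawSpectrum], precursor_tol: float = 1.0
) -> list[PrecursorGroup]:
    """Complete-linkage agglomeration on precursor m/z, cut at the tolerance.

    The cut guarantees the stated pairwise bound: every two members of a
    group differ by at most ``precursor_tol`` Da.  In one dimension
    complete-linkage clusters are contiguous intervals of the sorted
    precursor values, so only adjacent intervals are merge candidates.
    Tie-break: among merges at equal distance, the pair containing the
    lowest original spectrum index merges first.
    """
    n = len(spectra)
    if n == 0:
        return []
    values = np.array([s.precursor_mz for s in spectra], dtype=float)
    order = np.lexsort((np.arange(n), values))
    # intervals of sorted positions; each holds original indices
    intervals: list[list[int]] = [[int(i)] for i in order]
    while len(intervals) > 1:
        spans = []
        for a, b in zip(intervals[:-1], intervals[1:]):
            merged = a + b
            span = values[merged].max() - values[merged].min()
            spans.append((span, min(merged)))
        # distances within 1e-9 Da count as tied so the lowest-index rule
        # is not defeated by float representation of the m/z values
        min_span = min(s for s, _ in spans)
        if min_span > precursor_tol:
            break
        best = min(
            (i for i, (s, _) in enumerate(spans) if s <= min_span + 1e-9),
            key=lambda i: spans[i][1],
        )
        intervals[best] = intervals[best] + intervals.pop(best + 1)
    return [
        PrecursorGroup(indices=sorted(iv), precursor_mz=values[sorted(iv)])
        for iv in intervals
    ]


def cluster_within_group(
    group: PrecursorGroup,
    profiles: dict[int, MwaProfile],
    rho: float = 0.6,
) -> list[list[int]]:
    """Single-linkage clustering on d = 1 - r inside a precursor group.

    Cut at height 1 - rho, which equals the connected components of the
    graph with edges wherever r >= rho.  Returns lists of spectrum indices.
    """
    idx = group.indices
    if len(idx) == 1:
        return [list(idx)]
    m = len(idx)
    condensed = np.empty(m * (m - 1) // 2)
    for pos, (a, b) in enumerate(itertools.combinations(range(m), 2)):
        condensed[pos] = 1.0 - correlation_index(profiles[idx[a]], profiles[idx[b]])
    np.clip(condensed, 0.0, None, out=condensed)  # r may exceed 1 by an ulp
    labels = fcluster(linkage(condensed, method="single"), t=1.0 - rho,
                      criterion="distance")
    out: dict[int, list[int]] = {}
    for local, lab in enumerate(labels):
        out.setdefault(int(lab), []).append(idx[local])
    return [sorted(v) for v in sorted(out.values(), key=min)]


def build_reference(member_binned: list[BinnedSpectrum]) -> BinnedSpectrum:
    """Bin-wise arithmetic mean of the members' standardized spectra."""
    if not member_binned:
        raise ValueError("cannot build a reference spectrum for an empty cluster")
    grid = member_binned[0].grid
    stack = np.stack([b.values for b in member_binned])
    return BinnedSpectrum(stack.mean(axis=0), grid)


def q_score(reference: BinnedSpectrum, member_profiles: list[MwaProfile]) -> float:
    """Mean correlation index between the reference's MWA and each member's.

    High values mean the reference spectrum represents the cluster well; a
    singleton cluster scores 1 because the reference equals its only member.
    """
    ref_profile = moving_average(reference)
    return float(
        np.mean([correlation_index(ref_profile, p) for p in member_profiles])
    )


def cluster_spectra(
    spectra: list[RawSpectrum],
    grid: GridConfig | None = None,
    rho: float = 0.6,
    precursor_tol: float = 1.0,
    split_by_charge: bool = False,
) -> list[SpectralCluster]:
    """Run the full two-stage clustering and assemble spectral sets.

    Spectra from all samples and replicates are clustered jointly and only
    counted per replicate afterwards, so one peptide observed in both
    groups yields a single shared cluster.
    """
    grid = grid or GridConfig()
    binned = [bin_spectrum(s, grid) for s in spectra]
    profiles = {i: moving_average(b) for i, b in enumerate(binned)}

    if split_by_charge:
        partitions: dict[object, list[int]] = {}
        for i, s in enumerate(spectra):
            partitions.setdefault(s.precursor_charge, []).append(i)
    else:
        partitions = {None: list(range(len(spectra)))}

    clusters: list[SpectralCluster] = []
    serial = 0
    for part in partitions.values():
        sub = [spectra[i] for i in part]
        groups = group_by_precursor(sub, precursor_tol)
        for g in groups:
            g.indices = [part[i] for i in g.indices]  # back to global indices
        for g in groups:
            for member_idx in cluster_within_group(g, profiles, rho):
                serial += 1
                members = [spectra[i] for i in member_idx]
                ref = build_reference([binned[i] for i in member_idx])
                q = q_score(ref, [profiles[i] for i in member_idx])
                counts: dict[tuple[str, str], int] = {}
                for m in members:
                    counts[m.replicate_key] = counts.get(m.replicate_key, 0) + 1
                clusters.append(
                    SpectralCluster(
                        cluster_id=f"S{serial}",
                        members=members,
                        member_indices=list(member_idx),
                        reference=ref,
                        q_score=q,
                        counts=counts,
                        rt_values=np.array([m.retention_time for m in members]),
                    )
                )
    total = sum(c.size for c in clusters)
    if total != len(spectra):
        raise AssertionError("clustering lost or duplicated spectra")
    logger.info("clustered %d spectra into %d spectral sets", total, len(clusters))
    return clusters


def count_spectra(clusters: list[SpectralCluster]) -> CountTable:
    """Spectral-count matrix x (clusters x replicates) with totals n.

    Totals are per-replicate column sums over *all* clusters, computed
    before any filtering, and each cluster is labeled shared or
    group-exclusive.
    """
    keys = sorted({k for c in clusters for k in c.counts})
    x = np.zeros((len(clusters), len(keys)), dtype=int)
    for row, c in enumerate(clusters):
        for col, k in enumerate(keys):
            x[row, col] = c.counts.get(k, 0)
    return CountTable(
        x=x,
        n=x.sum(axis=0),
        replicate_keys=keys,
        groups=[k[0] for k in keys],
        cluster_ids=[c.cluster_id for c in clusters],
        occupancy=[c.occupancy for c in clusters],
    )
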