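"""Spectrum preprocessing and the pairwise similarity of MS/MS spectra.

A raw peak list is mapped onto a fixed m/z grid, scale-standardized by its
maximum intensity, smoothed with a moving-window average (MWA), and compared
to other spectra through the Pearson correlation of the MWA profiles.  The
MWA step makes the similarity robust to small m/z calibration shifts between
acquisitions of the same peptide, which is what allows spectra to be
clustered without any database search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateSpectrumError",
    "GridConfig",
    "BinnedSpectrum",
    "MwaProfile",
    "scale_standardize",
    "bin_spectrum",
    "moving_average",
    "correlation_index",
]


class DegenerateSpectrumError(ValueError):
    """Raised for spectra with no usable intensity on the analysis grid."""


@dataclass(frozen=True)
class GridConfig:
    """Fixed m/z grid and smoothing kernel shared by all compared spectra.

    Parameters
    ----------
    mz_min, mz_max : float
        Half-open analysis range ``[mz_min, mz_max)`` in Da.  Peaks outside
        the range are dropped before binning.
    bin_width : float
        Grid resolution in Da.
    window_k : int
        Moving-window size ``K`` in bins.  The default 30 bins (3.0 Da at
        0.1 Da resolution) trades shift tolerance against peak resolution.
    kernel : {"gaussian", "uniform"}
        Window weight shape.  Both kernels are normalized to sum to one.
    """

    mz_min: float = 200.0
    mz_max: float = 2000.0
    bin_width: float = 0.1
    window_k: int = 30
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if not self.mz_max > self.mz_min:
            raise ValueError("mz_max must exceed mz_min")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        if self.window_k < 1:
            raise ValueError("window_k must be >= 1")
        if self.kernel not in ("uniform", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.window_k > self.n_bins:
            raise ValueError("window_k exceeds the number of grid bins")

    @property
    def n_bins(self) -> int:
        return int(np.ceil(round((self.mz_max - self.mz_min) / self.bin_width, 9)))

    @property
    def n_windows(self) -> int:
        """Number of MWA windows N = bins - K + 1 (always derived)."""
        return self.n_bins - self.window_k + 1

    def bin_centers(self) -> np.ndarray:
        return self.mz_min + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def kernel_weights(self) -> np.ndarray:
        """Window weights w_j, j = 0..K-1, normalized to sum to 1.

        The grid is uniform, so the gaussian weights — the standard normal
        pdf at the z-scores of the within-window bin-center m/z values —
        are the same for every window position.
        """
        k = self.window_k
        if k == 1:
            return np.array([1.0])
        if self.kernel == "uniform":
            return np.full(k, 1.0 / k)
        centers = self.mz_min + (np.arange(k) + 0.5) * self.bin_width
        z = (centers - centers.mean()) / centers.std(ddof=1)
        w = norm.pdf(z)
        return w / w.sum()


@dataclass
class BinnedSpectrum:
    """Scale-standardized intensities y[i] on the grid; values in [0, 1]."""

    values: np.ndarray
    grid: GridConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError("binned vector length does not match the grid")


@dataclass
class MwaProfile:
    """Moving-window-average vector m[i], i = 1..N with N = bins - K + 1."""

    values: np.ndarray
    grid: GridConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_windows,):
            raise ValueError("profile length does not match the grid")


def scale_standardize(intensities: np.ndarray) -> np.ndarray:
    """Divide intensities by their maximum: y[i] = x[i] / max(x).

    Removes global scale differences caused by varying total ion current,
    so spectra are compared by relative peak pattern only.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise DegenerateSpectrumError("empty intensity vector")
    if np.any(x < 0):
        raise ValueError("negative intensities are not valid ion counts")
    m = x.max()
    if m <= 0:
        raise DegenerateSpectrumError("all intensities are zero")
    return x / m


def bin_spectrum(spectrum, grid: GridConfig) -> BinnedSpectrum:
    """Assign peaks to half-open grid bins, sum within bins, standardize.

    `spectrum` is any object with ``mz`` and ``intensity`` arrays (a
    :class:`qfish.spectra_io.RawSpectrum`).  Peaks outside
    ``[mz_min, mz_max)`` are dropped (counted in the debug log); a spectrum
    with no in-range intensity raises :class:`DegenerateSpectrumError`.
    """
    mz = np.asarray(spectrum.mz, dtype=float)
    inten = np.asarray(spectrum.intensity, dtype=float)
    in_range = (mz >= grid.mz_min) & (mz < grid.mz_max)
    n_dropped = int(np.size(mz) - in_range.sum())
    if n_dropped:
        logger.debug(
            "%s: %d peak(s) outside [%g, %g) dropped",
            getattr(spectrum, "spectrum_id", "<spectrum>"),
            n_dropped, grid.mz_min, grid.mz_max,
        )
    mz, inten = mz[in_range], inten[in_range]
    bins = np.floor((mz - grid.mz_min) / grid.bin_width).astype(int)
    # guard against float round-up at the top edge
    bins = np.clip(bins, 0, grid.n_bins - 1)
    values = np.zeros(grid.n_bins)
    np.add.at(values, bins, inten)
    return BinnedSpectrum(scale_standardize(values), grid)


def moving_average(binned: BinnedSpectrum) -> MwaProfile:
    """m[i] = sum_j w_j y[i+j] for every window position (stride one bin)."""
    w = binned.grid.kernel_weights()
    values = np.correlate(binned.values, w, mode="valid")
    return MwaProfile(values, binned.grid)


def correlation_index(p: MwaProfile, q: MwaProfile) -> float:
    """Pearson correlation of two MWA profiles on the same grid.

    A zero-variance (near-empty) profile makes the correlation undefined;
    such pairs are treated as dissimilar (r = 0) with a warning so that
    clustering stays total.
    """
    if p.grid != q.grid:
        raise ValueError("profiles computed on different grids are not comparable")
    a = p.values - p.values.mean()
    b = q.values - q.values.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    # norms at rounding-noise level mean a constant (near-empty) profile
    tol = 1e-9 * np.sqrt(p.values.size)
    if na <= tol * max(1.0, np.abs(p.values).max()) or \
       nb <= tol * max(1.0, np.abs(q.values).max()):
        logger.warning("zero-variance MWA profile: correlation set to 0")
        return 0.0
    return float((a @ b) / (na * nb))
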