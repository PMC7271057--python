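"""Kernel density estimation of intensity distributions and the
Bhattacharyya overlap coefficient.

The segmentation energy compares the intensity distribution of a candidate
region against a model distribution estimated from the complement domain.
Distributions live on a shared discrete binning of the image intensity
range; a Gaussian kernel gives a smoothed KDE, a Dirac kernel the plain
normalized histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "KernelSpec",
    "Binning",
    "IntensityDistribution",
    "make_bins",
    "gaussian_kernel",
    "kde_estimate",
    "bhattacharyya",
    "BinningError",
]

_NORM_TOL = 1e-9


class BinningError(ValueError):
    """Raised when two distributions do not share a binning."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel used for density estimation.

    ``kind`` is ``"gaussian"`` (bandwidth ``sigma`` in intensity units) or
    ``"dirac"`` (histogram counting).  ``sigma=None`` on a Gaussian kernel
    means "auto": twice the bin width of whatever binning it is used with.
    """

    kind: str = "gaussian"
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "dirac"):
            raise ValueError("kernel kind must be 'gaussian' or 'dirac'")
        if self.kind == "gaussian" and self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0 for a gaussian kernel")

    def resolve_sigma(self, bin_width: float) -> float:
        if self.kind != "gaussian":
            raise ValueError("sigma only defined for gaussian kernels")
        return 2.0 * bin_width if self.sigma is None else self.sigma


@dataclass(frozen=True)
class Binning:
    """Equal-width intensity bins: ``edges`` (n+1,) and ``centers`` (n,)."""

    edges: np.ndarray
    centers: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    @property
    def width(self) -> float:
        if len(self.centers) == 1:
            return float(self.edges[1] - self.edges[0])
        return float(self.centers[1] - self.centers[0])

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index of each value (clipped into range; right edge inclusive)."""
        idx = np.searchsorted(self.edges, values, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def make_bins(values: np.ndarray, n_bins: int = 256) -> Binning:
    """Equal-width binning spanning [min, max] of ``values``.

    A constant-valued input degenerates to a single bin centered on that
    value (unit nominal width), so downstream KDEs become a point mass.
    """
    v = np.asarray(values, dtype=float)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        edges = np.array([vmin - 0.5, vmin + 0.5])
        return Binning(edges=edges, centers=np.array([vmin]))
    edges = np.linspace(vmin, vmax, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Binning(edges=edges, centers=centers)


@dataclass(frozen=True)
class IntensityDistribution:
    """A normalized probability vector over intensity bin centers."""

    bin_centers: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.bin_centers, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if c.shape != p.shape or c.ndim != 1:
            raise ValueError("bin_centers and probabilities must be equal-length 1-D")
        if len(c) > 1 and not np.all(np.diff(c) > 0):
            raise ValueError("bin_centers must be strictly increasing")
        if p.min() < 0:
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"probabilities sum to {p.sum()}, expected 1")
        object.__setattr__(self, "bin_centers", c)
        object.__setattr__(self, "probabilities", p)

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.bin_centers, self.probabilities]),
            delimiter=",",
            header="bin_center,probability",
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "IntensityDistribution":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(bin_centers=arr[:, 0], probabilities=arr[:, 1])


def gaussian_kernel(x, y, sigma: float):
    """Gaussian kernel (1/√(2πσ²))·exp(−(x−y)²/(2σ²)); symmetric in x, y."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.exp(-((x - y) ** 2) / (2.0 * sigma**2)) / np.sqrt(2.0 * np.pi * sigma**2)
    return out if out.ndim else float(out)


def kernel_matrix(values: np.ndarray, kernel: KernelSpec, bins: Binning) -> np.ndarray:
    """Per-pixel kernel contributions: (n_bins, n_pixels) matrix.

    Column x holds K_z(I_x) over the bin centers z (Dirac: a one-hot
    column).  KDEs are column averages of this matrix; the segmentation
    energy reuses it for incremental updates.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty pixel set")
    if kernel.kind == "dirac":
        k = np.zeros((bins.n_bins, v.size))
        k[bins.assign(v), np.arange(v.size)] = 1.0
        return k
    sigma = kernel.resolve_sigma(bins.width)
    return gaussian_kernel(bins.centers[:, None], v[None, :], sigma)


def kde_estimate(
    values: np.ndarray, kernel: KernelSpec, bins: Binning
) -> IntensityDistribution:
    """Kernel density estimate of a pixel set on the given binning.

    Raw per-bin value is Σ_i K_z(I_i)/A; the discrete vector is then
    renormalized to sum exactly 1 so the Bhattacharyya coefficient keeps
    its [0, 1] semantics on the grid.  A Dirac kernel yields the normalized
    histogram.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty pixel set: cannot estimate a density")
    if kernel.kind == "dirac":
        raw = np.bincount(bins.assign(v), minlength=bins.n_bins).astype(float)
    else:
        raw = kernel_matrix(v, kernel, bins).sum(axis=1)
    total = raw.sum()
    if total <= 0:
        raise ValueError("kernel mass vanished on the binning grid")
    return IntensityDistribution(bin_centers=bins.centers, probabilities=raw / total)


def bhattacharyya(f: IntensityDistribution, g: IntensityDistribution) -> float:
    """Bhattacharyya coefficient Σ_z √(f(z)·g(z)) ∈ [0, 1].

    1 iff the distributions coincide bin-wise, 0 iff their supports are
    disjoint.  Requires a shared binning.
    """
    if f.bin_centers.shape != g.bin_centers.shape or not np.allclose(
        f.bin_centers, g.bin_centers
    ):
        raise BinningError("distributions are defined on different binnings")
    b = float(np.sqrt(f.probabilities * g.probabilities).sum())
    return min(max(b, 0.0), 1.0)
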