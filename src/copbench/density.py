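"""Group-wise CoP spatial-occupancy maps via 2-D Gaussian KDE.

All TUG CoP samples of one (group, foot) stratum are pooled and turned
into a continuous occupancy surface on a fixed lattice over the
normalized coordinate ranges.  A comparison set of maps (both groups x
both feet) shares one bandwidth — Scott's rule evaluated once on a
reference stratum and then frozen — and one grid, so panels are
directly comparable.

The kernel is axis-aligned Gaussian and the surface is evaluated
exactly (no binning): with diagonal bandwidth the kernel sum factorizes
into a product of one-dimensional kernel matrices, so the full grid is
a single matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .sensor_io import AP_BOUNDS, ML_BOUNDS, SimulatedTrial

__all__ = [
    "DensityMap",
    "default_grid",
    "scott_bandwidth",
    "pool_cop_samples",
    "compute_kde",
    "comparison_maps",
]


def default_grid(n: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """The standard n x n evaluation lattice over the normalized ranges."""
    return (
        np.linspace(ML_BOUNDS[0], ML_BOUNDS[1], n),
        np.linspace(AP_BOUNDS[0], AP_BOUNDS[1], n),
    )


@dataclass
class DensityMap:
    """A KDE occupancy surface for one (group, foot) stratum."""

    grid_ml: np.ndarray
    grid_ap: np.ndarray
    density: np.ndarray          # shape (len(grid_ml), len(grid_ap))
    bandwidth: tuple[float, float]
    source: tuple[str, str]      # (group, foot)

    def __post_init__(self) -> None:
        if self.density.shape != (self.grid_ml.size, self.grid_ap.size):
            raise ValueError("density shape must match the grid")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def integral(self) -> float:
        """Numerical integral over the grid (≈ 1 up to edge truncation)."""
        inner = np.trapezoid(self.density, self.grid_ap, axis=1)
        return float(np.trapezoid(inner, self.grid_ml))

    def mode(self) -> tuple[float, float]:
        """Grid location of the density maximum."""
        i, j = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return float(self.grid_ml[i]), float(self.grid_ap[j])

    def save_csv(self, path) -> None:
        """Export the surface as a CSV grid (rows: ML, columns: AP)."""
        import pandas as pd

        frame = pd.DataFrame(self.density, index=self.grid_ml, columns=self.grid_ap)
        frame.index.name = "ml\\ap"
        frame.to_csv(path)


def scott_bandwidth(points: np.ndarray) -> tuple[float, float]:
    """Scott's rule per axis for a 2-D sample: ``n**(-1/6) * std_j``."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("bandwidth estimation needs at least 2 points")
    stds = points.std(axis=0, ddof=1)
    if np.any(stds <= 0):
        raise ValueError("degenerate point cloud: zero variance along an axis")
    factor = n ** (-1.0 / 6.0)
    return float(factor * stds[0]), float(factor * stds[1])


def pool_cop_samples(
    trials: Iterable[SimulatedTrial], group: str, foot: str
) -> np.ndarray:
    """Concatenate all (ml, ap) CoP samples of one group/foot stratum."""
    clouds = [t.foot(foot).xy() for t in trials if t.group_label == group]
    if not clouds:
        raise ValueError(f"no trials in stratum (group={group!r}, foot={foot!r})")
    return np.vstack(clouds)


def compute_kde(
    points: np.ndarray,
    bandwidth: tuple[float, float],
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    source: tuple[str, str] = ("", ""),
) -> DensityMap:
    """Exact Gaussian-kernel density of a point cloud on the grid."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if np.unique(points, axis=0).shape[0] < 2:
        raise ValueError("KDE requires at least 2 distinct points")
    h_ml, h_ap = bandwidth
    if h_ml <= 0 or h_ap <= 0:
        raise ValueError("bandwidths must be positive")
    grid_ml, grid_ap = grid if grid is not None else default_grid()

    def kernel_matrix(grid_axis: np.ndarray, samples: np.ndarray, h: float) -> np.ndarray:
        z = (grid_axis[:, None] - samples[None, :]) / h
        return np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * h)

    a = kernel_matrix(grid_ml, points[:, 0], h_ml)
    b = kernel_matrix(grid_ap, points[:, 1], h_ap)
    density = a @ b.T / points.shape[0]
    return DensityMap(grid_ml, grid_ap, density, (float(h_ml), float(h_ap)), source)


def comparison_maps(
    trials: Iterable[SimulatedTrial],
    reference: tuple[str, str] = ("Control", "left"),
    grid: tuple[np.ndarray, np.ndarray] | None = None,
) -> Mapping[tuple[str, str], DensityMap]:
    """The four-panel comparison set (group x foot) with one shared
    bandwidth (Scott's rule on the reference stratum) and one grid."""
    trials = list(trials)
    bandwidth = scott_bandwidth(pool_cop_samples(trials, *reference))
    grid = grid if grid is not None else default_grid()
    maps = {}
    for group in ("Control", "PD"):
        for foot in ("left", "right"):
            points = pool_cop_samples(trials, group, foot)
            maps[(group, foot)] = compute_kde(points, bandwidth, grid, (group, foot))
    return maps
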