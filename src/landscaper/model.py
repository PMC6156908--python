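"""Model/results interface to landscape reconstruction.

:class:`EnergyLandscape` is the model: a set of energy-evaluated samples in
PC1-PC2 projection space plus a :class:`~landscaper.config.RunConfig`.
Fitting computes the alpha-convex domain boundary, lays the regular grid over
it and estimates a smooth energy surface on the grid by kernel regression.
The result is a :class:`LandscapeFit`, which can be queried for value,
gradient and Hessian anywhere in the domain and from which the two
reconstruction algorithms (basin-driven and saddle-driven) are launched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .boundary import (BoundaryPolygon, Grid, alpha_shape_geometry, build_grid,
                       geometry_to_polygons)
from .config import SMOOTH_KERNELS, RunConfig
from .hierarchy import Hierarchy
from .samples import SampleSet
from .surface import KernelSurface, estimate_energies

log = logging.getLogger(__name__)


class EnergyLandscape:
    """Kernel-regression model of a 2D-projected energy landscape."""

    def __init__(self, samples: SampleSet, config: RunConfig | None = None):
        self.samples = samples
        self.config = config or RunConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, pc1="pc1", pc2="pc2",
                       energy="energy", variant_label: str = "",
                       config: RunConfig | None = None) -> "EnergyLandscape":
        pts = df[[pc1, pc2]].to_numpy(float)
        return cls(SampleSet(pts, df[energy].to_numpy(float), variant_label), config)

    def fit(self) -> "LandscapeFit":
        """Compute boundary, grid and grid energies; return the fit results."""
        cfg = self.config
        geom = alpha_shape_geometry(self.samples.points, cfg.alpha)
        grid = build_grid(geom, cfg.delta1)
        surface, grid, energies, n_dropped = estimate_energies(
            grid, self.samples, cfg.kernel, cfg.h
        )
        return LandscapeFit(self, geom, grid, energies, surface, n_dropped)


class LandscapeFit:
    """Results of fitting an :class:`EnergyLandscape`.

    Carries the domain geometry, the grid ``S_max`` with estimated energies
    (``c_min``/``c_max`` their extremes), and the continuous estimator used
    for off-grid evaluation. Off-grid queries evaluate the kernel-regression
    estimator directly (one consistent C^2 surface; no grid interpolation).
    """

    def __init__(self, model: EnergyLandscape, geom, grid: Grid,
                 grid_energies: np.ndarray, surface: KernelSurface,
                 n_dropped_grid_points: int = 0):
        self.model = model
        self.config = model.config
        self.domain = geom
        shapely.prepare(self.domain)
        self.boundary_polygons: list[BoundaryPolygon] = geometry_to_polygons(geom)
        self.grid = grid
        self.grid_energies = np.asarray(grid_energies, dtype=float)
        self.surface = surface
        self.n_dropped_grid_points = n_dropped_grid_points
        self.c_min = float(self.grid_energies.min())
        self.c_max = float(self.grid_energies.max())

    # -- queries --------------------------------------------------------------
    def contains(self, x) -> np.ndarray:
        """Boundary-inclusive membership test against the alpha shape."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return shapely.intersects_xy(self.domain, x[:, 0], x[:, 1])

    def in_support(self, x) -> np.ndarray:
        """True where the kernel support around x contains samples."""
        return self.surface.in_support(x)

    def value(self, x) -> np.ndarray:
        values, _ = self.surface.estimate(x)
        return values

    def evaluate(self, x, check_domain: bool = True):
        """Energy, gradient and 2x2 Hessian of the smoothed surface at ``x``.

        ``x`` may be a single point or an (m, 2) array. Raises for points
        outside the alpha-convex domain (unless ``check_domain=False``) and
        for non-differentiable kernels.
        """
        single = np.asarray(x, dtype=float).ndim == 1
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        if check_domain and not self.contains(pts).all():
            raise ValueError("query point outside the alpha-convex domain")
        v, g, H, _ = self.surface.value_grad_hess(pts)
        if single:
            return v[0], g[0], H[0]
        return v, g, H

    # -- reconstruction -------------------------------------------------------
    def reconstruct(self, method: str = "bdr", config: RunConfig | None = None) -> Hierarchy:
        """Run a reconstruction algorithm on this fit.

        ``method`` is ``"bdr"`` (recursive sublevel-set descent) or ``"sdr"``
        (minima -> reduced-gradient saddle search -> boundary tracing).
        """
        cfg = config or self.config
        if method == "bdr":
            from .bdr import bdr_reconstruct
            return bdr_reconstruct(self, cfg)
        if method == "sdr":
            from .sdr import sdr_reconstruct
            return sdr_reconstruct(self, cfg)
        raise ValueError(f"unknown reconstruction method {method!r}")

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        s = self.model.samples
        lines = [
            "Energy landscape fit",
            "=" * 48,
            f"variant:            {s.variant_label or '(unlabeled)'}",
            f"samples:            {len(s)}",
            f"kernel / bandwidth: {cfg.kernel} / h={cfg.h}",
            f"alpha / delta1:     {cfg.alpha} / {cfg.delta1}",
            f"domain area:        {self.domain.area:.4f}",
            f"grid points (S_max): {len(self.grid)}"
            + (f"  ({self.n_dropped_grid_points} dropped, empty support)"
               if self.n_dropped_grid_points else ""),
            f"energy range:       c_min={self.c_min:.4f}  c_max={self.c_max:.4f}",
        ]
        return "\n".join(lines)

    def bandwidth_sweep(self, bandwidths) -> pd.DataFrame:
        """Grid-energy variance across bandwidths (smoothing diagnostics)."""
        rows = []
        for h in bandwidths:
            surf = KernelSurface(self.surface.points, self.surface.energies,
                                 self.config.kernel, float(h))
            vals, valid = surf.estimate(self.grid.points)
            rows.append({
                "h": float(h),
                "variance": float(np.var(vals[valid])),
                "n_valid": int(valid.sum()),
            })
        return pd.DataFrame(rows)

    def plot_contour(self, ax=None, levels: int = 30, hierarchy: Hierarchy | None = None,
                     states=None, path=None, cmap="RdYlBu_r"):
        """Filled contour of the estimated surface, optionally overlaying
        basin boundaries, saddles, minima and reference states."""
        import matplotlib
        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        nx, ny = self.grid.shape
        raster = np.full((nx, ny), np.nan)
        raster[self.grid.lattice[:, 0], self.grid.lattice[:, 1]] = self.grid_energies
        x0, y0 = self.grid.origin
        d = self.grid.spacing
        xs = x0 + np.arange(nx) * d
        ys = y0 + np.arange(ny) * d
        cs = ax.contourf(xs, ys, raster.T, levels=levels, cmap=cmap)
        plt.colorbar(cs, ax=ax, label="estimated energy")
        if hierarchy is not None:
            for b in hierarchy.basins:
                v = b.boundary.vertices
                if b.boundary.closed and len(v) >= 3:
                    ax.plot(np.r_[v[:, 0], v[0, 0]], np.r_[v[:, 1], v[0, 1]],
                            color="k", lw=0.8)
            for m in hierarchy.minima:
                ax.plot(*m.location, "ko", ms=5)
            for s in hierarchy.saddles:
                ax.plot(*s.location, "o", color="gold", ms=6, mec="k")
        if states:
            for st in states:
                ax.plot(*st.location, "^", color="magenta", ms=7, mec="k")
                ax.annotate(st.label, st.location, textcoords="offset points",
                            xytext=(4, 4), fontsize=8)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax
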