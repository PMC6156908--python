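"""Analytic test landscapes with exactly known minima, saddles and barriers.

The generator emulates the statistical structure of sample-based landscape
representations produced by stochastic conformational-sampling algorithms:
a rugged multi-basin energy surface over a bounded 2D projection domain,
sampled with non-uniform density and additive energy noise. Surfaces are
negated-Gaussian mixtures (wells, matching the minimization orientation of
molecular energy landscapes) plus an optional weak harmonic confinement term
that makes the energy rise away from the sampled basins, as force-field
landscapes do at the rim of the populated region:

    e(x) = baseline - sum_k depth_k exp(-||x - c_k||^2 / (2 width_k^2))
           + confinement * ||x||^2

Energy, gradient and Hessian are available in closed form, and all critical
points are enumerable by dense-seed Newton polishing, which makes these
surfaces exact oracles for the reconstruction algorithms.

Study-condition defaults (fixture catalogue): well widths are >= 3 PC units
— several times the default smoothing bandwidth h = 0.7 — so the
Nadaraya-Watson attenuation of well depth, width^2 / (width^2 + h^2), stays
within a few percent; sampling density follows a Boltzmann-like law
(beta = 0.1) so basins are oversampled relative to barrier regions; the
additive energy-noise standard deviation defaults to 2% of the deepest well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .samples import SampleSet

DENSITIES = ("uniform", "boltzmann_like", "clustered")


@dataclass(frozen=True)
class Well:
    center: tuple[float, float]
    depth: float
    width: float

    def __post_init__(self):
        if not (self.depth > 0 and self.width > 0):
            raise ValueError("well depth and width must be strictly positive")


@dataclass
class AnalyticLandscape:
    """Closed-form multi-well energy surface (see module docstring)."""

    wells: list[Well]
    baseline: float = 0.0
    confinement: float = 0.0   # kappa of the kappa*||x||^2 rim term
    bounds: tuple[float, float, float, float] | None = None  # xmin,xmax,ymin,ymax

    def __post_init__(self):
        if not self.wells:
            raise ValueError("at least one well is required")
        self._centers = np.asarray([w.center for w in self.wells], dtype=float)
        self._depths = np.asarray([w.depth for w in self.wells], dtype=float)
        self._w2 = np.asarray([w.width ** 2 for w in self.wells], dtype=float)
        if self.bounds is None:
            pad = 2.2 * max(w.width for w in self.wells)
            cx, cy = self._centers[:, 0], self._centers[:, 1]
            self.bounds = (float(cx.min() - pad), float(cx.max() + pad),
                           float(cy.min() - pad), float(cy.max() + pad))
        self._critical_cache = None

    # -- closed-form surface --------------------------------------------------
    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        pts = np.atleast_2d(x)
        dx = pts[:, None, :] - self._centers[None, :, :]       # (m, k, 2)
        s2 = np.einsum("mki,mki->mk", dx, dx)
        e = self.baseline - (self._depths * np.exp(-0.5 * s2 / self._w2)).sum(axis=1)
        e = e + self.confinement * np.einsum("mi,mi->m", pts, pts)
        return float(e[0]) if single else e

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        pts = np.atleast_2d(x)
        dx = pts[:, None, :] - self._centers[None, :, :]
        s2 = np.einsum("mki,mki->mk", dx, dx)
        amp = self._depths / self._w2 * np.exp(-0.5 * s2 / self._w2)   # (m, k)
        g = np.einsum("mk,mki->mi", amp, dx) + 2.0 * self.confinement * pts
        return g[0] if single else g

    def hessian(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        pts = np.atleast_2d(x)
        dx = pts[:, None, :] - self._centers[None, :, :]
        s2 = np.einsum("mki,mki->mk", dx, dx)
        amp = self._depths / self._w2 * np.exp(-0.5 * s2 / self._w2)
        outer = np.einsum("mki,mkj->mkij", dx, dx) / self._w2[None, :, None, None]
        eye = np.eye(2)[None, None, :, :]
        H = np.einsum("mk,mkij->mij", amp, eye - outer)
        H = H + 2.0 * self.confinement * np.eye(2)[None, :, :]
        return H[0] if single else H

    # -- surface protocol used by the saddle-driven machinery -----------------
    def value_grad_hess(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        valid = np.ones(len(pts), dtype=bool)
        return self.energy(pts), self.gradient(pts), self.hessian(pts), valid

    def estimate(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return self.energy(pts), np.ones(len(pts), dtype=bool)

    def in_region(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        xmin, xmax, ymin, ymax = self.bounds
        return ((pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
                & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax))

    # -- oracle ---------------------------------------------------------------
    def critical_points(self, resolution: float | None = None) -> dict:
        if self._critical_cache is None or resolution is not None:
            self._critical_cache = enumerate_critical_points(
                self, resolution or min(w.width for w in self.wells) / 4.0
            )
        return self._critical_cache

    def barrier(self, minimum_xy, saddle_xy) -> float:
        """Analytic barrier height e(saddle) - e(minimum)."""
        return float(self.energy(np.asarray(saddle_xy))
                     - self.energy(np.asarray(minimum_xy)))


def enumerate_critical_points(landscape: AnalyticLandscape,
                              resolution: float,
                              classify_tol: float = 1e-8) -> dict:
    """All roots of ``grad e = 0`` inside the bounds, by Newton polishing
    from a dense seed lattice, classified by the Hessian eigenvalue signs.

    Returns ``{"minima": [...], "saddles": [...], "maxima": [...],
    "degenerate": [...]}`` with ``(location, energy)`` tuples, deduplicated
    at 1e-8. Degenerate critical points (an eigenvalue within tolerance of
    zero) are flagged and excluded from the three main classes.
    """
    if resolution > min(w.width for w in landscape.wells) / 4.0 + 1e-12:
        raise ValueError("resolution must be finer than min(width)/4")
    xmin, xmax, ymin, ymax = landscape.bounds
    xs = np.arange(xmin, xmax + resolution / 2, resolution)
    ys = np.arange(ymin, ymax + resolution / 2, resolution)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    x = np.column_stack([gx.ravel(), gy.ravel()])
    # vectorized Newton iteration on grad e = 0
    for _ in range(60):
        g = landscape.gradient(x)
        H = landscape.hessian(x)
        det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
        ok = np.abs(det) > 1e-14
        step = np.zeros_like(g)
        step[ok, 0] = (-g[ok, 0] * H[ok, 1, 1] + g[ok, 1] * H[ok, 0, 1]) / det[ok]
        step[ok, 1] = (-g[ok, 1] * H[ok, 0, 0] + g[ok, 0] * H[ok, 0, 1]) / det[ok]
        norms = np.linalg.norm(step, axis=1)
        big = norms > resolution * 2
        step[big] *= (resolution * 2) / norms[big, None]
        x = x + step
    g = landscape.gradient(x)
    inside = landscape.in_region(x)
    converged = (np.linalg.norm(g, axis=1) < 1e-9) & inside
    x = x[converged]
    result = {"minima": [], "saddles": [], "maxima": [], "degenerate": []}
    if len(x) == 0:
        return result
    # deduplicate: exact round to the dedup scale, then classify
    from .sdr import leader_cluster  # single-pass dedup, same as the method uses
    reps, _ = leader_cluster(x, max(classify_tol, 1e-8) * 1e4)
    for r in reps:
        pt = x[r]
        H = landscape.hessian(pt)
        lam = np.linalg.eigvalsh(H)
        entry = ((float(pt[0]), float(pt[1])), float(landscape.energy(pt)))
        if abs(lam[0]) < classify_tol or abs(lam[1]) < classify_tol:
            result["degenerate"].append(entry)
        elif lam[0] > 0:
            result["minima"].append(entry)
        elif lam[1] < 0:
            result["maxima"].append(entry)
        else:
            result["saddles"].append(entry)
    for key in result:
        result[key].sort(key=lambda it: it[1])
    return result


# -- sampling -----------------------------------------------------------------

@dataclass
class SamplingModel:
    """How samples are drawn from an analytic landscape."""

    n: int = 5000
    density: str = "boltzmann_like"
    beta: float = 0.1            # inverse-temperature-like density exponent
    noise_sd: float | None = None  # additive energy noise; 0.02*max depth if None
    bounds: tuple[float, float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("need at least 3 samples")
        if self.density not in DENSITIES:
            raise ValueError(f"unknown density {self.density!r}; choose from {DENSITIES}")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def draw_samples(landscape: AnalyticLandscape, model: SamplingModel,
                 variant_label: str = "synthetic") -> SampleSet:
    """Draw an energy-evaluated sample set from an analytic landscape.

    Locations follow the requested density model (``boltzmann_like`` uses
    rejection sampling with weight exp(-beta * e)); energies are the exact
    surface values plus Gaussian noise. Deterministic for a given seed.
    """
    rng = np.random.default_rng(model.seed)
    bounds = model.bounds or landscape.bounds
    xmin, xmax, ymin, ymax = bounds
    noise_sd = model.noise_sd
    if noise_sd is None:
        noise_sd = 0.02 * max(w.depth for w in landscape.wells)

    def uniform(k):
        return np.column_stack([rng.uniform(xmin, xmax, k), rng.uniform(ymin, ymax, k)])

    if model.density == "uniform":
        pts = uniform(model.n)
    elif model.density == "clustered":
        weights = np.asarray([w.depth for w in landscape.wells], dtype=float)
        weights = weights / weights.sum()
        comp = rng.choice(len(landscape.wells), size=model.n, p=weights)
        centers = np.asarray([w.center for w in landscape.wells])
        widths = np.asarray([w.width for w in landscape.wells])
        pts = centers[comp] + rng.normal(size=(model.n, 2)) * widths[comp, None]
        pts[:, 0] = np.clip(pts[:, 0], xmin, xmax)
        pts[:, 1] = np.clip(pts[:, 1], ymin, ymax)
    else:  # boltzmann_like rejection sampling
        # normalize acceptance by the minimum energy over a probe lattice
        probe = np.column_stack([
            np.repeat(np.linspace(xmin, xmax, 101), 101),
            np.tile(np.linspace(ymin, ymax, 101), 101),
        ])
        e_min = float(landscape.energy(probe).min())
        pts_list = []
        total = accepted = 0
        while accepted < model.n:
            k = max(4 * (model.n - accepted), 1000)
            cand = uniform(k)
            acc_p = np.exp(-model.beta * (landscape.energy(cand) - e_min))
            keep = rng.uniform(size=k) < acc_p
            total += k
            accepted += int(keep.sum())
            pts_list.append(cand[keep])
            if total > 1000 and accepted / total < 1e-4:
                raise ValueError("rejection acceptance rate < 1e-4; reduce beta")
        pts = np.concatenate(pts_list)[: model.n]

    energies = landscape.energy(pts)
    if noise_sd > 0:
        energies = energies + rng.normal(scale=noise_sd, size=len(pts))
    return SampleSet(pts, energies, variant_label)


# -- named fixtures -----------------------------------------------------------

def make_two_well(separation: float = 15.0, depth_ratio: float = 1.0,
                  width: float = 3.4, depth: float = 10.0,
                  confinement: float = 0.02) -> AnalyticLandscape:
    """Symmetric-axis two-well landscape with exactly 2 minima and 1 saddle.

    Wells sit at (+-separation/2, 0) with depths ``depth`` and
    ``depth / depth_ratio`` (``depth_ratio > 1`` makes the second well
    shallower and pushes the saddle toward it). Requires
    ``separation > 4 * width`` so the wells do not merge.
    """
    if not separation > 4.0 * width:
        raise ValueError("separation must exceed 4*width for a genuine barrier")
    if depth_ratio <= 0:
        raise ValueError("depth_ratio must be strictly positive")
    half = separation / 2.0
    land = AnalyticLandscape(
        wells=[Well((-half, 0.0), depth, width),
               Well((+half, 0.0), depth / depth_ratio, width)],
        confinement=confinement,
        bounds=(-half - 5.5, half + 5.5, -6.5, 6.5),
    )
    cps = land.critical_points()
    if len(cps["minima"]) != 2 or len(cps["saddles"]) != 1:
        raise ValueError("wells merged: increase separation or reduce width")
    return land


def fixture(name: str) -> AnalyticLandscape:
    """Named study-condition landscapes used throughout the test suite."""
    if name == "one_well":
        return AnalyticLandscape([Well((0.0, 0.0), 10.0, 3.0)],
                                 confinement=0.02, bounds=(-6.0, 6.0, -6.0, 6.0))
    if name == "two_well_symmetric":
        return make_two_well(separation=15.0, depth_ratio=1.0, width=3.4)
    if name == "two_well_asymmetric":
        return make_two_well(separation=15.0, depth_ratio=1.6, width=3.4)
    if name == "three_well_line":
        return AnalyticLandscape(
            [Well((-7.5, 0.0), 10.0, 1.8),
             Well((0.0, 0.0), 8.0, 1.8),
             Well((7.5, 0.0), 12.0, 1.8)],
            confinement=0.02, bounds=(-11.5, 11.5, -4.5, 4.5),
        )
    if name == "nested_basin":
        # a broad shallow well containing two narrow deep wells: exercises
        # the hierarchical (nested) organization of basins
        return AnalyticLandscape(
            [Well((0.0, 0.0), 3.0, 5.0),
             Well((-2.2, 0.0), 6.0, 1.2),
             Well((+2.2, 0.0), 6.0, 1.2)],
            confinement=0.02, bounds=(-6.0, 6.0, -5.0, 5.0),
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")


FIXTURES = ("one_well", "two_well_symmetric", "two_well_asymmetric",
            "three_well_line", "nested_basin")


def random_landscape(rng: np.random.Generator, n_wells: int | None = None) -> AnalyticLandscape:
    """A randomized well-separated 2-4-well landscape (recovery studies).

    Wells share one width (so kernel smoothing rescales all of them alike)
    and are placed along a randomly bending chain with neighbor spacing of
    4.15-4.35 x width: just above the merge limit of ~4 x width, so every
    pair of adjacent wells has two distinct minima joined by a saddle with
    genuine curvature in both directions. Distant well pairs at many widths
    of separation would instead produce saddles on near-flat plateaus whose
    positions are conditioned on energy variations far below any realistic
    noise scale — features no estimator could recover — so the chain design
    keeps every analytic critical point robust by construction. Depth ratios
    are bounded (<= 1.8) to keep smoothing-induced saddle shifts small.
    """
    if n_wells is None:
        n_wells = int(rng.integers(2, 5))
    width = float(rng.uniform(1.4, 1.7))
    centers = [np.zeros(2)]
    theta = rng.uniform(0.0, 2.0 * np.pi)
    while len(centers) < n_wells:
        for _attempt in range(200):
            spacing = rng.uniform(4.15, 4.35) * width
            turn = rng.uniform(-0.9, 0.9)
            cand = centers[-1] + spacing * np.array([np.cos(theta + turn),
                                                     np.sin(theta + turn)])
            if all(np.linalg.norm(cand - c) >= 4.1 * width for c in centers[:-1]):
                centers.append(cand)
                theta = theta + turn
                break
        else:  # pathological draw: accept a shorter chain
            break
    chain = np.asarray(centers) - np.mean(centers, axis=0)
    wells = [Well((float(c[0]), float(c[1])), float(rng.uniform(6.0, 10.8)), width)
             for c in chain]
    return AnalyticLandscape(wells, confinement=0.02,
                             bounds=(float(chain[:, 0].min() - 2.0 * width),
                                     float(chain[:, 0].max() + 2.0 * width),
                                     float(chain[:, 1].min() - 2.0 * width),
                                     float(chain[:, 1].max() + 2.0 * width)))


# -- planted descriptor/parameter relations (correlation-screen oracle) -------

def make_planted_tables(n_variants: int, descriptor_names, parameter_names,
                        planted: dict, seed: int = 0):
    """Variant tables with exactly known descriptor-parameter correlations.

    ``planted`` maps parameter name -> (descriptor name, slope). Planted
    parameters are affine in their descriptor (correlation exactly +-1);
    non-planted parameters are built in the orthogonal complement of all
    centered descriptor columns, so their Pearson correlation with every
    descriptor is exactly zero. Requires
    ``n_variants > len(descriptor_names) + 1``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    d = len(descriptor_names)
    if n_variants <= d + 1:
        raise ValueError("need n_variants > n_descriptors + 1 for the null space")
    # descriptor columns: mutually orthogonal and centered (QR against the
    # ones vector), then arbitrarily rescaled/shifted — so the only nonzero
    # correlations in the tables are the planted ones
    raw = np.column_stack([np.ones(n_variants),
                           rng.normal(size=(n_variants, n_variants - 1))])
    q = np.linalg.qr(raw)[0]
    desc = q[:, 1:d + 1] * rng.uniform(0.5, 3.0, d) + rng.normal(size=d)
    desc_df = pd.DataFrame(desc, columns=list(descriptor_names),
                           index=[f"V{i}" for i in range(n_variants)])
    null_basis = q[:, d + 1:]
    params = {}
    for j, pname in enumerate(parameter_names):
        if pname in planted:
            dname, slope = planted[pname]
            params[pname] = slope * desc_df[dname].to_numpy() + float(j)
        else:
            coef = rng.normal(size=null_basis.shape[1])
            params[pname] = null_basis @ coef + float(j)
    param_df = pd.DataFrame(params, index=desc_df.index)
    return desc_df, param_df
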