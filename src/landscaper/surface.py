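"""Kernel-regression energy surface: values, gradients, Hessians.

The smoothed surface is the Nadaraya-Watson estimator

    e_hat(x) = sum_i K(||x - x_i|| / h) e_i  /  sum_i K(||x - x_i|| / h)

over the observed samples (x_i, e_i). Four kernels are supported: Gaussian,
Epanechnikov, Tricube and a bounded-support Gaussian that only admits samples
within an h-radius neighborhood of the query point, located through a kd-tree
proximity index. For the two Gaussian kernels the gradient and Hessian of the
estimator are available in closed form (quotient rule over the weighted sums),
which is what the saddle search and Newton descent consume.

Derivative algebra, with N(x) = sum K_i e_i and D(x) = sum K_i:

    v = N / D
    grad v = (grad N - v grad D) / D
    hess v = (hess N - v hess D - grad v grad D^T - grad D grad v^T) / D

and for the Gaussian profile K_i = exp(-||x - x_i||^2 / (2 h^2)):

    grad K_i = -K_i (x - x_i) / h^2
    hess K_i =  K_i ((x - x_i)(x - x_i)^T / h^4 - I / h^2)
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .config import SMOOTH_KERNELS

log = logging.getLogger(__name__)

#: pair-radius beyond which an (unbounded) Gaussian weight is numerically nil
_GAUSS_CUT = 5.0


def kernel_weights(kernel: str, r: np.ndarray, h: float) -> np.ndarray:
    """Unnormalized kernel profile K(r/h); constants cancel in the estimator."""
    u = np.asarray(r, dtype=float) / h
    if kernel == "gaussian":
        return np.exp(-0.5 * u * u)
    if kernel == "bounded_gaussian":
        w = np.exp(-0.5 * u * u)
        return np.where(u <= 1.0, w, 0.0)
    if kernel == "epanechnikov":
        return np.clip(1.0 - u * u, 0.0, None)
    if kernel == "tricube":
        return np.clip(1.0 - u ** 3, 0.0, None) ** 3
    raise ValueError(f"unknown kernel {kernel!r}")


def kernel_support_radius(kernel: str, h: float) -> float:
    """Radius beyond which samples do not contribute (inf truncated for speed)."""
    return h if kernel in ("bounded_gaussian", "epanechnikov", "tricube") else _GAUSS_CUT * h


class KernelSurface:
    """Evaluates the Nadaraya-Watson estimator and its derivatives.

    Parameters
    ----------
    points, energies : sample locations (n, 2) and energies (n,)
    kernel : one of gaussian / epanechnikov / tricube / bounded_gaussian
    h : bandwidth (support radius for the bounded kernels)
    """

    def __init__(self, points: np.ndarray, energies: np.ndarray, kernel: str,
                 h: float, radius_factor: float | None = None, _tree=None):
        self.points = np.ascontiguousarray(points, dtype=float)
        self.energies = np.ascontiguousarray(energies, dtype=float)
        if h <= 0:
            raise ValueError("bandwidth h must be strictly positive")
        self.kernel = kernel
        self.h = float(h)
        self.radius_factor = radius_factor
        self.tree = _tree if _tree is not None else cKDTree(self.points)

    def support_radius(self) -> float:
        if self.kernel == "gaussian" and self.radius_factor is not None:
            return self.radius_factor * self.h
        return kernel_support_radius(self.kernel, self.h)

    def coarse(self, radius_factor: float) -> "KernelSurface":
        """A clone with a tighter Gaussian truncation radius.

        Cheaper per evaluation but with a correspondingly higher numerical
        noise floor; used for the bulk phase of iterative searches, whose
        results are then polished on the accurately truncated estimator.
        """
        return KernelSurface(self.points, self.energies, self.kernel, self.h,
                             radius_factor=radius_factor, _tree=self.tree)

    # -- neighbor bookkeeping -------------------------------------------------
    def _pairs(self, queries: np.ndarray):
        """Sparse (query, sample) pairs within the kernel support radius."""
        radius = self.support_radius()
        lists = self.tree.query_ball_point(queries, r=radius)
        counts = np.fromiter((len(l) for l in lists), dtype=np.intp, count=len(lists))
        if counts.sum() == 0:
            return (np.empty(0, np.intp), np.empty(0, np.intp), counts)
        si = np.concatenate([np.asarray(l, dtype=np.intp) for l in lists if l])
        qi = np.repeat(np.arange(len(queries), dtype=np.intp), counts)
        return qi, si, counts

    def in_support(self, x: np.ndarray) -> np.ndarray:
        """True where at least one sample lies within the support radius."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d, _ = self.tree.query(x, k=1)
        return d <= self.support_radius()

    def in_region(self, x: np.ndarray) -> np.ndarray:
        """True where the nearest sample is within ``h`` — the adequately
        sampled region from which walks are allowed to proceed."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d, _ = self.tree.query(x, k=1)
        return d <= self.h

    # -- estimation -----------------------------------------------------------
    def estimate(self, queries: np.ndarray):
        """Estimated energies at ``queries`` via the proximity-index path.

        Returns ``(values, valid)``; ``valid`` is False where the kernel
        support contains no sample (bounded kernels in unsampled regions).
        """
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        if self.kernel == "gaussian" and self.radius_factor is None:
            # infinite support: dense all-pairs sums (chunked), so estimates
            # agree with the naive computation to float accumulation order
            return self._estimate_dense(queries)
        qi, si, _ = self._pairs(queries)
        dx = queries[qi] - self.points[si]
        r = np.sqrt(np.einsum("ij,ij->i", dx, dx))
        # fixed summation order: sort the kd-tree pair stream by sample index
        order = np.lexsort((si, qi))
        qi, si, r = qi[order], si[order], r[order]
        w = kernel_weights(self.kernel, r, self.h)
        m = len(queries)
        denom = np.bincount(qi, weights=w, minlength=m)
        numer = np.bincount(qi, weights=w * self.energies[si], minlength=m)
        valid = denom > 0.0
        values = np.full(m, np.nan)
        np.divide(numer, denom, out=values, where=valid)
        return values, valid

    def _estimate_dense(self, queries: np.ndarray):
        n = len(self.points)
        chunk = max(1, int(4e7 // max(n, 1)))
        values = np.empty(len(queries))
        h2 = self.h * self.h
        xx = np.einsum("ij,ij->i", self.points, self.points)
        for start in range(0, len(queries), chunk):
            q = queries[start:start + chunk]
            qq = np.einsum("ij,ij->i", q, q)
            d2 = qq[:, None] + xx[None, :] - 2.0 * (q @ self.points.T)
            np.maximum(d2, 0.0, out=d2)
            w = np.exp(-0.5 * d2 / h2)
            values[start:start + chunk] = (w @ self.energies) / w.sum(axis=1)
        return values, np.ones(len(queries), dtype=bool)

    def estimate_bruteforce(self, queries: np.ndarray):
        """All-pairs reference estimator (no proximity index); oracle path."""
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        values = np.full(len(queries), np.nan)
        valid = np.zeros(len(queries), dtype=bool)
        for j, q in enumerate(queries):
            r = np.linalg.norm(self.points - q, axis=1)
            w = kernel_weights(self.kernel, r, self.h)
            denom = w.sum()
            if denom > 0:
                values[j] = float(w @ self.energies) / denom
                valid[j] = True
        return values, valid

    # -- derivatives ----------------------------------------------------------
    def value_grad_hess(self, queries: np.ndarray):
        """Value, gradient and Hessian of the estimator at each query point.

        Only the smooth (Gaussian-family) kernels support derivatives.
        Returns ``(v (m,), g (m, 2), H (m, 2, 2), valid (m,))``.
        """
        if self.kernel not in SMOOTH_KERNELS:
            raise ValueError(
                f"kernel {self.kernel!r} is not differentiable; "
                f"use one of {SMOOTH_KERNELS}"
            )
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        m = len(queries)
        h2 = self.h * self.h
        qi, si, _ = self._pairs(queries)
        dx = queries[qi] - self.points[si]          # (P, 2)
        s2 = np.einsum("ij,ij->i", dx, dx)
        w = np.exp(-0.5 * s2 / h2)
        e = self.energies[si]
        we = w * e

        def acc(vals):
            return np.bincount(qi, weights=vals, minlength=m)

        D = acc(w)
        N = acc(we)
        # gradient sums: grad K = -K dx / h^2
        Dg = np.stack([acc(-w * dx[:, 0]), acc(-w * dx[:, 1])], axis=1) / h2
        Ng = np.stack([acc(-we * dx[:, 0]), acc(-we * dx[:, 1])], axis=1) / h2
        # Hessian sums: hess K = K (dx dx^T / h^4 - I / h^2)
        kxx = dx[:, 0] * dx[:, 0] / (h2 * h2) - 1.0 / h2
        kyy = dx[:, 1] * dx[:, 1] / (h2 * h2) - 1.0 / h2
        kxy = dx[:, 0] * dx[:, 1] / (h2 * h2)
        DH = np.empty((m, 2, 2))
        NH = np.empty((m, 2, 2))
        DH[:, 0, 0] = acc(w * kxx)
        DH[:, 1, 1] = acc(w * kyy)
        DH[:, 0, 1] = DH[:, 1, 0] = acc(w * kxy)
        NH[:, 0, 0] = acc(we * kxx)
        NH[:, 1, 1] = acc(we * kyy)
        NH[:, 0, 1] = NH[:, 1, 0] = acc(we * kxy)

        valid = D > 0.0
        v = np.full(m, np.nan)
        np.divide(N, D, out=v, where=valid)
        g = np.full((m, 2), np.nan)
        H = np.full((m, 2, 2), np.nan)
        ok = valid
        Dok = D[ok, None]
        g[ok] = (Ng[ok] - v[ok, None] * Dg[ok]) / Dok
        outer_gD = g[ok, :, None] * Dg[ok, None, :]
        H[ok] = (NH[ok] - v[ok, None, None] * DH[ok]
                 - outer_gD - np.swapaxes(outer_gD, 1, 2)) / Dok[:, :, None]
        return v, g, H, valid

    def value_grad_hess_one(self, x: np.ndarray):
        """Single-point convenience wrapper around :meth:`value_grad_hess`."""
        v, g, H, valid = self.value_grad_hess(np.asarray(x, dtype=float)[None, :])
        return v[0], g[0], H[0], bool(valid[0])


class KnnKernelSurface:
    """k-nearest-neighbor truncation of a :class:`KernelSurface`.

    Evaluates the same Gaussian-weighted estimator over the k nearest samples
    of each query (fixed-size arrays straight from the kd-tree, no ragged
    neighbor lists), trading a coarser truncation for much cheaper batched
    sweeps. Used as the bulk phase of iterative searches whose endpoints are
    re-polished on the exact estimator.
    """

    def __init__(self, base: KernelSurface, k: int = 64):
        self.base = base
        self.k = int(min(k, len(base.points)))
        self.h = base.h

    def _neighbors(self, queries):
        d, si = self.base.tree.query(queries, k=self.k)
        if self.k == 1:
            d, si = d[:, None], si[:, None]
        return d, si

    def estimate(self, queries):
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        d, si = self._neighbors(queries)
        w = np.exp(-0.5 * (d / self.h) ** 2)
        denom = w.sum(axis=1)
        np.maximum(denom, 1e-300, out=denom)
        return (w * self.base.energies[si]).sum(axis=1) / denom, np.ones(len(queries), bool)

    def value_grad_hess(self, queries):
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        h2 = self.h * self.h
        _, si = self._neighbors(queries)
        dx = queries[:, None, :] - self.base.points[si]          # (m, k, 2)
        s2 = np.einsum("mki,mki->mk", dx, dx)
        w = np.exp(-0.5 * s2 / h2)
        e = self.base.energies[si]
        we = w * e
        D = w.sum(axis=1)
        N = we.sum(axis=1)
        Dg = -np.einsum("mk,mki->mi", w, dx) / h2
        Ng = -np.einsum("mk,mki->mi", we, dx) / h2
        outer = np.einsum("mki,mkj->mkij", dx, dx) / (h2 * h2)
        outer -= np.eye(2)[None, None, :, :] / h2
        DH = np.einsum("mk,mkij->mij", w, outer)
        NH = np.einsum("mk,mkij->mij", we, outer)
        valid = D > 1e-300
        v = np.where(valid, N / np.maximum(D, 1e-300), np.nan)
        g = (Ng - v[:, None] * Dg) / np.maximum(D, 1e-300)[:, None]
        outer_gD = g[:, :, None] * Dg[:, None, :]
        H = (NH - v[:, None, None] * DH - outer_gD
             - np.swapaxes(outer_gD, 1, 2)) / np.maximum(D, 1e-300)[:, None, None]
        return v, g, H, valid

    def in_region(self, x):
        return self.base.in_region(x)

    def in_support(self, x):
        return self.base.in_support(x)


def estimate_energies(grid, samples, kernel: str, h: float, accelerated: bool = True):
    """Estimate grid-point energies; drop points with empty kernel support.

    Returns ``(surface, kept_grid, energies, n_dropped)`` where ``kept_grid``
    restricts the input grid to points whose bounded-kernel neighborhood is
    nonempty (dropped points are excluded from the reconstruction grid, with
    the count logged).
    """
    surface = KernelSurface(samples.points, samples.energies, kernel, h)
    if accelerated:
        values, valid = surface.estimate(grid.points)
    else:
        values, valid = surface.estimate_bruteforce(grid.points)
    # S_max keeps only adequately sampled grid points: at least one sample
    # within the h-neighborhood, whatever the kernel's numerical support
    valid &= surface.in_region(grid.points)
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.warning(
            "dropping %d of %d grid points with no sample inside the "
            "kernel support (radius %.3g)",
            n_dropped, len(grid), kernel_support_radius(kernel, h),
        )
        grid = grid.subset(valid)
        values = values[valid]
    return surface, grid, values, n_dropped
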