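"""Saddle-driven reconstruction: minima, reduced-gradient curves, tracing.

The saddle-driven method inverts the basin-driven logic: it first harvests
every local minimum of the smoothed surface by Newton descent from each grid
point (duplicates merged by leader clustering), then follows reduced-gradient
curves out of each minimum to locate all saddle points, and finally traces
the boundary of the two basins attached at each saddle by contour following.

Reduced-gradient curves: a critical point solves both components of
``grad e = 0``. Dropping one of the two equations leaves a curve (the zero
set of the retained gradient component ``g_j``) that threads through all
critical points. Its tangent is orthogonal to ``grad g_j``, i.e. to row/column
``j`` of the Hessian; in two dimensions this yields four launch variants
(two Hessian columns x two orthogonal orientations), all of which are
followed. Walking alternates a predictor step of length ``p`` along the
tangent with a corrector that solves the 2x2 linearization

    H_j(x) . c = -g_j(x),   t . c = 0

pulling the point back onto the curve; the combined mode solves for the
single step ``d`` with ``H_j . d = -g_j`` and ``t . d = p`` directly. A point
is a saddle when the gradient vanishes (tolerance ``eps_g``) and the Hessian
eigenvalues have opposite signs. On a discrete walk the retained component is
held at zero by the corrector while the neglected component ``g_i`` changes
sign when the walk passes a critical point, so a sign change triggers a local
Newton polish of ``grad e = 0`` followed by the exact saddle test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from .boundary import BoundaryPolygon
from .config import RunConfig
from .hierarchy import Basin, Hierarchy, LocalMinimum, SaddlePoint

log = logging.getLogger(__name__)

#: the four tangent variants in 2D: (Hessian column, orthogonal orientation)
RGF_VARIANTS = ((0, +1), (0, -1), (1, +1), (1, -1))


# -- small helpers ------------------------------------------------------------

def _values(surface, pts):
    """Value-only batch evaluation with validity mask."""
    if hasattr(surface, "estimate"):
        return surface.estimate(pts)
    v, _, _, valid = surface.value_grad_hess(pts)
    return v, valid


def _eval1(surface, x):
    v, g, H, valid = surface.value_grad_hess(np.asarray(x, float)[None, :])
    ok = bool(valid[0]) and bool(np.atleast_1d(surface.in_region(np.asarray(x, float)[None, :]))[0])
    return float(v[0]), g[0], H[0], ok


def _eig2(H):
    """Eigenvalues of a symmetric 2x2, ascending."""
    tr = H[0, 0] + H[1, 1]
    det = H[0, 0] * H[1, 1] - H[0, 1] * H[1, 0]
    disc = np.sqrt(max((tr * tr) / 4.0 - det, 0.0))
    return (tr / 2.0 - disc, tr / 2.0 + disc)


def saddle_test(surface, x, eps_g: float):
    """True iff ``||grad e(x)|| < eps_g`` and the Hessian eigenvalues at x
    have opposite signs. Returns ``(passed, eigenvalues)``."""
    _, g, H, ok = _eval1(surface, x)
    if not ok or not np.all(np.isfinite(g)):
        return False, (np.nan, np.nan)
    lam = _eig2(H)
    return bool(np.linalg.norm(g) < eps_g and lam[0] * lam[1] < 0.0), lam


def leader_cluster(points: np.ndarray, eps: float):
    """Single-pass leader clustering in input order.

    Each point joins the *first* existing cluster whose representative lies
    within ``eps`` (Euclidean), otherwise it founds a new cluster and becomes
    its representative. Returns ``(representative_indices, labels)``.
    """
    if eps <= 0:
        raise ValueError("eps must be strictly positive")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    reps: list[int] = []
    labels = np.empty(len(points), dtype=np.intp)
    rep_xy = np.empty((0, 2))
    for i, pt in enumerate(points):
        if len(reps):
            within = np.einsum("ij,ij->i", rep_xy - pt, rep_xy - pt) <= eps * eps
            if within.any():
                labels[i] = int(np.argmax(within))
                continue
        labels[i] = len(reps)
        reps.append(i)
        rep_xy = np.vstack([rep_xy, pt[None, :]])
    return np.asarray(reps, dtype=np.intp), labels


def _newton_root(surface, x0, eps_g=1e-3, max_iter=30, step_cap=0.5):
    """Polish a root of ``grad e = 0`` by Newton iteration; None on failure.

    Targets a gradient norm well below ``eps_g`` but accepts ``eps_g / 10``
    (the estimator is only numerically smooth to finite precision)."""
    x = np.asarray(x0, dtype=float).copy()
    target = eps_g * 1e-4
    for _ in range(max_iter):
        _, g, H, ok = _eval1(surface, x)
        if not ok:
            return None
        if np.linalg.norm(g) < target:
            return x
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            return None
        n = np.linalg.norm(step)
        if n > step_cap:
            step *= step_cap / n
        x = x + step
    _, g, _, ok = _eval1(surface, x)
    return x if ok and np.linalg.norm(g) < eps_g * 0.1 else None


# -- local minima -------------------------------------------------------------

def _minimize_batch(surface, seeds, eps_g, step_cap, max_iter=60):
    """Damped Newton descent from every seed simultaneously.

    Newton directions where the Hessian is positive definite, steepest
    descent otherwise; backtracking on the estimator value. A seed stops
    when its gradient norm falls below ``eps_g`` or no descent step remains
    (its endpoint is then a candidate); it fails when the evaluation leaves
    the sampled region. Returns ``(endpoints, candidate_mask)``.
    """
    x = np.array(seeds, dtype=float)
    n = len(x)
    settled = np.zeros(n, dtype=bool)
    failed = np.zeros(n, dtype=bool)
    gtol = eps_g * 0.5
    for _ in range(max_iter):
        active = np.flatnonzero(~settled & ~failed)
        if len(active) == 0:
            break
        v, g, H, valid = surface.value_grad_hess(x[active])
        bad = ~valid | ~np.isfinite(v)
        failed[active[bad]] = True
        sel = ~bad
        idx, v, g, H = active[sel], v[sel], g[sel], H[sel]
        gn = np.linalg.norm(g, axis=1)
        done = gn < gtol
        settled[idx[done]] = True
        idx, v, g, H, gn = idx[~done], v[~done], g[~done], H[~done], gn[~done]
        if len(idx) == 0:
            continue
        h00, h01, h11 = H[:, 0, 0], H[:, 0, 1], H[:, 1, 1]
        det = h00 * h11 - h01 * h01
        pd = (h00 > 0) & (det > 0)
        d = np.empty_like(g)
        # closed-form 2x2 solve of H d = -g where positive definite
        d[pd, 0] = (-g[pd, 0] * h11[pd] + g[pd, 1] * h01[pd]) / det[pd]
        d[pd, 1] = (-g[pd, 1] * h00[pd] + g[pd, 0] * h01[pd]) / det[pd]
        d[~pd] = -g[~pd]
        dn = np.linalg.norm(d, axis=1)
        scale = np.minimum(1.0, step_cap / np.maximum(dn, 1e-300))
        d *= scale[:, None]
        # backtracking line search on the shrinking pending subset
        pending = np.arange(len(idx))
        t = 1.0
        for _bt in range(6):
            trial = x[idx[pending]] + t * d[pending]
            tv, tvalid = _values(surface, trial)
            improve = tvalid & (tv < v[pending] - 1e-12)
            x[idx[pending[improve]]] = trial[improve]
            pending = pending[~improve]
            if len(pending) == 0:
                break
            t /= 2.0
        # no descent step remains: the endpoint is a candidate as it stands
        settled[idx[pending]] = True
    return x, ~failed


def _polish_minimum(surface, x0, eps_g, step_cap, max_iter=60):
    """Per-point damped Newton descent on the accurate estimator.

    Returns the refined location, or None when the walk leaves the sampled
    region or cannot reach the ``eps_g`` gradient test."""
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(max_iter):
        v, g, H, ok = _eval1(surface, x)
        if not ok:
            return None
        gn = np.linalg.norm(g)
        if gn < eps_g * 1e-2:
            return x
        det = H[0, 0] * H[1, 1] - H[0, 1] ** 2
        if H[0, 0] > 0 and det > 0:
            d = np.linalg.solve(H, -g)
        else:
            d = -g
        dn = np.linalg.norm(d)
        if dn > step_cap:
            d *= step_cap / dn
        t = 1.0
        for _bt in range(8):
            # value from the same (truncated) evaluator as the gradient,
            # so the descent test is consistent near the numerical floor
            tv, _, _, tok = _eval1(surface, x + t * d)
            if tok and tv < v - 1e-14:
                x = x + t * d
                break
            t /= 2.0
        else:
            return x if gn < eps_g else None
    _, g, _, ok = _eval1(surface, x)
    return x if ok and np.linalg.norm(g) < eps_g else None


#: neighbor count for the bulk descent phase; the candidate endpoints it
#: produces are re-polished at full accuracy afterwards
_BULK_KNN = 32


def find_local_minima(surface, seeds, eps: float, eps_g: float,
                      step_cap: float | None = None) -> list[LocalMinimum]:
    """All local minima reachable by Newton descent from the given seeds.

    The bulk descent runs on a coarsely truncated clone of the estimator
    (cheap batched sweeps over every seed); candidate endpoints are grouped
    and their representatives polished on the accurate estimator, where the
    minimum test (gradient below ``eps_g``, positive definite Hessian,
    adequately sampled neighborhood) is applied. Survivors are
    leader-clustered at radius ``eps`` and returned sorted by energy with
    their seed-cluster sizes. Divergent seeds are skipped and logged.
    """
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 2)
    if step_cap is None:
        step_cap = max(getattr(surface, "h", 1.0), 0.5)
    from .surface import KernelSurface, KnnKernelSurface
    bulk = (KnnKernelSurface(surface, _BULK_KNN)
            if isinstance(surface, KernelSurface) else surface)
    # the bulk phase may take long strides across featureless slopes; the
    # backtracking test still guards every step
    ends, ok = _minimize_batch(bulk, seeds, eps_g, 3.0 * step_cap)
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.info("local-minimum search: %d of %d seeds skipped (divergence or "
                 "unsampled region)", n_skipped, len(seeds))
    ends = ends[ok]
    if len(ends) == 0:
        return []
    # group coarse endpoints at a bandwidth-scale radius, polish the reps
    h = getattr(surface, "h", None)
    group_radius = max(eps, (h / 4.0) if h else eps)
    reps, labels = leader_cluster(ends, group_radius)
    sizes = np.bincount(labels, minlength=len(reps))
    polished: list[np.ndarray] = []
    weights: list[int] = []
    for c, r in enumerate(reps):
        refined = _polish_minimum(surface, ends[r], eps_g, step_cap)
        if refined is None:
            continue
        v, g, H, okk = _eval1(surface, refined)
        if not okk or np.linalg.norm(g) >= eps_g or _eig2(H)[0] <= 0:
            continue
        if not bool(np.atleast_1d(surface.in_region(refined[None, :]))[0]):
            continue
        polished.append(refined)
        weights.append(int(sizes[c]))
    if not polished:
        return []
    final_reps, final_labels = leader_cluster(np.asarray(polished), eps)
    minima = []
    for c, r in enumerate(final_reps):
        loc = polished[r]
        v, _, _, _ = _eval1(surface, loc)
        size = int(sum(w for w, lab in zip(weights, final_labels) if lab == c))
        minima.append(LocalMinimum((float(loc[0]), float(loc[1])), float(v), size))
    minima.sort(key=lambda m: (m.energy, m.location))
    return minima


# -- reduced-gradient curves --------------------------------------------------

@dataclass
class ReducedGradientCurve:
    """One followed solution curve of a reduced-gradient equation."""

    points: np.ndarray                 # (k, 2) visited locations
    variant: tuple[int, int]           # (Hessian column, orientation sign)
    origin: int                        # index of the launching minimum
    terminated_by: str                 # exited_grid | max_steps | cycle | degenerate
    saddle_candidates: list = field(default_factory=list)


def follow_reduced_gradient(surface, x0, variant, p: float, eps_g: float,
                            mode: str = "predictor_corrector",
                            max_steps: int = 10000, origin: int = -1,
                            cycle_eps: float | None = None) -> ReducedGradientCurve:
    """Walk one reduced-gradient curve from a local minimum.

    ``variant = (j, sign)`` selects Hessian column ``j`` (the curve is the
    zero set of gradient component ``g_j``) and the orientation of the
    orthogonal tangent. Walking stops when the curve leaves the sampled
    region, exceeds ``max_steps``, re-enters a small neighborhood of its
    start (cycle guard) or the tangent degenerates. Saddle candidates
    encountered along the way are collected (walking continues past them).
    """
    j, sgn = variant
    i = 1 - j
    x = np.asarray(x0, dtype=float).copy()
    _, g, H, ok = _eval1(surface, x)
    pts = [x.copy()]
    cands: list[np.ndarray] = []
    if not ok:
        return ReducedGradientCurve(np.asarray(pts), variant, origin, "exited_grid", cands)
    t_prev = None
    term = "max_steps"
    for _step in range(max_steps):
        hcol = H[:, j]
        nh = np.linalg.norm(hcol)
        if nh < eps_g:
            term = "degenerate"
            break
        t = np.array([-hcol[1], hcol[0]]) / nh
        if t_prev is None:
            t = sgn * t
        elif float(t @ t_prev) < 0.0:
            t = -t
        if mode == "combined":
            A = np.vstack([H[j, :], t])
            try:
                d = np.linalg.solve(A, np.array([-g[j], p]))
            except np.linalg.LinAlgError:
                term = "degenerate"
                break
            nd = np.linalg.norm(d)
            if nd > 3.0 * p:
                d *= 3.0 * p / nd
            x_new = x + d
            _, g2, H2, ok2 = _eval1(surface, x_new)
            if not ok2:
                term = "exited_grid"
                break
        else:
            x_new = x + p * t
            ok2 = False
            g2 = H2 = None
            for _c in range(10):
                _, g2, H2, okc = _eval1(surface, x_new)
                if not okc:
                    break
                if abs(g2[j]) < eps_g * 0.1:
                    ok2 = True
                    break
                A = np.vstack([H2[j, :], t])
                try:
                    c = np.linalg.solve(A, np.array([-g2[j], 0.0]))
                except np.linalg.LinAlgError:
                    break
                nc = np.linalg.norm(c)
                if nc > 2.0 * p:
                    c *= 2.0 * p / nc
                x_new = x_new + c
                ok2 = True
            if g2 is None or not ok2:
                term = "exited_grid"
                break
        # saddle detection: the neglected gradient component changes sign
        # when the walk passes a critical point on the curve
        if np.isfinite(g2[i]) and np.isfinite(g[i]) and g2[i] * g[i] < 0.0:
            polished = _newton_root(surface, (x + x_new) / 2.0, eps_g)
            if polished is not None and np.linalg.norm(polished - x_new) < 10.0 * p:
                passed, _lam = saddle_test(surface, polished, eps_g)
                if passed:
                    cands.append(polished)
        elif np.linalg.norm(g2) < eps_g:
            passed, _lam = saddle_test(surface, x_new, eps_g)
            if passed:
                cands.append(x_new.copy())
        pts.append(x_new.copy())
        if cycle_eps is not None and _step > 10 and np.linalg.norm(x_new - pts[0]) < cycle_eps:
            term = "cycle"
            break
        x, g, H, t_prev = x_new, g2, H2, t
    return ReducedGradientCurve(np.asarray(pts), variant, origin, term, cands)


def dedupe_saddles(surface, candidates, eps: float, eps_g: float) -> list[SaddlePoint]:
    """Leader-cluster saddle candidates and re-verify the saddle test.

    A saddle is crossed by several reduced-gradient curves, so the same
    critical point is found repeatedly; representatives are returned sorted
    by energy with their Hessian eigenvalues.
    """
    if len(candidates) == 0:
        return []
    pts = np.asarray(candidates, dtype=float).reshape(-1, 2)
    reps, _ = leader_cluster(pts, eps)
    out = []
    for r in reps:
        x = pts[r]
        passed, lam = saddle_test(surface, x, eps_g)
        if not passed:
            continue
        v, _, _, _ = _eval1(surface, x)
        out.append(SaddlePoint((float(x[0]), float(x[1])), float(v),
                               "sdr_critical", hessian_eigenvalues=lam))
    out.sort(key=lambda s: (s.energy, s.location))
    return out


# -- basin boundary tracing ---------------------------------------------------

def _project_to_level(surface, x, level, e_tol, max_iter=30):
    x = np.asarray(x, dtype=float).copy()
    for _ in range(max_iter):
        v, g, _, ok = _eval1(surface, x)
        if not ok:
            return None
        err = v - level
        if abs(err) < e_tol:
            return x
        gn2 = float(g @ g)
        if gn2 < 1e-18:
            return None
        x = x - err * g / gn2
    return None


def _trace_contour(surface, seed, level, step, e_tol, max_steps):
    """Follow the level curve through ``seed`` orthogonally to the gradient,
    projecting back onto the level after every step, until it closes.

    Where the curve bends sharply (hairpins near a saddle pinch) the local
    step is refined so the tracer stays on its own branch instead of cutting
    the corner onto the neighboring one."""
    x = _project_to_level(surface, seed, level, e_tol)
    if x is None:
        return np.empty((0, 2)), "failed"
    pts = [x.copy()]
    t_prev = None
    status = "open"
    for k in range(max_steps):
        _, g, _, ok = _eval1(surface, x)
        if not ok:
            status = "truncated"
            break
        gn = np.linalg.norm(g)
        if gn < 1e-15:
            status = "truncated"
            break
        t = np.array([-g[1], g[0]]) / gn
        if t_prev is not None and float(t @ t_prev) < 0.0:
            t = -t
        x_new = None
        local = step
        for _refine in range(4):
            cand = _project_to_level(surface, x + local * t, level, e_tol)
            if cand is not None:
                _, g2, _, ok2 = _eval1(surface, cand)
                if ok2 and np.linalg.norm(g2) > 1e-15:
                    t2 = np.array([-g2[1], g2[0]]) / np.linalg.norm(g2)
                    if float(np.abs(t2 @ t)) >= 0.5:  # bend below ~60 degrees
                        x_new = cand
                        break
            local /= 2.0
        if x_new is None:
            status = "truncated"
            break
        pts.append(x_new.copy())
        if k > 4 and np.linalg.norm(x_new - pts[0]) < 1.5 * step:
            status = "closed"
            break
        t_prev, x = t, x_new
    return np.asarray(pts), status


def trace_basin_pair(surface, saddle: SaddlePoint, step: float,
                     jitter: float, level_drop: float | None = None,
                     max_steps: int = 10000):
    """Trace the two basin boundaries attached at a saddle.

    The gradient vanishes at the saddle, so tracing starts from two seeds
    jittered off the saddle along the eigenvector of the Hessian's smallest
    (negative) eigenvalue — the direction pointing into the two basins. Each
    seed is projected onto the contour at the saddle energy (lowered by
    ``level_drop``: at the saddle energy itself the two boundaries pinch
    together and a discrete tracer can hop branches, so the level is dropped
    until the pinch gap, ~2*sqrt(2*drop/|lambda_minus|), spans several trace
    steps) and followed until it closes. Returns a list of two
    ``(level, BoundaryPolygon, status)`` triples.
    """
    s = np.asarray(saddle.location, dtype=float)
    _, _, H, ok = _eval1(surface, s)
    if not ok:
        raise ValueError("saddle location is outside the sampled region")
    lam, vec = np.linalg.eigh(H)
    v_min = vec[:, 0]  # eigenvector of the smallest (negative) eigenvalue
    if level_drop is None:
        level_drop = max(1e-9, 4.0 * step * step * abs(lam[0]))
    level = saddle.energy - level_drop
    e_tol = max(1e-9, 1e-6 * (abs(level) + 1.0))
    out = []
    for sign in (+1.0, -1.0):
        seed = s + sign * jitter * v_min
        pts, status = _trace_contour(surface, seed, level, step, e_tol, max_steps)
        if len(pts) >= 3:
            poly = BoundaryPolygon(pts, closed=(status == "closed"))
        else:
            poly = BoundaryPolygon(np.vstack([seed[None, :]]), closed=False)
        out.append((level, poly, status))
    return out


# -- full reconstruction ------------------------------------------------------

def sdr_reconstruct(fit, config: RunConfig | None = None) -> Hierarchy:
    """Run the full saddle-driven reconstruction on a landscape fit.

    Composition: Newton descent from every grid point -> leader-clustered
    local minima -> four reduced-gradient curves per minimum -> deduplicated
    saddles -> two traced basin boundaries per saddle. Minima with no
    saddle-reaching curve are retained as isolated minima. The result is a
    flat hierarchy (saddle-attached basin pairs; nesting is the basin-driven
    method's output).
    """
    cfg = config or fit.config
    surface = fit.surface
    minima = find_local_minima(surface, fit.grid.points, cfg.eps, cfg.eps_g,
                               step_cap=max(cfg.h, 5 * cfg.delta1))
    # do not advance curves from minima in poorly sampled regions
    if minima:
        locs = np.asarray([m.location for m in minima])
        ok = fit.contains(locs) & surface.in_region(locs)
        minima = [m for m, keep in zip(minima, ok) if keep]
    curves: list[ReducedGradientCurve] = []
    candidates: list[np.ndarray] = []
    for mi, minimum in enumerate(minima):
        for variant in RGF_VARIANTS:
            curve = follow_reduced_gradient(
                surface, minimum.location, variant, cfg.p, cfg.eps_g,
                mode=cfg.rgf_mode, max_steps=cfg.max_curve_steps,
                origin=mi, cycle_eps=cfg.eps,
            )
            curves.append(curve)
            candidates.extend(curve.saddle_candidates)
    saddles = dedupe_saddles(surface, candidates, cfg.eps, cfg.eps_g)

    basins: list[Basin] = []
    next_id = 0
    for s in saddles:
        traced = trace_basin_pair(surface, s, step=cfg.p, jitter=cfg.jitter,
                                  max_steps=cfg.max_trace_steps)
        ids = []
        for level, poly, status in traced:
            if len(poly.vertices) < 3:
                ids.append(None)
                continue
            ring = Polygon(poly.vertices)
            inside = shapely.contains_xy(ring, fit.grid.points[:, 0],
                                         fit.grid.points[:, 1])
            idx = np.flatnonzero(inside)
            if len(idx) == 0:
                ids.append(None)
                continue
            j = idx[int(np.argmin(fit.grid_energies[idx]))]
            # birth_level records the traced level (a hair below the saddle
            # energy; see trace_basin_pair)
            basins.append(Basin(
                next_id, fit.grid.points[idx], poly, float(level),
                (float(fit.grid.points[j, 0]), float(fit.grid.points[j, 1])),
                float(fit.grid_energies[j]), None,
            ))
            ids.append(next_id)
            next_id += 1
        s.basin_a, s.basin_b = ids[0], ids[1]

    h = Hierarchy(basins, saddles, minima,
                  variant_label=fit.model.samples.variant_label, method="sdr")
    h.curves = curves  # kept for plotting / diagnostics
    log.info("SDR: %d minima, %d saddles, %d traced basins",
             len(minima), len(saddles), len(basins))
    return h
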