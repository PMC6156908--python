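"""Basin-driven reconstruction: recursive sublevel-set descent.

Starting from the full grid at the maximum estimated energy ``c_max``, the
energy level ``c`` is lowered step by step (``delta2``). While the sublevel
set ``{x in S : e(x) <= c}`` stays connected nothing happens; when it splits
into k > 1 components a basin split has been detected: the components become
basins (children of the enclosing basin), working-definition saddles are
assigned between neighboring components, and the descent recurses into each
component. Three cost-control modifications apply above the low-energy detail
region (``c > c_min + c0``): a jump test that tries ``c - m*delta2`` at once
and reverts to ``c - delta2`` if the jumped sublevel set splits, and pruning
of components with fewer than ``n0`` grid points. Components that appear and
die inside an accepted jump are knowingly missed (they are small and shallow
by construction).

Connectivity of sublevel components is 8-neighbor adjacency on the regular
grid (flood fill on the raster); the alpha-convex hull is then fitted to each
component for its polygonal boundary and for saddle geometry.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .boundary import component_boundary
from .config import RunConfig
from .hierarchy import Basin, Hierarchy, SaddlePoint

log = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=int)


def level_components(fit, S: np.ndarray, c: float) -> list[np.ndarray]:
    """Connected components of the sublevel set {x in S : e(x) <= c}.

    ``S`` is an integer index array into the fit's grid. Returns a partition
    of the sublevel subset as index arrays (8-neighbor grid connectivity),
    ordered by lowest contained energy; empty list when the sublevel set is
    empty (this drives termination of the descent).
    """
    S = np.asarray(S, dtype=np.intp)
    sub = S[fit.grid_energies[S] <= c]
    if len(sub) == 0:
        return []
    mask = fit.grid.raster_mask(sub)
    labels, k = ndimage.label(mask, structure=_STRUCT8)
    lat = fit.grid.lattice[sub]
    lab = labels[lat[:, 0], lat[:, 1]]
    comps = [sub[lab == i] for i in range(1, k + 1)]
    comps.sort(key=lambda idx: (float(fit.grid_energies[idx].min()), int(idx[0])))
    return comps


def _deepest(fit, comp: np.ndarray):
    energies = fit.grid_energies[comp]
    j = int(np.argmin(energies))  # ties: lowest grid index (grid order is fixed)
    pt = fit.grid.points[comp[j]]
    return (float(pt[0]), float(pt[1])), float(energies[j])


def _make_basin(fit, comp: np.ndarray, basin_id: int, birth_level: float,
                parent_id, alpha: float) -> Basin:
    boundary = component_boundary(fit.grid.points[comp], alpha)
    deepest_point, deepest_energy = _deepest(fit, comp)
    return Basin(basin_id, fit.grid.points[comp], boundary, float(birth_level),
                 deepest_point, deepest_energy, parent_id)


def detect_saddles_between(basins: list[Basin], fit, d_th: float) -> list[SaddlePoint]:
    """Working-definition saddles between neighboring basins.

    For each unordered basin pair whose minimum boundary-vertex distance does
    not exceed ``d_th``, the midpoint of the minimum-length segment is the
    saddle; its energy is evaluated on the smoothed surface. Ties between
    vertex pairs at the same distance break to the lexicographically smallest
    pair, making the choice deterministic.
    """
    saddles: list[SaddlePoint] = []
    for a, b in itertools.combinations(basins, 2):
        va = np.asarray(a.boundary.vertices, dtype=float)
        vb = np.asarray(b.boundary.vertices, dtype=float)
        if len(va) == 0 or len(vb) == 0:
            continue
        dist, idx = cKDTree(vb).query(va)
        dmin = float(dist.min())
        if dmin > d_th:
            continue
        tied = np.flatnonzero(dist <= dmin + 1e-12)
        pairs = sorted(
            (tuple(va[i]) + tuple(vb[idx[i]]) for i in tied)
        )
        x1, y1, x2, y2 = pairs[0]
        mid = np.array([(x1 + x2) / 2.0, (y1 + y2) / 2.0])
        vals, valid = fit.surface.estimate(mid[None, :])
        if valid[0]:
            v = float(vals[0])
        else:  # midpoint fell in an unsampled gap: nearest grid estimate
            v = float(fit.grid_energies[fit.grid.tree.query(mid)[1]])
        saddles.append(SaddlePoint((float(mid[0]), float(mid[1])), v,
                                   "bdr_midpoint", a.id, b.id))
    return saddles


def bdr_reconstruct(fit, config: RunConfig | None = None) -> Hierarchy:
    """Run the full basin-driven reconstruction on a landscape fit.

    Returns a :class:`~landscaper.hierarchy.Hierarchy` whose root basin is the
    whole grid at ``c_max``; every split adds child basins and the pairwise
    working-definition saddles between them. The recursion is realized with an
    explicit work stack (no recursion-depth limit).
    """
    cfg = config or fit.config
    delta2, m = cfg.delta2, cfg.m
    c_min, c_max = fit.c_min, fit.c_max
    cutoff = c_min + cfg.c0

    hierarchy_basins: list[Basin] = []
    hierarchy_saddles: list[SaddlePoint] = []
    all_idx = np.arange(len(fit.grid), dtype=np.intp)
    root = _make_basin(fit, all_idx, 0, c_max, None, cfg.alpha)
    hierarchy_basins.append(root)
    next_id = 1
    n_level_evals = 0

    # work stack of (basin id, its grid subset, current level)
    stack: list[tuple[int, np.ndarray, float]] = [(0, all_idx, c_max)]
    while stack:
        bid, S, c = stack.pop()
        while True:
            comps = level_components(fit, S, c)
            n_level_evals += 1
            if not comps:
                break  # no grid points remain below c: this branch bottomed out
            if len(comps) == 1:
                S = comps[0]
                if c > cutoff and m > 1:
                    jumped = level_components(fit, S, c - m * delta2)
                    n_level_evals += 1
                    if len(jumped) == 1:
                        c = c - m * delta2
                        S = jumped[0]
                        continue
                    # the jump missed a split (or emptied the set): revert
                c = c - delta2
                continue
            # basin split detected: the components become basins
            children = []
            for comp in comps:
                child = _make_basin(fit, comp, next_id, c, bid, cfg.alpha)
                next_id += 1
                children.append(child)
            hierarchy_basins.extend(children)
            hierarchy_saddles.extend(detect_saddles_between(children, fit, cfg.d_th))
            for child, comp in zip(children, comps):
                if c > cutoff and len(comp) < cfg.n0:
                    continue  # small high-energy basin: do not dig further
                stack.append((child.id, comp, c - delta2))
            break

    h = Hierarchy(hierarchy_basins, hierarchy_saddles,
                  variant_label=fit.model.samples.variant_label, method="bdr")
    h.n_level_evals = n_level_evals  # descent-cost diagnostic
    log.info("BDR: %d basins (%d leaves), %d saddles, %d level evaluations",
             len(h.basins), len(h.leaves()), len(h.saddles), n_level_evals)
    return h
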