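"""Saddle-driven reconstruction machinery, checked on analytic surfaces.

Most operations here accept any C^2 surface exposing value/gradient/Hessian,
so the exact Gaussian-mixture landscapes (and hand-written quadratics) serve
as fast oracles with analytically known critical points; the full pipeline is
additionally exercised on kernel-regression fits of sampled data.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from landscaper import RunConfig, SamplingModel, draw_samples, fixture, make_two_well
from landscaper.sdr import (RGF_VARIANTS, dedupe_saddles, find_local_minima,
                            follow_reduced_gradient, leader_cluster,
                            saddle_test, trace_basin_pair)


class QuadraticSurface:
    """e(x) = x^T A x / 2 on a square domain; exact derivatives."""

    def __init__(self, a11, a22, half_width=10.0):
        self.A = np.diag([a11, a22]).astype(float)
        self.half_width = half_width

    def value_grad_hess(self, pts):
        pts = np.atleast_2d(np.asarray(pts, float))
        v = 0.5 * np.einsum("mi,ij,mj->m", pts, self.A, pts)
        g = pts @ self.A
        H = np.broadcast_to(self.A, (len(pts), 2, 2)).copy()
        return v, g, H, np.ones(len(pts), bool)

    def estimate(self, pts):
        v, _, _, valid = self.value_grad_hess(pts)
        return v, valid

    def in_region(self, pts):
        pts = np.atleast_2d(np.asarray(pts, float))
        return (np.abs(pts) <= self.half_width).all(axis=1)


# -- leader clustering --------------------------------------------------------

def test_leader_cluster_basic():
    pts = np.array([[0, 0], [0.005, 0], [1, 1]], float)
    reps, labels = leader_cluster(pts, eps=0.01)
    assert list(reps) == [0, 2]
    assert list(labels) == [0, 0, 1]


def test_leader_cluster_identical_points():
    reps, labels = leader_cluster(np.zeros((7, 2)), eps=0.1)
    assert len(reps) == 1 and set(labels) == {0}


def test_leader_cluster_joins_first_not_nearest():
    # point at 0.9 is within eps of both reps; leader clustering assigns it
    # to the *first* qualifying cluster even though the second is nearer
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.9, 0.0]])
    _, labels = leader_cluster(pts, eps=0.95)
    assert list(labels) == [0, 1, 0]


@given(st.integers(0, 500))
def test_leader_cluster_membership_radius_under_permutation(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-1, 1, size=(30, 2))
    order = rng.permutation(30)
    reps, labels = leader_cluster(pts[order], eps=0.3)
    rep_xy = pts[order][reps]
    d = np.linalg.norm(pts[order] - rep_xy[labels], axis=1)
    assert (d <= 0.3 + 1e-12).all()


# -- saddle test --------------------------------------------------------------

def test_saddle_test_canonical_saddle():
    surf = QuadraticSurface(2.0, -2.0)  # e = x^2 - y^2
    passed, lam = saddle_test(surf, np.zeros(2), eps_g=1e-3)
    assert passed
    assert lam == pytest.approx((-2.0, 2.0))


def test_saddle_test_rejects_minimum():
    surf = QuadraticSurface(2.0, 2.0)   # e = x^2 + y^2
    passed, _ = saddle_test(surf, np.zeros(2), eps_g=1e-3)
    assert not passed


def test_saddle_test_on_analytic_mixture():
    land = fixture("two_well_symmetric")
    (sloc, _), = land.critical_points()["saddles"]
    passed, lam = saddle_test(land, np.asarray(sloc), eps_g=1e-3)
    assert passed and lam[0] < 0 < lam[1]
    off = np.asarray(sloc) + [0.0, 0.5]  # off the critical point
    assert not saddle_test(land, off, eps_g=1e-3)[0]


# -- local minima -------------------------------------------------------------

def test_single_bowl_one_minimum():
    surf = QuadraticSurface(1.0, 3.0)
    rng = np.random.default_rng(0)
    seeds = rng.uniform(-5, 5, size=(100, 2))
    minima = find_local_minima(surf, seeds, eps=0.01, eps_g=1e-3, step_cap=1.0)
    assert len(minima) == 1
    assert np.hypot(*minima[0].location) < 0.01
    assert minima[0].cluster_size == 100


def test_two_well_analytic_minima_positions():
    land = fixture("two_well_symmetric")
    xs = np.linspace(*land.bounds[:2], 30)
    ys = np.linspace(*land.bounds[2:], 12)
    seeds = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
    minima = find_local_minima(land, seeds, eps=0.01, eps_g=1e-3, step_cap=1.0)
    assert len(minima) == 2
    truth = land.critical_points()["minima"]
    for m in minima:
        err = min(np.hypot(m.location[0] - x, m.location[1] - y)
                  for (x, y), _ in truth)
        assert err < 1e-2


def test_minima_stable_under_seed_density():
    land = fixture("two_well_symmetric")

    def run(n_side):
        xs = np.linspace(-12, 12, n_side)
        ys = np.linspace(-5, 5, max(3, n_side // 3))
        seeds = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
        return find_local_minima(land, seeds, eps=0.01, eps_g=1e-3, step_cap=1.0)

    sparse, dense = run(10), run(100)
    assert len(sparse) == len(dense) == 2
    for a, b in zip(sparse, dense):
        assert np.hypot(a.location[0] - b.location[0],
                        a.location[1] - b.location[1]) < 0.01


# -- reduced-gradient following ----------------------------------------------

def test_bowl_curves_exit_without_saddles():
    surf = QuadraticSurface(1.0, 2.0, half_width=3.0)
    for variant in RGF_VARIANTS:
        curve = follow_reduced_gradient(surf, np.zeros(2), variant, p=0.1,
                                        eps_g=1e-3)
        assert curve.terminated_by == "exited_grid"
        assert curve.saddle_candidates == []


@pytest.mark.parametrize("mode", ["predictor_corrector", "combined"])
def test_two_well_curves_find_the_saddle(mode):
    land = fixture("two_well_symmetric")
    (min_loc, _), _ = land.critical_points()["minima"]
    (saddle_loc, _), = land.critical_points()["saddles"]
    cands = []
    for variant in RGF_VARIANTS:
        curve = follow_reduced_gradient(land, np.asarray(min_loc), variant,
                                        p=0.1, eps_g=1e-3, mode=mode)
        cands.extend(curve.saddle_candidates)
    assert cands, "no curve reached the saddle"
    best = min(np.hypot(c[0] - saddle_loc[0], c[1] - saddle_loc[1]) for c in cands)
    assert best < 1e-2


def test_modes_agree_on_saddle_location():
    land = fixture("two_well_symmetric")
    (min_loc, _), _ = land.critical_points()["minima"]
    found = {}
    for mode in ("predictor_corrector", "combined"):
        cands = []
        for variant in RGF_VARIANTS:
            cands.extend(follow_reduced_gradient(
                land, np.asarray(min_loc), variant, p=0.1, eps_g=1e-3,
                mode=mode).saddle_candidates)
        saddles = dedupe_saddles(land, cands, eps=0.01, eps_g=1e-3)
        assert len(saddles) == 1
        found[mode] = np.asarray(saddles[0].location)
    assert np.linalg.norm(found["predictor_corrector"] - found["combined"]) < 0.01


def test_curve_points_stay_on_reduced_gradient_curve():
    land = fixture("two_well_symmetric")
    (min_loc, _), _ = land.critical_points()["minima"]
    curve = follow_reduced_gradient(land, np.asarray(min_loc), (0, +1),
                                    p=0.1, eps_g=1e-3)
    interior = curve.points[1:-1]
    if len(interior):
        g = land.gradient(interior)
        # retained component (column 0) is held near zero by the corrector
        assert np.abs(g[:, 0]).max() < 1e-3
        # consecutive spacing approximately p (within corrector adjustment)
        steps = np.linalg.norm(np.diff(curve.points, axis=0), axis=1)
        assert np.median(steps) == pytest.approx(0.1, rel=0.5)


# -- saddle dedup -------------------------------------------------------------

def test_dedupe_identical_candidates():
    land = fixture("two_well_symmetric")
    (sloc, _), = land.critical_points()["saddles"]
    cands = [np.asarray(sloc)] * 4
    saddles = dedupe_saddles(land, cands, eps=0.01, eps_g=1e-3)
    assert len(saddles) == 1
    assert saddles[0].method == "sdr_critical"
    lam = saddles[0].hessian_eigenvalues
    assert lam[0] * lam[1] < 0


def test_dedupe_empty():
    land = fixture("two_well_symmetric")
    assert dedupe_saddles(land, [], eps=0.01, eps_g=1e-3) == []


# -- basin tracing ------------------------------------------------------------

def test_traced_basins_enclose_their_minima_with_correct_area():
    from shapely.geometry import Point, Polygon

    land = fixture("two_well_symmetric")
    cps = land.critical_points()
    (sloc, se), = cps["saddles"]
    from landscaper.hierarchy import SaddlePoint
    s = SaddlePoint(tuple(sloc), se, "sdr_critical")
    traced = trace_basin_pair(land, s, step=0.1, jitter=0.2)
    assert len(traced) == 2
    enclosed = []
    for level, poly, status in traced:
        assert status == "closed"
        assert level < se
        ring = Polygon(poly.vertices)
        inside = [loc for loc, _ in cps["minima"] if ring.contains(Point(loc))]
        assert len(inside) == 1
        enclosed.append(tuple(np.round(inside[0], 6)))
        # area oracle: fine-grid flood count of {e <= level} on this side
        side = np.sign(inside[0][0])
        xs = np.arange(0.0, 14.0, 0.05) * side
        ys = np.arange(-5.5, 5.5, 0.05)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        vals = land.energy(np.column_stack([gx.ravel(), gy.ravel()]))
        area = (vals <= level).sum() * 0.05 * 0.05
        assert ring.area == pytest.approx(area, rel=0.05)
    assert len(set(enclosed)) == 2
    # symmetric mixture: traced polygons are mirror images across x=0
    areas = [Polygon(p.vertices).area for _, p, _ in traced]
    assert areas[0] == pytest.approx(areas[1], rel=0.02)


# -- full reconstruction on fitted surfaces -----------------------------------

def test_single_well_fit_reconstruction(one_well):
    _, _, fit = one_well
    h = fit.reconstruct("sdr")
    assert len(h.minima) == 1
    assert h.saddles == [] and h.basins == []


def test_two_well_fit_reconstruction(two_well, two_well_sdr):
    land, _, fit = two_well
    h = two_well_sdr
    assert len(h.minima) == 2
    assert len(h.saddles) == 1
    assert len(h.basins) == 2
    (s,) = h.saddles
    lam = s.hessian_eigenvalues
    assert lam[0] < 0 < lam[1]
    (sx, sy), _ = land.critical_points()["saddles"][0]
    assert np.hypot(s.location[0] - sx, s.location[1] - sy) <= 3 * fit.config.delta1
    # every reported minimum/saddle re-passes its gradient/Hessian test
    for m in h.minima:
        _, g, H, _ = fit.surface.value_grad_hess(np.asarray(m.location)[None])
        assert np.linalg.norm(g[0]) < fit.config.eps_g
        assert np.linalg.eigvalsh(H[0])[0] > 0
    _, g, H, _ = fit.surface.value_grad_hess(np.asarray(s.location)[None])
    assert np.linalg.norm(g[0]) < fit.config.eps_g
    assert np.prod(np.linalg.eigvalsh(H[0])) < 0
    # saddle energy above both attached minima
    assert all(s.energy > m.energy for m in h.minima)
    # each traced basin contains exactly one reported minimum
    from shapely.geometry import Point, Polygon
    for b in h.basins:
        ring = Polygon(b.boundary.vertices)
        inside = [m for m in h.minima if ring.contains(Point(m.location))]
        assert len(inside) == 1


def test_three_well_line_counts():
    land = fixture("three_well_line")
    samples = draw_samples(land, SamplingModel(n=4000, seed=11), "three")
    from landscaper import EnergyLandscape
    fit = EnergyLandscape(samples, RunConfig()).fit()
    h = fit.reconstruct("sdr")
    assert len(h.minima) == 3
    assert len(h.saddles) == 2
    assert len(h.basins) == 4  # two traced basins per saddle
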