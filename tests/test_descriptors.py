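"""Landscape descriptors, normalization and the correlation screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from landscaper import ReferenceState, correlate, minmax_normalize
from landscaper.descriptors import (DEFAULT_STATES, descriptor_table,
                                    extract_descriptors, select_on_off_saddle,
                                    state_saddle_barrier, state_saddle_distance)
from landscaper.hierarchy import SaddlePoint
from landscaper.synthetic import make_planted_tables


def _saddle(x=0.0, y=0.0, e=0.0):
    return SaddlePoint((x, y), e, "bdr_midpoint")


def test_distance_345():
    st_ = ReferenceState("On", (0.0, 0.0), -2.0)
    assert state_saddle_distance(st_, _saddle(3.0, 4.0)) == pytest.approx(5.0)


def test_distance_coincident_zero():
    st_ = ReferenceState("On", (1.0, -1.0), 0.0)
    assert state_saddle_distance(st_, _saddle(1.0, -1.0)) == 0.0


@given(st.integers(0, 300))
def test_distance_matches_formula(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=2), rng.normal(size=2)
    got = state_saddle_distance(ReferenceState("s", tuple(a), 0.0),
                                _saddle(b[0], b[1]))
    assert got == pytest.approx(float(np.sqrt(((a - b) ** 2).sum())))


def test_barrier_height_and_sign():
    st_ = ReferenceState("Off", (0, 0), 4.0)
    assert state_saddle_barrier(st_, _saddle(e=10.0)) == 6.0
    assert state_saddle_barrier(st_, _saddle(e=4.0)) == 0.0
    assert state_saddle_barrier(st_, _saddle(e=1.0)) == -3.0  # state above saddle


def test_descriptor_vector_zeros_when_states_at_saddle():
    s = _saddle(0.5, 0.5, e=-3.0)
    states = [ReferenceState(lbl, (0.5, 0.5), -3.0) for lbl in DEFAULT_STATES]
    from landscaper.hierarchy import Hierarchy
    h = Hierarchy([], [s], variant_label="v")
    vec = extract_descriptors(h, states, saddle=s)
    assert len(vec.values) == 10
    assert all(v == pytest.approx(0.0) for v in vec.values.values())


def test_descriptors_on_reconstructed_two_well(two_well, two_well_bdr):
    land, _, fit = two_well
    cps = land.critical_points()
    (m1, e1), (m2, e2) = cps["minima"]
    states = [
        ReferenceState("On", m1, e1),
        ReferenceState("Off", m2, e2),
        ReferenceState("T-", m1, e1),
        ReferenceState("R-", m2, e2),
        ReferenceState("T*-", m1, e1),
    ]
    vec = extract_descriptors(two_well_bdr, states)
    ser = vec.to_series()
    assert len(ser) == 10
    # states sit at the well minima: both d components ~ half the separation
    assert ser["d(On,Saddle)"] == pytest.approx(7.5, abs=1.0)
    # barrier positive and near the analytic value
    true_barrier = cps["saddles"][0][1] - e1
    assert ser["dE(On,Saddle)"] == pytest.approx(true_barrier, rel=0.15)


def test_reference_vs_basin_minimum_modes(two_well, two_well_bdr):
    land, _, fit = two_well
    h = two_well_bdr
    # states placed exactly at the recovered deepest points force equality
    leaves = sorted(h.leaves(), key=lambda b: b.deepest_point[0])
    states = [
        ReferenceState("On", leaves[0].deepest_point, leaves[0].deepest_energy),
        ReferenceState("Off", leaves[1].deepest_point, leaves[1].deepest_energy),
        ReferenceState("T-", leaves[0].deepest_point, leaves[0].deepest_energy),
        ReferenceState("R-", leaves[1].deepest_point, leaves[1].deepest_energy),
        ReferenceState("T*-", leaves[0].deepest_point, leaves[0].deepest_energy),
    ]
    v_ref = extract_descriptors(h, states, mode="reference").to_series()
    v_min = extract_descriptors(h, states, mode="basin_minimum").to_series()
    pd.testing.assert_series_equal(v_ref, v_min, rtol=1e-9)


def test_missing_saddle_is_an_error():
    from landscaper.hierarchy import Hierarchy
    h = Hierarchy([], [])
    states = [ReferenceState(lbl, (0, 0), 0.0) for lbl in DEFAULT_STATES]
    with pytest.raises(ValueError, match="no saddle"):
        extract_descriptors(h, states)


def test_on_off_saddle_selection(two_well, two_well_bdr):
    land, _, _ = two_well
    (m1, e1), (m2, e2) = land.critical_points()["minima"]
    on = ReferenceState("On", m1, e1)
    off = ReferenceState("Off", m2, e2)
    s = select_on_off_saddle(two_well_bdr, on, off)
    assert {s.basin_a, s.basin_b} == {b.id for b in two_well_bdr.leaves()}


# -- normalization ------------------------------------------------------------

def test_minmax_basic():
    np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])
    np.testing.assert_allclose(minmax_normalize([0.0, 0.25, 1.0]), [0.0, 0.25, 1.0])


def test_minmax_constant_rejected():
    with pytest.raises(ValueError, match="constant"):
        minmax_normalize([3.0, 3.0, 3.0])


@given(st.integers(0, 300))
def test_pearson_invariant_under_minmax(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = 0.3 * x + rng.normal(size=12)
    r_raw = np.corrcoef(x, y)[0, 1]
    r_norm = np.corrcoef(minmax_normalize(x), minmax_normalize(y))[0, 1]
    assert abs(r_raw - r_norm) < 1e-12


# -- correlation screen -------------------------------------------------------

def _tables(n=15, seed=0):
    desc_names = [f"{k}({s},Saddle)" for s in DEFAULT_STATES for k in ("d", "dE")]
    param_names = [f"P{i}" for i in range(10)]
    planted = {"P7": ("d(R-,Saddle)", -1.2), "P0": ("dE(Off,Saddle)", 0.8)}
    desc, params = make_planted_tables(n, desc_names, param_names, planted,
                                       seed=seed)
    return desc, params, planted


def test_identical_and_negated_columns():
    desc, params, _ = _tables()
    params["P5"] = desc["d(On,Saddle)"]
    params["P6"] = -desc["d(On,Saddle)"]
    rep = correlate(desc, params)
    t = rep.table.set_index(["descriptor", "parameter"])["r"]
    assert t.loc[("d(On,Saddle)", "P5")] == pytest.approx(1.0)
    assert t.loc[("d(On,Saddle)", "P6")] == pytest.approx(-1.0)


def test_planted_screen_recovers_exactly_the_planted_pairs():
    desc, params, planted = _tables()
    rep = correlate(desc, params, threshold=0.5)
    sel = {(row.descriptor, row.parameter) for row in rep.selected.itertuples()}
    want = {(d, p) for p, (d, _) in planted.items()}
    assert sel == want
    # signs retained
    r_p7 = rep.table.query("descriptor == 'd(R-,Saddle)' and parameter == 'P7'")
    assert float(r_p7["r"].iloc[0]) == pytest.approx(-1.0, abs=1e-9)


def test_pearson_matches_covariance_formula():
    desc, params, _ = _tables()
    rep = correlate(desc, params)
    for row in rep.table.itertuples():
        x = desc[row.descriptor].to_numpy()
        y = params[row.parameter].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        want = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert abs(row.r - want) < 1e-12


def test_screen_invariant_under_normalization():
    desc, params, _ = _tables()
    desc_n = desc.apply(lambda c: pd.Series(minmax_normalize(c), index=c.index))
    params_n = params.apply(lambda c: pd.Series(minmax_normalize(c), index=c.index))
    r1 = correlate(desc, params).table["r"].to_numpy()
    r2 = correlate(desc_n, params_n).table["r"].to_numpy()
    np.testing.assert_allclose(r1, r2, atol=1e-12)


def test_correlation_symmetry():
    desc, params, _ = _tables()
    a = correlate(desc, params).table.set_index(["descriptor", "parameter"])["r"]
    b = correlate(params, desc).table.set_index(["descriptor", "parameter"])["r"]
    for (d, p), r in a.items():
        assert b.loc[(p, d)] == pytest.approx(r, abs=1e-12)


def test_threshold_monotonicity():
    desc, params, _ = _tables()
    n_rows = [len(correlate(desc, params, threshold=t).selected)
              for t in (0.2, 0.5, 0.8, 0.99)]
    assert all(a >= b for a, b in zip(n_rows, n_rows[1:]))


def test_mismatched_variant_labels_listed():
    desc, params, _ = _tables()
    params = params.rename(index={"V3": "V99"})
    with pytest.raises(ValueError) as err:
        correlate(desc, params)
    assert "V3" in str(err.value) and "V99" in str(err.value)


def test_pairwise_complete_missing_values():
    desc, params, _ = _tables()
    params.loc["V2", "P1"] = np.nan
    rep = correlate(desc, params)
    n = rep.table.query("parameter == 'P1'")["n"]
    assert (n == 14).all()
    assert (rep.table.query("parameter == 'P0'")["n"] == 15).all()


def test_pivot_shape(two_well_bdr):
    desc, params, _ = _tables()
    rep = correlate(desc, params)
    piv = rep.pivot()
    assert set(piv.columns) == {"d(State,Saddle)", "dE(State,Saddle)"}
    assert "P7(-1.00)" in piv.loc["R-", "d(State,Saddle)"]


def test_descriptor_table_stacking():
    from landscaper.descriptors import DescriptorVector
    vecs = [DescriptorVector(f"V{i}", {(s, k): float(i)
                                       for s in DEFAULT_STATES
                                       for k in ("d", "dE")})
            for i in range(3)]
    tab = descriptor_table(vecs)
    assert tab.shape == (3, 10)
    assert list(tab.index) == ["V0", "V1", "V2"]
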