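"""Landscape descriptors and correlation mining against parameter tables.

A reconstructed landscape is summarized by 10 descriptors: for each of the
five tracked reference states, the Euclidean distance in PC1-PC2 space from
the state to the saddle separating the On and Off basins, d(State, Saddle),
and the barrier height dE(State, Saddle) = E(Saddle) - E(State). Descriptor
vectors across protein variants are then screened against tables of
per-variant biochemical parameters by Pearson correlation; entries with
|r| at or above the threshold (default 0.5) are reported with their sign.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .hierarchy import Basin, Hierarchy, SaddlePoint
from .samples import ReferenceState

log = logging.getLogger(__name__)

DEFAULT_STATES = ("On", "Off", "T-", "R-", "T*-")


def state_saddle_distance(state: ReferenceState, saddle: SaddlePoint) -> float:
    """Euclidean PC-space distance between a state and a saddle."""
    dx = np.asarray(state.location, float) - np.asarray(saddle.location, float)
    return float(np.hypot(dx[0], dx[1]))


def state_saddle_barrier(state: ReferenceState, saddle: SaddlePoint) -> float:
    """Barrier height E(Saddle) - E(State); negative if the state lies above."""
    return float(saddle.energy - state.energy)


@dataclass
class DescriptorVector:
    """The 10 per-variant landscape descriptors (d and dE per state)."""

    variant_label: str
    values: dict  # (state label, "d"|"dE") -> float (NaN when unmapped)

    def to_series(self) -> pd.Series:
        data = {f"{kind}({state},Saddle)": val
                for (state, kind), val in self.values.items()}
        return pd.Series(data, name=self.variant_label)


def _containing_basin(h: Hierarchy, location) -> Basin | None:
    """Smallest basin whose boundary polygon contains the location."""
    x, y = float(location[0]), float(location[1])
    candidates = []
    for b in h.basins:
        if not b.boundary.closed or len(b.boundary.vertices) < 3:
            continue
        if shapely.intersects_xy(Polygon(b.boundary.vertices), x, y):
            candidates.append(b)
    if not candidates:
        return None
    return min(candidates, key=lambda b: (b.n_grid_points or np.inf,
                                          Polygon(b.boundary.vertices).area))


def select_on_off_saddle(h: Hierarchy, on: ReferenceState,
                         off: ReferenceState) -> SaddlePoint:
    """The saddle separating the basins containing the On and Off states.

    The saddle recorded at the split separating the two states' basins (its
    referenced basins are ancestors of exactly one of the two containing
    basins each); falls back to the lowest-energy saddle when the states
    cannot both be mapped into basins.
    """
    if not h.saddles:
        raise ValueError(
            "hierarchy contains no saddle; run a reconstruction that "
            "produced at least one basin split first"
        )
    basin_on = _containing_basin(h, on.location)
    basin_off = _containing_basin(h, off.location)
    if basin_on is not None and basin_off is not None and basin_on.id != basin_off.id:
        anc_on = set(h.ancestors(basin_on.id))
        anc_off = set(h.ancestors(basin_off.id))
        matches = [
            s for s in h.saddles
            if s.basin_a is not None and s.basin_b is not None
            and ((s.basin_a in anc_on and s.basin_b in anc_off)
                 or (s.basin_b in anc_on and s.basin_a in anc_off))
        ]
        if matches:
            return min(matches, key=lambda s: s.energy)
    log.warning("could not map On/Off states to distinct basins; "
                "falling back to the lowest-energy saddle")
    return min(h.saddles, key=lambda s: s.energy)


def extract_descriptors(h: Hierarchy, states, saddle: SaddlePoint | None = None,
                        mode: str = "reference") -> DescriptorVector:
    """Build the 10-component descriptor vector for one variant.

    ``states`` are the five tracked reference states (must include labels
    "On" and "Off" unless ``saddle`` is given explicitly). ``mode`` selects
    the state representation: ``"reference"`` uses the experimentally known
    conformation's location and energy; ``"basin_minimum"`` maps each state
    to the deepest point of the basin containing it. States that fall
    outside every basin in basin_minimum mode yield NaN components (logged).
    """
    if mode not in ("reference", "basin_minimum"):
        raise ValueError(f"unknown descriptor mode {mode!r}")
    states = list(states)
    if saddle is None:
        by_label = {s.label: s for s in states}
        if "On" not in by_label or "Off" not in by_label:
            raise ValueError("need On and Off states to select the saddle")
        saddle = select_on_off_saddle(h, by_label["On"], by_label["Off"])
    values = {}
    for st in states:
        rep = st
        if mode == "basin_minimum":
            basin = _containing_basin(h, st.location)
            if basin is None:
                log.warning("state %s lies outside every basin; descriptor "
                            "components flagged missing", st.label)
                values[(st.label, "d")] = float("nan")
                values[(st.label, "dE")] = float("nan")
                continue
            rep = ReferenceState(st.label,
                                 (float(basin.deepest_point[0]),
                                  float(basin.deepest_point[1])),
                                 float(basin.deepest_energy))
        values[(st.label, "d")] = state_saddle_distance(rep, saddle)
        values[(st.label, "dE")] = state_saddle_barrier(rep, saddle)
    return DescriptorVector(h.variant_label, values)


def descriptor_table(vectors) -> pd.DataFrame:
    """Stack per-variant descriptor vectors into a variants x 10 table."""
    return pd.DataFrame([v.to_series() for v in vectors])


def minmax_normalize(values) -> np.ndarray:
    """Rescale to [0, 1] as (x - min) / (max - min).

    Raises for constant input, where the normalization is undefined.
    Pearson correlation is invariant under this (affine) rescaling.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if not hi > lo:
        raise ValueError("constant vector: min-max normalization undefined")
    return (x - lo) / (hi - lo)


@dataclass
class CorrelationReport:
    """All descriptor-parameter Pearson correlations plus the screen."""

    table: pd.DataFrame       # rows: state, kind, descriptor, parameter, r, n, selected
    threshold: float

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    def pivot(self) -> pd.DataFrame:
        """State x (d, dE) grid listing the selected parameters with signed r."""
        rows = {}
        for state in self.table["state"].unique():
            row = {}
            for kind in ("d", "dE"):
                sel = self.selected
                sub = sel[(sel["state"] == state) & (sel["kind"] == kind)]
                sub = sub.reindex(sub["r"].abs().sort_values(ascending=False).index)
                row[f"{kind}(State,Saddle)"] = ", ".join(
                    f"{p}({r:+.2f})" for p, r in zip(sub["parameter"], sub["r"])
                ) or "-"
            rows[state] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def correlate(descriptors: pd.DataFrame, parameters: pd.DataFrame,
              threshold: float = 0.5) -> CorrelationReport:
    """Pearson-correlation screen of descriptors against parameters.

    Both tables are indexed by variant label and must align exactly.
    Correlations are computed pairwise-complete (rows with a missing value in
    either column are dropped for that pair; the per-pair n is reported).
    The screen keeps |r| >= threshold, retaining the sign of r.
    """
    missing = sorted(set(descriptors.index) ^ set(parameters.index))
    if missing:
        raise ValueError(f"variant labels do not align; mismatches: {missing}")
    parameters = parameters.loc[descriptors.index]
    if len(descriptors) < 3:
        raise ValueError("need at least 3 aligned variants")
    for name, table in (("descriptor", descriptors), ("parameter", parameters)):
        const = [c for c in table.columns
                 if table[c].nunique(dropna=True) <= 1]
        if const:
            raise ValueError(f"constant {name} columns (correlation undefined): {const}")
    rows = []
    for dcol, pcol in itertools.product(descriptors.columns, parameters.columns):
        x = descriptors[dcol].to_numpy(float)
        y = parameters[pcol].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        else:
            r = float("nan")
        kind, rest = dcol.split("(", 1) if "(" in dcol else ("", dcol)
        state = rest.split(",")[0] if "(" in dcol else dcol
        rows.append({"state": state, "kind": kind, "descriptor": dcol,
                     "parameter": pcol, "r": r, "n": n,
                     "selected": bool(np.isfinite(r) and abs(r) >= threshold)})
    return CorrelationReport(pd.DataFrame(rows), threshold)
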