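"""Design-matrix construction: Shannon index, rotation rule, climate windows,
nearest-grid matching, log ratio and exclusion rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from soctrend.covariates import (
    AnalysisConfig,
    assign_grid_points,
    build_design,
    classify_rotation,
    climate_delta,
    nearest_grid_point,
    shannon_index,
    soc_fine_log_ratio,
)


class TestShannonIndex:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"cereals": 9}, 0.0),
            ({"cereals": 3, "grasses": 3, "oilseeds": 3}, math.log(3)),
            ({"cereals": 5, "grasses": 4}, 0.6870),
            ({"cereals": 3, "legumes": 2, "oilseeds": 2, "grasses": 2}, 1.3689),
        ],
    )
    def test_closed_form_values(self, counts, expected):
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-4)

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            shannon_index({})

    @given(
        counts=hst.lists(hst.integers(min_value=1, max_value=20), min_size=1, max_size=7),
        data=hst.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_bounded(self, counts, data):
        groups = [f"g{i}" for i in range(len(counts))]
        h = shannon_index(dict(zip(groups, counts)))
        perm = data.draw(hst.permutations(counts))
        assert shannon_index(dict(zip(groups, perm))) == pytest.approx(h)
        assert 0.0 <= h <= math.log(len(counts)) + 1e-12
        # maximal iff uniform
        if len(set(counts)) == 1 and len(counts) > 1:
            assert h == pytest.approx(math.log(len(counts)))


class TestRotationClassifier:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["grasses"] * 9, "Perennial"),
            (["cereals"] * 9, "Annual"),
            (["cereals"] * 5 + ["grasses"] * 4, "Rotation"),
            (["cereals"] * 3 + ["legumes"] * 2 + ["oilseeds"] * 2 + ["grasses"] * 2, "Diverse"),
            # exactly 80% perennial with H <= 0.8: strict ">" falls through to Rotation
            (["grasses"] * 8 + ["cereals"] * 2, "Rotation"),
            (["cereals"] * 8 + ["grasses"] * 2, "Rotation"),
        ],
    )
    def test_rule_table(self, labels, expected):
        assert classify_rotation(labels).label == expected

    def test_worked_rotation_example_details(self):
        rc = classify_rotation(["cereals"] * 5 + ["grasses"] * 4)
        assert rc.shannon_h == pytest.approx(0.6870, abs=1e-4)
        assert rc.annual_share == pytest.approx(5 / 9)
        assert rc.perennial_share == pytest.approx(4 / 9)

    def test_unmapped_label_named_in_error(self):
        with pytest.raises(ValueError, match="ruis"):
            classify_rotation(["cereals", "ruis"])

    def test_group_map_applied(self):
        rc = classify_rotation(["barley"] * 9, group_map={"barley": "cereals"})
        assert rc.label == "Annual"

    @given(
        hst.lists(
            hst.sampled_from(["cereals", "legumes", "oilseeds", "grasses", "green fallow"]),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_total_function_onto_four_labels(self, labels):
        assert classify_rotation(labels).label in {"Annual", "Perennial", "Diverse", "Rotation"}


def _grid_frame(coords):
    rows = []
    for gid, (e, n) in enumerate(coords):
        rows.append({"grid_point_id": gid, "easting": e, "northing": n, "year": 2000, "month": 5,
                     "temperature": 10.0, "precipitation": 50.0})
    return pd.DataFrame(rows)


class TestNearestGridPoint:
    def test_coincident_point(self):
        grid = _grid_frame([(0, 0), (10, 10)])
        assert nearest_grid_point(10, 10, grid) == 1

    def test_equidistant_tie_breaks_to_lower_id(self):
        grid = _grid_frame([(0, 0), (2, 0)])
        assert nearest_grid_point(1.0, 0.0, grid) == 0

    def test_matches_bruteforce_scan(self, rng):
        coords = rng.uniform(0, 100, size=(30, 2))
        grid = _grid_frame([tuple(c) for c in coords])
        plots = pd.DataFrame(
            {"easting": rng.uniform(0, 100, 100), "northing": rng.uniform(0, 100, 100)}
        )
        got = assign_grid_points(plots, grid)
        for i, row in plots.iterrows():
            d = np.hypot(coords[:, 0] - row.easting, coords[:, 1] - row.northing)
            best = int(np.flatnonzero(d == d.min()).min())
            assert got[i] == best


def _series(temp_fn, precip=50.0, years=range(1989, 2019)):
    rows = []
    for y in years:
        for m in (5, 6, 7, 8, 9):
            rows.append(
                {"year": y, "month": m, "temperature": temp_fn(y, m), "precipitation": precip}
            )
    return pd.DataFrame(rows)


class TestClimateDelta:
    def test_constant_series_gives_zero(self):
        s = _series(lambda y, m: 12.0)
        assert climate_delta(s, "temperature") == pytest.approx(0.0)
        assert climate_delta(s, "precipitation") == pytest.approx(0.0)

    def test_linear_trend_closed_form(self):
        # summertime mean a + 0.1 (y - 1989): the two 21-year windows are
        # offset by exactly 9 years, so the delta is 0.1 * 9
        s = _series(lambda y, m: 5.0 + 0.1 * (y - 1989))
        assert climate_delta(s, "temperature") == pytest.approx(0.9, abs=1e-12)

    def test_linearity_and_shift_invariance(self):
        s = _series(lambda y, m: 5.0 + 0.07 * (y - 1989) + (m - 7) * 0.5)
        base = climate_delta(s, "temperature")
        s2 = s.assign(temperature=3.0 * s["temperature"] + 11.0)
        assert climate_delta(s2, "temperature") == pytest.approx(3.0 * base)

    def test_missing_months_reported(self):
        s = _series(lambda y, m: 10.0)
        s = s[~((s.year == 2001) & (s.month == 7))]
        with pytest.raises(ValueError, match="2001"):
            climate_delta(s, "temperature")

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            climate_delta(_series(lambda y, m: 1.0), "humidity")


class TestLogRatio:
    @pytest.mark.parametrize(
        "soc, fine, expected",
        [(30, 600, -2.9957), (50, 250, -1.6094), (100, 100, 0.0)],
    )
    def test_values(self, soc, fine, expected):
        assert soc_fine_log_ratio(soc, fine) == pytest.approx(expected, abs=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            soc_fine_log_ratio(0.0, 100.0)


def _toy_tables(socs):
    n = len(socs)
    plots = pd.DataFrame(
        {
            "plot_id": range(n),
            "group_id": [0, 1] * (n // 2) + [0] * (n % 2),
            "easting": np.linspace(0, 10, n),
            "northing": np.zeros(n),
            "soc_t0": socs,
            "soc_t1": [s - 1.0 for s in socs],
            "fine_fraction": [600.0] * n,
            "farm_type": ["plant"] * n,
        }
    )
    crops = pd.DataFrame(
        [(pid, y, "cereals") for pid in range(n) for y in range(2010, 2019)],
        columns=["plot_id", "year", "crop_group"],
    )
    grid = _series(lambda y, m: 10.0).assign(grid_point_id=0, easting=0.0, northing=0.0)
    return plots, crops, grid


class TestBuildDesign:
    def test_organic_soil_excluded(self):
        # 130 g/kg SOC is ~22% organic matter via the 1.724 conversion
        plots, crops, grid = _toy_tables([30.0, 40.0, 130.0, 25.0, 35.0])
        design, excl = build_design(plots, crops, grid)
        assert len(design) == 4
        assert excl.to_dict("records") == [{"plot_id": 2, "reason": "organic_soil"}]

    def test_missing_crop_history_logged_not_silent(self):
        plots, crops, grid = _toy_tables([30.0, 40.0, 25.0, 35.0])
        crops = crops[crops.plot_id != 1]
        design, excl = build_design(plots, crops, grid)
        assert 1 not in set(design.plot_id)
        assert ("missing_crop_history" == excl.set_index("plot_id").loc[1, "reason"])

    def test_centering_and_determinism(self):
        plots, crops, grid = _toy_tables([30.0, 40.0, 25.0, 35.0])
        d1, _ = build_design(plots, crops, grid)
        d2, _ = build_design(plots, crops, grid)
        assert abs(d1["log_ratio_centered"].mean()) < 1e-12
        pd.testing.assert_frame_equal(d1, d2)

    def test_uncentered_option_keeps_raw_log_ratio(self):
        plots, crops, grid = _toy_tables([30.0, 40.0, 25.0, 35.0])
        d, _ = build_design(plots, crops, grid, AnalysisConfig(center_log_ratio=False))
        assert d["log_ratio_centered"].iloc[0] == pytest.approx(np.log(30.0 / 600.0))

    def test_at_most_one_rotation_dummy(self, design):
        dummies = design[["rot_per", "rot_div", "rot_rot"]].sum(axis=1)
        assert dummies.isin([0, 1]).all()
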