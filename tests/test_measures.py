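"""Access measures: spatial join, ratios, per-capita, intensity, and the
supermarket-distance shares."""

import numpy as np
import pandas as pd
import pytest
from shapely import affinity
from shapely.geometry import box

from foodaccess.measures import (
    access_measure_table,
    count_outlets_by_tract,
    intensity,
    per_capita,
    relative_environment,
    share_beyond,
)

MILE_M = 1609.344


def _classified(rows):
    return pd.DataFrame(
        [
            {"outlet_id": f"O{i}", "x": x, "y": y, "group": g}
            for i, (x, y, g) in enumerate(rows)
        ]
    )


def _two_tracts():
    return pd.DataFrame(
        {
            "tract_id": ["001", "002"],
            "geometry": [box(0, 0, 1, 1), box(1, 0, 2, 1)],
        }
    )


class TestCountByTract:
    def test_interior_point_counted(self):
        tracts = _two_tracts()
        c = count_outlets_by_tract(
            _classified([(0.5, 0.5, "aapi_restaurants")]), tracts
        )
        assert c.set_index("tract_id").loc["001", "n_aapi_rest"] == 1

    def test_boundary_point_tie_break_smallest_id(self):
        tracts = _two_tracts()
        c = count_outlets_by_tract(
            _classified([(1.0, 0.5, "aapi_groceries")]), tracts
        ).set_index("tract_id")
        assert c.loc["001", "n_aapi_groc"] == 1
        assert c.loc["002", "n_aapi_groc"] == 0

    def test_outside_outlets_dropped(self):
        tracts = _two_tracts()
        c = count_outlets_by_tract(
            _classified([(10.0, 10.0, "aapi_restaurants")]), tracts
        )
        assert c[["n_aapi_rest"]].to_numpy().sum() == 0

    def test_ten_outlets_in_one_tract(self, small_county):
        tracts = _two_tracts()
        rows = [(0.1 + 0.08 * i, 0.5, "non_aapi_restaurants") for i in range(10)]
        c = count_outlets_by_tract(_classified(rows), tracts).set_index("tract_id")
        assert c.loc["001"].sum() == 10


class TestRatios:
    def test_worked_examples(self):
        counts = pd.DataFrame(
            {
                "tract_id": ["a", "b", "c"],
                "n_aapi_rest": [4, 0, 3],
                "n_nonaapi_rest": [16, 5, 0],
                "n_aapi_groc": [0, 0, 0],
                "n_nonaapi_groc": [0, 0, 0],
            }
        )
        r = relative_environment(counts)
        assert r["rest_ratio"].tolist()[:2] == [0.25, 0.0]
        assert np.isnan(r["rest_ratio"].iloc[2])
        assert bool(r["rest_ratio_missing"].iloc[2])
        # groceries: (0,0) -> 0 everywhere
        assert (r["groc_ratio"] == 0).all()

    def test_scale_invariance(self):
        base = pd.DataFrame(
            {
                "tract_id": ["a"],
                "n_aapi_rest": [3],
                "n_nonaapi_rest": [7],
                "n_aapi_groc": [2],
                "n_nonaapi_groc": [5],
            }
        )
        scaled = base.copy()
        for c in base.columns[1:]:
            scaled[c] = base[c] * 13
        r1, r2 = relative_environment(base), relative_environment(scaled)
        assert r1["rest_ratio"].iloc[0] == pytest.approx(r2["rest_ratio"].iloc[0])
        assert r1["groc_ratio"].iloc[0] == pytest.approx(r2["groc_ratio"].iloc[0])


class TestPerCapita:
    def test_worked_examples(self):
        counts = pd.DataFrame(
            {
                "tract_id": ["a", "b", "c"],
                "n_aapi_rest": [9, 0, 2],
                "n_nonaapi_rest": [0, 0, 0],
                "n_aapi_groc": [0, 0, 0],
                "n_nonaapi_groc": [0, 0, 0],
            }
        )
        r = per_capita(counts, [1000, 0, 0])
        assert r["rest_per_aapi"].iloc[0] == pytest.approx(0.009)  # 9 per 1000
        assert r["rest_per_aapi"].iloc[1] == 0.0
        assert np.isnan(r["rest_per_aapi"].iloc[2])
        assert bool(r["rest_per_aapi_missing"].iloc[2])

    def test_negative_population_rejected(self):
        counts = pd.DataFrame(
            {"tract_id": ["a"], "n_aapi_rest": [1], "n_nonaapi_rest": [0],
             "n_aapi_groc": [0], "n_nonaapi_groc": [0]}
        )
        with pytest.raises(ValueError):
            per_capita(counts, [-5])


class TestIntensity:
    def test_concentration_and_symmetry(self):
        counts = pd.DataFrame(
            {
                "tract_id": list("abcd"),
                "n_aapi_rest": [1, 1, 1, 1],
                "n_nonaapi_rest": [0] * 4,
                "n_aapi_groc": [7, 0, 0, 0],
                "n_nonaapi_groc": [0] * 4,
            }
        )
        r = intensity(counts)
        assert r["groc_intensity"].iloc[0] == 1.0
        assert (r["rest_intensity"] == 0.25).all()

    def test_normalization_on_generated_county(self, small_county):
        from foodaccess.classify import Lexicon, classify_outlets

        classified, _ = classify_outlets(
            small_county.outlets, Lexicon.default(), small_county.resolutions
        )
        counts = count_outlets_by_tract(classified, small_county.tracts)
        r = intensity(counts)
        assert r["rest_intensity"].sum() == pytest.approx(1.0)
        assert r["groc_intensity"].sum() == pytest.approx(1.0)

    def test_all_zero_county_warns(self):
        counts = pd.DataFrame(
            {"tract_id": ["a"], "n_aapi_rest": [0], "n_nonaapi_rest": [0],
             "n_aapi_groc": [0], "n_nonaapi_groc": [0]}
        )
        with pytest.warns(UserWarning):
            r = intensity(counts)
        assert (r[["rest_intensity", "groc_intensity"]] == 0).all().all()


class TestShareBeyond:
    def _tract_and_points(self, dists_miles):
        tracts = pd.DataFrame(
            {"tract_id": ["t"], "geometry": [box(0, 0, 5000, 5000)],
             "pop_total": [300], "pop_aapi": [30]}
        )
        pts = pd.DataFrame(
            {
                "tract_id": "t",
                "x": [d * MILE_M for d in dists_miles],
                "y": 0.0,
                "weight_total": 100.0,
                "weight_aapi": 10.0,
            }
        )
        return tracts, pts

    def test_hand_counted_share(self):
        # equal-weight points at 0.2, 0.4, 0.9 miles; threshold half a mile
        tracts, pts = self._tract_and_points([0.2, 0.4, 0.9])
        sm = pd.DataFrame({"supermarket_id": ["s"], "x": [0.0], "y": [0.0]})
        r = share_beyond(tracts, pts, sm, threshold=0.5 * MILE_M)
        assert r["fara_ct"].iloc[0] == pytest.approx(100 / 3)
        assert r["fara_aapi"].iloc[0] == pytest.approx(100 / 3)

    def test_colocated_supermarket_gives_zero(self):
        tracts, pts = self._tract_and_points([0.2, 0.4, 0.9])
        sm = pd.DataFrame(
            {"supermarket_id": list("abc"), "x": pts["x"], "y": pts["y"]}
        )
        r = share_beyond(tracts, pts, sm)
        assert r["fara_ct"].iloc[0] == 0.0

    def test_no_supermarkets_gives_100(self):
        tracts, pts = self._tract_and_points([0.2])
        r = share_beyond(tracts, pts, pd.DataFrame(columns=["supermarket_id", "x", "y"]))
        assert r["fara_ct"].iloc[0] == 100.0

    def test_zero_population_is_missing(self):
        tracts, pts = self._tract_and_points([0.2])
        pts["weight_total"] = 0.0
        pts["weight_aapi"] = 0.0
        sm = pd.DataFrame({"supermarket_id": ["s"], "x": [0.0], "y": [0.0]})
        r = share_beyond(tracts, pts, sm)
        assert np.isnan(r["fara_ct"].iloc[0])

    def test_invalid_threshold_rejected(self):
        tracts, pts = self._tract_and_points([0.2])
        with pytest.raises(ValueError):
            share_beyond(tracts, pts, pd.DataFrame(columns=["x", "y"]), threshold=0)


def test_translation_invariance(small_county):
    """Rigidly translating every geometry leaves all measures unchanged."""
    from foodaccess.classify import Lexicon, classify_outlets

    classified, _ = classify_outlets(
        small_county.outlets, Lexicon.default(), small_county.resolutions
    )
    dx, dy = 12345.0, -9876.0
    t2 = small_county.tracts.copy()
    t2["geometry"] = [
        affinity.translate(g, dx, dy) for g in small_county.tracts["geometry"]
    ]
    c2 = classified.copy()
    c2["x"] += dx
    c2["y"] += dy
    pp2 = small_county.pop_points.copy()
    pp2["x"] += dx
    pp2["y"] += dy
    sm2 = small_county.supermarkets.copy()
    sm2["x"] += dx
    sm2["y"] += dy
    a = access_measure_table(
        classified, small_county.tracts, small_county.pop_points,
        small_county.supermarkets,
    )
    b = access_measure_table(c2, t2, pp2, sm2)
    pd.testing.assert_frame_equal(a, b)
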