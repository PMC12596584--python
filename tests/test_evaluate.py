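import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from geoloci import (
    CoordinateSet,
    error_surface,
    haversine_km,
    render_reports,
    summarize_errors,
)
from geoloci.errors import DegenerateGeometryError, InputError

lon_st = st.floats(-179.0, 179.0)
lat_st = st.floats(-89.0, 89.0)


def _law_of_cosines_km(p1, p2):
    lam1, phi1 = np.radians(p1)
    lam2, phi2 = np.radians(p2)
    c = np.sin(phi1) * np.sin(phi2) + np.cos(phi1) * np.cos(phi2) * np.cos(lam2 - lam1)
    return 6371.0 * np.arccos(np.clip(c, -1.0, 1.0))


class TestHaversine:
    def test_analytic_cases(self):
        assert haversine_km((10.0, 20.0), (10.0, 20.0)) == 0.0
        assert haversine_km((0.0, 0.0), (180.0, 0.0)) == pytest.approx(
            np.pi * 6371.0, abs=1e-3
        )
        assert haversine_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(111.195, abs=1e-3)

    def test_matches_law_of_cosines_oracle(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-180, 180, 1000), rng.uniform(-89, 89, 1000)])
        qts = np.column_stack([rng.uniform(-180, 180, 1000), rng.uniform(-89, 89, 1000)])
        d1 = haversine_km(pts, qts)
        d2 = np.array([_law_of_cosines_km(p, q) for p, q in zip(pts, qts)])
        keep = d2 > 1.0
        np.testing.assert_allclose(d1[keep], d2[keep], rtol=1e-6)

    @given(lon_st, lat_st, lon_st, lat_st)
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_nonnegativity(self, lon1, lat1, lon2, lat2):
        d = haversine_km((lon1, lat1), (lon2, lat2))
        assert d >= 0
        assert d == pytest.approx(haversine_km((lon2, lat2), (lon1, lat1)), abs=1e-9)

    def test_triangle_inequality_random_triples(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            a, b, c = [(rng.uniform(-180, 180), rng.uniform(-89, 89)) for _ in range(3)]
            assert haversine_km(a, c) <= haversine_km(a, b) + haversine_km(b, c) + 1e-6

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            haversine_km((0.0, 95.0), (0.0, 0.0))


def _cs(ids, lonlat):
    lonlat = np.asarray(lonlat, float)
    return CoordinateSet(np.asarray(ids, dtype=object), lonlat[:, 0], lonlat[:, 1])


class TestSummarizeErrors:
    def test_exact_predictions_zero_summary(self):
        C = _cs(["a", "b"], [[-92.0, 35.0], [-91.0, 36.0]])
        s = summarize_errors(C, C)
        assert s.mean_km == 0 and s.median_km == 0 and s.sd_km == 0

    def test_hand_arithmetic_two_samples(self):
        truths = _cs(["a", "b"], [[0.0, 0.0], [10.0, 0.0]])
        # displace along the equator: 1° ≈ 111.195 km
        km_per_deg = np.pi * 6371.0 / 180.0
        preds = _cs(
            ["a", "b"], [[10.0 / km_per_deg, 0.0], [10.0 + 30.0 / km_per_deg, 0.0]]
        )
        s = summarize_errors(preds, truths)
        assert s.mean_km == pytest.approx(20.0, rel=1e-6)
        assert s.sd_km == pytest.approx(np.sqrt(((10 - 20) ** 2 + (30 - 20) ** 2) / 1), rel=1e-6)

    def test_reorder_invariance_of_aggregates(self, rng):
        n = 20
        lonlat = np.column_stack([rng.uniform(-93, -91, n), rng.uniform(35, 37, n)])
        pred = lonlat + rng.normal(0, 0.05, lonlat.shape)
        ids = [f"s{i}" for i in range(n)]
        s1 = summarize_errors(_cs(ids, pred), _cs(ids, lonlat))
        perm = rng.permutation(n)
        s2 = summarize_errors(
            _cs(np.array(ids, dtype=object)[perm], pred[perm]),
            _cs(np.array(ids, dtype=object)[perm], lonlat[perm]),
        )
        assert s1.mean_km == pytest.approx(s2.mean_km)
        assert s1.median_km == pytest.approx(s2.median_km)

    def test_mismatched_ids_rejected(self):
        a = _cs(["a"], [[0.0, 0.0]])
        b = _cs(["b"], [[0.0, 0.0]])
        with pytest.raises(InputError):
            summarize_errors(a, b)


class TestErrorSurface:
    def test_constant_field_constant_surface(self, rng):
        lonlat = np.column_stack([rng.uniform(-93, -91, 30), rng.uniform(35, 37, 30)])
        C = _cs([f"s{i}" for i in range(30)], lonlat)
        _, _, field = error_surface(C, np.full(30, 7.5))
        inside = np.isfinite(field)
        assert inside.any()
        np.testing.assert_allclose(field[inside], 7.5)

    def test_exact_at_sample_node(self):
        # grid corners coincide with samples at the bounding box corners
        lonlat = np.array([[-93.0, 35.0], [-91.0, 35.0], [-93.0, 37.0], [-91.0, 37.0]])
        errs = np.array([1.0, 2.0, 3.0, 4.0])
        C = _cs(list("abcd"), lonlat)
        lon_g, lat_g, field = error_surface(C, errs, grid_size=21)
        assert field[0, 0] == pytest.approx(1.0)
        assert field[-1, -1] == pytest.approx(4.0)

    def test_two_value_field_midpoint_and_proximity(self):
        lonlat = np.array([[-93.0, 36.0], [-91.0, 36.0], [-92.0, 36.5]])
        errs = np.array([0.0, 10.0, 5.0])
        C = _cs(list("abc"), lonlat)
        lon_g, lat_g, field = error_surface(C, errs, grid_size=41, n_neighbors=2)
        # nodes nearer sample a take values nearer a's error
        col_near_a = np.nanmean(field[:, 2])
        col_near_b = np.nanmean(field[:, -3])
        assert col_near_a < col_near_b

    def test_degenerate_geometry(self):
        C = _cs(list("ab"), [[-92.0, 36.0], [-91.0, 36.0]])
        with pytest.raises(DegenerateGeometryError):
            error_surface(C, np.array([1.0, 2.0]))


class TestRenderReports:
    def test_manifest_and_determinism(self, tmp_path, rng):
        n = 15
        lonlat = np.column_stack([rng.uniform(-93, -91, n), rng.uniform(35, 37, n)])
        pred = lonlat + rng.normal(0, 0.05, lonlat.shape)
        ids = [f"s{i}" for i in range(n)]
        s = summarize_errors(_cs(ids, pred), _cs(ids, lonlat))
        import pandas as pd

        hist = pd.DataFrame({"epoch": [1, 2], "train_loss": [1.0, 0.5],
                             "val_loss": [1.1, 0.6], "lr": [1e-3, 1e-3]})
        clouds = {"u1": np.array([[-92.0, 36.0], [-92.1, 36.1]])}
        d1 = tmp_path / "r1"
        files = render_reports(d1, summary=s, history=hist, prediction_clouds=clouds)
        assert "per_sample_errors.csv" in files
        assert "loss_curves.png" in files
        assert "bootstrap_predictions.csv" in files
        assert (d1 / "manifest.txt").exists()
        d2 = tmp_path / "r2"
        render_reports(d2, summary=s, history=hist, prediction_clouds=clouds)
        assert (d1 / "per_sample_errors.csv").read_text() == (
            d2 / "per_sample_errors.csv"
        ).read_text()

    def test_evaluation_only_manifest(self, tmp_path, rng):
        n = 8
        lonlat = np.column_stack([rng.uniform(-93, -91, n), rng.uniform(35, 37, n)])
        ids = [f"s{i}" for i in range(n)]
        s = summarize_errors(_cs(ids, lonlat), _cs(ids, lonlat))
        files = render_reports(tmp_path / "r", summary=s)
        assert "bootstrap_predictions.csv" not in files
        assert "per_sample_errors.csv" in files
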