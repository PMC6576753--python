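import numpy as np
import pandas as pd
import pytest

from invasdm import griddata as gd


def make_occ(rows):
    return pd.DataFrame(rows, columns=["species", "cell_id", "date", "region"])


class TestPredictorStack:
    def test_rejects_unknown_tag(self, square_grid):
        frame = pd.DataFrame({"t": np.zeros(len(square_grid))},
                             index=square_grid["cell_id"].to_numpy())
        with pytest.raises(gd.GridDataError, match="climate"):
            gd.PredictorStack(frame, {"t": "climate"})

    def test_rejects_non_finite(self, square_grid):
        vals = np.zeros(len(square_grid))
        vals[3] = np.nan
        frame = pd.DataFrame({"t": vals}, index=square_grid["cell_id"].to_numpy())
        with pytest.raises(gd.GridDataError, match="t"):
            gd.PredictorStack(frame, {"t": gd.ENVIRONMENTAL})

    def test_round_trip(self, tmp_path, square_grid, toy_stack):
        path = tmp_path / "pred.csv"
        gd.write_predictors(path, square_grid, toy_stack, "invaded")
        grid2, stack2, region = gd.read_predictors(path)
        assert region == "invaded"
        assert stack2 == toy_stack
        assert np.allclose(grid2["area_fraction"], square_grid["area_fraction"])

    def test_read_rejects_untagged_header(self, tmp_path, square_grid, toy_stack):
        path = tmp_path / "pred.csv"
        gd.write_predictors(path, square_grid, toy_stack, "invaded")
        text = path.read_text().replace("temp:environmental", "temp")
        path.write_text(text)
        with pytest.raises(gd.GridDataError, match="temp"):
            gd.read_predictors(path)

    def test_read_missing_value_names_row(self, tmp_path, square_grid, toy_stack):
        path = tmp_path / "pred.csv"
        gd.write_predictors(path, square_grid, toy_stack, "invaded")
        lines = path.read_text().splitlines()
        parts = lines[3].split(",")
        parts[-1] = ""
        lines[3] = ",".join(parts)
        path.write_text("\n".join(lines))
        with pytest.raises(gd.GridDataError, match="row 2"):
            gd.read_predictors(path)


class TestOccurrences:
    def test_duplicates_collapse_and_are_counted(self, tmp_path):
        df = make_occ(
            [
                ("sp", 5, 2001, "invaded"),
                ("sp", 5, 2001, "invaded"),
                ("sp", 5, 2003, "invaded"),  # same cell, later date
                ("sp", 6, 2002, "invaded"),
            ]
        )
        path = tmp_path / "occ.csv"
        df.to_csv(path, index=False)
        occ, n_dup = gd.read_occurrences(path)
        assert len(occ) == 2
        assert n_dup == 2
        kept = occ.for_species("sp")
        assert kept.loc[kept.cell_id == 5, "date"].item() == 2001  # earliest kept

    def test_region_case_folded(self, tmp_path):
        df = make_occ([("sp", 1, 2000, "Native"), ("sp", 2, 2001, "INVADED")])
        path = tmp_path / "occ.csv"
        df.to_csv(path, index=False)
        occ, _ = gd.read_occurrences(path)
        assert set(occ.records["region"]) == {"native", "invaded"}

    def test_round_trip_preserves_count(self, tmp_path):
        df = make_occ([("sp", i, 2000 + i, "invaded") for i in range(6)])
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        df.to_csv(p1, index=False)
        occ, _ = gd.read_occurrences(p1)
        gd.write_occurrences(occ, p2)
        occ2, _ = gd.read_occurrences(p2)
        assert len(occ2) == len(occ) == 6

    def test_unparseable_date_names_row(self, tmp_path):
        df = make_occ([("sp", 1, "2000-01-01", "invaded"), ("sp", 2, "not a date", "invaded")])
        path = tmp_path / "occ.csv"
        df.to_csv(path, index=False)
        with pytest.raises(gd.GridDataError, match="row 1"):
            gd.read_occurrences(path)

    def test_iso_dates_keep_ordering(self, tmp_path):
        df = make_occ([("sp", 1, "2001-06-01", "invaded"), ("sp", 2, "1999-01-01", "invaded")])
        path = tmp_path / "occ.csv"
        df.to_csv(path, index=False)
        occ, _ = gd.read_occurrences(path)
        r = occ.records.set_index("cell_id")["date"]
        assert r.loc[2] < r.loc[1]

    def test_xy_resolved_to_nearest_cell(self, tmp_path, square_grid):
        df = pd.DataFrame(
            {"species": ["sp"], "x_km": [2.6], "y_km": [2.4], "date": [2000], "region": ["invaded"]}
        )
        path = tmp_path / "occ.csv"
        df.to_csv(path, index=False)
        occ, _ = gd.read_occurrences(path, grid=square_grid)
        cell = occ.records["cell_id"].item()
        g = square_grid.set_index("cell_id")
        assert g.loc[cell, "x_km"] == 2.5 and g.loc[cell, "y_km"] == 2.5


class TestDomainConstraints:
    def test_area_fraction_boundary(self):
        grid = pd.DataFrame(
            {"cell_id": [0, 1, 2], "x_km": [0, 5, 10], "y_km": [0, 0, 0],
             "area_fraction": [0.69, 0.70, 1.0]}
        )
        kept = gd.filter_valid_cells(grid)
        assert list(kept["cell_id"]) == [1, 2]

    def test_full_fraction_identity(self, square_grid):
        assert len(gd.filter_valid_cells(square_grid)) == len(square_grid)

    def test_survivors_match_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        grid = pd.DataFrame(
            {"cell_id": np.arange(200), "x_km": rng.uniform(0, 100, 200),
             "y_km": rng.uniform(0, 100, 200), "area_fraction": rng.uniform(0, 1, 200)}
        )
        kept = gd.filter_valid_cells(grid)
        brute = sum(1 for f in grid["area_fraction"] if f >= 0.70)
        assert len(kept) == brute

    def test_northern_buffer(self):
        grid = pd.DataFrame(
            {"cell_id": [0, 1, 2], "x_km": [0, 0, 0], "y_km": [0.0, 150.0, 250.0],
             "area_fraction": [1.0] * 3}
        )
        pres = make_occ([("sp", 0, 2000, "invaded")])
        kept = gd.constrain_invaded_domain(grid, pres, buffer_km=200)
        assert list(kept["cell_id"]) == [0, 1]
        assert len(gd.constrain_invaded_domain(grid, pres, buffer_km=np.inf)) == 3
        with pytest.raises(gd.GridDataError):
            gd.constrain_invaded_domain(grid, pres.iloc[:0], buffer_km=200)

    def test_northern_buffer_matches_exhaustive_scan(self, square_grid):
        rng = np.random.default_rng(1)
        cells = rng.choice(square_grid["cell_id"].to_numpy(), 5, replace=False)
        pres = make_occ([("sp", int(c), 2000, "invaded") for c in cells])
        kept = gd.constrain_invaded_domain(square_grid, pres, buffer_km=10)
        g = square_grid.set_index("cell_id")
        y_max = g.loc[cells, "y_km"].max()
        brute = {int(c) for c, y in zip(square_grid["cell_id"], square_grid["y_km"]) if y <= y_max + 10}
        assert set(kept["cell_id"]) == brute

    def test_convex_hull_keeps_vertices_drops_outside(self, square_grid):
        # presences at three corners of the grid
        g = square_grid.set_index("cell_id")
        corners = [
            g.index[(g.x_km == 2.5) & (g.y_km == 2.5)][0],
            g.index[(g.x_km == 47.5) & (g.y_km == 2.5)][0],
            g.index[(g.x_km == 2.5) & (g.y_km == 47.5)][0],
        ]
        pres = make_occ([("sp", int(c), 2000, "native") for c in corners])
        kept = gd.constrain_native_domain(square_grid, pres)
        assert set(corners) <= set(kept["cell_id"])
        far = g.index[(g.x_km == 47.5) & (g.y_km == 47.5)][0]
        assert far not in set(kept["cell_id"])

    def test_convex_hull_matches_half_plane_oracle(self, square_grid):
        rng = np.random.default_rng(5)
        cells = rng.choice(square_grid["cell_id"].to_numpy(), 7, replace=False)
        pres = make_occ([("sp", int(c), 2000, "native") for c in cells])
        try:
            kept = gd.constrain_native_domain(square_grid, pres)
        except gd.GridDataError:
            pytest.skip("degenerate draw")
        g = square_grid.set_index("cell_id")
        pts = g.loc[cells, ["x_km", "y_km"]].to_numpy()
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        # half-plane test: inside iff on the non-positive side of every edge
        A, b = hull.equations[:, :2], hull.equations[:, 2]
        inside = {
            int(c)
            for c, x, y in zip(square_grid.cell_id, square_grid.x_km, square_grid.y_km)
            if (A @ [x, y] + b <= 1e-9).all()
        }
        assert set(kept["cell_id"]) == inside

    def test_collinear_presences_rejected(self, square_grid):
        g = square_grid.set_index("cell_id")
        col = g.index[g.x_km == 2.5][:4]
        pres = make_occ([("sp", int(c), 2000, "native") for c in col])
        with pytest.raises(gd.GridDataError, match="collinear"):
            gd.constrain_native_domain(square_grid, pres)

    def test_adding_presences_never_shrinks_domains(self, square_grid):
        rng = np.random.default_rng(9)
        cells = rng.choice(square_grid["cell_id"].to_numpy(), 8, replace=False)
        base = make_occ([("sp", int(c), 2000, "invaded") for c in cells[:4]])
        more = make_occ([("sp", int(c), 2000, "invaded") for c in cells])
        kept_base = gd.constrain_invaded_domain(square_grid, base, buffer_km=20)
        kept_more = gd.constrain_invaded_domain(square_grid, more, buffer_km=20)
        assert set(kept_base["cell_id"]) <= set(kept_more["cell_id"])
        base_n = make_occ([("sp", int(c), 2000, "native") for c in cells[:4]])
        more_n = make_occ([("sp", int(c), 2000, "native") for c in cells])
        try:
            kb = gd.constrain_native_domain(square_grid, base_n)
            km = gd.constrain_native_domain(square_grid, more_n)
        except gd.GridDataError:
            pytest.skip("degenerate draw")
        assert set(kb["cell_id"]) <= set(km["cell_id"])


class TestDistanceToFirstRecord:
    def test_examples_and_brute_force(self):
        grid = pd.DataFrame(
            {"cell_id": [0, 1, 2], "x_km": [0.0, 6.0, 3.0], "y_km": [0.0, 8.0, 4.0],
             "area_fraction": [1.0] * 3}
        )
        occ = make_occ([("sp", 0, 1990, "invaded"), ("sp", 1, 1995, "invaded")])
        d = gd.distance_to_first_record(grid, occ)
        assert d.loc[0] == 0.0
        assert d.loc[1] == 10.0
        assert d.loc[2] == 5.0  # 3-4-5 triangle

    def test_earliest_tie_breaks_to_lowest_cell(self):
        grid = pd.DataFrame(
            {"cell_id": [3, 7], "x_km": [0.0, 100.0], "y_km": [0.0, 0.0],
             "area_fraction": [1.0, 1.0]}
        )
        occ = make_occ([("sp", 7, 1990, "invaded"), ("sp", 3, 1990, "invaded")])
        d = gd.distance_to_first_record(grid, occ)
        assert d.loc[3] == 0.0  # cell 3 wins the tie


class TestSamplingCoverage:
    def test_extremes_and_direct_count(self, square_grid):
        all_recs = make_occ([("rel", int(c), 0, "invaded") for c in square_grid["cell_id"]])
        assert gd.sampling_coverage(square_grid, all_recs) == 1.0
        assert gd.sampling_coverage(square_grid, all_recs.iloc[:0]) == 0.0
        quarter = make_occ([("rel", int(c), 0, "invaded") for c in square_grid["cell_id"][:25]])
        assert gd.sampling_coverage(square_grid, quarter) == 0.25


class TestProfiles:
    def test_round_trip(self, tmp_path):
        profs = [
            gd.SpeciesProfile("zebra_mussel_like", 191, False, 376, 398),
            gd.SpeciesProfile("slider_like", 60, True, 87, 406),
        ]
        path = tmp_path / "profiles.csv"
        gd.write_profiles(profs, path)
        back = gd.read_profiles(path)
        assert back == profs

    def test_negative_fields_rejected(self):
        with pytest.raises(gd.GridDataError):
            gd.SpeciesProfile("x", -1, False, 3, 5)
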