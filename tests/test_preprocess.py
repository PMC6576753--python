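import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from invasdm import preprocess as pp
from invasdm.griddata import GridDataError


def brute_force_vif_path(X: pd.DataFrame, threshold: float):
    """Independent elimination oracle: recompute every VIF by explicit
    least-squares at each step, drop the worst while above threshold."""
    import statsmodels.api as sm

    cols = list(X.columns)
    path = []
    while len(cols) > 1:
        vifs = {}
        for c in cols:
            others = [o for o in cols if o != c]
            res = sm.OLS(X[c], sm.add_constant(X[others])).fit()
            r2 = min(res.rsquared, 1 - 1e-10)
            vifs[c] = 1.0 / (1.0 - r2)
        worst = max(vifs, key=lambda c: (vifs[c], -cols.index(c)))
        if vifs[worst] <= threshold:
            break
        cols.remove(worst)
        path.append(worst)
    return cols, path


class TestVifFilter:
    def test_orthogonal_columns_all_retained(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(60, 4)))
        X = pd.DataFrame(Q, columns=list("abcd"))
        retained, _ = pp.vif_filter(X)
        assert retained == list("abcd")
        assert (pp.vif_scores(X) < 1.01).all()

    def test_duplicated_column_one_removed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "a_copy": a, "b": rng.normal(size=50)})
        retained, log = pp.vif_filter(X)
        assert len(retained) == 2 and "b" in retained
        assert len({"a", "a_copy"} & set(retained)) == 1

    def test_matches_brute_force_oracle_on_correlated_fixture(self):
        # five columns with a known correlated structure
        rng = np.random.default_rng(7)
        z = rng.normal(size=(200, 2))
        X = pd.DataFrame(
            {
                "x1": z[:, 0],
                "x2": z[:, 0] * 0.98 + 0.02 * rng.normal(size=200),
                "x3": z[:, 1],
                "x4": z[:, 0] + z[:, 1] + 0.05 * rng.normal(size=200),
                "x5": rng.normal(size=200),
            }
        )
        retained, _ = pp.vif_filter(X, threshold=10)
        oracle_cols, _ = brute_force_vif_path(X, 10)
        assert retained == oracle_cols
        assert (pp.vif_scores(X[retained]) <= 10).all()

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(80, 3))
        X = pd.DataFrame(
            {"a": z[:, 0], "b": z[:, 0] + 0.1 * z[:, 1], "c": z[:, 2], "d": z[:, 1]}
        )
        r1, _ = pp.vif_filter(X)
        r2, _ = pp.vif_filter(X[r1])
        assert r1 == r2

    def test_zero_variance_dropped_first(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"flat": np.ones(30), "a": rng.normal(size=30), "b": rng.normal(size=30)})
        retained, log = pp.vif_filter(X)
        assert "flat" not in retained
        assert any("zero-variance" in m for m in log)


def dated(records):
    return pd.DataFrame(records, columns=["species", "cell_id", "date", "region"])


class TestTemporalSplit:
    def test_ten_records_split_7_3(self):
        occ = dated([("sp", i, 2000 + i, "invaded") for i in range(10)])
        train, test = pp.temporal_split(occ)
        assert len(train) == 7 and len(test) == 3
        assert train["date"].max() == 2006 and test["date"].min() == 2007

    def test_nine_records_round_half_up(self):
        occ = dated([("sp", i, 2000 + i, "invaded") for i in range(9)])
        train, test = pp.temporal_split(occ)
        assert len(train) == 6  # round(6.3) = 6

    def test_single_date_rejected(self):
        occ = dated([("sp", i, 2000, "invaded") for i in range(6)])
        with pytest.raises(GridDataError, match="temporal"):
            pp.temporal_split(occ)

    def test_order_invariance(self):
        occ = dated([("sp", i, 2010 - i, "invaded") for i in range(8)])
        shuffled = occ.sample(frac=1, random_state=5).reset_index(drop=True)
        t1, _ = pp.temporal_split(occ)
        t2, _ = pp.temporal_split(shuffled)
        assert sorted(t1["cell_id"]) == sorted(t2["cell_id"])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        dates=st.lists(st.integers(min_value=0, max_value=50), min_size=4, max_size=40),
    )
    def test_every_training_date_precedes_testing(self, dates):
        occ = dated([("sp", i, d, "invaded") for i, d in enumerate(dates)])
        if occ["date"].nunique() < 2:
            return
        train, test = pp.temporal_split(occ)
        assert len(train) == int(np.floor(0.7 * len(occ) + 0.5))
        assert train["date"].max() <= test["date"].min()


class TestPseudoAbsences:
    def test_never_hits_presences_and_is_reproducible(self, square_grid):
        pres = [0, 1, 2, 3]
        s1 = pp.sample_pseudoabsences(square_grid, pres, 10, seed=5)
        s2 = pp.sample_pseudoabsences(square_grid, pres, 10, seed=5)
        assert np.array_equal(s1, s2)
        assert not set(s1) & set(pres)
        assert len(set(s1)) == 10

    def test_sampled_pool_restricted_to_covered_cells(self, square_grid):
        covered = list(range(30))
        s = pp.sample_pseudoabsences(
            square_grid, [0, 1], 5, seed=0, pool="sampled", related_cells=covered
        )
        assert set(s) <= set(covered)

    def test_small_pool_rejected(self, square_grid):
        with pytest.raises(GridDataError, match="pool"):
            pp.sample_pseudoabsences(square_grid, list(range(95)), 10, seed=0)


class TestSsb:
    def test_coincident_presences_drive_ratio_to_zero(self):
        train = np.array([[0.0, 0.0], [10.0, 0.0]])
        test_pres = train.copy()
        test_abs = np.array([[100.0, 100.0], [120.0, 100.0]])
        d_p, d_a, ratio = pp.calc_ssb(test_pres, test_abs, train)
        assert d_p == 0.0 and ratio == 0.0

    def test_matches_brute_force_nearest_neighbour(self):
        rng = np.random.default_rng(2)
        tp, ta, tr = rng.uniform(0, 100, (12, 2)), rng.uniform(0, 100, (15, 2)), rng.uniform(0, 100, (9, 2))
        d_p, d_a, ratio = pp.calc_ssb(tp, ta, tr)
        bp = np.mean([min(np.hypot(*(p - t)) for t in tr) for p in tp])
        ba = np.mean([min(np.hypot(*(a - t)) for t in tr) for a in ta])
        assert np.isclose(d_p, bp) and np.isclose(d_a, ba) and np.isclose(ratio, bp / ba)

    def test_same_distribution_gives_ratio_near_one(self):
        ratios = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            tr = rng.uniform(0, 100, (30, 2))
            tp = rng.uniform(0, 100, (25, 2))
            ta = rng.uniform(0, 100, (25, 2))
            ratios.append(pp.calc_ssb(tp, ta, tr)[2])
        assert abs(np.mean(ratios) - 1.0) < 0.15


class TestPwdSample:
    def test_perfect_candidates_pair_everything(self):
        train = np.array([[0.0, 0.0]])
        test_pres = np.array([[3.0, 0.0], [6.0, 0.0]])
        cand = np.array([[0.0, 3.0], [0.0, 6.0], [50.0, 50.0]])
        res = pp.pwd_sample(test_pres, cand, train, tr=0.33)
        assert len(res.matched_pres) == 2
        d_s = np.hypot(cand[res.matched_abs, 0], cand[res.matched_abs, 1])
        assert sorted(d_s) == [3.0, 6.0]

    def test_tolerance_arithmetic_rejects_double_distance(self):
        train = np.array([[0.0, 0.0]])
        test_pres = np.array([[5.0, 0.0]])
        cand = np.array([[10.0, 0.0]])  # d_s = 2 x d_f
        with pytest.raises(GridDataError, match="no admissible"):
            pp.pwd_sample(test_pres, cand, train, tr=0.33)

    def test_recheck_ratio_lands_inside_tolerance_band(self):
        rng = np.random.default_rng(8)
        train = rng.uniform(0, 50, (20, 2))
        # clustered test presences near training points
        test_pres = train[:15] + rng.normal(0, 2, (15, 2))
        cand = rng.uniform(0, 120, (300, 2))
        tr = 0.33
        res = pp.pwd_sample(test_pres, cand, train, tr=tr)
        _, _, ratio = pp.calc_ssb(test_pres[res.matched_pres], cand[res.matched_abs], train)
        assert 1 - tr <= ratio <= 1 + tr
        assert len(res.matched_abs) <= len(test_pres)

    def test_improves_bias_on_clustered_inputs(self):
        rng = np.random.default_rng(9)
        train = rng.uniform(0, 30, (25, 2))
        test_pres = train[:20] + rng.normal(0, 1.5, (20, 2))
        cand = rng.uniform(0, 150, (400, 2))
        _, _, before = pp.calc_ssb(test_pres, cand, train)
        res = pp.pwd_sample(test_pres, cand, train, tr=0.33)
        _, _, after = pp.calc_ssb(test_pres[res.matched_pres], cand[res.matched_abs], train)
        assert abs(after - 1) < abs(before - 1)


class TestScenarioAssembly:
    def test_scenario_tag_rules(self, toy_stack, square_grid):
        import invasdm.preprocess as P

        split = _tiny_split(square_grid)
        inv = P.assemble_scenario("INVADED", _with_dtfr(toy_stack), split)
        mixed = P.assemble_scenario("MIXED", _with_dtfr(toy_stack), split)
        assert set(inv.columns) <= set(mixed.columns)
        assert "dist_shops" not in inv.columns
        tags = _with_dtfr(toy_stack).tags
        for c in mixed.columns:
            assert tags[c] in {"environmental", "anthropic", "distance_to_first_record"}

    def test_native_scenario_rejects_anthropic_spec(self):
        with pytest.raises(GridDataError, match="anthropic"):
            pp.ScenarioSpec("BAD", frozenset({"environmental", "anthropic"}), True)

    def test_native_row_accounting(self, toy_stack, square_grid, small_landscape):
        split = _tiny_split(square_grid)
        native_pres = small_landscape.native_grid["cell_id"].to_numpy()[:5]
        native_abs = small_landscape.native_grid["cell_id"].to_numpy()[10:15]
        # use a native stack restricted to the toy env columns
        nat = small_landscape.predictors_native
        stack = _with_dtfr(toy_stack)
        env_cols = ["temp", "rain"]
        nat_frame = nat.frame.iloc[:, :2].copy()
        nat_frame.columns = env_cols
        from invasdm.griddata import ENVIRONMENTAL, PredictorStack

        nat_stack = PredictorStack(nat_frame, {c: ENVIRONMENTAL for c in env_cols})
        sd = pp.assemble_scenario(
            "NATIVE", stack, split, native_stack=nat_stack,
            native_pres=native_pres, native_abs=native_abs,
        )
        expected = len(native_pres) + len(native_abs) + len(split.train_pres) + len(split.train_abs)
        assert len(sd.X_train) == expected
        assert "dist_shops" not in sd.columns


def _with_dtfr(stack):
    from invasdm.griddata import DIST_FIRST_RECORD

    rng = np.random.default_rng(0)
    return stack.with_column("dist_first_record", rng.uniform(0, 30, stack.n_cells), DIST_FIRST_RECORD)


def _tiny_split(grid):
    ids = grid["cell_id"].to_numpy()
    return pp.DatasetSplit(
        train_pres=ids[:6], train_abs=ids[20:26], test_pres=ids[40:43], test_abs=ids[50:53]
    )
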