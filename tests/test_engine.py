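import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sleepsca.engine import (
    BootstrapConfig,
    DegenerateSpecError,
    EngineError,
    InsufficientDataError,
    SCACurve,
    SpecResult,
    _DayCache,
    _fit_from_cache,
    bootstrap_sca,
    coef_to_minutes,
    compare_day_types,
    correlation_matrix,
    curve_from_frame,
    difficulties_regression,
    fit_spec,
    run_sca,
    summarize,
)
from sleepsca.grid import Specification, build_grid
from sleepsca.measures import covariate_set


def ols_oracle(y_raw, x_raw, continuous=(), factor=None):
    """Independent brute-force oracle: z-score, dummy-code, normal equations."""

    def z(v):
        v = np.asarray(v, float)
        return (v - v.mean()) / v.std(ddof=1)

    cols = [np.ones(len(y_raw)), z(x_raw)] + [z(c) for c in continuous]
    if factor is not None:
        levels = np.unique(factor)
        for level in levels[1:]:
            cols.append((np.asarray(factor) == level).astype(float))
    X = np.column_stack(cols)
    y = z(y_raw)
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ y
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t_stat = coef[1] / se
    p = 2 * stats.t.sf(abs(t_stat), dof)
    return float(coef[1]), float(se), float(p)


def small_fixture(n=30, seed=0, rho=0.4):
    """Random person-level table with every analysis column populated."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1),
            "day_type": "weekday",
            "bedtime_retro": y,
            "onset_score": rng.standard_normal(n),
            "total_sleep_retro": rng.standard_normal(n),
            "composite_screen": x,
            "participation": rng.integers(0, 2, n).astype(float),
            "bedtime_use": rng.integers(0, 2, n).astype(float),
            "time_spent": rng.exponential(3, n),
            "fall_asleep_time": rng.standard_normal(n),
            "night_waking": rng.standard_normal(n),
            "sex": rng.integers(0, 2, n).astype(float),
            "age": rng.choice([13.0, 14.0, 15.0], n),
            "mother_white": rng.integers(0, 2, n).astype(float),
            "closeness": rng.uniform(1, 4, n),
            "longterm_illness": rng.integers(0, 2, n).astype(float),
            "motivation": rng.uniform(1, 4, n),
            "word_activity": rng.uniform(0, 20, n),
            "nvq": rng.integers(1, 5, n).astype(float),
            "time_with_child": rng.uniform(1, 5, n),
            "kessler": rng.uniform(0, 24, n),
            "income": rng.lognormal(6, 0.5, n),
            "father_home": rng.integers(0, 2, n).astype(float),
            "n_siblings": rng.poisson(1.3, n).astype(float),
        }
    )
    return df


class TestFitOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_demographics_controls_match_oracle(self, seed):
        df = small_fixture(n=30, seed=seed)
        spec = Specification("weekday", "bedtime_retro", "time_spent_retro", "demographics")
        got = fit_spec(df, spec)
        beta, se, p = ols_oracle(
            df["bedtime_retro"],
            df["composite_screen"],
            continuous=[df["sex"], df["age"], df["mother_white"]],
        )
        assert got.beta == pytest.approx(beta, abs=1e-10)
        assert got.se == pytest.approx(se, abs=1e-10)
        assert got.p == pytest.approx(p, abs=1e-10)
        assert got.n == 30

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_all_controls_with_factor_match_oracle(self, seed):
        df = small_fixture(n=50, seed=seed)
        spec = Specification("weekday", "total_sleep_retro", "time_spent_diary", "all")
        got = fit_spec(df, spec)
        continuous = [
            df[c] for c in covariate_set("all") if c != "nvq"
        ]
        beta, se, p = ols_oracle(
            df["total_sleep_retro"], df["time_spent"], continuous, factor=df["nvq"]
        )
        assert got.beta == pytest.approx(beta, abs=1e-8)
        assert got.se == pytest.approx(se, abs=1e-8)
        assert got.p == pytest.approx(p, abs=1e-8)

    def test_outcome_equals_predictor(self):
        df = small_fixture(seed=3)
        df["bedtime_retro"] = df["composite_screen"]
        spec = Specification("weekday", "bedtime_retro", "time_spent_retro", "demographics")
        got = fit_spec(df, spec)
        assert got.beta == pytest.approx(1.0, abs=1e-10)
        assert got.r2 == pytest.approx(1.0, abs=1e-10)

    def test_no_covariates_beta_is_pearson_r(self):
        df = small_fixture(seed=4)
        cache = _DayCache(df)
        got = _fit_from_cache(
            cache, "bedtime_retro", "composite_screen", (), 0.05, "test", None
        )
        r = np.corrcoef(df["bedtime_retro"], df["composite_screen"])[0, 1]
        assert got.beta == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize("a,b", [(2.0, -3.0), (0.1, 100.0)])
    def test_affine_invariance(self, a, b):
        df = small_fixture(seed=5)
        spec = Specification("weekday", "bedtime_retro", "time_spent_retro", "demographics")
        base = fit_spec(df, spec)
        scaled = df.copy()
        scaled["bedtime_retro"] = a * scaled["bedtime_retro"] + b
        scaled["composite_screen"] = a * scaled["composite_screen"] - b
        got = fit_spec(scaled, spec)
        sign = np.sign(a) * np.sign(a)
        assert got.beta == pytest.approx(sign * base.beta, abs=1e-10)
        assert got.p == pytest.approx(base.p, abs=1e-10)

    def test_sign_flip_on_negated_predictor(self):
        df = small_fixture(seed=6)
        spec = Specification("weekday", "bedtime_retro", "time_spent_retro", "demographics")
        base = fit_spec(df, spec)
        flipped = df.copy()
        flipped["composite_screen"] = -flipped["composite_screen"]
        assert fit_spec(flipped, spec).beta == pytest.approx(-base.beta, abs=1e-12)

    def test_degenerate_predictor(self):
        df = small_fixture(seed=7)
        df["composite_screen"] = 5.0
        spec = Specification("weekday", "bedtime_retro", "time_spent_retro", "demographics")
        with pytest.raises(DegenerateSpecError):
            fit_spec(df, spec)

    def test_insufficient_data(self):
        df = small_fixture(n=4, seed=8)
        spec = Specification("weekday", "bedtime_retro", "time_spent_retro", "all")
        with pytest.raises(InsufficientDataError):
            fit_spec(df, spec)

    def test_listwise_deletion_counts(self):
        df = small_fixture(seed=9)
        df.loc[:4, "sex"] = np.nan
        spec = Specification("weekday", "bedtime_retro", "time_spent_retro", "demographics")
        assert fit_spec(df, spec).n == 25


class TestRunSCA:
    def test_full_grid_on_synthetic(self, default_run):
        *_, derived = default_run
        curve = run_sca(derived, build_grid())
        assert len(curve.results) == 120
        by_day = {"weekday": 0, "weekend": 0}
        for r in curve.results:
            by_day[r.spec.day_type] += 1
        assert by_day == {"weekday": 60, "weekend": 60}
        assert all(r.status == "ok" for r in curve.results)
        betas = [r.beta for r in curve.results]
        assert betas == sorted(betas)
        for r in curve.results:
            assert 0.0 <= r.r2 <= 1.0 and 0.0 <= r.p <= 1.0
            assert r.significant == (r.p < 0.05)

    def test_single_spec_grid(self, default_run):
        *_, derived = default_run
        grid = build_grid()[:1]
        curve = run_sca(derived, grid)
        assert len(curve.results) == 1

    def test_empty_grid_rejected(self, default_run):
        *_, derived = default_run
        with pytest.raises(EngineError):
            run_sca(derived, ())

    def test_degenerate_spec_flagged_not_dropped(self, default_run):
        *_, derived = default_run
        broken = derived.copy()
        broken["participation"] = 1.0
        curve = run_sca(broken, build_grid())
        assert len(curve.results) == 120
        statuses = {r.spec.tech_measure: r.status for r in curve.results}
        assert statuses["participation"] == "degenerate"

    def test_n_monotone_in_control_blocks(self, default_run):
        *_, derived = default_run
        base = Specification("weekday", "bedtime_retro", "time_spent_retro", "demographics")
        ns = {
            cs: fit_spec(derived, Specification("weekday", "bedtime_retro", "time_spent_retro", cs)).n
            for cs in ("demographics", "demographics_child", "demographics_mother", "all")
        }
        assert ns["demographics"] >= ns["demographics_child"] >= ns["all"]
        assert ns["demographics"] >= ns["demographics_mother"] >= ns["all"]

    def test_time_spent_specs_have_lower_n(self, default_run):
        *_, derived = default_run
        part = fit_spec(derived, Specification("weekday", "bedtime_diary", "participation", "demographics"))
        spent = fit_spec(derived, Specification("weekday", "bedtime_diary", "time_spent_diary", "demographics"))
        assert spent.n < part.n  # non-participants are deleted listwise


class TestMedianBeta:
    def make_curve(self, betas, day="weekday"):
        results = [
            SpecResult(
                spec_id=f"s{i}",
                beta=b,
                se=0.1,
                p=0.5,
                n=10,
                r2=0.1,
                significant=False,
                spec=Specification(day, "bedtime_retro", "participation", "all"),
            )
            for i, b in enumerate(betas)
        ]
        return SCACurve(results=results, alpha=0.05)

    def test_single(self):
        assert self.make_curve([-0.2]).median_beta() == -0.2

    def test_odd(self):
        assert self.make_curve([-0.1, 0.0, 0.1]).median_beta() == 0.0

    def test_even(self):
        assert self.make_curve([-0.2, -0.1, 0.1, 0.3]).median_beta() == pytest.approx(0.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(EngineError):
            self.make_curve([0.1]).median_beta(day_type="weekend")


class TestCompareDayTypes:
    def make_curve(self, weekday_betas, weekend_betas):
        results = []
        grid = build_grid()
        wd = [s for s in grid if s.day_type == "weekday"]
        we = [s for s in grid if s.day_type == "weekend"]
        for spec, beta in zip(wd, weekday_betas):
            results.append(SpecResult(spec.spec_id, beta, 0.1, 0.5, 10, 0.1, False, spec=spec))
        for spec, beta in zip(we, weekend_betas):
            results.append(SpecResult(spec.spec_id, beta, 0.1, 0.5, 10, 0.1, False, spec=spec))
        return SCACurve(results=results, alpha=0.05)

    def test_identical_betas(self):
        betas = list(np.linspace(-0.3, 0.3, 60))
        cmp = compare_day_types(self.make_curve(betas, betas))
        assert cmp.t_statistic == 0.0 and cmp.p == 1.0
        assert cmp.df == 59

    def test_shifted_negative(self):
        rng = np.random.default_rng(0)
        we = rng.normal(0, 0.1, 60)
        wd = we - 0.05 + rng.normal(0, 0.01, 60)
        cmp = compare_day_types(self.make_curve(list(wd), list(we)))
        assert cmp.t_statistic < 0 and cmp.p < 0.001

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(1)
        wd = rng.normal(-0.05, 0.1, 60)
        we = rng.normal(0.0, 0.1, 60)
        cmp = compare_day_types(self.make_curve(list(wd), list(we)))
        d = wd - we
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(60))
        assert cmp.t_statistic == pytest.approx(t_expected, abs=1e-12)
        assert cmp.mean_difference == pytest.approx(d.mean(), abs=1e-12)

    def test_unmatched_grid_rejected(self):
        curve = self.make_curve(list(np.linspace(-0.3, 0.3, 60)), [])
        with pytest.raises(EngineError):
            compare_day_types(curve)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, default_run):
        *_, derived = default_run
        cm = correlation_matrix(
            derived, ["composite_screen", "bedtime_retro", "total_sleep_retro"]
        )
        assert np.allclose(np.diag(cm.values), 1.0)
        assert np.allclose(cm.values, cm.values.T, equal_nan=True)

    def test_perfect_negative(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = -df["x"]
        cm = correlation_matrix(df, ["x", "y"])
        assert cm.r("x", "y") == pytest.approx(-1.0)

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.standard_normal(40), "b": rng.standard_normal(40)})
        cm = correlation_matrix(df, ["a", "b"])
        a, b = df["a"].to_numpy(), df["b"].to_numpy()
        r_oracle = np.mean((a - a.mean()) * (b - b.mean())) / (
            a.std() * b.std()
        )
        assert cm.r("a", "b") == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        cm = correlation_matrix(df, ["x", "c"])
        assert "c" in cm.flagged

    def test_needs_two_variables(self):
        with pytest.raises(EngineError):
            correlation_matrix(pd.DataFrame({"x": [1.0]}), ["x"])


class TestDifficulties:
    def test_outcome_equals_predictor(self, default_run):
        *_, derived = default_run
        data = derived.copy()
        data["fall_asleep_time"] = data["composite_screen"]
        got = difficulties_regression(data, "fall_asleep_time")
        assert got.beta == pytest.approx(1.0, abs=1e-10)

    def test_null_data_consistent_with_zero(self, null_run):
        *_, derived = null_run
        got = difficulties_regression(derived, "night_waking")
        assert abs(got.beta) < 4 * got.se

    def test_matches_oracle(self):
        df = small_fixture(n=40, seed=20)
        got = difficulties_regression(df, "fall_asleep_time")
        continuous = [df[c] for c in covariate_set("all") if c != "nvq"]
        beta, se, p = ols_oracle(
            df["fall_asleep_time"], df["composite_screen"], continuous, factor=df["nvq"]
        )
        assert got.beta == pytest.approx(beta, abs=1e-8)

    def test_unknown_outcome(self, default_run):
        *_, derived = default_run
        with pytest.raises(EngineError):
            difficulties_regression(derived, "bedtime_retro")


class TestCoefToMinutes:
    def test_zero(self):
        got = coef_to_minutes(0.0)
        assert (got.sign, got.minutes, got.seconds) == (0, 0, 0)

    def test_published_translation(self):
        got = coef_to_minutes(-0.15472)
        assert (got.sign, got.minutes, got.seconds) == (-1, 9, 17)

    def test_unit_hour(self):
        got = coef_to_minutes(1.0)
        assert (got.sign, got.minutes, got.seconds) == (1, 60, 0)


class TestBootstrap:
    def test_nreps_one_degenerate_ci(self, small_run):
        *_, derived = small_run
        grid = build_grid()[:2]
        boot = bootstrap_sca(derived, grid, BootstrapConfig(n_reps=1, seed=0))
        for sid, (lo, hi) in boot.spec_ci.items():
            assert lo == hi

    def test_same_seed_identical(self, small_run):
        *_, derived = small_run
        grid = build_grid()[:3]
        a = bootstrap_sca(derived, grid, BootstrapConfig(n_reps=20, seed=4))
        b = bootstrap_sca(derived, grid, BootstrapConfig(n_reps=20, seed=4))
        assert a.spec_ci == b.spec_ci
        assert np.array_equal(a.rep_betas, b.rep_betas)

    def test_invalid_reps(self, small_run):
        *_, derived = small_run
        with pytest.raises(EngineError):
            bootstrap_sca(derived, build_grid()[:1], BootstrapConfig(n_reps=0, seed=0))

    def test_cis_contain_point_estimates(self, small_run):
        *_, derived = small_run
        grid = build_grid()
        curve = run_sca(derived, grid)
        boot = bootstrap_sca(derived, grid, BootstrapConfig(n_reps=200, seed=11))
        ok = curve.ok_results()
        contained = sum(
            1
            for r in ok
            if boot.spec_ci[r.spec_id][0] <= r.beta <= boot.spec_ci[r.spec_id][1]
        )
        assert contained / len(ok) >= 0.99


class TestCurveIO:
    def test_roundtrip(self, default_run):
        *_, derived = default_run
        grid = build_grid()[:10]
        curve = run_sca(derived, grid)
        back = curve_from_frame(curve.to_frame())
        for a, b in zip(curve.results, back.results):
            assert a.spec_id == b.spec_id
            assert a.beta == pytest.approx(b.beta)
            assert a.n == b.n and a.significant == b.significant

    def test_summarize(self, default_run):
        *_, derived = default_run
        curve = run_sca(derived, build_grid())
        table = summarize(curve, "day_type")
        assert set(table["day_type"]) == {"weekday", "weekend"}
        assert (table["n_specs"] == 60).all()
        with pytest.raises(EngineError):
            summarize(curve, "nope")
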