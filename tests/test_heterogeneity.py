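import json
import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, strategies as st

from forestmeta.effects import EffectEstimate, TwoByTwoTable
from forestmeta.errors import (
    HeterogeneityUndefinedError,
    NoDataError,
    PredictionIntervalUndefinedError,
)
from forestmeta.heterogeneity import (
    MetaInput,
    analyze,
    compare_measures,
    dl_scaling_constant,
    format_report,
    i_squared,
    pool_fixed,
    pool_random,
    prediction_interval,
    q_statistic,
    tau2_dl,
    to_json_dict,
)


def meta_of(points, variances):
    ests = [
        EffectEstimate(measure="log-rr", point=p, variance=v, label=f"s{i}")
        for i, (p, v) in enumerate(zip(points, variances))
    ]
    return MetaInput(estimates=tuple(ests))


def random_meta(rng, k=None):
    k = k if k is not None else int(rng.integers(2, 11))
    points = rng.normal(0, 1, size=k)
    variances = rng.uniform(0.02, 2.0, size=k)
    return meta_of(points, variances)


class TestPooling:
    def test_equal_weights_give_arithmetic_mean(self):
        res = pool_fixed(meta_of([0, 1], [1, 1]))
        assert res.point == pytest.approx(0.5)
        assert res.se == pytest.approx(math.sqrt(0.5))

    def test_unequal_weights(self):
        res = pool_fixed(meta_of([0, 1], [1, 0.25]))
        assert res.point == pytest.approx(0.8)
        assert res.se == pytest.approx(math.sqrt(0.2))

    def test_fixture_pooled_log_rr(self, fixture_meta):
        # independent route: v_i = 1/a_i for this design, so weights are a_i
        a = np.array([50, 46.25, 42.5, 38.75, 35.0])
        expected = float((a * np.log(a / 50)).sum() / a.sum())
        res = pool_fixed(fixture_meta)
        assert res.point == pytest.approx(expected, abs=1e-12)
        assert res.point == pytest.approx(-0.1547, abs=1e-4)

    def test_empty_input_signals_no_data(self):
        with pytest.raises(NoDataError):
            MetaInput(estimates=())

    def test_random_with_zero_tau2_equals_fixed(self):
        m = meta_of([0.2, -0.1, 0.4], [0.5, 0.2, 1.0])
        assert pool_random(m, 0.0) == pool_fixed(m)

    def test_random_pool_equal_shrunk_weights(self):
        res = pool_random(meta_of([0, 0, 3], [1, 1, 1]), tau2=2.0)
        assert res.point == pytest.approx(1.0)
        assert res.se == pytest.approx(1.0)

    def test_single_study_passes_through(self):
        m = meta_of([0.3], [0.04])
        res = pool_random(m, 0.5)
        assert res.point == pytest.approx(0.3)


class TestQStatistic:
    def test_identical_effects_have_zero_q(self):
        q, df, p = q_statistic(meta_of([0.4, 0.4, 0.4], [1, 0.5, 2]))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        q, df, p = q_statistic(meta_of([0, 0, 3], [1, 1, 1]))
        assert q == pytest.approx(6.0)
        assert df == 2
        assert p == pytest.approx(math.exp(-3.0), rel=1e-10)

    def test_fixture_is_homogeneous(self, fixture_meta):
        q, df, p = q_statistic(fixture_meta)
        assert df == 4
        assert q < 4  # below its expectation under homogeneity
        assert p > 0.4

    def test_single_study_undefined(self):
        with pytest.raises(HeterogeneityUndefinedError):
            q_statistic(meta_of([0.1], [1.0]))

    def test_chi2_tail_matches_closed_form_at_two_df(self):
        # at df = 2 the chi-square upper tail is exactly exp(-Q/2)
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = random_meta(rng, k=3)
            q, df, p = q_statistic(m)
            assert df == 2
            assert p == pytest.approx(math.exp(-q / 2.0), abs=1e-10)


class TestISquared:
    @pytest.mark.parametrize(
        "q, df, expected",
        [(0.0, 1, 0.0), (3.29, 4, 0.0), (6.0, 2, 2.0 / 3.0), (4.0, 4, 0.0)],
    )
    def test_examples(self, q, df, expected):
        assert i_squared(q, df) == pytest.approx(expected)

    @given(q=st.floats(0, 1e3), df=st.integers(1, 50))
    def test_always_a_fraction(self, q, df):
        assert 0.0 <= i_squared(q, df) <= 1.0


class TestTau2:
    def test_identical_effects_give_zero(self):
        assert tau2_dl(meta_of([1.1, 1.1], [0.3, 0.7])) == 0.0

    def test_hand_computed_example(self):
        m = meta_of([0, 0, 3], [1, 1, 1])
        assert dl_scaling_constant(m) == pytest.approx(2.0)
        assert tau2_dl(m) == pytest.approx(2.0)

    def test_fixture_truncates_to_zero(self, fixture_meta):
        assert tau2_dl(fixture_meta) == 0.0

    def test_matches_grid_search_moment_oracle(self):
        """Brute-force grid solve of the method-of-moments equation
        Q - df - C*tau2 = 0 over tau2 in [0, 100] at step 1e-4."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            m = random_meta(rng, k=int(rng.integers(2, 7)))
            q, df, _ = q_statistic(m)
            c = dl_scaling_constant(m)
            grid = np.arange(0.0, 100.0, 1e-4)
            oracle = grid[np.argmin(np.abs(q - df - c * grid))]
            assert tau2_dl(m) == pytest.approx(oracle, abs=1e-4)


class TestPredictionInterval:
    def test_degenerate_point_interval(self):
        lo, hi = prediction_interval(0.5, 0.0, 0.0, k=5)
        assert lo == hi == pytest.approx(0.5)

    def test_one_df_t_quantile(self):
        lo, hi = prediction_interval(1.0, 1.0, 2.0, k=3, level=0.95)
        half = 12.706204736174694 * math.sqrt(3.0)
        assert lo == pytest.approx(1.0 - half, rel=1e-9)
        assert hi == pytest.approx(1.0 + half, rel=1e-9)

    def test_reduces_to_t_interval_when_tau2_zero(self, fixture_meta):
        res = analyze(fixture_meta)
        assert res.tau2 == 0.0
        from scipy import stats

        half = stats.t.ppf(0.975, df=3) * res.random.se
        assert res.prediction_interval[0] == pytest.approx(res.random.point - half)
        assert res.prediction_interval[1] == pytest.approx(res.random.point + half)

    def test_contains_and_widens_the_ci(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = random_meta(rng, k=int(rng.integers(3, 8)))
            res = analyze(m)
            z = 1.9599639845400545
            ci = (res.random.point - z * res.random.se, res.random.point + z * res.random.se)
            lo, hi = res.prediction_interval
            assert lo <= ci[0] + 1e-12 and hi >= ci[1] - 1e-12

    def test_needs_three_studies(self):
        with pytest.raises(PredictionIntervalUndefinedError):
            prediction_interval(0.0, 1.0, 0.0, k=2)


class TestOrderInvariance:
    @given(seed=st.integers(0, 10_000))
    def test_statistics_ignore_study_order(self, seed):
        rng = np.random.default_rng(seed)
        m = random_meta(rng)
        perm = rng.permutation(m.k)
        shuffled = MetaInput(estimates=tuple(m.estimates[i] for i in perm))
        a, b = analyze(m), analyze(shuffled)
        assert (a.Q, a.p_value, a.I2, a.tau2) == (b.Q, b.p_value, b.I2, b.tau2)
        assert a.fixed == b.fixed and a.random == b.random
        assert a.prediction_interval == b.prediction_interval


class TestCompareMeasures:
    def test_identical_tables_homogeneous_on_all_measures(self):
        tabs = [
            TwoByTwoTable(label=f"t{i}", a=30, n1=100, c=40, n0=100) for i in range(3)
        ]
        res = compare_measures(tabs)
        for r in res.values():
            assert r.Q == pytest.approx(0.0, abs=1e-12)

    def test_constant_or_heterogeneous_on_rd_scale(self):
        # two large trials with OR 0.5 and control risks 0.5 / 0.1:
        # treated risks 1/3 and 1/19, so RDs -1/6 vs -0.04737 differ
        n = 30_000
        tabs = [
            TwoByTwoTable(label="lo", a=n / 3, n1=n, c=n / 2, n0=n),
            TwoByTwoTable(label="hi", a=n / 19, n1=n, c=n / 10, n0=n),
        ]
        res = compare_measures(tabs)
        assert res["log-or"].Q == pytest.approx(0.0, abs=1e-10)
        assert res["rd"].Q > 3.84
        assert res["rd"].I2 > 0.5

    def test_fixture_homogeneous_on_log_rr(self, fixture_tables):
        res = compare_measures(fixture_tables)
        assert res["log-rr"].I2 == 0.0


class TestReporting:
    def test_report_style(self, fixture_meta):
        report = format_report(analyze(fixture_meta))
        assert "Q = 3.29" in report
        assert "p = 0.51" in report
        assert "I2 = 0%" in report
        assert "T2 = 0" in report

    def test_json_mirrors_result(self, fixture_meta):
        res = analyze(fixture_meta)
        d = to_json_dict(res)
        assert set(d) >= {"Q", "df", "p", "I2", "tau2", "fixed", "random",
                          "prediction_interval"}
        assert d["Q"] == res.Q and d["tau2"] == res.tau2
        json.dumps(d)  # serializable


class TestAgainstMetafor:
    def test_dl_model_matches_metafor(self, tmp_path):
        """Independent cross-check of Q, I2, tau2 and both pooled models
        against metafor::rma(method='DL') run through Rscript."""
        rng = np.random.default_rng(11)
        m = random_meta(rng, k=6)
        yi = ",".join(repr(float(e.point)) for e in m.estimates)
        vi = ",".join(repr(float(e.variance)) for e in m.estimates)
        script = tmp_path / "dl.R"
        script.write_text(
            f"""
suppressMessages(library(metafor))
yi <- c({yi}); vi <- c({vi})
fit <- rma(yi = yi, vi = vi, method = "DL")
fe <- rma(yi = yi, vi = vi, method = "FE")
cat(jsonlite::toJSON(list(Q = fit$QE, p = fit$QEp, I2 = fit$I2,
    tau2 = fit$tau2, re_b = as.numeric(fit$b), re_se = fit$se,
    fe_b = as.numeric(fe$b), fe_se = fe$se), digits = 12, auto_unbox = TRUE))
"""
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        res = analyze(m)
        assert res.Q == pytest.approx(ref["Q"], rel=1e-8)
        assert res.p_value == pytest.approx(ref["p"], rel=1e-8)
        assert res.I2 * 100 == pytest.approx(ref["I2"], abs=1e-6)
        assert res.tau2 == pytest.approx(ref["tau2"], rel=1e-8, abs=1e-10)
        assert res.fixed.point == pytest.approx(ref["fe_b"], rel=1e-8)
        assert res.fixed.se == pytest.approx(ref["fe_se"], rel=1e-8)
        assert res.random.point == pytest.approx(ref["re_b"], rel=1e-8)
        assert res.random.se == pytest.approx(ref["re_se"], rel=1e-8)
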