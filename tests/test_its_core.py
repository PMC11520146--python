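import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from parkrun_its.calendars import WEEKS_PER_YEAR
from parkrun_its.data_ingest import WeeklySeries
from parkrun_its.its_core import (
    InterruptionConfig,
    ITSFit,
    RankDeficientDesign,
    build_design,
    fit_quasipoisson,
    fit_series,
    rate_ratio_table,
    residual_diagnostics,
    season_index,
)
from parkrun_its.synthetic_data import make_default_scenario, simulate_series

from conftest import make_series, poisson_mle


@pytest.mark.parametrize(
    "day,level",
    [
        (dt.date(2019, 1, 3), 1),    # first four-week block
        (dt.date(2019, 1, 28), 1),   # day 28, still block 1
        (dt.date(2019, 2, 1), 2),    # day 32
        (dt.date(2019, 12, 31), 13), # day 365, remainder block
        (dt.date(2020, 12, 31), 13), # leap year day 366
        (dt.date(2019, 11, 30), 12),
    ],
)
def test_season_index(day, level):
    assert season_index(day) == level


def test_season_levels_cover_1_to_13_over_a_year():
    days = [dt.date(2019, 1, 1) + dt.timedelta(days=i) for i in range(365)]
    levels = pd.Series([season_index(d) for d in days])
    assert sorted(levels.unique()) == list(range(1, 14))
    counts = levels.value_counts()
    assert (counts.loc[range(1, 13)] == 28).all()
    assert counts.loc[13] == 365 - 12 * 28


@pytest.fixture(scope="module")
def design():
    series = make_series(np.ones(425, int), start=dt.date(2015, 1, 3))
    return build_design(series, InterruptionConfig())


class TestBuildDesign:
    @pytest.mark.parametrize(
        "day,lam,sig,T",
        [
            (dt.date(2019, 6, 1), 0, 0, 0.0),   # pre-pandemic
            (dt.date(2020, 6, 6), 1, 0, 0.0),   # inside the gap
            (dt.date(2021, 7, 24), 0, 1, 0.0),  # first post-reopening Saturday
        ],
    )
    def test_indicators(self, design, day, lam, sig, T):
        row = design.frame[design.frame["date"] == day].iloc[0]
        assert (row["lam"], row["sig"], row["T"]) == (lam, sig, T)

    def test_lam_and_sig_mutually_exclusive(self, design):
        assert (design.frame["lam"] * design.frame["sig"]).max() == 0

    def test_T_advances_one_week_per_row_after_reopening(self, design):
        post = design.frame[design.frame["sig"] == 1]
        diffs = np.diff(post["T"].to_numpy())
        np.testing.assert_allclose(diffs, 1.0 / WEEKS_PER_YEAR, rtol=1e-12)
        assert (design.frame.loc[design.frame["sig"] == 0, "T"] == 0).all()

    def test_offset_is_log_population_per_1000(self, design):
        np.testing.assert_allclose(design.offsets(), math.log(1000 / 1000.0))

    def test_reopen_before_window_rejected(self):
        series = make_series([1, 2, 3], start=dt.date(2022, 1, 1))
        with pytest.raises(ValueError, match="reopen"):
            build_design(series, InterruptionConfig())


class TestFitQuasipoisson:
    def test_intercept_only_closed_form(self):
        # constant counts, offset log(1000/1000) = 0: beta0 = ln(c)
        series = make_series(np.full(30, 17), population=1000)
        fit, _ = fit_series(series)
        assert fit.params["intercept"] == pytest.approx(math.log(17), abs=1e-8)
        others = fit.params.drop("intercept")
        np.testing.assert_allclose(others, 0.0, atol=1e-6)

    def test_matches_brute_force_mle_on_fibonacci_counts(self):
        counts = [2, 3, 5, 8, 13, 20]
        series = make_series(counts)
        design = build_design(series, InterruptionConfig())
        fit = fit_quasipoisson(design, counts, terms=["intercept", "t"])
        X = design.matrix()[["intercept", "t"]].to_numpy()
        oracle = poisson_mle(X, counts, design.offsets())
        np.testing.assert_allclose(fit.params.to_numpy(), oracle, rtol=1e-6)

    def test_dispersion_near_one_for_poisson_data(self):
        cfg = make_default_scenario(
            seed=404, n_weeks=400, dispersion=1.0,
            beta1=0.0, beta2=0.0, beta4=0.0, beta5=0.0, beta6=0.0,
        )
        series, _ = simulate_series(cfg)
        total = next(s for s in series if s.stratum == "total")
        fit, _ = fit_series(total)
        assert 0.8 <= fit.dispersion <= 1.2

    def test_population_scale_changes_only_intercept(self, default_sim):
        _, series, _ = default_sim
        total = next(s for s in series if s.stratum == "total")
        fit_a, _ = fit_series(total)
        scaled = WeeklySeries(
            stratum="total", population=total.population * 10, data=total.data.copy()
        )
        fit_b, _ = fit_series(scaled)
        # larger denominator, same counts: the baseline rate drops tenfold
        assert fit_b.params["intercept"] == pytest.approx(
            fit_a.params["intercept"] - math.log(10), abs=1e-8
        )
        rest = [c for c in fit_a.params.index if c != "intercept"]
        np.testing.assert_allclose(
            fit_a.params[rest], fit_b.params[rest], rtol=1e-8, atol=1e-8
        )

    def test_gap_exclusion_equals_pinned_gap_offset(self, default_sim):
        _, series, _ = default_sim
        total = next(s for s in series if s.stratum == "total")
        design = build_design(total, InterruptionConfig())
        excl = fit_quasipoisson(design, total.counts, gap_handling="exclude")
        pinned = fit_quasipoisson(design, total.counts, gap_handling="offset", gap_offset=-20.0)
        np.testing.assert_allclose(
            excl.params.to_numpy(), pinned.params[excl.params.index].to_numpy(),
            rtol=1e-6, atol=1e-9,
        )

    def test_post_terms_dropped_for_pre_period_window(self):
        # 50-week 2018 window: sig/T/T_sq identically zero on estimation rows
        rng = np.random.default_rng(3)
        series = make_series(rng.poisson(40, 50))
        fit, _ = fit_series(series)
        assert set(fit.dropped_terms) >= {"sig", "T", "T_sq"}

    def test_collinear_design_raises_naming_columns(self):
        series = make_series(np.arange(10) + 5)
        design = build_design(series, InterruptionConfig())
        design.frame["t_sq"] = design.frame["t"]  # manufacture exact collinearity
        with pytest.raises(RankDeficientDesign, match="t"):
            fit_quasipoisson(design, series.counts)

    def test_misaligned_counts_rejected(self):
        series = make_series([1, 2, 3])
        design = build_design(series, InterruptionConfig())
        with pytest.raises(ValueError, match="aligned"):
            fit_quasipoisson(design, [1, 2])


def _manual_fit(params: dict, se: float = 0.0) -> ITSFit:
    names = list(params)
    return ITSFit(
        params=pd.Series(params),
        cov=pd.DataFrame(np.eye(len(names)) * se**2, index=names, columns=names),
        dispersion=1.0,
        n_obs=100,
        df_resid=100 - len(names),
        converged=True,
        dropped_terms=(),
        stratum="manual",
    )


class TestRateRatioTable:
    def test_zero_coefficient_gives_unit_rr(self):
        fit = _manual_fit({t: 0.0 for t in ("intercept", "t", "t_sq", "sig", "T", "T_sq")})
        table = rate_ratio_table({"manual": fit})
        assert table.loc[0, "Step change"] == "1.00 (1.00-1.00)"

    def test_wald_interval_and_shape(self, default_sim):
        _, series, _ = default_sim
        fits = {}
        for s in series:
            fits[s.stratum], _ = fit_series(s)
        table = rate_ratio_table(fits)
        assert len(table) == 6
        assert list(table["stratum"]) == ["q1", "q2", "q3", "q4", "q5", "total"]
        for _, label in [("t", "Pre-pandemic trend: linear (per year)")]:
            rr = table[f"{label} [RR]"]
            lo = table[f"{label} [lo]"]
            hi = table[f"{label} [hi]"]
            assert ((lo <= rr) & (rr <= hi) & (lo > 0)).all()
        # CI endpoints are exp(beta +- 1.96 se)
        fit = fits["total"]
        rr, lo, hi = fit.rate_ratio("sig")
        b, s = fit.params["sig"], fit.se("sig")
        assert lo == pytest.approx(math.exp(b - 1.959963984540054 * s))
        assert hi == pytest.approx(math.exp(b + 1.959963984540054 * s))


class TestResidualDiagnostics:
    def test_perfect_fit_gives_zero_residuals(self):
        # counts equal the model's fitted means exactly
        series = make_series(np.full(20, 50))
        fit, design = fit_series(series)
        res = residual_diagnostics(fit, design, series.counts)
        np.testing.assert_allclose(res.pearson, 0.0, atol=1e-6)
        np.testing.assert_allclose(res.deviance, 0.0, atol=1e-6)

    def test_pearson_identity_reproduces_dispersion(self, total_fit):
        total, fit, design = total_fit
        res = residual_diagnostics(fit, design, total.counts)
        n_p = fit.n_obs - len(fit.params)
        assert np.sum(res.pearson**2) / n_p == pytest.approx(fit.dispersion, rel=1e-10)

    def test_low_lag1_autocorrelation_when_well_specified(self):
        cfg = make_default_scenario(seed=2024, n_weeks=400)
        series, _ = simulate_series(cfg)
        total = next(s for s in series if s.stratum == "total")
        fit, design = fit_series(total)
        res = residual_diagnostics(fit, design, total.counts)
        assert abs(res.lag1_autocorr) < 0.15

    def test_plot_file_written(self, total_fit, tmp_path):
        total, fit, design = total_fit
        path = tmp_path / "resid.png"
        residual_diagnostics(fit, design, total.counts, plot_path=str(path))
        assert path.exists() and path.stat().st_size > 0
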