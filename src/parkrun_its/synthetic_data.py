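"""Synthetic weekly finisher series from the segmented generative model.

Emulates the structure of the real data: near-linear growth with slight
quadratic damping from January 2015, multiplicative 13-level seasonality,
overdispersed counts (variance phi * mean via a gamma-Poisson mixture), a
total-shutdown gap of exactly-zero weeks, an immediate step decrease at
reopening, and altered post-reopening linear + quadratic growth.  Five
quintile-like strata differ in baseline level and population only, mirroring
the near-proportional deprivation-quintile curves of the real series.

Because quasi-Poisson specifies only a variance function, the generative
stand-in is the negative binomial parameterised by mean mu and variance
phi * mu (shape mu/(phi-1)), the standard choice; phi = 1 degenerates to
Poisson exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math

import numpy as np
import pandas as pd

from .calendars import DEFAULT_WINDOW_START
from .data_ingest import STRATA, WeeklySeries
from .its_core import InterruptionConfig, ITSDesign, build_design

#: paper-period study length: Saturdays 2015-01-03 .. 2023-02-18
DEFAULT_N_WEEKS = 425


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Full generative parameterisation of the simulator.

    Trend coefficients are on the log scale with time in years, so
    ``exp(beta1)`` is the pre-interruption per-year growth rate ratio, etc.
    ``baseline_log_rate`` is log(finishes per 1000 residents per week) at
    the window start for each stratum (season level 1).
    """

    n_weeks: int = DEFAULT_N_WEEKS
    window_start: dt.date = DEFAULT_WINDOW_START
    gap_start: dt.date = dt.date(2020, 3, 21)
    reopen_date: dt.date = dt.date(2021, 7, 24)
    populations: tuple[int, ...] = (11_200_000,) * 5
    baseline_log_rate: tuple[float, ...] = tuple(
        math.log(r) for r in (0.35, 0.70, 1.10, 1.50, 2.10)
    )
    beta1: float = math.log(1.34)
    beta2: float = math.log(0.98)
    beta4: float = math.log(0.71)
    beta5: float = math.log(0.76)
    beta6: float = math.log(1.21)
    seasonal_multipliers: tuple[float, ...] = (
        1.00, 1.06, 1.10, 1.08, 1.02, 0.97, 0.94, 0.92, 0.96, 1.01, 0.99, 0.93, 0.88,
    )
    dispersion: float = 3.0
    seed: int = 20150103

    def __post_init__(self) -> None:
        if self.n_weeks <= 0:
            raise ValueError("n_weeks must be positive")
        if len(self.populations) != len(self.baseline_log_rate):
            raise ValueError("populations and baseline_log_rate lengths differ")
        if len(self.seasonal_multipliers) != 13:
            raise ValueError("need 13 seasonal multipliers")
        if abs(self.seasonal_multipliers[0] - 1.0) > 1e-12:
            raise ValueError("seasonal multiplier for level 1 must be 1 (reference)")
        if any(s <= 0 for s in self.seasonal_multipliers):
            raise ValueError("seasonal multipliers must be positive")
        if self.dispersion < 1.0:
            raise ValueError("dispersion must be >= 1")
        if not (self.window_start < self.gap_start < self.reopen_date):
            raise ValueError("gap dates must lie inside the window")

    @property
    def interruption(self) -> InterruptionConfig:
        return InterruptionConfig(self.gap_start, self.reopen_date)

    def coefficients(self, stratum_idx: int) -> dict[str, float]:
        """Generating coefficients in the estimator's term names."""
        coef = {
            "intercept": self.baseline_log_rate[stratum_idx],
            "t": self.beta1,
            "t_sq": self.beta2,
            "sig": self.beta4,
            "T": self.beta5,
            "T_sq": self.beta6,
        }
        for k in range(2, 14):
            coef[f"season_{k}"] = math.log(self.seasonal_multipliers[k - 1])
        return coef


@dataclasses.dataclass
class SyntheticTruth:
    """Generating means and coefficients, the oracle for recovery tests.

    Per stratum: ``mu`` — true weekly mean (0 exactly in the gap);
    ``mu_counterfactual`` — true no-interruption mean; ``coefficients`` —
    the generating vector keyed by estimator term names.
    """

    mu: dict[str, np.ndarray]
    mu_counterfactual: dict[str, np.ndarray]
    coefficients: dict[str, dict[str, float]]
    rng_seed: int


def _true_means(design: ITSDesign, coef: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    X = design.matrix()
    beta = np.array([coef[c] for c in X.columns])
    eta = X.to_numpy() @ beta + design.offsets()
    mu_cf = np.exp(eta - X[["sig", "T", "T_sq"]].to_numpy() @ np.array(
        [coef["sig"], coef["T"], coef["T_sq"]]
    ))
    mu = np.exp(eta)
    mu[design.gap_mask] = 0.0
    return mu, mu_cf


def _draw_counts(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    counts = np.zeros(len(mu), dtype=np.int64)
    live = mu > 0
    if phi == 1.0:
        counts[live] = rng.poisson(mu[live])
    else:
        shape = mu[live] / (phi - 1.0)  # NB with mean mu, variance phi*mu
        counts[live] = rng.negative_binomial(shape, 1.0 / phi)
    return counts


def simulate_series(cfg: SyntheticConfig) -> tuple[list[WeeklySeries], SyntheticTruth]:
    """Draw one replicate: a WeeklySeries per stratum plus the total.

    Counts are negative-binomial with mean mu_w and variance phi * mu_w,
    independent across weeks and strata; gap weeks are exactly zero.
    Byte-for-byte reproducible for a fixed config (the seed is part of it).
    """
    rng = np.random.default_rng(cfg.seed)
    n_strata = len(cfg.populations)
    series: list[WeeklySeries] = []
    mu_all: dict[str, np.ndarray] = {}
    mu_cf_all: dict[str, np.ndarray] = {}
    coefs: dict[str, dict[str, float]] = {}

    template = _template_series(cfg)
    for i in range(n_strata):
        stratum = STRATA[i] if n_strata == 5 else f"s{i + 1}"
        skeleton = WeeklySeries(stratum=stratum, population=cfg.populations[i], data=template.copy())
        design = build_design(skeleton, cfg.interruption)
        coef = cfg.coefficients(i)
        mu, mu_cf = _true_means(design, coef)
        counts = _draw_counts(mu, cfg.dispersion, rng)

        data = template.copy()
        data["count"] = counts
        data["rate_per_1000"] = counts / cfg.populations[i] * 1000.0
        series.append(WeeklySeries(stratum=stratum, population=cfg.populations[i], data=data))
        mu_all[stratum], mu_cf_all[stratum], coefs[stratum] = mu, mu_cf, coef

    if n_strata == 5:  # aggregate total stratum, mirroring data_ingest
        pop_total = sum(cfg.populations)
        counts = np.sum([s.counts for s in series], axis=0)
        data = template.copy()
        data["count"] = counts
        data["rate_per_1000"] = counts / pop_total * 1000.0
        series.append(WeeklySeries(stratum="total", population=pop_total, data=data))
        mu_all["total"] = np.sum([mu_all[s.stratum] for s in series[:5]], axis=0)
        mu_cf_all["total"] = np.sum([mu_cf_all[s.stratum] for s in series[:5]], axis=0)

    truth = SyntheticTruth(
        mu=mu_all, mu_counterfactual=mu_cf_all, coefficients=coefs, rng_seed=cfg.seed
    )
    return series, truth


def _template_series(cfg: SyntheticConfig) -> pd.DataFrame:
    from .calendars import first_saturday_on_or_after

    anchor = first_saturday_on_or_after(cfg.window_start)
    weeks = np.arange(cfg.n_weeks)
    return pd.DataFrame(
        {
            "week_index": weeks,
            "date": [anchor + dt.timedelta(weeks=int(k)) for k in weeks],
            "count": 0,
            "rate_per_1000": 0.0,
        }
    )


def make_default_scenario(seed: int = 20150103, **overrides) -> SyntheticConfig:
    """The canonical recovery-test scenario.

    Generating rate ratios equal the headline total-population point
    estimates for the real series (pre-trend 1.34/yr, damping 0.98, step
    0.71, trend change 0.76 and 1.21), over 425 weeks from 2015-01-03 with
    the 2020-03-21 / 2021-07-24 shutdown gap and dispersion 3.
    """
    return SyntheticConfig(seed=seed, **overrides)


def simulate_to_csv(cfg: SyntheticConfig, path) -> None:
    """Write one replicate in the tidy stratum-level CSV schema."""
    from .data_ingest import write_series_csv

    series, _ = simulate_series(cfg)
    write_series_csv(series, path)


def write_synthetic_inputs(cfg: SyntheticConfig, out_dir) -> dict[str, str]:
    """Write raw-style input CSVs (finishers, IMD, population) for pipeline tests.

    Each stratum is represented as a single pseudo-area whose decile maps to
    the intended quintile, so the files exercise the full ingest path.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, _ = simulate_series(cfg)
    strata = [s for s in series if s.stratum != "total"]

    codes = [f"SYN{i + 1:03d}" for i in range(len(strata))]
    pd.DataFrame(
        {"lsoa_code": codes, "imd_decile": [2 * (i + 1) - 1 for i in range(len(strata))]}
    ).to_csv(out / "imd.csv", index=False)
    pd.DataFrame({"lsoa_code": codes, "population": [s.population for s in strata]}).to_csv(
        out / "population.csv", index=False
    )
    rows = []
    for code, s in zip(codes, strata):
        f = s.data
        rows.append(pd.DataFrame({"lsoa_code": code, "date": f["date"], "finishers": f["count"]}))
    pd.concat(rows, ignore_index=True).to_csv(out / "finishers.csv", index=False)
    return {
        "imd": str(out / "imd.csv"),
        "population": str(out / "population.csv"),
        "finishers": str(out / "finishers.csv"),
    }
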