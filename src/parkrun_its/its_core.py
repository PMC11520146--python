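"""Segmented quasi-Poisson regression for the interrupted weekly series.

The model for the expected weekly count mu_w of a stratum is

    log mu_w = log(pop/1000) + b0 + b1*t + b2*t^2
               + sigma_w * (b4 + b5*T + b6*T^2) + gamma_season(w)

with t = years since the window start, sigma_w = 1 from the reopening date
onward, T = years since reopening (0 before), and a 13-level categorical
seasonality (four-week calendar blocks, level 1 = reference).  Variance is
phi * mu (quasi-Poisson): the dispersion phi is estimated from the Pearson
chi-square and scales the Wald standard errors without moving the point
estimates.

The total-shutdown gap (every count exactly zero) makes the gap-level
coefficient's MLE diverge to -infinity, so estimation excludes the gap rows;
the remaining coefficients are identical to the limit of a fit that keeps
the gap rows with the gap effect pinned at a large negative offset (an
equivalence asserted in the test suite).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .calendars import WEEKS_PER_YEAR
from .data_ingest import WeeklySeries

#: design columns in fitting order (before the 12 seasonal contrasts)
BASE_TERMS = ("intercept", "t", "t_sq", "sig", "T", "T_sq")
SEASON_TERMS = tuple(f"season_{k}" for k in range(2, 14))

#: the five effects reported as per-year rate ratios, with display labels
RR_TERMS = (
    ("t", "Pre-pandemic trend: linear (per year)"),
    ("t_sq", "Pre-pandemic trend: quadratic (per year)"),
    ("sig", "Step change"),
    ("T", "Change in trend: linear (per year)"),
    ("T_sq", "Change in trend: quadratic (per year)"),
)


class RankDeficientDesign(ValueError):
    """The estimation design matrix is collinear beyond degenerate columns."""


@dataclasses.dataclass(frozen=True)
class InterruptionConfig:
    """Shutdown gap boundaries: [gap_start, reopen_date) has zero events."""

    gap_start: dt.date = dt.date(2020, 3, 21)
    reopen_date: dt.date = dt.date(2021, 7, 24)

    def __post_init__(self) -> None:
        if self.gap_start >= self.reopen_date:
            raise ValueError("gap_start must precede reopen_date")


@dataclasses.dataclass
class ITSDesign:
    """Per-week covariate rows for one stratum.

    ``frame`` columns: week_index, date, t, t_sq, season (1-13), lam, sig,
    T, T_sq, offset_log.  Rows with lam = 1 (the gap) are excluded from
    estimation but retained for prediction.
    """

    frame: pd.DataFrame
    population: int
    cfg: InterruptionConfig

    @property
    def gap_mask(self) -> np.ndarray:
        return self.frame["lam"].to_numpy() == 1

    def matrix(self, rows: np.ndarray | None = None) -> pd.DataFrame:
        """Model matrix (intercept, trends, step, post-trends, season dummies)."""
        f = self.frame if rows is None else self.frame[rows]
        X = pd.DataFrame(index=f.index)
        X["intercept"] = 1.0
        X["t"] = f["t"]
        X["t_sq"] = f["t_sq"]
        X["sig"] = f["sig"].astype(float)
        X["T"] = f["T"]
        X["T_sq"] = f["T_sq"]
        for k in range(2, 14):
            X[f"season_{k}"] = (f["season"] == k).astype(float)
        return X

    def offsets(self, rows: np.ndarray | None = None) -> np.ndarray:
        f = self.frame if rows is None else self.frame[rows]
        return f["offset_log"].to_numpy(float)


def season_index(day: dt.date) -> int:
    """13-level seasonal block of a date: 28-day blocks from 1 January.

    Levels 1-12 each span four weeks of the year; level 13 absorbs the final
    29 (30 in leap years) days.
    """
    doy = day.timetuple().tm_yday
    return min((doy - 1) // 28, 12) + 1


def build_design(series: WeeklySeries, cfg: InterruptionConfig | None = None) -> ITSDesign:
    """One covariate row per week of ``series`` under the interruption config."""
    cfg = cfg or InterruptionConfig()
    dates = series.dates
    if cfg.reopen_date < dates[0]:
        raise ValueError("reopen_date precedes the series window")

    week = series.data["week_index"].to_numpy()
    t = (week - week[0]) / WEEKS_PER_YEAR
    lam = np.array([cfg.gap_start <= d < cfg.reopen_date for d in dates], dtype=int)
    sig = np.array([d >= cfg.reopen_date for d in dates], dtype=int)
    # T advances by one week per row once reopened, converted to years
    weeks_since_reopen = np.where(sig == 1, np.cumsum(sig) - 1, 0)
    T = weeks_since_reopen / WEEKS_PER_YEAR

    frame = pd.DataFrame(
        {
            "week_index": week,
            "date": dates,
            "t": t,
            "t_sq": t**2,
            "season": [season_index(d) for d in dates],
            "lam": lam,
            "sig": sig,
            "T": T,
            "T_sq": T**2,
            "offset_log": np.log(series.population / 1000.0),
        }
    )
    return ITSDesign(frame=frame, population=series.population, cfg=cfg)


@dataclasses.dataclass
class ITSFit:
    """Fitted segmented quasi-Poisson model for one stratum.

    ``params``/``cov`` are indexed by term name; ``cov`` is already scaled by
    the Pearson dispersion.  Terms that were identically zero on the
    estimation rows are listed in ``dropped_terms`` (coefficient undefined).
    """

    params: pd.Series
    cov: pd.DataFrame
    dispersion: float
    n_obs: int
    df_resid: int
    converged: bool
    dropped_terms: tuple[str, ...]
    stratum: str = ""

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov.loc[term, term]))

    def coef(self, term: str) -> float:
        if term in self.dropped_terms:
            return 0.0
        return float(self.params[term])

    def rate_ratio(self, term: str, z: float = 1.959963984540054) -> tuple[float, float, float]:
        """(RR, lower, upper) for one coefficient, Wald 95% interval."""
        b, s = self.coef(term), self.se(term) if term in self.params.index else 0.0
        return float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s))

    def seasonal_multipliers(self) -> pd.Series:
        """exp(gamma) for levels 1..13 (level 1 = 1 by construction)."""
        vals = {1: 1.0}
        for k in range(2, 14):
            term = f"season_{k}"
            vals[k] = float(np.exp(self.params.get(term, 0.0)))
        return pd.Series(vals, name="seasonal_multiplier")

    def linear_predictor(self, X: pd.DataFrame, offset: np.ndarray) -> np.ndarray:
        cols = [c for c in X.columns if c in self.params.index]
        return X[cols].to_numpy() @ self.params[cols].to_numpy() + offset


def fit_quasipoisson(
    design: ITSDesign,
    counts: Sequence[int] | np.ndarray,
    *,
    gap_handling: str = "exclude",
    gap_offset: float = -20.0,
    maxiter: int = 100,
    tol: float = 1e-8,
    stratum: str = "",
    terms: Sequence[str] | None = None,
) -> ITSFit:
    """Fit the segmented model by IRLS with Pearson-dispersion scaled errors.

    ``gap_handling``: ``"exclude"`` drops the gap rows from estimation (the
    default, since an all-zero gap makes the gap level inestimable);
    ``"offset"`` keeps them with the gap effect fixed at ``gap_offset`` on
    the log scale, which converges to the same remaining coefficients.
    ``terms`` restricts the model to a subset of design columns (reduced
    models, e.g. intercept-only).
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) != len(design.frame):
        raise ValueError("counts not aligned with design rows")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")

    if gap_handling == "exclude":
        keep = ~design.gap_mask
    elif gap_handling == "offset":
        keep = np.ones(len(counts), dtype=bool)
    else:
        raise ValueError("gap_handling must be 'exclude' or 'offset'")

    X = design.matrix(keep)
    if terms is not None:
        unknown = [t for t in terms if t not in X.columns]
        if unknown:
            raise ValueError(f"unknown design terms: {unknown}")
        X = X[list(terms)]
    offset = design.offsets(keep)
    if gap_handling == "offset":
        offset = offset + gap_offset * design.frame["lam"].to_numpy(float)[keep]
    y = counts[keep]

    # degenerate columns (all-zero on estimation rows) carry no information
    nonzero = [c for c in X.columns if np.any(X[c].to_numpy() != 0.0)]
    dropped = tuple(c for c in X.columns if c not in nonzero)
    X = X[nonzero]

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns involved in the collinearity via QR pivoting
        _, R = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(R))
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] < 1e-10 * diag.max()]
        raise RankDeficientDesign(f"collinear design columns: {bad or list(X.columns)}")
    if len(y) < X.shape[1]:
        raise ValueError("fewer estimation weeks than parameters")

    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=maxiter, tol=tol)

    # Pearson dispersion applied post-fit (point estimates are scale-free);
    # a saturated fit gives phi = 0 and degenerate zero-width intervals
    df_resid = int(res.df_resid)
    phi = float(res.pearson_chi2 / df_resid) if df_resid > 0 else 0.0
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params() * phi, index=X.columns, columns=X.columns)
    return ITSFit(
        params=params,
        cov=cov,
        dispersion=phi,
        n_obs=int(len(y)),
        df_resid=df_resid,
        converged=bool(res.converged),
        dropped_terms=dropped,
        stratum=stratum,
    )


def fit_series(
    series: WeeklySeries, cfg: InterruptionConfig | None = None, **kwargs
) -> tuple[ITSFit, ITSDesign]:
    """Convenience: build the design for a series and fit it."""
    design = build_design(series, cfg)
    fit = fit_quasipoisson(design, series.counts, stratum=series.stratum, **kwargs)
    return fit, design


def rate_ratio_table(fits: dict[str, ITSFit]) -> pd.DataFrame:
    """Per-stratum rate ratios with 95% Wald intervals (wide display table).

    Rows follow the insertion order of ``fits`` (quintiles then total);
    columns are the five segmented-model effects, formatted "RR (lo-hi)"
    at 2 decimal places alongside numeric columns.
    """
    rows = []
    for stratum, fit in fits.items():
        row: dict[str, object] = {"stratum": stratum}
        for term, label in RR_TERMS:
            rr, lo, hi = fit.rate_ratio(term)
            row[f"{label}"] = f"{rr:.2f} ({lo:.2f}-{hi:.2f})"
            row[f"{label} [RR]"] = rr
            row[f"{label} [lo]"] = lo
            row[f"{label} [hi]"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ResidualSummary:
    pearson: np.ndarray
    deviance: np.ndarray
    mean_pearson: float
    lag1_autocorr: float
    dispersion: float


def residual_diagnostics(
    fit: ITSFit,
    design: ITSDesign,
    counts: Sequence[int] | np.ndarray,
    plot_path: str | None = None,
) -> ResidualSummary:
    """Deviance and Pearson residuals on the non-gap weeks, plus a plot."""
    counts = np.asarray(counts, dtype=float)
    keep = ~design.gap_mask
    X = design.matrix(keep)
    mu = np.exp(fit.linear_predictor(X, design.offsets(keep)))
    y = counts[keep]

    pearson = (y - mu) / np.sqrt(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_term = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
    deviance = np.sign(y - mu) * np.sqrt(2.0 * np.clip(dev_term, 0.0, None))

    r = pearson - pearson.mean()
    lag1 = float(np.sum(r[1:] * r[:-1]) / np.sum(r**2)) if len(r) > 1 else 0.0

    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
        dates = list(design.frame["date"][keep])
        axes[0].axhline(0.0, color="grey", lw=0.8)
        axes[0].plot(dates, pearson, ".", ms=3)
        axes[0].set_ylabel("Pearson residual")
        axes[1].axhline(0.0, color="grey", lw=0.8)
        axes[1].plot(dates, deviance, ".", ms=3, color="darkred")
        axes[1].set_ylabel("Deviance residual")
        fig.suptitle(f"Residuals — {fit.stratum or 'series'}")
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)

    return ResidualSummary(
        pearson=pearson,
        deviance=deviance,
        mean_pearson=float(pearson.mean()),
        lag1_autocorr=lag1,
        dispersion=float(np.sum(pearson**2) / (len(y) - len(fit.params))),
    )
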