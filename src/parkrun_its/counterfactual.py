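"""Counterfactual extrapolation, lost-finish accounting and trend crossover.

The no-interruption counterfactual sets the step and post-reopening trend
terms to zero for every week and extrapolates the pre-interruption model
(with full seasonality) across the whole window.  "Trend" curves average
the seasonal effect out multiplicatively — the mean of exp(gamma) over the
13 levels weighted by how many weeks each level covers in the window — so
they can be compared without seasonal wiggle.  Shortfalls are counterfactual
minus observed counts, summed over calendar periods.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .calendars import WEEKS_PER_YEAR
from .its_core import ITSDesign, ITSFit

logger = logging.getLogger(__name__)

#: default reporting periods (label, start, end) — half-open [start, end)
DEFAULT_PERIODS = (
    ("March 2020-July 2021", dt.date(2020, 3, 21), dt.date(2021, 7, 24)),
    ("July 2021-February 2023", dt.date(2021, 7, 24), dt.date(2023, 3, 1)),
)


@dataclasses.dataclass
class CounterfactualResult:
    """Weekly expected-vs-observed counts for one stratum.

    ``frame`` columns: week_index, date, observed, expected_count (seasonal
    counterfactual), expected_trend (season-averaged counterfactual),
    fitted_post (season-averaged post-reopening model, 0 before reopening),
    shortfall (expected_count - observed).
    """

    frame: pd.DataFrame
    stratum: str = ""


@dataclasses.dataclass
class PeriodSummary:
    label: str
    n_weeks: int
    counterfactual_total: float
    observed_total: int

    @property
    def difference(self) -> float:
        return self.counterfactual_total - self.observed_total

    @property
    def pct_decrease(self) -> float:
        return 100.0 * self.difference / self.counterfactual_total


def mean_seasonal_factor(fit: ITSFit, design: ITSDesign) -> float:
    """Average multiplicative seasonal effect, weighted by weeks per level."""
    mult = fit.seasonal_multipliers()
    weights = design.frame["season"].value_counts()
    levels = weights.index.to_numpy()
    return float(np.average(mult[levels], weights=weights.to_numpy()))


def predict_counterfactual(
    fit: ITSFit, design: ITSDesign, observed: Sequence[int] | np.ndarray
) -> CounterfactualResult:
    """Extrapolate the pre-interruption model across the design window."""
    observed = np.asarray(observed)
    if len(observed) != len(design.frame):
        raise ValueError("observed counts not aligned with design rows")

    X = design.matrix()
    offset = design.offsets()

    # counterfactual: no step, no post-trend, full seasonality
    X_cf = X.copy()
    X_cf[["sig", "T", "T_sq"]] = 0.0
    expected = np.exp(fit.linear_predictor(X_cf, offset))

    season_bar = mean_seasonal_factor(fit, design)
    X_trend = X_cf.copy()
    X_trend[[c for c in X_trend.columns if c.startswith("season_")]] = 0.0
    expected_trend = np.exp(fit.linear_predictor(X_trend, offset)) * season_bar

    # post-reopening model trend (step + changed slope), season-averaged
    X_post = X.copy()
    X_post[[c for c in X_post.columns if c.startswith("season_")]] = 0.0
    sig = design.frame["sig"].to_numpy()
    fitted_post = np.where(sig == 1, np.exp(fit.linear_predictor(X_post, offset)) * season_bar, 0.0)

    frame = pd.DataFrame(
        {
            "week_index": design.frame["week_index"].to_numpy(),
            "date": list(design.frame["date"]),
            "observed": observed,
            "expected_count": expected,
            "expected_trend": expected_trend,
            "fitted_post": fitted_post,
        }
    )
    frame["shortfall"] = frame["expected_count"] - frame["observed"]
    return CounterfactualResult(frame=frame, stratum=fit.stratum)


def lost_finishes(
    cf: CounterfactualResult,
    periods: Sequence[tuple[str, dt.date, dt.date]] = DEFAULT_PERIODS,
    *,
    all_periods_label: str = "Total",
) -> list[PeriodSummary]:
    """Period totals of counterfactual, observed and lost finishes.

    Week membership is by Saturday date in the half-open window
    ``[start, end)``.  A final row labelled ``all_periods_label`` covers the
    union of the periods; overlapping periods trigger a warning since their
    union row would not equal the column sums.
    """
    dates = np.array(cf.frame["date"])
    union = np.zeros(len(dates), dtype=bool)
    out: list[PeriodSummary] = []
    overlap = False
    for label, start, end in periods:
        member = np.array([start <= d < end for d in dates])
        if (member & union).any():
            overlap = True
        union |= member
        out.append(_summarise(cf, member, label))
    if overlap:
        logger.warning("lost_finishes: overlapping periods — totals double-count weeks")
    out.append(_summarise(cf, union, all_periods_label))
    return out


def _summarise(cf: CounterfactualResult, member: np.ndarray, label: str) -> PeriodSummary:
    sub = cf.frame[member]
    return PeriodSummary(
        label=label,
        n_weeks=int(member.sum()),
        counterfactual_total=float(sub["expected_count"].sum()),
        observed_total=int(sub["observed"].sum()),
    )


def weekly_average_shortfall(summary: PeriodSummary, n_weeks: int | None = None) -> float:
    """Mean lost finishes per week over a period."""
    n = summary.n_weeks if n_weeks is None else n_weeks
    if n <= 0:
        raise ValueError("n_weeks must be positive")
    return summary.difference / n


def period_table(summaries: Sequence[PeriodSummary]) -> pd.DataFrame:
    """Display table: counterfactual / observed / difference (% decrease)."""
    return pd.DataFrame(
        {
            "Time period": [s.label for s in summaries],
            "Counterfactual N": [round(s.counterfactual_total) for s in summaries],
            "Observed N": [s.observed_total for s in summaries],
            "Difference N": [round(s.difference) for s in summaries],
            "% decrease": [round(s.pct_decrease, 1) for s in summaries],
        }
    )


def crossover_week(
    fit: ITSFit,
    design: ITSDesign,
    horizon_years: float = 5.0,
) -> dt.date | None:
    """First Saturday on/after reopening where the post-reopening trend
    reaches the counterfactual trend (season-averaged scales cancel, so the
    condition is b4 + b5*T + b6*T^2 >= 0), or None within the horizon."""
    b4, b5, b6 = fit.coef("sig"), fit.coef("T"), fit.coef("T_sq")
    reopen = design.cfg.reopen_date
    n = int(np.ceil(horizon_years * WEEKS_PER_YEAR)) + 1
    for k in range(n):
        T = k / WEEKS_PER_YEAR
        if b4 + b5 * T + b6 * T**2 >= 0.0:
            return reopen + dt.timedelta(weeks=k)
    return None


# ---------------------------------------------------------------------------
# figures


def plot_participation(
    series: Sequence, path: str, events_per_week: pd.Series | None = None
) -> None:
    """Weekly participation rates per stratum; optional event counts on a twin axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 5))
    for s in series:
        ax.plot(list(s.data["date"]), s.data["rate_per_1000"], lw=0.8, label=s.stratum)
    ax.set_ylabel("finishes per 1000 residents")
    ax.set_xlabel("week")
    ax.legend(loc="upper left", fontsize=8, ncol=2)
    if events_per_week is not None:
        ax2 = ax.twinx()
        ax2.plot(events_per_week.index, events_per_week.to_numpy(), color="grey", lw=0.6)
        ax2.set_ylabel("events per week")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_counterfactual(results: Sequence[CounterfactualResult], populations: dict, path: str) -> None:
    """Observed rates (thin), counterfactual trend (dotted), post trend (solid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 5))
    for cf in results:
        pop = populations[cf.stratum] / 1000.0
        f = cf.frame
        dates = list(f["date"])
        (line,) = ax.plot(dates, f["observed"] / pop, lw=0.6, alpha=0.6, label=cf.stratum)
        ax.plot(dates, f["expected_trend"] / pop, ls=":", lw=1.4, color=line.get_color())
        post = f[f["fitted_post"] > 0]
        ax.plot(list(post["date"]), post["fitted_post"] / pop, lw=2.0, color=line.get_color())
    ax.set_ylabel("finishes per 1000 residents")
    ax.set_xlabel("week")
    ax.legend(loc="upper left", fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
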