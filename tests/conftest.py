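import datetime as dt

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from parkrun_its.data_ingest import WeeklySeries
from parkrun_its.its_core import fit_series
from parkrun_its.synthetic_data import make_default_scenario, simulate_series


def make_series(counts, population=1000, start=dt.date(2018, 1, 6), stratum="s"):
    """Consecutive weekly series starting on a given Saturday."""
    counts = np.asarray(counts, dtype=int)
    weeks = np.arange(len(counts))
    data = pd.DataFrame(
        {
            "week_index": weeks,
            "date": [start + dt.timedelta(weeks=int(k)) for k in weeks],
            "count": counts,
            "rate_per_1000": counts / population * 1000.0,
        }
    )
    return WeeklySeries(stratum=stratum, population=population, data=data)


def poisson_mle(X, y, offset):
    """Brute-force Poisson log-likelihood maximisation (independent oracle).

    Newton iterations on the exact gradient/Hessian of the log link
    likelihood, written directly from the formulas — no GLM machinery.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)

    def nll(beta):
        eta = X @ beta + offset
        return float(np.sum(np.exp(eta)) - y @ eta)

    def grad(beta):
        mu = np.exp(X @ beta + offset)
        return X.T @ (mu - y)

    def hess(beta):
        mu = np.exp(X @ beta + offset)
        return (X * mu[:, None]).T @ X

    res = scipy.optimize.minimize(
        nll, np.zeros(X.shape[1]), jac=grad, hess=hess, method="Newton-CG",
        options={"xtol": 1e-14, "maxiter": 500},
    )
    # polish with one explicit Newton step for machine-precision stationarity
    beta = res.x
    for _ in range(5):
        beta = beta - np.linalg.solve(hess(beta), grad(beta))
    return beta


@pytest.fixture(scope="session")
def default_sim():
    cfg = make_default_scenario(seed=11)
    series, truth = simulate_series(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def total_fit(default_sim):
    """Fitted segmented model on the total stratum of the default scenario."""
    _, series, _ = default_sim
    total = next(s for s in series if s.stratum == "total")
    fit, design = fit_series(total)
    return total, fit, design
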