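"""Statistical pipeline for the behavioural (or simulated) trial data.

Steps mirror the analysis applied to the experiment: trials at the two
non-zero disparities are recoded as natural versus reversed depth;
per-participant proportions are pooled by probit averaging,
``Phi(mean_i Phi^-1(p_i))``; 95% confidence limits come from a
parametric bootstrap in which each participant's success count is
redrawn from a binomial at their observed rate (10 000 resamples); and
each condition is fitted with a probit regression of the binary
natural/reversed outcome on eccentricity, estimated here from first
principles by iteratively reweighted least squares (a fixed-effects
probit GLM; no random-effects structure is modelled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_N_BOOT = 10_000


def code_natural(trials: pd.DataFrame) -> pd.DataFrame:
    """Recode near/far responses as natural/reversed depth.

    Natural means the judgment agrees with the disparity sign: ``near``
    at a crossed (positive) disparity or ``far`` at an uncrossed one.
    Zero-disparity rows carry no depth-direction code and are dropped.
    """
    if "disparity_arcmin" not in trials:
        raise KeyError("trials table lacks a 'disparity_arcmin' column")
    out = trials[trials["disparity_arcmin"] != 0].copy()
    near = out["response"] == "near"
    out["natural"] = (near & (out["disparity_arcmin"] > 0)
                      | ~near & (out["disparity_arcmin"] < 0))
    return out


def continuity_correct(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Pull proportions of 0 or 1 inside (0, 1) by half a trial's worth."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    return np.clip(p, 1.0 / (2.0 * n), 1.0 - 1.0 / (2.0 * n))


def probit_average(proportions: np.ndarray) -> float:
    """Pool proportions through the probit transform.

    Returns ``Phi(mean_i Phi^-1(p_i))``.  Inputs must lie strictly
    inside (0, 1); apply :func:`continuity_correct` first if a
    participant scored 0 or 1.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise ValueError("no proportions to average")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("proportions must be strictly inside (0, 1); "
                         "apply a continuity correction first")
    return float(norm.cdf(norm.ppf(p).mean()))


def bootstrap_ci(
    successes: np.ndarray,
    n: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = 0.95,
    rng: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Parametric-bootstrap percentile interval for the probit-averaged
    proportion.

    Each replicate redraws every participant's count from
    ``Binomial(n_i, p_hat_i)`` and recomputes the probit average;
    the percentile interval of the replicates is returned.
    """
    successes = np.atleast_1d(np.asarray(successes, dtype=int))
    n = np.atleast_1d(np.asarray(n, dtype=int))
    if np.any(n < 1):
        raise ValueError("each participant needs at least one trial")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p_hat = continuity_correct(successes / n, n)
    draws = rng.binomial(n[None, :], p_hat[None, :], size=(n_boot, len(n)))
    p_rep = continuity_correct(draws / n[None, :], n[None, :])
    stat = norm.cdf(norm.ppf(p_rep).mean(axis=1))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stat, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class ProbitFit:
    """Maximum-likelihood probit regression coefficients and diagnostics."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    converged: bool
    n_iter: int
    n_obs: int
    message: str = ""

    @property
    def t_intercept(self) -> float:
        return self.intercept / self.se_intercept

    @property
    def t_slope(self) -> float:
        return self.slope / self.se_slope

    @property
    def df(self) -> int:
        return self.n_obs - 2


def probit_loglik(beta: np.ndarray, x: np.ndarray, successes: np.ndarray,
                  n: np.ndarray) -> float:
    """Binomial-probit log-likelihood at coefficients ``(b0, b1)``."""
    eta = beta[0] + beta[1] * x
    mu = np.clip(norm.cdf(eta), 1e-12, 1.0 - 1e-12)
    return float((successes * np.log(mu) + (n - successes) * np.log1p(-mu)).sum())


def probit_fit_counts(
    x: np.ndarray,
    successes: np.ndarray,
    n: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProbitFit:
    """Probit GLM on grouped binomial data by Fisher-scoring IRLS.

    `x` is the predictor (eccentricity in arcmin), `successes` the
    natural-direction counts out of `n` trials per group.  Convergence
    is declared when the largest score component falls below `tol`;
    separation (all-success or all-failure data, or a diverging fit) is
    flagged as non-converged with a diagnostic message.
    """
    x = np.asarray(x, dtype=float)
    successes = np.asarray(successes, dtype=float)
    n = np.asarray(n, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("at least two distinct predictor values are required")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    message = ""
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.clip(norm.cdf(eta), 1e-10, 1.0 - 1e-10)
        phi = norm.pdf(eta)
        score = X.T @ (phi * (successes - n * mu) / (mu * (1.0 - mu)))
        w = n * phi**2 / (mu * (1.0 - mu))
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "singular Fisher information (separation?)"
            break
        beta = beta + step
        if np.abs(eta).max() > 30.0 or np.abs(beta[0]) > 1e3:
            message = "diverging estimates; data are (quasi-)separable"
            break
        if np.abs(score).max() < tol:
            converged = True
            break
    eta = X @ beta
    mu = np.clip(norm.cdf(eta), 1e-10, 1.0 - 1e-10)
    phi = norm.pdf(eta)
    w = n * phi**2 / (mu * (1.0 - mu))
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    return ProbitFit(
        intercept=float(beta[0]), slope=float(beta[1]),
        se_intercept=float(se[0]), se_slope=float(se[1]),
        converged=converged, n_iter=it, n_obs=int(n.sum()), message=message,
    )


def probit_glm_fit(
    trials: pd.DataFrame,
    predictor: str = "eccentricity_arcmin",
    outcome: str = "natural",
    **kwargs,
) -> ProbitFit:
    """Probit regression of a binary outcome on one predictor.

    Expects a coded trial table (see :func:`code_natural`); rows with a
    missing outcome are dropped.  Trials are grouped by predictor value
    and fitted with :func:`probit_fit_counts`.
    """
    t = trials.dropna(subset=[outcome])
    g = t.groupby(predictor)[outcome].agg(["sum", "count"]).reset_index()
    return probit_fit_counts(g[predictor].to_numpy(dtype=float),
                             g["sum"].to_numpy(dtype=float),
                             g["count"].to_numpy(dtype=float), **kwargs)


CONDITION_KEYS = ["configuration", "duration_ms", "correlation"]


def summarize(
    trials: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = 0.95,
    rng: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Probit-averaged proportions with bootstrap CIs, per condition and
    eccentricity, for both the depth judgments and the confidence flags."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    coded = code_natural(trials)
    rows = []
    keys = CONDITION_KEYS + ["eccentricity_arcmin"]
    for key, grp in coded.groupby(keys, sort=True):
        per = grp.groupby("participant").agg(
            k_nat=("natural", "sum"), n=("natural", "count"),
            k_conf=("confident", "sum"))
        rec = dict(zip(keys, key))
        rec["n_participants"] = len(per)
        rec["n_trials"] = int(per["n"].sum())
        for name, col in (("natural", "k_nat"), ("confident", "k_conf")):
            k = per[col].to_numpy(dtype=int)
            n = per["n"].to_numpy(dtype=int)
            p = continuity_correct(k / n, n)
            lo, hi = bootstrap_ci(k, n, n_boot=n_boot, level=level, rng=rng)
            rec[f"proportion_{name}"] = probit_average(p)
            rec[f"ci_low_{name}"], rec[f"ci_high_{name}"] = lo, hi
        rows.append(rec)
    return pd.DataFrame(rows)


def fit_conditions(trials: pd.DataFrame,
                   predictor: str = "eccentricity_arcmin") -> pd.DataFrame:
    """Per-condition probit regressions of natural coding on eccentricity."""
    coded = code_natural(trials)
    rows = []
    for key, grp in coded.groupby(CONDITION_KEYS, sort=True):
        fit = probit_glm_fit(grp, predictor=predictor)
        rec = dict(zip(CONDITION_KEYS, key))
        rec.update(intercept=fit.intercept, slope=fit.slope,
                   se_intercept=fit.se_intercept, se_slope=fit.se_slope,
                   t_intercept=fit.t_intercept, t_slope=fit.t_slope,
                   df=fit.df, converged=fit.converged, n_iter=fit.n_iter)
        rows.append(rec)
    return pd.DataFrame(rows)
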