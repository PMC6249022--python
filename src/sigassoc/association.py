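"""Driver–signature association tests.

The central model is a binary univariate logistic regression within one
cancer type: for each (driver mutation, signature) pair, driver presence y
is regressed on the signature's exposure proportion x,

    p(x) = 1 / (1 + exp(-(beta0 + beta1 * x))),

and the association is summarised by the odds ratio exp(beta1) with a
two-sided Wald p-value for beta1 = 0. A pair is tested only if at least 10
samples of the cancer type carry the driver and at least 10 samples have
>= 20% exposure to the signature.

The Newton/IRLS fitter is written for this exact two-parameter design so
that the permutation-FDR machinery can refit thousands of shuffled response
columns in one vectorised pass (:func:`fit_logistic_batch`).

Secondary group comparisons (rank and location tests between driver-mutant
and wild-type samples) live here too.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from scipy.stats import t as t_dist

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "fit_logistic_batch",
    "odds_ratio",
    "eligible_pairs",
    "run_associations",
    "mann_whitney_u",
    "t_test_unpaired",
]

logger = logging.getLogger(__name__)

#: |beta1| beyond which the likelihood is treated as monotone (separation)
SEPARATION_BETA = 30.0
_MAX_STEP = 5.0  # Newton step clip, keeps early iterations stable


@dataclass
class LogisticFit:
    beta0: float
    beta1: float
    se_beta1: float
    p_value: float
    fit_status: str  # ok | separation | no_convergence
    n_iter: int

    @property
    def odds_ratio(self) -> float:
        return odds_ratio(self.beta1)


def odds_ratio(beta1: float) -> float:
    """Odds ratio per unit exposure proportion: exp(beta1)."""
    if not np.isfinite(beta1):
        raise ValueError(f"beta1 must be finite, got {beta1!r}")
    return float(np.exp(beta1))


def fit_logistic_batch(
    y: np.ndarray,
    x: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``p(x) = expit(beta0 + beta1 x)`` to many response columns at once.

    Parameters
    ----------
    y : (n, B) array of 0/1 responses — B designs sharing the covariate.
    x : (n,) covariate.

    Returns
    -------
    beta0, beta1, se_beta1, p_value : (B,) arrays
    status : (B,) object array of {"ok", "separation", "no_convergence"}

    Newton–Raphson on the log-likelihood; the 2×2 Hessian solve is closed
    form. Columns where |beta1| exceeds ``SEPARATION_BETA`` are flagged as
    separation; a constant covariate yields ``no_convergence`` with p = 1.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(x, dtype=float)
    n, B = y.shape
    if x.shape != (n,):
        raise ValueError("x must have one value per row of y")
    if ((y != 0) & (y != 1)).any():
        raise ValueError("y must be binary")
    if (y.sum(axis=0) == 0).any() or (y.sum(axis=0) == n).any():
        raise ValueError("each response column must contain both classes")

    status = np.full(B, "ok", dtype=object)
    if np.ptp(x) == 0:
        logger.warning("constant covariate: logistic slope undefined, p set to 1")
        base = math.log(y.mean() / (1 - y.mean())) if 0 < y.mean() < 1 else 0.0
        return (
            np.full(B, base),
            np.full(B, np.nan),
            np.full(B, np.nan),
            np.ones(B),
            np.full(B, "no_convergence", dtype=object),
        )

    b0 = np.zeros(B)
    b1 = np.zeros(B)
    live = np.ones(B, dtype=bool)
    x2 = x * x
    it = 0
    for it in range(1, max_iter + 1):
        eta = b0[None, :] + np.outer(x, b1)
        p = expit(eta)
        resid = y - p
        g0 = resid.sum(axis=0)
        g1 = x @ resid
        if not (np.maximum(np.abs(g0), np.abs(g1))[live] > tol * n).any():
            break
        w = p * (1.0 - p)
        h00 = w.sum(axis=0)
        h01 = x @ w
        h11 = x2 @ w
        det = h00 * h11 - h01 * h01
        sing = det <= np.finfo(float).tiny
        det = np.where(sing, 1.0, det)
        d0 = np.clip((h11 * g0 - h01 * g1) / det, -_MAX_STEP, _MAX_STEP)
        d1 = np.clip((h00 * g1 - h01 * g0) / det, -_MAX_STEP, _MAX_STEP)
        step = live & ~sing
        b0[step] += d0[step]
        b1[step] += d1[step]
        status[sing & live] = "no_convergence"
        live &= ~sing
        sep = live & (np.abs(b1) > SEPARATION_BETA)
        status[sep] = "separation"
        live &= ~sep
        if not live.any():
            break
    else:
        grad_big = np.maximum(np.abs(g0), np.abs(g1)) > 1e-6 * n
        status[live & grad_big] = "no_convergence"

    # Wald standard error of beta1 from the final Hessian
    p = expit(b0[None, :] + np.outer(x, b1))
    w = p * (1.0 - p)
    h00 = w.sum(axis=0)
    h01 = x @ w
    h11 = x2 @ w
    det = h00 * h11 - h01 * h01
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 0, h00 / det, np.nan))
        z = b1 / se1
    pval = 2.0 * norm.sf(np.abs(z))
    pval = np.where(np.isnan(pval), 1.0, pval)
    return b0, b1, se1, pval, status


def fit_logistic(
    y, x, max_iter: int = 100, tol: float = 1e-10
) -> LogisticFit:
    """Fit the binary univariate logistic model for one response vector."""
    b0, b1, se1, p, status = fit_logistic_batch(
        np.asarray(y)[:, None], np.asarray(x), max_iter=max_iter, tol=tol
    )
    return LogisticFit(
        beta0=float(b0[0]),
        beta1=float(b1[0]),
        se_beta1=float(se1[0]),
        p_value=float(p[0]),
        fit_status=str(status[0]),
        n_iter=max_iter,
    )


def eligible_pairs(
    call_matrix: pd.DataFrame,
    exposures: pd.DataFrame,
    cancer_types: pd.Series,
    min_mut: int = 10,
    min_sig: int = 10,
    sig_prop: float = 0.20,
) -> pd.DataFrame:
    """Enumerate the (cancer type, driver, signature) triples worth testing.

    A triple is eligible when, within the cancer type, at least ``min_mut``
    samples carry the driver and at least ``min_sig`` samples hold an
    exposure of at least ``sig_prop`` to the signature.

    Returns a DataFrame with columns ``cancer_type``, ``driver``,
    ``signature``, ``n_samples``, ``n_mutant``, ``n_sig_eligible``.
    """
    if not call_matrix.index.equals(exposures.index):
        raise ValueError("call matrix and exposures must cover the same samples")
    rows = []
    for ctype, idx in call_matrix.groupby(cancer_types).groups.items():
        calls = call_matrix.loc[idx]
        expo = exposures.loc[idx]
        n_mut = calls.sum(axis=0)
        n_sig = (expo >= sig_prop).sum(axis=0)
        for driver in calls.columns[n_mut >= min_mut]:
            for signature in expo.columns[n_sig >= min_sig]:
                rows.append(
                    {
                        "cancer_type": ctype,
                        "driver": driver,
                        "signature": signature,
                        "n_samples": len(idx),
                        "n_mutant": int(n_mut[driver]),
                        "n_sig_eligible": int(n_sig[signature]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "cancer_type", "driver", "signature",
            "n_samples", "n_mutant", "n_sig_eligible",
        ],
    )


def run_associations(
    call_matrix: pd.DataFrame,
    exposures: pd.DataFrame,
    cancer_types: pd.Series,
    min_mut: int = 10,
    min_sig: int = 10,
    sig_prop: float = 0.20,
) -> pd.DataFrame:
    """Fit the logistic model for every eligible triple.

    Returns one row per triple with the regression estimates, odds ratio,
    Wald p-value and fit status appended to the eligibility columns.
    """
    triples = eligible_pairs(
        call_matrix, exposures, cancer_types,
        min_mut=min_mut, min_sig=min_sig, sig_prop=sig_prop,
    )
    results = []
    for _, row in triples.iterrows():
        idx = cancer_types.index[cancer_types == row["cancer_type"]]
        y = call_matrix.loc[idx, row["driver"]].to_numpy()
        x = exposures.loc[idx, row["signature"]].to_numpy()
        fit = fit_logistic(y, x)
        results.append(
            {
                **row,
                "pct_mutant": 100.0 * row["n_mutant"] / row["n_samples"],
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "se_beta1": fit.se_beta1,
                "p_value": fit.p_value,
                "odds_ratio": np.exp(fit.beta1),
                "fit_status": fit.fit_status,
                "eligible": True,
            }
        )
    cols = list(triples.columns) + [
        "pct_mutant", "beta0", "beta1", "se_beta1",
        "p_value", "odds_ratio", "fit_status", "eligible",
    ]
    return pd.DataFrame(results, columns=cols)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann–Whitney U for sample ``a``, with midrank handling of ties."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank(method="average").to_numpy()
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def mann_whitney_u(a, b, sided: str = "two") -> tuple[float, float]:
    """Mann–Whitney U test with midranks.

    For pooled sizes up to 12 the p-value is computed by exact enumeration
    of all group assignments of the pooled multiset (ties included); larger
    samples use the normal approximation with tie and continuity
    corrections. ``sided`` is one of ``"two"``, ``"one_greater"`` (a tends
    larger than b) or ``"one_less"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if sided not in ("two", "one_greater", "one_less"):
        raise ValueError(f"unknown sidedness {sided!r}")
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)

    if n_a + n_b <= 12:
        pooled = np.concatenate([a, b])
        us = np.array(
            [
                _u_statistic(pooled[list(pick)],
                             np.delete(pooled, list(pick)))
                for pick in combinations(range(n_a + n_b), n_a)
            ]
        )
        eps = 1e-9
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        if sided == "one_greater":
            p = p_ge
        elif sided == "one_less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, float(p)

    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all values identical
        return u_obs, 1.0
    sigma = math.sqrt(sigma2)
    if sided == "one_greater":
        p = norm.sf((u_obs - mu - 0.5) / sigma)
    elif sided == "one_less":
        p = norm.cdf((u_obs - mu + 0.5) / sigma)
    else:
        z = (abs(u_obs - mu) - 0.5) / sigma
        p = 2.0 * norm.sf(max(z, 0.0))
    return u_obs, float(min(p, 1.0))


def t_test_unpaired(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance (Student) t-test.

    Degenerate zero-variance input yields p = 1 when the means agree and
    p = 0 otherwise (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    n_a, n_b = len(a), len(b)
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        logger.warning("zero pooled variance in t-test (degenerate input)")
        return (0.0, 1.0) if diff == 0 else (math.copysign(math.inf, diff), 0.0)
    t = diff / math.sqrt(sp2 * (1 / n_a + 1 / n_b))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(p)
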