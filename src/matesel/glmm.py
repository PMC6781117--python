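"""Male reproductive success: Poisson GLMM with a per-male random intercept.

The model for clutch ``j`` of male ``i``::

    y_ij ~ Poisson(mu_ij),  log mu_ij = beta0 + beta_zyg * z_i + u_i,
    u_i ~ Normal(0, sigma_u^2)

``z_i`` codes the male's MHC zygosity (0 = homozygote, 1 = heterozygote) and
``y_ij`` is the clutch offspring count.  The marginal likelihood integrates
the random intercept per male by the Laplace approximation (default) or
adaptive Gauss-Hermite quadrature (``nagq > 1``); with ``sigma_u`` fixed at
0 the fit reduces to a plain Poisson regression solved by an internal
iteratively reweighted least squares routine, which provides the nested-
model check.  Standard errors come from the numerical Hessian of the
marginal log-likelihood; the zygosity effect is tested by a Wald z-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special, stats

__all__ = [
    "GlmmFit",
    "fit_poisson_random_intercept",
    "poisson_glm_irls",
    "bootstrap_effect_ci",
    "simulate_clutches",
]


@dataclass
class GlmmFit:
    beta0: float
    beta_zyg: float
    sigma_u: float
    se_beta0: float
    se_beta_zyg: float
    wald_p: float
    loglik: float
    n_clutches: int
    n_males: int
    converged: bool
    nagq: int

    def predict(self, zygosity: int) -> float:
        """Conditional (u = 0) predicted clutch size for a zygosity class."""
        return float(np.exp(self.beta0 + self.beta_zyg * zygosity))


def _as_frame(clutches) -> pd.DataFrame:
    if isinstance(clutches, pd.DataFrame):
        df = clutches.copy()
    else:
        df = pd.DataFrame(clutches, columns=["male_id", "zygosity", "count"])
    for col in ("male_id", "zygosity", "count"):
        if col not in df.columns:
            raise ValueError(f"clutch table missing column {col!r}")
    if (df["count"] < 0).any():
        raise ValueError("negative clutch counts")
    if not set(df["zygosity"].unique()) <= {0, 1}:
        raise ValueError("zygosity must be coded 0 (homozygote) / 1 (heterozygote)")
    return df


def _group_arrays(df: pd.DataFrame):
    groups = []
    for _, sub in df.groupby("male_id", sort=True):
        z = float(sub["zygosity"].iloc[0])
        if sub["zygosity"].nunique() != 1:
            raise ValueError("a male's zygosity must be constant across clutches")
        groups.append((z, sub["count"].to_numpy(dtype=float)))
    return groups


def _group_loglik(
    y: np.ndarray, x: float, sigma: float, nagq: int, ghq
) -> float:
    """Marginal log-likelihood contribution of one male (Laplace or AGHQ)."""
    ysum = y.sum()
    const = -special.gammaln(y + 1.0).sum()
    if sigma < 1e-10:
        eta = x
        return const + float(ysum * eta - y.size * np.exp(eta))
    # inner Newton for the posterior mode of u
    u = 0.0
    for _ in range(50):
        mu = y.size * np.exp(x + u)
        grad = ysum - mu - u / sigma**2
        hess = -mu - 1.0 / sigma**2
        step = grad / hess
        u -= step
        if abs(step) < 1e-12:
            break
    mu = y.size * np.exp(x + u)
    h = ysum * (x + u) - mu - u**2 / (2.0 * sigma**2)
    curv = mu + 1.0 / sigma**2  # -h''(u_hat)
    if nagq <= 1:
        return const + h - np.log(sigma) - 0.5 * np.log(curv)
    nodes, weights = ghq
    s = 1.0 / np.sqrt(curv)
    ui = u + s * nodes
    hi = ysum * (x + ui) - y.size * np.exp(x + ui) - ui**2 / (2.0 * sigma**2)
    # adaptive GHQ with probabilists' nodes: int e^h du = s * sum w_i e^{h_i + t_i^2/2} / ...
    vals = hi + 0.5 * nodes**2
    m = vals.max()
    integral = s * np.sum(weights * np.exp(vals - m))
    return const + m + np.log(integral) - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)


def _total_loglik(theta: np.ndarray, groups, nagq: int, ghq) -> float:
    beta0, beta1, log_sigma = theta
    sigma = np.exp(log_sigma)
    return sum(
        _group_loglik(y, beta0 + beta1 * z, sigma, nagq, ghq) for z, y in groups
    )


def poisson_glm_irls(
    z: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Plain Poisson regression of y on [1, z] by IRLS; returns (beta, cov)."""
    X = np.column_stack([np.ones_like(z, dtype=float), z.astype(float)])
    beta = np.zeros(2)
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(max_iter):
        mu = np.exp(X @ beta)
        W = mu
        info = X.T @ (W[:, None] * X)
        score = X.T @ (y - mu)
        step = np.linalg.solve(info, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = np.exp(X @ beta)
    cov = np.linalg.inv(X.T @ (mu[:, None] * X))
    return beta, cov


def fit_poisson_random_intercept(
    clutches,
    nagq: int = 1,
    fix_sigma: Optional[float] = None,
) -> GlmmFit:
    """Fit the Poisson random-intercept model by marginal maximum likelihood.

    ``nagq=1`` uses the Laplace approximation; larger values switch to
    adaptive Gauss-Hermite quadrature with that many nodes.  ``fix_sigma=0``
    constrains the random intercept away, reproducing a plain Poisson GLM.
    """
    df = _as_frame(clutches)
    groups = _group_arrays(df)
    n_classes = {0: 0, 1: 0}
    for z, _ in groups:
        n_classes[int(z)] += 1
    if min(n_classes.values()) < 2:
        raise ValueError(
            f"need at least 2 males per zygosity class, got {n_classes}"
        )
    by_class = df.groupby("zygosity")["count"].sum()
    if (by_class == 0).any():
        raise ValueError("complete separation: one zygosity class has all-zero counts")

    ghq = hermegauss(max(nagq, 2))
    y_all = df["count"].to_numpy(dtype=float)
    z_all = df["zygosity"].to_numpy(dtype=float)

    if fix_sigma is not None and fix_sigma == 0.0:
        beta, cov = poisson_glm_irls(z_all, y_all)
        se = np.sqrt(np.diag(cov))
        wald_p = 2.0 * stats.norm.sf(abs(beta[1] / se[1]))
        ll = float(
            np.sum(y_all * (beta[0] + beta[1] * z_all))
            - np.sum(np.exp(beta[0] + beta[1] * z_all))
            - special.gammaln(y_all + 1.0).sum()
        )
        return GlmmFit(
            float(beta[0]), float(beta[1]), 0.0, float(se[0]), float(se[1]),
            float(wald_p), ll, len(df), len(groups), True, nagq,
        )

    beta_start, _ = poisson_glm_irls(z_all, y_all)
    start = np.array([beta_start[0], beta_start[1], np.log(0.3)])

    def neg(theta: np.ndarray) -> float:
        return -_total_loglik(theta, groups, nagq, ghq)

    res = optimize.minimize(neg, start, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    converged = bool(res.success)
    res2 = optimize.minimize(neg, res.x, method="BFGS")
    if res2.fun <= res.fun:
        res = res2
        converged = converged or bool(res2.success)
    theta = res.x
    loglik = -res.fun

    if np.exp(theta[2]) < 1e-4:
        # optimum on the sigma_u = 0 boundary: the log-sigma Hessian is
        # degenerate there, so report the constrained Poisson GLM, whose
        # fixed-effect SEs are exact for that model
        fit0 = fit_poisson_random_intercept(df, nagq=nagq, fix_sigma=0.0)
        fit0.converged = fit0.converged and converged
        return fit0

    # observed-information SEs for the fixed effects (numerical Hessian)
    hess = _numerical_hessian(neg, theta)
    try:
        cov = np.linalg.inv(hess)
        se0, se1 = np.sqrt(np.abs(np.diag(cov)[:2]))
        ses_ok = np.all(np.diag(cov)[:2] > 0)
    except np.linalg.LinAlgError:
        se0 = se1 = np.nan
        ses_ok = False
    wald_p = 2.0 * stats.norm.sf(abs(theta[1] / se1)) if ses_ok else np.nan
    return GlmmFit(
        float(theta[0]), float(theta[1]), float(np.exp(theta[2])),
        float(se0), float(se1), float(wald_p), float(loglik),
        len(df), len(groups), converged, nagq,
    )


def _numerical_hessian(fn, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    hess = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            val = (
                fn(x + ei + ej) - fn(x + ei - ej) - fn(x - ei + ej) + fn(x - ei - ej)
            ) / (4.0 * eps**2)
            hess[i, j] = hess[j, i] = val
    return hess


def bootstrap_effect_ci(
    clutches,
    n_boot: int = 10000,
    seed: Optional[int] = None,
    nagq: int = 1,
) -> pd.DataFrame:
    """Cluster bootstrap (males resampled with replacement) of the fitted
    response curve; returns the 2.5/97.5 percentile band of the predicted
    clutch size per zygosity class."""
    df = _as_frame(clutches)
    male_ids = sorted(df["male_id"].unique())
    by_male = {m: df[df["male_id"] == m] for m in male_ids}
    rng = np.random.default_rng(seed)
    preds = np.empty((n_boot, 2))
    point = fit_poisson_random_intercept(df, nagq=nagq)
    for b in range(n_boot):
        chosen = rng.choice(male_ids, size=len(male_ids), replace=True)
        parts = []
        for k, m in enumerate(chosen):
            sub = by_male[m].copy()
            sub["male_id"] = f"boot_{k}"  # resampled males are distinct clusters
            parts.append(sub)
        boot = pd.concat(parts, ignore_index=True)
        try:
            fit = fit_poisson_random_intercept(boot, nagq=nagq)
            preds[b] = [fit.predict(0), fit.predict(1)]
        except ValueError:
            preds[b] = [np.nan, np.nan]
    lo = np.nanpercentile(preds, 2.5, axis=0)
    hi = np.nanpercentile(preds, 97.5, axis=0)
    return pd.DataFrame(
        {
            "zygosity": [0, 1],
            "predicted": [point.predict(0), point.predict(1)],
            "ci_low": lo,
            "ci_high": hi,
        }
    )


def simulate_clutches(
    beta0: float = 2.5,
    beta_zyg: float = 0.3,
    sigma_u: float = 0.2,
    n_males: int = 40,
    clutches_per_male: int = 3,
    p_het: float = 0.5,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate clutch counts from the model itself (for recovery checks)."""
    rng = np.random.default_rng(seed)
    rows = []
    z = (rng.random(n_males) < p_het).astype(int)
    # guarantee both classes are populated
    z[0], z[1] = 0, 1
    u = rng.normal(0.0, sigma_u, size=n_males)
    for i in range(n_males):
        mu = np.exp(beta0 + beta_zyg * z[i] + u[i])
        for _ in range(clutches_per_male):
            rows.append(
                {"male_id": f"M{i:03d}", "zygosity": int(z[i]),
                 "count": int(rng.poisson(mu))}
            )
    return pd.DataFrame(rows)
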