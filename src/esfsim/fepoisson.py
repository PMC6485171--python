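"""Fixed-effects Poisson regression for municipality-year count panels.

Maximum-likelihood estimation of

    deaths_it ~ Poisson( exposure_it * exp(alpha_i + x_it' beta) )

with one intercept per municipality.  The intercepts are profiled out
analytically (given beta, the MLE is alpha_i = log(sum_t y / sum_t mu))
and Newton steps are taken on the profile likelihood of beta, whose
Hessian is the Schur complement of the full-model Hessian; the Wald
covariance of beta therefore equals the one from the equivalent
dummy-variable GLM, at O(n k^2) cost per iteration.  Non-integer
(expected-count) responses are accepted, as in quasi-likelihood fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FEPoissonResult", "fit_fe_poisson"]


@dataclass
class FEPoissonResult:
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    alpha: pd.Series
    converged: bool
    n_iter: int
    loglike: float
    dropped_groups: list

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {
                "lo": self.params - z * self.bse,
                "hi": self.params + z * self.bse,
            }
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Fixed-effects Poisson regression",
            "=" * 60,
            f"groups: {self.alpha.size}   converged: {self.converged} "
            f"({self.n_iter} iterations)   loglike: {self.loglike:.2f}",
            f"{'term':<28}{'coef':>10}{'se':>9}{'95% CI':>16}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<28}{self.params[name]:>10.4f}{self.bse[name]:>9.4f}"
                f"   [{ci.loc[name, 'lo']:>6.3f}, {ci.loc[name, 'hi']:>6.3f}]"
            )
        return "\n".join(lines)


def fit_fe_poisson(
    y,
    X: pd.DataFrame,
    groups,
    exposure,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> FEPoissonResult:
    """Fit the fixed-effects Poisson model.

    Parameters
    ----------
    y : array-like
        Death counts (non-negative; may be non-integer expectations).
    X : DataFrame
        Covariates; columns are internally standardised for conditioning
        and results returned on the original scale.
    groups : array-like
        Municipality labels; groups whose counts are all zero contribute
        no information to beta and are dropped (reported in
        ``dropped_groups``).
    exposure : array-like
        Person-years (the offset enters as log(exposure)).
    """
    y = np.asarray(y, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if (exposure <= 0).any():
        raise ValueError("exposure must be strictly positive")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    codes, labels = pd.factorize(np.asarray(groups), sort=True)
    G = labels.size

    group_y = np.bincount(codes, weights=y, minlength=G)
    keep_groups = group_y > 0
    dropped = [labels[g] for g in range(G) if not keep_groups[g]]
    keep = keep_groups[codes]
    y, Xv, exposure, codes = y[keep], Xv[keep], exposure[keep], codes[keep]
    codes, labels = pd.factorize(labels[codes], sort=True)
    G = labels.size
    if G == 0:
        raise ValueError("all groups have zero total counts")
    group_y = np.bincount(codes, weights=y, minlength=G)

    # column standardisation (within-group variation is what identifies beta)
    center = Xv.mean(axis=0)
    scale = Xv.std(axis=0)
    if (scale == 0).any():
        flat = [names[j] for j in range(len(names)) if scale[j] == 0]
        raise ValueError(
            f"covariates with no variation (collinear with the intercepts): {flat}"
        )
    Z = (Xv - center) / scale
    k = Z.shape[1]

    # a column constant within every group is absorbed by the intercepts
    counts = np.bincount(codes, minlength=G).astype(float)
    gmean = np.zeros((G, k))
    for j in range(k):
        gmean[:, j] = np.bincount(codes, weights=Z[:, j], minlength=G) / counts
    within_ss = ((Z - gmean[codes]) ** 2).sum(axis=0)
    if (within_ss < 1e-10 * len(y)).any():
        flat = [names[j] for j in range(k) if within_ss[j] < 1e-10 * len(y)]
        raise ValueError(
            f"covariates with no within-group variation (collinear with the "
            f"fixed effects): {flat}"
        )

    beta = np.zeros(k)
    converged = False
    ll_old = -np.inf
    H = np.eye(k)
    for it in range(1, max_iter + 1):
        lin = Z @ beta
        base = exposure * np.exp(lin)
        group_base = np.bincount(codes, weights=base, minlength=G)
        alpha = np.log(group_y / group_base)
        mu = base * np.exp(alpha[codes])
        ll = float(np.sum(y * np.log(mu) - mu))
        score = Z.T @ (y - mu)
        A = Z.T @ (mu[:, None] * Z)
        B = np.zeros((G, k))
        for j in range(k):
            B[:, j] = np.bincount(codes, weights=mu * Z[:, j], minlength=G)
        Dg = np.bincount(codes, weights=mu, minlength=G)
        H = A - B.T @ (B / Dg[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "singular profile Hessian: covariates are collinear"
            ) from err
        norm = np.max(np.abs(step))
        if norm > 10.0:  # trust region on the standardised scale
            step *= 10.0 / norm
        # damped Newton: halve the step while the likelihood would decrease
        t = 1.0
        llc = -np.inf
        accepted = False
        for _ in range(40):
            cand = beta + t * step
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                linc = Z @ cand
                basec = exposure * np.exp(linc)
                gb = np.bincount(codes, weights=basec, minlength=G)
                alc = np.log(group_y / gb)
                muc = basec * np.exp(alc[codes])
                llc = float(np.sum(y * np.log(muc) - muc))
            if np.isfinite(llc) and llc >= ll - 1e-12:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break  # cannot improve further; report non-convergence below
        beta = beta + t * step
        if np.max(np.abs(t * step)) < tol and abs(llc - ll_old) < 1e-9:
            converged = True
            ll_old = llc
            break
        ll_old = llc

    # final state at the converged beta
    lin = Z @ beta
    base = exposure * np.exp(lin)
    group_base = np.bincount(codes, weights=base, minlength=G)
    alpha = np.log(group_y / group_base)
    mu = base * np.exp(alpha[codes])
    score = Z.T @ (y - mu)
    A = Z.T @ (mu[:, None] * Z)
    B = np.zeros((G, k))
    for j in range(k):
        B[:, j] = np.bincount(codes, weights=mu * Z[:, j], minlength=G)
    Dg = np.bincount(codes, weights=mu, minlength=G)
    H = A - B.T @ (B / Dg[:, None])
    cov_z = np.linalg.inv(H)
    loglike = float(np.sum(y * np.log(mu) - mu))
    # a stalled line search at a (numerically) zero gradient is converged
    if not converged and np.max(np.abs(score)) < 1e-6 * max(1.0, abs(loglike)):
        converged = True

    # back-transform to the original covariate scale
    beta_orig = beta / scale
    cov_orig = cov_z / np.outer(scale, scale)
    alpha_orig = alpha - float(np.dot(beta_orig, center))

    params = pd.Series(beta_orig, index=names)
    bse = pd.Series(np.sqrt(np.diag(cov_orig)), index=names)
    return FEPoissonResult(
        params=params,
        bse=bse,
        cov_params=pd.DataFrame(cov_orig, index=names, columns=names),
        alpha=pd.Series(alpha_orig, index=labels, name="alpha"),
        converged=converged,
        n_iter=it,
        loglike=loglike,
        dropped_groups=dropped,
    )
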