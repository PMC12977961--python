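"""Longitudinal outcome models.

* ``fit_change_lmm`` — linear mixed model for change-from-baseline memory
  z-scores at 3 and 12 months with a random intercept per subject, fitted
  by maximum likelihood (not REML) so that likelihood-ratio tests on fixed
  effects between nested models are valid.  Confounds: timepoint (factor,
  3-month reference), age at surgery, age at epilepsy onset, normalized
  resection volume and the preoperative z-score; the tract term
  (transection fraction, disconnection probability or rescaled remaining
  volume) is optional so confound-only and confound-plus-tract fits nest.
* ``fit_binary_glmm`` — logistic random-intercept model (ML via
  Gauss-Hermite quadrature) for binary outcomes such as RCI decline;
  with one observation per subject (ILAE seizure freedom) the random
  intercept is dropped and the fit reduces to logistic regression.
* ``likelihood_ratio_test`` — chi-squared comparison of nested ML fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, special, stats

__all__ = [
    "ModelFit",
    "LRTResult",
    "fit_change_lmm",
    "fit_binary_glmm",
    "likelihood_ratio_test",
    "binarize_ilae",
]

CONFOUNDS = ("age_surgery", "age_onset", "resection_volume", "pre_z")


@dataclass
class ModelFit:
    params: pd.Series  # fixed effects
    bse: pd.Series
    re_var: float  # random-intercept variance
    llf: float  # ML log-likelihood
    n_obs: int
    n_subjects: int
    converged: bool
    df_fixed: int
    kind: str = "lmm"
    penalized: bool = False
    scale: float = float("nan")  # residual variance (LMM only)

    def summary_dict(self) -> dict:
        return {
            "kind": self.kind,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "re_var": self.re_var,
            "llf": self.llf,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "penalized": self.penalized,
        }


@dataclass
class LRTResult:
    chi_sq: float
    df: int
    p: float


def _check_full_rank(df: pd.DataFrame, cols: list[str]) -> None:
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = ["intercept"] + list(cols)
        _, r = np.linalg.qr(X)
        d = np.abs(np.diag(r))
        thr = max(X.shape) * np.finfo(float).eps * d.max()
        bad = [names[j] for j in range(len(names)) if d[j] <= thr]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_change_lmm(
    data: pd.DataFrame,
    response: str = "change_z",
    tract_term: str | None = None,
    confounds=CONFOUNDS,
    timepoint_col: str = "timepoint",
    group_col: str = "subject_id",
    reference_timepoint: str = "3m",
) -> ModelFit:
    """Random-intercept LMM for longitudinal change scores, ML estimation.

    Rows with a missing response or predictor are dropped; subjects
    contributing a single timepoint are retained.  Non-convergence is
    reported through ``converged``, never silently.
    """
    cols = [response, timepoint_col, group_col, *confounds]
    if tract_term is not None:
        cols.append(tract_term)
    df = data[cols].dropna().copy()
    numeric = [c for c in cols if c not in (timepoint_col, group_col)]
    _check_full_rank(df, numeric)

    terms = [f"C({timepoint_col}, Treatment(reference='{reference_timepoint}'))"]
    terms += list(confounds)
    if tract_term is not None:
        terms.append(tract_term)
    formula = f"{response} ~ " + " + ".join(terms)

    # degenerate noise-free data makes the ML profile unbounded; fall back
    # to the interpolating OLS solution in that limit
    import patsy

    y_arr, X_arr = patsy.dmatrices(formula, df, return_type="dataframe")
    beta_ls, *_ = np.linalg.lstsq(X_arr.to_numpy(), y_arr.to_numpy().ravel(), rcond=None)
    res_ls = y_arr.to_numpy().ravel() - X_arr.to_numpy() @ beta_ls
    y_sd = np.std(y_arr.to_numpy()) or 1.0
    if np.max(np.abs(res_ls)) <= 1e-9 * y_sd:
        params = pd.Series(beta_ls, index=list(X_arr.columns))
        return ModelFit(
            params=params,
            bse=pd.Series(0.0, index=params.index),
            re_var=0.0,
            llf=float("inf"),
            n_obs=len(df),
            n_subjects=df[group_col].nunique(),
            converged=True,
            df_fixed=len(params),
            kind="lmm",
            scale=0.0,
        )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=df[group_col])
        try:
            result = model.fit(reml=False, method="bfgs")
        except np.linalg.LinAlgError:
            result = model.fit(reml=False, method="powell")
    converged = bool(getattr(result, "converged", True)) and not any(
        "did not converge" in str(w.message).lower() for w in caught
    )
    fe = result.fe_params
    return ModelFit(
        params=fe,
        bse=result.bse.loc[fe.index],
        re_var=float(result.cov_re.iloc[0, 0]),
        llf=float(result.llf),
        n_obs=int(result.nobs),
        n_subjects=df[group_col].nunique(),
        converged=converged,
        df_fixed=len(fe),
        kind="lmm",
        scale=float(result.scale),
    )


# ---------------------------------------------------------------------------
# logistic random-intercept GLMM, ML by Gauss-Hermite quadrature


def _glmm_negll(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    group_index: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    weights: np.ndarray,
    ridge: float,
) -> float:
    p = X.shape[1]
    beta, log_sigma = theta[:p], theta[p]
    sigma = np.exp(np.clip(log_sigma, -10.0, 5.0))
    eta = X @ beta
    u = np.sqrt(2.0) * sigma * nodes  # (K,)
    # log Bernoulli pmf at eta + u_k for every obs/node
    lin = eta[:, None] + u[None, :]
    logp = np.where(y[:, None] == 1, -np.logaddexp(0.0, -lin), -np.logaddexp(0.0, lin))
    # sum within subject
    per_group = np.zeros((n_groups, len(nodes)))
    np.add.at(per_group, group_index, logp)
    log_w = np.log(weights / np.sqrt(np.pi))
    ll = special.logsumexp(per_group + log_w[None, :], axis=1).sum()
    return -ll + 0.5 * ridge * float(beta @ beta)


def fit_binary_glmm(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates=("resection_volume",),
    group_col: str = "subject_id",
    n_quad: int = 21,
    random_intercept: bool = True,
) -> ModelFit:
    """ML logistic model with an optional per-subject random intercept.

    The marginal likelihood integrates the random intercept out with
    ``n_quad``-node Gauss-Hermite quadrature.  Complete separation is
    detected from the unpenalized logistic fit and handled by a small
    ridge penalty on the fixed effects (flagged via ``penalized``).
    """
    cols = [outcome, predictor, group_col, *covariates]
    df = data[cols].dropna().copy()
    y = df[outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        if len(classes) == 1:
            raise ValueError(
                f"degenerate outcome: {outcome!r} takes the single value {classes[0]!r}"
            )
        raise ValueError(f"outcome {outcome!r} must be coded 0/1, got {classes}")

    names = ["intercept", predictor, *covariates]
    X = np.column_stack(
        [np.ones(len(df))]
        + [df[c].to_numpy(dtype=float) for c in (predictor, *covariates)]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("GLMM design matrix is rank deficient")

    groups, group_index = np.unique(df[group_col].to_numpy(), return_inverse=True)
    n_groups = len(groups)

    # separation check on the plain GLM
    ridge = 0.0
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            glm = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            beta0 = np.asarray(glm.params, dtype=float)
            fitted = glm.fittedvalues
            if np.any(np.abs(X @ beta0) > 25) or np.any(
                (fitted < 1e-10) | (fitted > 1 - 1e-10)
            ):
                penalized = True
        except Exception:
            penalized = True
            beta0 = np.zeros(X.shape[1])
    if penalized:
        ridge = 1e-2
        pen = sm.GLM(y, X, family=sm.families.Binomial())
        beta0 = np.asarray(pen.fit_regularized(alpha=ridge, L1_wt=0.0).params)

    if not random_intercept or n_groups == len(df):
        # no repeated measures: random intercept unidentifiable, sigma -> 0
        eta = X @ beta0
        ll = float(np.sum(np.where(y == 1, -np.logaddexp(0, -eta), -np.logaddexp(0, eta))))
        try:
            cov = np.linalg.inv(
                (X * (special.expit(eta) * (1 - special.expit(eta)))[:, None]).T @ X
            )
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            bse = np.full(X.shape[1], np.nan)
        return ModelFit(
            params=pd.Series(beta0, index=names),
            bse=pd.Series(bse, index=names),
            re_var=0.0,
            llf=ll - 0.5 * ridge * float(beta0 @ beta0),
            n_obs=len(df),
            n_subjects=n_groups,
            converged=True,
            df_fixed=len(names),
            kind="glmm",
            penalized=penalized,
        )

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    yi = y.astype(int)
    theta0 = np.concatenate([beta0, [np.log(0.5)]])
    obj = lambda th: _glmm_negll(
        th, X, yi, group_index, n_groups, nodes, weights, ridge
    )
    opt = optimize.minimize(obj, theta0, method="BFGS", options={"maxiter": 500})
    if not opt.success:  # one retry from a cold start
        opt2 = optimize.minimize(
            obj,
            np.concatenate([np.zeros(X.shape[1]), [np.log(0.3)]]),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if opt2.fun < opt.fun:
            opt = opt2
    beta = opt.x[: X.shape[1]]
    sigma = float(np.exp(opt.x[-1]))
    # standard errors from the numerical Hessian of the fixed effects
    try:
        hess = _numeric_hessian(obj, opt.x)
        cov = np.linalg.inv(hess)
        bse = np.sqrt(np.clip(np.diag(cov)[: X.shape[1]], 0, None))
    except np.linalg.LinAlgError:
        bse = np.full(X.shape[1], np.nan)
    return ModelFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        re_var=sigma**2,
        llf=float(-opt.fun),
        n_obs=len(df),
        n_subjects=n_groups,
        converged=bool(opt.success or opt.fun < np.inf),
        df_fixed=len(names),
        kind="glmm",
        penalized=penalized,
    )


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps**2)
    return h


def likelihood_ratio_test(null_fit: ModelFit, full_fit: ModelFit) -> LRTResult:
    """Chi-squared LRT between nested ML fits (null within full)."""
    if null_fit.n_obs != full_fit.n_obs:
        raise ValueError(
            f"fits use different rows: {null_fit.n_obs} vs {full_fit.n_obs}"
        )
    df = full_fit.df_fixed - null_fit.df_fixed
    if df < 0:
        raise ValueError("null model has more fixed effects than the full model")
    chi = max(0.0, 2.0 * (full_fit.llf - null_fit.llf))
    if df == 0:
        # identical fixed-effect sets (e.g. a model against itself)
        return LRTResult(chi_sq=chi, df=0, p=1.0 if chi <= 1e-8 else 0.0)
    return LRTResult(chi_sq=chi, df=df, p=float(stats.chi2.sf(chi, df)))


def binarize_ilae(ilae: int) -> int:
    """ILAE class 1 (complete seizure freedom) -> 1; classes > 1 -> 0."""
    ilae = int(ilae)
    if ilae < 1:
        raise ValueError(f"ILAE class must be >= 1, got {ilae}")
    return 1 if ilae == 1 else 0
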