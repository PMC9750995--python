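"""Cohort-level statistics: group tests, correlations, relapse models.

Three stages mirror a typical relapse analysis over derived sleep variables:

* bivariate screening — chi-square for categorical variables, Student's t or
  Wilcoxon rank-sum for continuous ones, Pearson correlations with pairwise
  deletion;
* a blockwise (hierarchical) logistic regression of relapse, entering the
  Sleep Regularity Index first and screened covariates in later blocks, with
  Wald odds-ratio confidence intervals per block;
* a repeated-measures linear model of weekly SRI with fixed effects for
  relapse, week (categorical), nap duration and their interactions, fitted
  by REML under candidate residual covariance structures (compound symmetry,
  AR(1), unstructured) with the final structure chosen by AIC, BIC breaking
  ties. Fixed effects are reported as Wald F-tests; the denominator degrees
  of freedom use the residual method (N observations minus fixed-effect
  rank), which is stated in the report.

No multiple-testing correction is applied by default (alpha = 0.05
two-sided throughout); ``bonferroni=True`` switches one on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats as sps
from scipy.linalg import cho_factor, cho_solve

import statsmodels.api as sm

__all__ = [
    "ModelReport",
    "bivariate_tests",
    "correlate_sri_metrics",
    "stepwise_logistic_relapse",
    "lmm_weekly_sri",
    "DEFAULT_LOGISTIC_BLOCKS",
    "LMM_FORMULA",
]

DEFAULT_LOGISTIC_BLOCKS: tuple[tuple[str, ...], ...] = (
    ("total_sri",),
    ("age",),
    ("subjective_sleep_efficiency",),
)

LMM_FORMULA = "sri ~ relapse + C(week) + nap_duration + relapse:C(week) + relapse:nap_duration"


@dataclass
class ModelReport:
    """One fitted model: term table plus fit criteria and diagnostics."""

    model: str  # "logistic" | "lmm"
    terms: pd.DataFrame
    loglik: float = float("nan")
    aic: float = float("nan")
    bic: float = float("nan")
    deviance: float = float("nan")
    block: int | None = None
    structure: str | None = None
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    notes: str = ""
    n_obs: int = 0


class StatsRefusal(ValueError):
    """Raised when a model cannot be fitted meaningfully (bad inputs)."""


# ---------------------------------------------------------------------------
# bivariate screening


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == bool or s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)


def bivariate_tests(
    table: pd.DataFrame,
    outcome: str = "relapse",
    variables: list[str] | None = None,
    continuous_test: str = "t",
) -> pd.DataFrame:
    """Screen variables against a binary outcome.

    Categorical variables get a chi-square test of independence; continuous
    variables a Student's t-test (``continuous_test="t"``) or Wilcoxon
    rank-sum (``"wilcoxon"``). Zero-variance variables are flagged and
    skipped. Returns one row per variable: test name, statistic, p, n.
    """
    if continuous_test not in ("t", "wilcoxon"):
        raise ValueError("continuous_test must be 't' or 'wilcoxon'")
    y = table[outcome].astype(bool)
    if y.nunique() < 2:
        raise StatsRefusal(f"outcome {outcome!r} has a single class")
    if variables is None:
        variables = [c for c in table.columns if c not in (outcome, "participant_id")]
    rows = []
    for var in variables:
        s = table[var]
        mask = s.notna() & y.notna()
        sv, yv = s[mask], y[mask]
        row = {"variable": var, "n": int(mask.sum()), "skipped": False}
        if sv.nunique() < 2:
            row.update(test="none", statistic=np.nan, p=np.nan, skipped=True)
            rows.append(row)
            continue
        if _is_categorical(sv):
            ct = pd.crosstab(sv, yv)
            chi2, p, _, _ = sps.chi2_contingency(ct, correction=False)
            row.update(test="chi-square", statistic=float(chi2), p=float(p))
        else:
            g0 = sv[~yv].astype(float)
            g1 = sv[yv].astype(float)
            if len(g0) < 2 or len(g1) < 2:
                row.update(test="none", statistic=np.nan, p=np.nan, skipped=True)
                rows.append(row)
                continue
            if continuous_test == "t":
                stat, p = sps.ttest_ind(g0, g1, equal_var=True)
                row.update(test="t", statistic=float(stat), p=float(p))
            else:
                stat, p = sps.ranksums(g0, g1)
                row.update(test="wilcoxon", statistic=float(stat), p=float(p))
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_sri_metrics(
    table: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson correlations for the given column pairs, pairwise deletion.

    A pair with fewer than 3 complete observations is reported with NaN.
    """
    rows = []
    for x, y in pairs:
        sub = table[[x, y]].dropna()
        if len(sub) < 3:
            rows.append({"x": x, "y": y, "n": len(sub), "r": np.nan, "p": np.nan})
            continue
        r, p = sps.pearsonr(sub[x].astype(float), sub[y].astype(float))
        rows.append({"x": x, "y": y, "n": len(sub), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# blockwise logistic regression


def _fit_logit_block(y: np.ndarray, X: pd.DataFrame, block: int) -> ModelReport:
    Xc = sm.add_constant(X, has_constant="add")
    flags: list[str] = []
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=False, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # PerfectSeparationError and friends
        flags.append(f"fit-failed: {type(exc).__name__}")
        terms = pd.DataFrame(
            {
                "term": ["const", *X.columns],
                "estimate": np.nan,
                "odds_ratio": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
            }
        )
        return ModelReport(
            "logistic", terms, block=block, converged=False, flags=flags, n_obs=len(y)
        )
    if not converged or np.abs(res.params).max() > 15:
        flags.append("possible-separation")
        converged = False
    ci = res.conf_int()
    terms = pd.DataFrame(
        {
            "term": Xc.columns,
            "estimate": res.params.to_numpy(),
            "odds_ratio": np.exp(res.params.to_numpy()),
            "ci_low": np.exp(ci[0].to_numpy()),
            "ci_high": np.exp(ci[1].to_numpy()),
            "p": res.pvalues.to_numpy(),
        }
    )
    return ModelReport(
        "logistic",
        terms,
        loglik=float(res.llf),
        aic=float(res.aic),
        bic=float(res.bic),
        deviance=float(-2 * res.llf),
        block=block,
        converged=converged,
        flags=flags,
        n_obs=len(y),
    )


def stepwise_logistic_relapse(
    table: pd.DataFrame,
    blocks: tuple[tuple[str, ...], ...] = DEFAULT_LOGISTIC_BLOCKS,
    outcome: str = "relapse",
    min_n: int = 20,
) -> list[ModelReport]:
    """Nested (blockwise) logistic regressions of relapse.

    Block k fits the outcome on the union of blocks 1..k; by default the
    SRI enters first, then age, then subjective sleep efficiency. Odds
    ratios are per unit of the predictor with Wald 95% CIs. Refuses to fit
    (raises :class:`StatsRefusal`) on a single-class outcome, a constant
    predictor, or fewer than ``min_n`` complete observations; complete
    separation yields a flagged report with no estimates.
    """
    all_vars = [v for blk in blocks for v in blk]
    sub = table[[outcome, *all_vars]].dropna()
    if len(sub) < min_n:
        raise StatsRefusal(f"only {len(sub)} complete observations (need >= {min_n})")
    y = sub[outcome].astype(bool)
    if y.nunique() < 2:
        raise StatsRefusal("outcome has a single class; cannot fit logistic model")
    for var in all_vars:
        if sub[var].nunique() < 2:
            raise StatsRefusal(f"predictor {var!r} is constant")
    reports = []
    cum: list[str] = []
    for k, blk in enumerate(blocks, start=1):
        cum.extend(blk)
        X = sub[cum].astype(float)
        reports.append(_fit_logit_block(y.to_numpy(dtype=float), X, block=k))
    return reports


# ---------------------------------------------------------------------------
# repeated-measures GLS with structured residual covariance
#
# The weekly-SRI model is y_s = X_s beta + e_s per participant s, with
# e_s ~ N(0, Sigma[weeks_s, weeks_s]) and Sigma built over the full week
# grid from one of three structures. beta is profiled out by GLS and the
# structure parameters are estimated by REML.


def _cs_corr(rho: float, m: int) -> np.ndarray:
    return np.full((m, m), rho) + (1.0 - rho) * np.eye(m)


def _ar1_corr(rho: float, times: np.ndarray) -> np.ndarray:
    lags = np.abs(times[:, None] - times[None, :])
    return rho ** lags


def _group_patterns(ids, week_idx, X, y):
    """Group subjects by their observed-week pattern for vectorized likelihoods.

    Returns a list of (Xg, Yg, idx) where Xg is (n_g, m_p, p), Yg is
    (n_g, m_p) and idx are the week-grid indices of the pattern.
    """
    order = np.lexsort((week_idx, ids))
    ids, week_idx, X, y = ids[order], week_idx[order], X[order], y[order]
    groups: dict[tuple, list] = {}
    start = 0
    for end in range(1, len(ids) + 1):
        if end == len(ids) or ids[end] != ids[start]:
            pat = tuple(week_idx[start:end])
            groups.setdefault(pat, []).append((X[start:end], y[start:end]))
            start = end
    out = []
    for pat, members in groups.items():
        Xg = np.stack([m[0] for m in members])
        Yg = np.stack([m[1] for m in members])
        out.append((Xg, Yg, np.asarray(pat)))
    return out


def _gls_pieces(groups, R_full):
    """Accumulate X'R^-1X, X'R^-1y, y'R^-1y and sum of log|R_s| over blocks."""
    p = groups[0][0].shape[2]
    A = np.zeros((p, p))
    b = np.zeros(p)
    q = 0.0
    logdet = 0.0
    for Xg, Yg, idx in groups:
        R = R_full[np.ix_(idx, idx)]
        c, low = cho_factor(R)
        logdet += Xg.shape[0] * 2.0 * np.sum(np.log(np.diag(c)))
        Rinv = cho_solve((c, low), np.eye(len(idx)))
        RiY = Yg @ Rinv  # (n_g, m_p); Rinv symmetric
        RiX = np.einsum("jk,nkl->njl", Rinv, Xg)  # (n_g, m_p, p)
        A += np.einsum("nji,njl->il", Xg, RiX)
        b += np.einsum("nij,ni->j", Xg, RiY)
        q += float(np.einsum("ni,ni->", Yg, RiY))
    return A, b, q, logdet


def _reml_profiled(groups, R_full, n, p):
    """REML -2 log-likelihood with the scale sigma^2 profiled out."""
    A, b, q, logdetR = _gls_pieces(groups, R_full)
    cA, lowA = cho_factor(A)
    beta = cho_solve((cA, lowA), b)
    rss = q - float(b @ beta)
    if rss <= 0:
        return np.inf, None, None, None
    sigma2 = rss / (n - p)
    logdetA = 2.0 * np.sum(np.log(np.diag(cA)))
    neg2ll = (
        (n - p) * np.log(sigma2)
        + logdetR
        + logdetA
        + (n - p) * (1.0 + np.log(2.0 * np.pi))
    )
    cov_beta = sigma2 * cho_solve((cA, lowA), np.eye(len(beta)))
    return neg2ll, beta, cov_beta, sigma2


def _reml_unstructured(params, groups, m, n, p, times, return_fit=False):
    L = np.zeros((m, m))
    tril = np.tril_indices(m, -1)
    L[np.diag_indices(m)] = np.exp(params[:m])
    L[tril] = params[m:]
    Sigma = L @ L.T
    try:
        A, b, q, logdetS = _gls_pieces(groups, Sigma)
        cA, lowA = cho_factor(A)
    except np.linalg.LinAlgError:
        return np.inf if not return_fit else (np.inf, None, None, None)
    beta = cho_solve((cA, lowA), b)
    rss = q - float(b @ beta)
    logdetA = 2.0 * np.sum(np.log(np.diag(cA)))
    neg2ll = logdetS + logdetA + rss + (n - p) * np.log(2.0 * np.pi)
    if not return_fit:
        return neg2ll
    cov_beta = cho_solve((cA, lowA), np.eye(len(beta)))
    return neg2ll, beta, cov_beta, Sigma


def _fit_structure(structure, groups, times, n, p):
    """Fit one residual covariance structure by REML.

    Returns (neg2ll, beta, cov_beta, k_cov, detail) or raises on failure.
    """
    m = len(times)
    if structure == "cs":
        lo = -1.0 / (m - 1) + 1e-6 if m > 1 else -0.99
        obj = lambda r: _reml_profiled(groups, _cs_corr(r, m), n, p)[0]
        res = optimize.minimize_scalar(obj, bounds=(lo, 1 - 1e-6), method="bounded")
        rho = float(res.x)
        neg2ll, beta, cov, sigma2 = _reml_profiled(groups, _cs_corr(rho, m), n, p)
        return neg2ll, beta, cov, 2, {"rho": rho, "sigma2": sigma2}
    if structure == "ar1":
        obj = lambda r: _reml_profiled(groups, _ar1_corr(r, times), n, p)[0]
        res = optimize.minimize_scalar(obj, bounds=(-1 + 1e-6, 1 - 1e-6), method="bounded")
        rho = float(res.x)
        neg2ll, beta, cov, sigma2 = _reml_profiled(groups, _ar1_corr(rho, times), n, p)
        return neg2ll, beta, cov, 2, {"rho": rho, "sigma2": sigma2}
    if structure == "un":
        # start from the empirical covariance of OLS residuals
        neg2_cs, beta0, _, s2 = _reml_profiled(groups, np.eye(m), n, p)
        resid_cov = np.eye(m) * (s2 if s2 else 1.0)
        counts = np.zeros((m, m))
        acc = np.zeros((m, m))
        for Xg, Yg, idx in groups:
            E = Yg - Xg @ beta0
            acc[np.ix_(idx, idx)] += E.T @ E
            counts[np.ix_(idx, idx)] += Xg.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            emp = np.where(counts > 0, acc / np.maximum(counts, 1), resid_cov)
        emp = emp + 1e-3 * np.trace(emp) / m * np.eye(m)
        L0 = np.linalg.cholesky(emp)
        x0 = np.concatenate([np.log(np.diag(L0)), L0[np.tril_indices(m, -1)]])
        res = optimize.minimize(
            _reml_unstructured,
            x0,
            args=(groups, m, n, p, times),
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if not np.isfinite(res.fun):
            raise np.linalg.LinAlgError("unstructured fit diverged")
        neg2ll, beta, cov, Sigma = _reml_unstructured(
            res.x, groups, m, n, p, times, return_fit=True
        )
        return neg2ll, beta, cov, m * (m + 1) // 2, {"Sigma": Sigma}
    raise ValueError(f"unknown structure {structure!r}")


def lmm_weekly_sri(
    long_table: pd.DataFrame,
    formula: str = LMM_FORMULA,
    structures: tuple[str, ...] = ("cs", "ar1", "un"),
) -> ModelReport:
    """Repeated-measures model of weekly SRI with structured residuals.

    ``long_table`` holds one row per participant-week with columns
    ``participant_id``, ``week`` (integer), ``sri``, ``relapse`` and
    ``nap_duration``. Each candidate residual covariance structure is
    fitted by REML; the structure with the smallest AIC wins (BIC breaks
    ties), and the winning fit is reported as Wald F-tests per fixed-effect
    term. Denominator df = N observations - fixed-effect rank (residual
    method, noted in the report). Candidates that fail to converge are
    dropped with a warning; if all fail an error is raised.
    """
    df = long_table.copy()
    needed = {"participant_id", "week"}
    if missing := needed - set(df.columns):
        raise ValueError(f"long table missing column(s) {sorted(missing)}")
    if "relapse" in df.columns:
        df["relapse"] = df["relapse"].astype(float)
    ydm, Xdm = patsy.dmatrices(formula, df, return_type="dataframe", NA_action="drop")
    used_idx = Xdm.index
    weeks = np.sort(df.loc[used_idx, "week"].unique())
    if len(weeks) < 2:
        raise StatsRefusal("need at least two distinct weeks of data")
    week_idx = df.loc[used_idx, "week"].map({w: i for i, w in enumerate(weeks)}).to_numpy()
    ids = df.loc[used_idx, "participant_id"].to_numpy()
    X = np.asarray(Xdm, dtype=float)
    y = np.asarray(ydm, dtype=float).ravel()
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise StatsRefusal("fixed-effect design is rank deficient")
    mean_weeks = n / len(np.unique(ids))
    if mean_weeks < 2:
        raise StatsRefusal("fewer than two weeks per participant on average")
    groups = _group_patterns(ids, week_idx, X, y)
    times = np.arange(len(weeks), dtype=float)

    fits = {}
    for structure in structures:
        try:
            neg2ll, beta, cov, k_cov, detail = _fit_structure(structure, groups, times, n, p)
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"covariance structure {structure!r} failed: {exc}", stacklevel=2)
            continue
        if not np.isfinite(neg2ll) or beta is None:
            warnings.warn(f"covariance structure {structure!r} did not converge", stacklevel=2)
            continue
        aic = neg2ll + 2 * k_cov
        bic = neg2ll + k_cov * np.log(n - p)
        fits[structure] = (neg2ll, aic, bic, beta, cov, detail)
    if not fits:
        raise RuntimeError("no residual covariance structure converged")
    best = min(fits, key=lambda s: (round(fits[s][1], 6), round(fits[s][2], 6)))
    neg2ll, aic, bic, beta, cov, detail = fits[best]

    ddf = n - p
    rows = []
    for term, sl in Xdm.design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        b = beta[sl]
        C = cov[sl, sl]
        qdim = len(b)
        F = float(b @ np.linalg.solve(C, b) / qdim)
        rows.append(
            {
                "term": term,
                "F": F,
                "df_num": qdim,
                "df_den": ddf,
                "p": float(sps.f.sf(F, qdim, ddf)),
            }
        )
    terms = pd.DataFrame(rows)
    return ModelReport(
        "lmm",
        terms,
        loglik=-0.5 * neg2ll,
        aic=aic,
        bic=bic,
        structure=best,
        n_obs=n,
        notes=(
            "REML; denominator df = N_obs - rank(X) (residual method); "
            f"candidates tried: {sorted(fits)}"
        ),
    )
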