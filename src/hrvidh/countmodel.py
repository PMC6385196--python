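"""Negative-binomial count models of monthly IDH frequency.

Monthly intradialytic-hypotension counts in small dialysis cohorts are
over-dispersed, so the canonical model is NB2 regression with a log link:
counts y_i ~ NB(mu_i, alpha) with mu_i = exp(x_i' beta) and variance
mu + alpha mu^2, fitted by maximum likelihood jointly in (beta, alpha).
No exposure offset is used: all patients contribute the same number of
sessions per month, so a log-exposure term is constant and absorbed by
the intercept.

This module provides the fit itself (delegating the likelihood
maximisation to statsmodels), Wald rate-ratio tables (Exp(B) with 95% CI),
a p < 0.10 univariate screen with a force-include list, variance-inflation
factors, an exhaustive HRV-delta model search with collinearity exclusion,
and linear-predictor risk scores for ROC analysis.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .roc import auc

log = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the NB likelihood maximisation fails to converge."""


@dataclasses.dataclass(frozen=True)
class NBFit:
    """A converged NB2 maximum-likelihood fit.

    ``params`` holds the regression coefficients (model scale, including
    ``const``); ``alpha`` is the NB2 dispersion.  ``cov`` is the Wald
    covariance of (beta, alpha) from the observed information.  AIC/BIC
    count the dispersion as a fitted parameter:
    aic = -2 logL + 2k, bic = -2 logL + k ln n with k = len(beta) + 1.
    """

    params: pd.Series
    alpha: float
    cov: pd.DataFrame
    llf: float
    n: int
    linear_predictor: np.ndarray
    exog_names: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.params) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k * np.log(self.n)

    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov.loc[self.params.index, self.params.index])),
            index=self.params.index,
        )


def _check_design(X: pd.DataFrame, y: np.ndarray) -> None:
    if X.columns.duplicated().any():
        raise ValueError("design matrix column names must be unique")
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"design matrix has missing values in columns {bad}")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be nonnegative integers")
    if not np.any(y > 0):
        raise ValueError("all counts are zero; the count model is degenerate")
    if len(y) <= X.shape[1] + 1:
        raise ValueError(
            f"n={len(y)} too small for {X.shape[1]} regression parameters"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns involved in the rank deficiency via the smallest
        # right singular vectors
        _, s, vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
        null = vt[rank:]
        involved = [
            c
            for j, c in enumerate(X.columns)
            if np.any(np.abs(null[:, j]) > 1e-8)
        ]
        raise ValueError(f"design matrix is rank deficient; columns involved: {involved}")


def fit_negative_binomial(y, X: pd.DataFrame, add_intercept: bool = True) -> NBFit:
    """Fit an NB2 regression of counts ``y`` on the columns of ``X``.

    ``X`` is given on the reporting scales (no intercept column); a
    ``const`` column is prepended unless ``add_intercept`` is False.
    Raises :class:`ConvergenceError` with the optimiser trace if no method
    converges, and ``ValueError`` on degenerate inputs (all-zero counts,
    rank-deficient design).
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    _check_design(X, y)

    import warnings as _warnings

    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    trace: list[str] = []
    res = None
    cov_arr = None
    converged_cands: list = []
    with _warnings.catch_warnings(), np.errstate(all="ignore"):
        _warnings.simplefilter("ignore")
        # Poisson warm start keeps the dispersion search well-conditioned;
        # clipped, because quasi-separated binary covariates (all events in
        # one stratum) send their Poisson coefficient toward infinity
        start_params = None
        try:
            pois = sm.Poisson(y, X).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(pois.params)):
                start_params = np.append(np.clip(pois.params, -10.0, 10.0), 0.1)
        except Exception:  # noqa: BLE001 - fall back to default starts
            pass
        # lbfgs runs with box bounds: under quasi-separation the likelihood
        # plateaus as a coefficient diverges, and a bounded optimiser pins it
        # at a finite value on the plateau instead of wandering to NaN
        bounds = [(-15.0, 15.0)] * X.shape[1] + [(1e-6, 50.0)]
        for method, maxiter in (("bfgs", 500), ("newton", 300), ("lbfgs", 1000)):
            try:
                kwargs = {"bounds": bounds} if method == "lbfgs" else {}
                cand = model.fit(
                    start_params=start_params,
                    method=method,
                    maxiter=maxiter,
                    disp=0,
                    warn_convergence=False,
                    **kwargs,
                )
            except Exception as e:  # noqa: BLE001 - record and try next optimiser
                trace.append(f"{method}: raised {type(e).__name__}: {e}")
                continue
            converged = bool(cand.mle_retvals.get("converged", False))
            trace.append(
                f"{method}: converged={converged} llf={cand.llf:.4f} "
                f"iterations={cand.mle_retvals.get('iterations', '?')}"
            )
            if not (converged and np.all(np.isfinite(cand.params))):
                continue
            # a converged point with a singular observed information
            # (dispersion on the Poisson boundary) cannot supply a Wald
            # covariance directly; keep the point and try the next optimiser
            try:
                c = np.asarray(cand.cov_params())
                if np.all(np.isfinite(c)):
                    res, cov_arr = cand, c
                    break
                trace.append(f"{method}: non-finite covariance")
            except Exception as e:  # noqa: BLE001
                trace.append(f"{method}: covariance failed: {e}")
            converged_cands.append(cand)
        if res is None and converged_cands:
            # take the best converged optimum and use the pseudo-inverse of
            # the observed information for its covariance
            best = max(converged_cands, key=lambda c: c.llf)
            H = model.hessian(best.params)
            c = -np.linalg.pinv(H)
            if np.all(np.isfinite(c)):
                res, cov_arr = best, c
                trace.append("covariance from pseudo-inverse of the Hessian")
    if res is None:
        raise ConvergenceError(
            "negative-binomial fit did not converge; trace:\n  " + "\n  ".join(trace)
        )

    params = pd.Series(res.params, index=list(X.columns) + ["alpha"])
    alpha = float(params.pop("alpha"))
    if alpha <= 0:
        # ML can park the dispersion on the Poisson boundary
        alpha = max(alpha, 1e-10)
    cov = pd.DataFrame(
        cov_arr,
        index=list(X.columns) + ["alpha"],
        columns=list(X.columns) + ["alpha"],
    )
    eta = X.to_numpy() @ params.to_numpy()
    return NBFit(
        params=params,
        alpha=alpha,
        cov=cov,
        llf=float(res.llf),
        n=len(y),
        linear_predictor=eta,
        exog_names=tuple(X.columns),
    )


def wald_exp_coefficients(fit: NBFit, level: float = 0.95) -> pd.DataFrame:
    """Rate-ratio table: Exp(B) with Wald CI and two-sided p per covariate.

    Exp(B) = exp(beta); CI = exp(beta -/+ z * SE); p from the Wald z
    statistic against the standard normal.  Rows with a non-finite SE are
    flagged and carry no interval.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = fit.se()
    rows = []
    for name in fit.params.index:
        b, s = fit.params[name], se[name]
        if not np.isfinite(s) or s <= 0:
            rows.append((name, np.exp(b), np.nan, np.nan, np.nan, True))
            continue
        with np.errstate(over="ignore"):  # a separated coefficient's huge SE
            rows.append(
                (
                    name,
                    np.exp(b),
                    np.exp(b - z * s),
                    np.exp(b + z * s),
                    2.0 * stats.norm.sf(abs(b / s)),
                    False,
                )
            )
    return pd.DataFrame(
        rows, columns=["variable", "exp_b", "ci_low", "ci_high", "p", "se_flag"]
    ).set_index("variable")


@dataclasses.dataclass(frozen=True)
class ScreenResult:
    selected: tuple[str, ...]
    pvalues: pd.Series
    unscreenable: dict[str, str]


def univariate_screen(
    y,
    X: pd.DataFrame,
    p_threshold: float = 0.10,
    force_include: tuple[str, ...] = (),
) -> ScreenResult:
    """Univariate NB screen: keep columns with Wald p < ``p_threshold``.

    Each candidate is fitted alone (with intercept).  ``force_include``
    columns are kept regardless of their p-value — the usual way of
    retaining clinically established risk factors (e.g. coronary disease
    and heart failure) that a small sample cannot confirm.  A failed
    univariate fit marks the column unscreenable rather than silently
    dropping it.
    """
    pvals: dict[str, float] = {}
    failed: dict[str, str] = {}
    for col in X.columns:
        try:
            fit = fit_negative_binomial(y, X[[col]])
            pvals[col] = float(wald_exp_coefficients(fit).loc[col, "p"])
        except (ValueError, ConvergenceError) as e:
            failed[col] = str(e)
            log.warning("univariate screen: column %r unscreenable: %s", col, e)
    selected = [c for c, p in pvals.items() if p < p_threshold]
    for c in force_include:
        if c not in selected and c in X.columns:
            selected.append(c)
    selected.sort(key=list(X.columns).index)
    return ScreenResult(
        selected=tuple(selected),
        pvalues=pd.Series(pvals, dtype=float),
        unscreenable=failed,
    )


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2) of a
    least-squares regression of that column on all others plus an
    intercept.  Perfect collinearity yields ``inf``."""
    X = pd.DataFrame(X).astype(float)
    if len(X) <= X.shape[1] + 1:
        raise ValueError("too few rows to compute VIFs")
    out = {}
    Xv = X.to_numpy()
    for j, col in enumerate(X.columns):
        target = Xv[:, j]
        others = np.column_stack(
            [np.ones(len(X))] + [Xv[:, i] for i in range(Xv.shape[1]) if i != j]
        )
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_tot = np.sum((target - target.mean()) ** 2)
        if ss_tot == 0:
            out[col] = np.inf  # constant column: degenerate by convention
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def linear_predictor(fit: NBFit, X: pd.DataFrame, add_intercept: bool = True) -> np.ndarray:
    """Risk scores eta_i = x_i' beta for new data with matching columns."""
    X = pd.DataFrame(X).astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    expected = list(fit.exog_names)
    missing = [c for c in expected if c not in X.columns]
    extra = [c for c in X.columns if c not in expected]
    if missing or extra:
        raise ValueError(
            f"design mismatch: missing columns {missing}, unexpected columns {extra}"
        )
    return X[expected].to_numpy() @ fit.params.reindex(expected).to_numpy()


@dataclasses.dataclass(frozen=True)
class CandidateModel:
    added: tuple[str, ...]
    fit: NBFit | None
    auc: float
    max_vif: float
    max_abs_corr: float
    excluded: str | None  # reason, or None if the model survives


@dataclasses.dataclass(frozen=True)
class ModelSearchResult:
    basic: CandidateModel
    candidates: list[CandidateModel]

    @property
    def survivors(self) -> list[CandidateModel]:
        ranked = [c for c in self.candidates if c.excluded is None]
        return sorted(ranked, key=lambda c: -c.auc)

    @property
    def best(self) -> CandidateModel:
        ranked = self.survivors
        return ranked[0] if ranked else self.basic

    def table(self, top: int = 5) -> pd.DataFrame:
        """Ranked summary of the basic model plus the top candidates."""
        rows = []
        for label, c in [("basic", self.basic)] + [
            ("+".join(c.added), c) for c in self.survivors[:top]
        ]:
            rows.append(
                {
                    "model": label,
                    "auc": c.auc,
                    "aic": c.fit.aic if c.fit else np.nan,
                    "bic": c.fit.bic if c.fit else np.nan,
                    "max_vif": c.max_vif,
                }
            )
        return pd.DataFrame(rows)


def model_search(
    y,
    X_basic: pd.DataFrame,
    X_delta: pd.DataFrame,
    max_added: int = 4,
    vif_bound: float = 10.0,
    corr_bound: float = 0.8,
) -> ModelSearchResult:
    """Exhaustively augment the basic model with HRV delta features.

    Fits the basic clinical model plus every subset of delta columns up to
    ``max_added`` terms.  A candidate is excluded when any VIF in its
    design exceeds ``vif_bound`` or any pairwise correlation among its
    *added* columns (or between an added column and a basic column)
    exceeds ``corr_bound`` in absolute value.  Survivors are ranked by the
    AUC of their linear predictor against the binary outcome "at least one
    IDH event" (count >= 1).  The basic model is always reported and never
    excluded.
    """
    y = np.asarray(y, dtype=float)
    labels = (y >= 1).astype(int)

    def evaluate(added: tuple[str, ...]) -> CandidateModel:
        X = pd.concat([X_basic, X_delta[list(added)]], axis=1) if added else X_basic
        vifs = vif(X)
        max_vif = float(vifs.max())
        corr = X.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        # only correlations involving an added column can exclude a candidate
        if added:
            cols = list(X.columns)
            added_ix = [cols.index(a) for a in added]
            max_corr = float(np.nanmax(np.abs(corr[added_ix, :])))
        else:
            max_corr = float(np.nanmax(np.abs(corr))) if corr.size else 0.0
        excluded = None
        if added and max_vif > vif_bound:
            excluded = f"max VIF {max_vif:.1f} > {vif_bound}"
        elif added and max_corr > corr_bound:
            excluded = f"|r| {max_corr:.2f} > {corr_bound}"
        fit = None
        score = np.nan
        if excluded is None:
            try:
                fit = fit_negative_binomial(y, X)
                score = auc(fit.linear_predictor, labels)
            except (ValueError, ConvergenceError) as e:
                excluded = f"fit failed: {e}"
        return CandidateModel(
            added=added,
            fit=fit,
            auc=score,
            max_vif=max_vif,
            max_abs_corr=max_corr,
            excluded=excluded,
        )

    basic = evaluate(())
    if basic.fit is None:
        raise ValueError(f"basic model failed: {basic.excluded}")
    basic = dataclasses.replace(basic, excluded=None)

    candidates = []
    names = list(X_delta.columns)
    for size in range(1, min(max_added, len(names)) + 1):
        for combo in itertools.combinations(names, size):
            candidates.append(evaluate(combo))
    if not any(c.excluded is None for c in candidates) and names:
        log.warning("no augmented model survived the collinearity screens")
    return ModelSearchResult(basic=basic, candidates=candidates)
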