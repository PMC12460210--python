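"""Linking node metrics to bimanual performance.

The chain is: screen the 16 node metrics with partial Spearman
correlations against the bimanual score, controlling for session and
participant (both dummy-coded fixed effects); keep the nodes that
survive Bonferroni correction; diagnose their collinearity with
variance inflation factors; collapse them to a first principal
component; and regress the control-residualized score on the
control-residualized component,

    y' = beta0 * x' + beta1,

evaluated in-sample (R^2) and by leave-one-out cross-validation, where
every fitted quantity — feature standardization, the PCA loadings, the
control residualization and the OLS coefficients — is refit on each
fold's training rows.

Method defaults where the procedure admits variants: partial Spearman
is rank-transform followed by fixed-effect residualization and a
Pearson correlation of the rank residuals, its p-value from the t
approximation with degrees of freedom reduced by the number of control
columns, and its 95% CI from the Fisher z transform; these are the
package's documented choices, not claims about any particular prior
analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Control designs
# ---------------------------------------------------------------------------

def control_design(controls: pd.DataFrame | None, n: int) -> np.ndarray:
    """Design matrix for the control variables, intercept included.

    Categorical (object/category/bool) columns are dummy-coded with the
    first level dropped; numeric columns enter as-is.  Raises when the
    design is rank-deficient (controls collinear with the intercept or
    each other).
    """
    if controls is None or controls.shape[1] == 0:
        return np.ones((n, 1))
    if len(controls) != n:
        raise ValueError("controls must have one row per observation")
    cols = [np.ones(n)]
    for name in controls.columns:
        col = controls[name]
        if col.dtype.kind in "OUSb" or isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            dummies = pd.get_dummies(col.astype("category"), drop_first=True)
            for dname in dummies.columns:
                cols.append(dummies[dname].to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float))
    Z = np.column_stack(cols)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("control design is rank-deficient (collinear controls)")
    return Z


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


# ---------------------------------------------------------------------------
# Partial Spearman screening
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrelation:
    """A partial Spearman coefficient with its test and CI."""

    name: str
    rho: float
    p: float
    ci95: tuple[float, float]
    n: int
    df: int
    controls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")


def partial_spearman(
    x,
    y,
    controls: pd.DataFrame | None = None,
    name: str = "x",
) -> PartialCorrelation:
    """Partial Spearman correlation of x and y given controls.

    Both series are rank-transformed (average ranks on ties), each rank
    vector is residualized on the dummy-coded control design, and the
    Pearson correlation of the residuals is returned.  With no controls
    this reduces to the ordinary Spearman coefficient.  The p-value uses
    the t approximation with df = n - 2 - q (q control columns beyond
    the intercept); the CI is Fisher-z with se = 1/sqrt(n - q - 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    n = x.shape[0]
    Z = control_design(controls, n)
    q = Z.shape[1] - 1
    df = n - 2 - q
    if df < 3:
        raise ValueError(
            f"only {df} residual degrees of freedom after {q} control columns"
        )
    rx = _residualize(sst.rankdata(x), Z)
    ry = _residualize(sst.rankdata(y), Z)
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        raise ValueError("zero-variance rank residuals: correlation undefined")
    rho = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho ** 2))
        p = float(2 * sst.t.sf(abs(t), df))
    se_z = 1.0 / np.sqrt(max(n - q - 3, 1))
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    ci = (float(np.tanh(z - 1.959964 * se_z)), float(np.tanh(z + 1.959964 * se_z)))
    return PartialCorrelation(
        name=name, rho=rho, p=p, ci95=ci, n=n, df=df,
        controls=tuple(controls.columns) if controls is not None else (),
    )


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni flags: p_i < alpha / m over the m tests given."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p < alpha / p.shape[0]


def screen_nodes(
    features: pd.DataFrame,
    y,
    controls: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partial Spearman per feature column with Bonferroni flags.

    Returns one row per node: rho, p, CI bounds and ``significant``
    (Bonferroni over the number of columns screened).
    """
    results = [
        partial_spearman(features[c], y, controls=controls, name=str(c))
        for c in features.columns
    ]
    flags = bonferroni([r.p for r in results], alpha=alpha)
    return pd.DataFrame(
        {
            "node": [r.name for r in results],
            "rho": [r.rho for r in results],
            "p": [r.p for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "significant": flags,
        }
    )


# ---------------------------------------------------------------------------
# Collinearity
# ---------------------------------------------------------------------------

def vif(features: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per feature: 1/(1 - R^2_j) from
    regressing feature j (with intercept) on the remaining features.
    Perfectly collinear features report inf with a logged note."""
    X = features.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least 2 features for VIF")
    if n <= m:
        raise ValueError("need more observations than features for VIF")
    out = {}
    for j, name in enumerate(features.columns):
        target = X[:, j]
        others = np.column_stack(
            [np.ones(n), np.delete(X, j, axis=1)]
        )
        beta, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ beta
        ss_tot = ((target - target.mean()) ** 2).sum()
        if ss_tot == 0:
            out[name] = np.inf
            logger.warning("vif: feature %s is constant", name)
            continue
        r2 = 1.0 - (resid ** 2).sum() / ss_tot
        if 1.0 - r2 < 1e-12:
            out[name] = np.inf
            logger.warning("vif: feature %s is perfectly collinear", name)
        else:
            out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# Principal-component regression
# ---------------------------------------------------------------------------

@dataclass
class PCRModel:
    """A fitted one-component principal-component regression."""

    selected_nodes: tuple[str, ...]
    loadings: np.ndarray
    explained_variance: float
    beta0: float  # slope of y' on x'
    beta1: float  # intercept
    beta0_se: float
    r2: float
    n: int
    loocv_r2: float | None = None
    loocv_rmse: float | None = None


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature: cannot standardize")
    return mu, sd


def _pc_scores(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Standardize, project on PC1 (sign fixed positive with y), and
    return scores, loadings, explained variance and the fit moments."""
    mu, sd = _standardize_fit(X)
    Z = (X - mu) / sd
    pca = PCA(n_components=1)
    scores = pca.fit_transform(Z)[:, 0]
    loadings = pca.components_[0]
    ev = float(pca.explained_variance_ratio_[0])
    if scores.std() == 0:
        raise ValueError("zero-variance principal component")
    if np.corrcoef(scores, y)[0, 1] < 0:
        scores = -scores
        loadings = -loadings
    return scores, loadings, ev, mu, sd


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and slope SE of simple OLS y = b0 x + b1."""
    xc = x - x.mean()
    sxx = (xc ** 2).sum()
    if sxx == 0:
        raise ValueError("zero-variance predictor in OLS")
    b0 = float((xc * (y - y.mean())).sum() / sxx)
    b1 = float(y.mean() - b0 * x.mean())
    resid = y - (b0 * x + b1)
    dof = max(x.shape[0] - 2, 1)
    se = float(np.sqrt((resid ** 2).sum() / dof / sxx))
    return b0, b1, se


def pcr_fit(
    features: pd.DataFrame,
    y,
    controls: pd.DataFrame | None = None,
) -> PCRModel:
    """Fit the screening-free core of the chain on selected features.

    Standardizes the selected node columns, projects on the first
    principal component (sign fixed to correlate positively with the
    outcome), residualizes both the component and the outcome on the
    dummy-coded controls, and fits OLS y' = beta0 x' + beta1 with its
    in-sample R^2.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if X.shape[1] < 1:
        raise ValueError("need at least one selected node")
    Z = control_design(controls, n)
    if n - Z.shape[1] - 1 < 3:
        raise ValueError("fewer than 3 residual degrees of freedom")
    scores, loadings, ev, _, _ = _pc_scores(X, y)
    x_res = _residualize(scores, Z)
    y_res = _residualize(y, Z)
    b0, b1, se = _ols_line(x_res, y_res)
    fitted = b0 * x_res + b1
    ss_tot = ((y_res - y_res.mean()) ** 2).sum()
    r2 = float(1.0 - ((y_res - fitted) ** 2).sum() / ss_tot) if ss_tot > 0 else 0.0
    return PCRModel(
        selected_nodes=tuple(map(str, features.columns)),
        loadings=loadings,
        explained_variance=ev,
        beta0=b0,
        beta1=b1,
        beta0_se=se,
        r2=r2,
        n=n,
    )


def loocv(
    features: pd.DataFrame,
    y,
    controls: pd.DataFrame | None = None,
    rescreen: bool = False,
    alpha: float = 0.05,
    return_details: bool = False,
):
    """Leave-one-out cross-validation of the PCR chain.

    For each held-out observation the full chain — feature
    standardization, PCA projection, control residualization and OLS —
    is refit on the remaining rows and the held-out control-residualized
    outcome is predicted.  Reports cross-validated R^2 (1 - SSE/SST over
    the held-out residuals) and RMSE.

    With ``rescreen=True`` node selection (partial Spearman + Bonferroni
    over all given columns) is additionally re-run inside each fold; a
    fold with no surviving node falls back to the minimum-p node.  Folds
    with a degenerate PCA are recorded and excluded with a warning.
    ``return_details=True`` appends per-fold standardization means and
    selected nodes, used to audit that nothing leaks across folds.
    """
    X_all = features
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 observations for LOOCV")
    Z = control_design(controls, n)
    preds, truths = [], []
    details = {"fold_means": [], "fold_nodes": [], "excluded": []}
    for i in range(n):
        tr = np.arange(n) != i
        cols = list(X_all.columns)
        if rescreen:
            ctrl_tr = controls.iloc[tr] if controls is not None else None
            try:
                table = screen_nodes(
                    X_all.iloc[tr], y[tr], controls=ctrl_tr, alpha=alpha
                )
                sel = table.loc[table["significant"], "node"].tolist()
                if not sel:
                    sel = [table.loc[table["p"].idxmin(), "node"]]
                cols = sel
            except ValueError as err:
                details["excluded"].append((i, str(err)))
                warnings.warn(f"fold {i} excluded: {err}", stacklevel=2)
                continue
        X = X_all[cols].to_numpy(dtype=float)
        try:
            scores_tr, loadings, _, mu, sd = _pc_scores(X[tr], y[tr])
        except ValueError as err:
            details["excluded"].append((i, str(err)))
            warnings.warn(f"fold {i} excluded: {err}", stacklevel=2)
            continue
        beta_x, *_ = np.linalg.lstsq(Z[tr], scores_tr, rcond=None)
        beta_y, *_ = np.linalg.lstsq(Z[tr], y[tr], rcond=None)
        x_res_tr = scores_tr - Z[tr] @ beta_x
        y_res_tr = y[tr] - Z[tr] @ beta_y
        b0, b1, _ = _ols_line(x_res_tr, y_res_tr)
        score_te = float(((X[i] - mu) / sd) @ loadings)
        x_res_te = score_te - float(Z[i] @ beta_x)
        y_res_te = y[i] - float(Z[i] @ beta_y)
        preds.append(b0 * x_res_te + b1)
        truths.append(y_res_te)
        details["fold_means"].append(mu)
        details["fold_nodes"].append(tuple(cols))
    if len(preds) < 2:
        raise ValueError("too few usable folds for cross-validated metrics")
    preds_a = np.asarray(preds)
    truths_a = np.asarray(truths)
    sse = ((truths_a - preds_a) ** 2).sum()
    sst = ((truths_a - truths_a.mean()) ** 2).sum()
    r2 = float(1.0 - sse / sst) if sst > 0 else 0.0
    rmse = float(np.sqrt(sse / len(preds)))
    if return_details:
        return r2, rmse, details
    return r2, rmse


def pcr_with_loocv(
    features: pd.DataFrame,
    y,
    controls: pd.DataFrame | None = None,
) -> PCRModel:
    """Convenience: :func:`pcr_fit` plus LOOCV metrics on the same data."""
    model = pcr_fit(features, y, controls=controls)
    model.loocv_r2, model.loocv_rmse = loocv(features, y, controls=controls)
    return model
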