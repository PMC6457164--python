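"""Weighted ROC analysis and covariate-adjusted ROC regression.

The empirical ROC sweeps the rule ``score >= c`` over the observed score
values with design-weighted TPR/FPR; the trapezoid AUC then equals the
weighted concordance probability with the mid-rank tie convention (ties get
half credit), which matters for an ordinal 0-30 score.

The covariate-adjusted fit is the parametric distribution-free ROC-GLM
(Pepe's placement-value approach):

    ROC_Z(t) = Phi(alpha0 + alpha1 * Phi^-1(t) + beta' Z)

Covariates shift the ROC curve of the cases only; the control score
distribution is left unadjusted.  Each case's placement value is the
weighted proportion of controls scoring at or above her (mid-rank at ties);
binary indicators U_it = 1[PV_i <= t] over a grid of false-positive rates t
are regressed on {Phi^-1(t), Z} with a probit link and case design weights,
with a sandwich covariance clustered on case (each case contributes one row
per grid point).  Wald chi-square tests address whole covariate groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import SpecificationWarning

from .accuracy import (TestDefinition, accuracy_from_2x2, diagnosis_column,
                       module_column, weighted_2x2)
from .exceptions import EstimationError

DEFAULT_T_GRID = np.round(np.arange(0.01, 1.0, 0.01), 2)


# ---------------------------------------------------------------------------
# empirical ROC


@dataclass(frozen=True)
class ROCCurve:
    """Empirical (possibly weighted) ROC: points from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    weighted: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise EstimationError(f"AUC {self.auc} outside [0, 1]")


def _case_control_arrays(records, score_col, diagnosis_label, weight_col):
    dx_col = diagnosis_column(diagnosis_label)
    usable = (records[dx_col].notna() & records[score_col].notna()
              & records[weight_col].notna())
    mod_col = module_column(diagnosis_label)
    if mod_col in records.columns:
        usable &= records[mod_col] == 1
    sub = records[usable]
    dx = sub[dx_col].to_numpy() > 0
    s = sub[score_col].to_numpy(dtype=float)
    w = sub[weight_col].to_numpy(dtype=float)
    if not dx.any():
        raise EstimationError("no cases with observed score")
    if dx.all():
        raise EstimationError("no controls with observed score")
    return s[dx], w[dx], s[~dx], w[~dx]


def empirical_roc(
    records: pd.DataFrame,
    score_col: str,
    diagnosis_label: str,
    weight_col: str = "design_weight",
) -> ROCCurve:
    """Design-weighted empirical ROC with trapezoid AUC."""
    s_case, w_case, s_ctrl, w_ctrl = _case_control_arrays(
        records, score_col, diagnosis_label, weight_col)
    thresholds = np.unique(np.concatenate([s_case, s_ctrl]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    wc = w_case.sum()
    wn = w_ctrl.sum()
    for c in thresholds:
        tpr.append(float(w_case[s_case >= c].sum() / wc))
        fpr.append(float(w_ctrl[s_ctrl >= c].sum() / wn))
    tpr.append(1.0)
    fpr.append(1.0)
    fpr_arr = np.array(fpr)
    tpr_arr = np.array(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return ROCCurve(fpr_arr, tpr_arr, auc, weighted=True)


def cutpoint_table(
    records: pd.DataFrame,
    score_col: str,
    diagnosis_label: str,
    weight_col: str = "design_weight",
    cutoffs: list[int] | None = None,
    criterion: str = "youden",
) -> pd.DataFrame:
    """Accuracy measures at each score cut-off; flags the optimal row.

    Default optimality criterion is Youden's J = Se + Sp - 1; the full table
    is always returned so any other criterion can be applied to it.
    """
    if not cutoffs:
        raise EstimationError("cutoff list is empty")
    rows = []
    for c in cutoffs:
        test = TestDefinition(f"score_ge_{c}", "score_threshold", int(c))
        table = weighted_2x2(records, test, diagnosis_label, weight_col, score_col)
        try:
            est = accuracy_from_2x2(table)
            rows.append({
                "cutoff": int(c), "sensitivity": est.sensitivity,
                "specificity": est.specificity, "ppv": est.ppv, "npv": est.npv,
                "lr_pos": est.lr_pos, "lr_neg": est.lr_neg,
                "youden": est.sensitivity + est.specificity - 1.0,
            })
        except EstimationError:
            rows.append({"cutoff": int(c), "sensitivity": np.nan,
                         "specificity": np.nan, "ppv": np.nan, "npv": np.nan,
                         "lr_pos": np.nan, "lr_neg": np.nan, "youden": np.nan})
    out = pd.DataFrame(rows)
    if criterion != "youden":
        raise EstimationError(f"unknown optimality criterion {criterion!r}")
    out["optimal"] = False
    if out["youden"].notna().any():
        out.loc[out["youden"].idxmax(), "optimal"] = True
    return out


# ---------------------------------------------------------------------------
# placement values and ROC-GLM


def placement_values(
    case_scores: np.ndarray,
    control_scores: np.ndarray,
    control_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted proportion of controls scoring >= each case (mid-rank at ties).

    Placement values of the cases are uniform on [0, 1] when cases and
    controls share a distribution; small values mean high case scores.
    """
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    if control_weights is None:
        control_weights = np.ones_like(control_scores)
    control_weights = np.asarray(control_weights, dtype=float)
    order = np.argsort(control_scores)
    s = control_scores[order]
    w = control_weights[order]
    cum = np.concatenate([[0.0], np.cumsum(w)])
    total = cum[-1]
    lo = np.searchsorted(s, case_scores, side="left")
    hi = np.searchsorted(s, case_scores, side="right")
    w_below = cum[lo]
    w_equal = cum[hi] - cum[lo]
    return (total - w_below - 0.5 * w_equal) / total


@dataclass(frozen=True)
class ROCGLMFit:
    """Fitted binormal ROC-GLM with clustered sandwich covariance."""

    alpha0: float
    alpha1: float
    beta: pd.Series
    params: pd.Series
    vcov: pd.DataFrame
    groups: dict[str, list[str]]
    t_grid: np.ndarray
    n_cases: int
    n_controls: int
    alpha1_positive: bool = True
    warnings: list[str] = field(default_factory=list)

    def auc(self, covariate_values: dict[str, float] | None = None) -> float:
        """Covariate-specific AUC = Phi((alpha0 + beta'Z) / sqrt(1 + alpha1^2))."""
        shift = 0.0
        if covariate_values:
            for col, value in covariate_values.items():
                shift += self.beta[col] * value
        return float(stats.norm.cdf(
            (self.alpha0 + shift) / np.sqrt(1.0 + self.alpha1 ** 2)))

    def roc(self, t: np.ndarray,
            covariate_values: dict[str, float] | None = None) -> np.ndarray:
        shift = 0.0
        if covariate_values:
            for col, value in covariate_values.items():
                shift += self.beta[col] * value
        return stats.norm.cdf(self.alpha0 + shift
                              + self.alpha1 * stats.norm.ppf(np.asarray(t)))


def _build_covariate_matrix(cases: pd.DataFrame,
                            covariates: list[str]) -> tuple[pd.DataFrame, dict]:
    """Numeric columns pass through; object/categorical expand to dummies."""
    blocks = []
    groups: dict[str, list[str]] = {}
    for cov in covariates:
        if cov not in cases.columns:
            raise EstimationError(f"covariate {cov!r} not in records")
        col = cases[cov]
        if col.isna().any():
            raise EstimationError(f"covariate {cov!r} missing for some cases")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            blocks.append(dummies)
            groups[cov] = list(dummies.columns)
        else:
            blocks.append(col.astype(float).to_frame(cov))
            groups[cov] = [cov]
    if blocks:
        return pd.concat(blocks, axis=1), groups
    return pd.DataFrame(index=cases.index), groups


def fit_roc_glm(
    records: pd.DataFrame,
    score_col: str,
    diagnosis_label: str,
    covariates: list[str] | None = None,
    weight_col: str = "design_weight",
    t_grid: np.ndarray | None = None,
    min_group_size: int = 20,
    bootstrap_B: int = 0,
    bootstrap_seed: int = 0,
) -> ROCGLMFit:
    """Covariate-adjusted binormal ROC-GLM on placement values.

    Controls enter only through the (weighted, unadjusted) reference
    distribution used to compute the cases' placement values.

    ``bootstrap_B > 0`` replaces the clustered sandwich covariance with a
    case/control resampling bootstrap covariance (clustered on woman), for
    when the sandwich approximation -- which treats the control placement
    distribution as fixed -- is in doubt.  Default off.
    """
    covariates = covariates or []
    if t_grid is None:
        t_grid = DEFAULT_T_GRID
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any((t_grid <= 0) | (t_grid >= 1)):
        raise EstimationError("t_grid values must lie strictly inside (0, 1)")

    dx_col = diagnosis_column(diagnosis_label)
    usable = (records[dx_col].notna() & records[score_col].notna()
              & records[weight_col].notna())
    mod_col = module_column(diagnosis_label)
    if mod_col in records.columns:
        usable &= records[mod_col] == 1
    sub = records[usable]
    is_case = sub[dx_col].to_numpy() > 0
    cases = sub[is_case].reset_index(drop=True)
    controls = sub[~is_case]
    if len(cases) < min_group_size or len(controls) < min_group_size:
        raise EstimationError(
            f"need >= {min_group_size} weighted cases and controls, have "
            f"{len(cases)} cases / {len(controls)} controls")

    pv = placement_values(
        cases[score_col].to_numpy(), controls[score_col].to_numpy(),
        controls[weight_col].to_numpy())

    z_mat, groups = _build_covariate_matrix(cases, covariates)
    n_cases = len(cases)
    n_t = len(t_grid)
    probit_t = stats.norm.ppf(t_grid)

    # long data: one row per case per grid point
    u = (np.repeat(pv, n_t) <= np.tile(t_grid, n_cases)).astype(float)
    design = {"const": np.ones(n_cases * n_t),
              "probit_t": np.tile(probit_t, n_cases)}
    for col in z_mat.columns:
        design[col] = np.repeat(z_mat[col].to_numpy(dtype=float), n_t)
    X = pd.DataFrame(design)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise EstimationError(
            f"singular design; check collinearity among columns {list(X.columns)}")

    w = np.repeat(cases[weight_col].to_numpy(dtype=float), n_t)
    cluster = np.repeat(np.arange(n_cases), n_t)
    model = sm.GLM(u, X, family=sm.families.Binomial(sm.families.links.Probit()),
                   var_weights=w)
    with warnings.catch_warnings():
        # the clustered sandwich over case-level rows with design weights is
        # the intended weighted-estimating-equation variance
        warnings.filterwarnings("ignore", category=SpecificationWarning)
        result = model.fit(cov_type="cluster", cov_kwds={"groups": cluster})

    params = pd.Series(result.params, index=X.columns)
    vcov = pd.DataFrame(result.cov_params(), index=X.columns, columns=X.columns)

    if bootstrap_B > 0:
        rng = np.random.default_rng(bootstrap_seed)
        replicate_params = []
        for _ in range(bootstrap_B):
            case_idx = rng.integers(0, len(cases), len(cases))
            ctrl_idx = rng.integers(0, len(controls), len(controls))
            boot = pd.concat([cases.iloc[case_idx],
                              controls.iloc[ctrl_idx]], ignore_index=True)
            try:
                refit = fit_roc_glm(boot, score_col, diagnosis_label,
                                    covariates, weight_col, t_grid,
                                    min_group_size=min_group_size)
            except EstimationError:
                continue
            replicate_params.append(refit.params)
        if len(replicate_params) < 0.9 * bootstrap_B:
            raise EstimationError(
                f"bootstrap failed on {bootstrap_B - len(replicate_params)}"
                f"/{bootstrap_B} replicates")
        boot_mat = pd.DataFrame(replicate_params)
        vcov = boot_mat.cov()

    alpha1 = float(params["probit_t"])
    warn_list = []
    if alpha1 <= 0:
        warn_list.append("fitted alpha1 <= 0: ROC slope non-positive")
    beta = params.drop(["const", "probit_t"])
    return ROCGLMFit(
        alpha0=float(params["const"]), alpha1=alpha1, beta=beta, params=params,
        vcov=vcov, groups=groups, t_grid=t_grid,
        n_cases=n_cases, n_controls=len(controls),
        alpha1_positive=alpha1 > 0, warnings=warn_list)


def compare_roc_groups(fit: ROCGLMFit, covariate_group: str) -> tuple[float, int, float]:
    """Wald chi-square test that a covariate group's ROC effects are all zero."""
    if covariate_group not in fit.groups:
        raise EstimationError(f"unknown covariate group {covariate_group!r}; "
                              f"fitted groups: {sorted(fit.groups)}")
    cols = fit.groups[covariate_group]
    b = fit.params[cols].to_numpy()
    v = fit.vcov.loc[cols, cols].to_numpy()
    chi2 = float(b @ np.linalg.solve(v, b))
    df = len(cols)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
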