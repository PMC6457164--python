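"""Missing-data handling: single-round PMM imputation and IPW for the gold standard.

Two distinct mechanisms are handled:

* questionnaire items missing at the item level -- imputed by a single round
  of predictive mean matching (PMM) for women with at most 30% of items
  missing; women above that threshold are excluded from score-based analyses
  (list-wise), never imputed;
* whole gold-standard modules missing -- corrected by inverse-probability
  weights from a logistic response model on the questionnaire total score,
  ethnicity and employment, multiplied into the sampling design weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .accuracy import module_column
from .exceptions import MissingDataError

ITEM_VALUES = (0.0, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class ImputationResult:
    completed: pd.DataFrame          # full frame with items imputed, total recomputed
    imputed_mask: pd.DataFrame       # boolean, item columns only
    donor_ids: dict[tuple, str]      # (record id, item col) -> donor record id
    excluded_ids: list[str]          # > 30% of items missing; untouched


@dataclass(frozen=True)
class ResponseModel:
    """Logistic model for P(gold-standard module observed | predictors)."""

    module_label: str
    params: pd.Series
    bse: pd.Series
    fitted: pd.Series                # indexed by record id, interviewed records
    predictors: list[str] = field(default_factory=lambda: [
        "total_score", "ethnicity", "employment"])

    def summary_dict(self) -> dict:
        return {"module": self.module_label,
                "coefficients": self.params.to_dict(),
                "standard_errors": self.bse.to_dict()}


def item_columns(records: pd.DataFrame) -> list[str]:
    cols = [c for c in records.columns if c.startswith("item_")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def pmm_impute(
    records: pd.DataFrame,
    predictors: list[str] | None = None,
    donor_k: int = 5,
    seed: int = 0,
    max_missing_fraction: float = 0.3,
) -> ImputationResult:
    """Single-round predictive mean matching over the questionnaire items.

    For each item with missing values an OLS of the item on the predictors
    (age plus the mean of the record's other observed items) is fitted on the
    observed records; each missing cell takes the value of one of the
    ``donor_k`` observed records nearest in predicted mean, drawn uniformly.
    Imputed values therefore always belong to the item's observed value set.
    Records with more than ``max_missing_fraction`` of items missing are
    excluded, not imputed.
    """
    if donor_k < 1:
        raise MissingDataError(f"donor_k must be >= 1, got {donor_k}")
    rng = np.random.default_rng(seed)
    cols = item_columns(records)
    if not cols:
        raise MissingDataError("no item_* columns found")
    items = records[cols].to_numpy(dtype=float)
    n, p = items.shape
    n_missing = np.isnan(items).sum(axis=1)
    excluded = n_missing > max_missing_fraction * p
    ids = records["id"].to_numpy()

    base_predictors = predictors if predictors is not None else ["age"]
    for col in base_predictors:
        if records[col].isna().any():
            raise MissingDataError(f"PMM predictor {col!r} has missing values")
    base = records[list(base_predictors)].to_numpy(dtype=float)

    completed_items = items.copy()
    mask = np.zeros_like(items, dtype=bool)
    donor_ids: dict[tuple, str] = {}

    for j in range(p):
        col_missing = np.isnan(items[:, j]) & ~excluded
        if not col_missing.any():
            continue
        donors = ~np.isnan(items[:, j]) & ~excluded
        if not donors.any():
            raise MissingDataError(f"no complete donors for {cols[j]}")
        # predictor: other observed items' mean plus the base covariates
        others = np.delete(items, j, axis=1)
        with np.errstate(invalid="ignore"):
            other_mean = np.nanmean(others, axis=1)
        other_mean = np.where(np.isnan(other_mean), 0.0, other_mean)
        X = np.column_stack([np.ones(n), other_mean, base])
        y = items[:, j]
        coef, *_ = np.linalg.lstsq(X[donors], y[donors], rcond=None)
        pred = X @ coef
        donor_idx = np.flatnonzero(donors)
        donor_pred = pred[donor_idx]
        for i in np.flatnonzero(col_missing):
            dist = np.abs(donor_pred - pred[i])
            k = min(donor_k, len(donor_idx))
            # stable partial sort: ties broken by record order
            pool = donor_idx[np.argsort(dist, kind="stable")[:k]]
            chosen = pool[rng.integers(0, len(pool))]
            completed_items[i, j] = items[chosen, j]
            mask[i, j] = True
            donor_ids[(ids[i], cols[j])] = ids[chosen]

    completed = records.copy()
    for j, col in enumerate(cols):
        completed[col] = completed_items[:, j]
    fully_observed = ~np.isnan(completed_items).any(axis=1)
    completed["total_score"] = np.where(
        fully_observed, np.nansum(completed_items, axis=1), np.nan)
    return ImputationResult(
        completed=completed,
        imputed_mask=pd.DataFrame(mask, columns=cols, index=records.index),
        donor_ids=donor_ids,
        excluded_ids=[str(i) for i in ids[excluded]],
    )


def fit_response_model(
    records: pd.DataFrame,
    module_label: str,
    total_col: str = "total_score",
) -> ResponseModel:
    """Logistic regression of module response on total score, ethnicity, employment.

    Fitted on interviewed records with an observed (post-imputation) total
    score.  Raises on perfect separation with a hint to collapse categories.
    """
    mod_col = module_column(module_label)
    if mod_col not in records.columns:
        raise MissingDataError(f"no module-observed column {mod_col!r}")
    sub = records[records[total_col].notna()].copy()
    if "interviewed" in sub.columns:
        sub = sub[sub["interviewed"] == 1]
    y = sub[mod_col].astype(float)
    if y.nunique() < 2:
        if (y == 1).all():
            # no missingness: degenerate model with response probability 1
            fitted = pd.Series(1.0, index=sub["id"])
            params = pd.Series({"const": np.inf, total_col: 0.0})
            return ResponseModel(module_label, params, params * np.nan, fitted)
        raise MissingDataError(
            f"module {module_label!r}: all records missing; nothing to weight")

    X = pd.concat([
        pd.Series(1.0, index=sub.index, name="const"),
        sub[total_col].astype(float),
        pd.get_dummies(sub["ethnicity"], prefix="ethnicity",
                       drop_first=True, dtype=float),
        pd.get_dummies(sub["employment"], prefix="employment",
                       drop_first=True, dtype=float),
    ], axis=1)
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise MissingDataError(
            f"response model failed ({exc}); consider collapsing sparse "
            "ethnicity/employment categories") from exc
    fitted_p = fit.fittedvalues
    if (fitted_p < 1e-8).any() or np.isnan(fit.bse).all():
        raise MissingDataError(
            "separation detected in response model; collapse sparse categories")
    return ResponseModel(
        module_label,
        params=pd.Series(fit.params, index=X.columns),
        bse=pd.Series(fit.bse, index=X.columns),
        fitted=pd.Series(fitted_p.to_numpy(), index=sub["id"].to_numpy()),
    )


def apply_combined_weights(
    records: pd.DataFrame,
    model: ResponseModel,
    weight_floor: float = 0.02,
) -> pd.DataFrame:
    """Attach analysis_weight = design_weight / response probability.

    Only records with the module observed get an analysis weight; module-
    missing records keep NaN and drop out of that module's analyses.
    Probabilities below ``weight_floor`` are clipped (weight capped) and
    counted in the returned frame's ``attrs['n_weight_capped']``.
    """
    out = records.copy()
    mod_col = module_column(model.module_label)
    p = out["id"].map(model.fitted)
    capped = (p < weight_floor) & p.notna()
    p = p.clip(lower=weight_floor)
    observed = out[mod_col] == 1
    out["analysis_weight"] = np.where(
        observed & out["design_weight"].notna() & p.notna(),
        out["design_weight"] / p, np.nan)
    out.attrs["n_weight_capped"] = int(capped.sum())
    return out
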