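"""Weighted 2x2 tables, diagnostic accuracy measures and bootstrap CIs.

All estimators are Horvitz-Thompson style: each interviewed woman contributes
her design (or combined design x IPW) weight to the cell she falls in, which
removes the verification bias of the screen-stratified phase-two sample.
Confidence intervals are percentile bootstrap, resampling with replacement
within each screening stratum with stratum sizes held at the observed counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import BootstrapError, EstimationError

TEST_RULES = ("either_positive", "both_positive", "either_plus_help", "score_threshold")

_LABEL_ALIASES = {"any": "any", "any_disorder": "any"}


def diagnosis_column(label: str) -> str:
    """Map a diagnosis label to its cohort column (``any_disorder`` -> ``dx_any``)."""
    return f"dx_{_LABEL_ALIASES.get(label, label)}"


def module_column(label: str) -> str:
    return f"module_observed_{_LABEL_ALIASES.get(label, label)}"


# ---------------------------------------------------------------------------
# test definitions


@dataclass(frozen=True)
class TestDefinition:
    """One index-test rule against the 0/1 screen answers or the total score."""

    __test__ = False  # not a pytest collection target

    name: str
    rule: str
    cutoff: int | None = None

    def __post_init__(self) -> None:
        if self.rule not in TEST_RULES:
            raise EstimationError(f"unknown test rule {self.rule!r}")
        if self.rule == "score_threshold":
            if self.cutoff is None or int(self.cutoff) != self.cutoff \
                    or not (1 <= self.cutoff <= 30):
                raise EstimationError(
                    f"score_threshold requires integer cutoff in [1, 30], "
                    f"got {self.cutoff!r}")
        elif self.cutoff is not None:
            raise EstimationError(f"rule {self.rule!r} takes no cutoff")

    @classmethod
    def parse(cls, spec: str) -> "TestDefinition":
        """Parse ``either`` / ``both`` / ``help`` / ``epds:<c>``."""
        if spec == "either":
            return cls("whooley_either", "either_positive")
        if spec == "both":
            return cls("whooley_both", "both_positive")
        if spec == "help":
            return cls("whooley_either_plus_help", "either_plus_help")
        if spec.startswith("epds:"):
            return cls(f"epds_ge_{spec[5:]}", "score_threshold", int(spec[5:]))
        raise EstimationError(f"cannot parse test spec {spec!r}")


def evaluate_test(records: pd.DataFrame, test: TestDefinition,
                  score_col: str = "total_score") -> pd.Series:
    """Per-record test result: 1/0, or NaN where the rule is unevaluable.

    The help rule is False (not missing) for screen-negatives: the help
    question is only asked of positives, and a negative screen fails the
    combined rule regardless.
    """
    if test.rule == "score_threshold":
        score = records[score_col]
        result = (score >= test.cutoff).astype(float)
        result[score.isna()] = np.nan
        return result
    q1 = records["screen_q1"].astype(float)
    q2 = records["screen_q2"].astype(float)
    if test.rule == "either_positive":
        return ((q1 > 0) | (q2 > 0)).astype(float)
    if test.rule == "both_positive":
        return ((q1 > 0) & (q2 > 0)).astype(float)
    if test.rule == "either_plus_help":
        either = (q1 > 0) | (q2 > 0)
        result = pd.Series(0.0, index=records.index)
        help_q = records["help_q"]
        result[either & (help_q == 1)] = 1.0
        result[either & help_q.isna()] = np.nan
        return result
    raise EstimationError(f"unknown test rule {test.rule!r}")


# ---------------------------------------------------------------------------
# 2x2 and accuracy measures


@dataclass(frozen=True)
class TwoByTwoWeighted:
    """Weighted and raw cells of one test-vs-diagnosis cross-table."""

    tp: float
    fp: float
    fn: float
    tn: float
    raw_tp: int
    raw_fp: int
    raw_fn: int
    raw_tn: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for cell in ("tp", "fp", "fn", "tn"):
            if getattr(self, cell) < 0:
                raise EstimationError(f"weighted cell {cell} is negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def raw_total(self) -> int:
        return self.raw_tp + self.raw_fp + self.raw_fn + self.raw_tn


@dataclass(frozen=True)
class AccuracyEstimates:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    prevalence: float
    lr_pos_infinite: bool = False
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg, "prevalence": self.prevalence,
            "lr_pos_infinite": self.lr_pos_infinite,
        }
        if self.ci:
            out["ci"] = {k: list(v) for k, v in self.ci.items()}
        return out


def weighted_2x2(
    records: pd.DataFrame,
    test: TestDefinition,
    diagnosis_label: str,
    weight_col: str = "design_weight",
    score_col: str = "total_score",
) -> TwoByTwoWeighted:
    """Sum design weights into TP/FP/FN/TN for one test rule and diagnosis.

    Records lacking a weight, an observed gold standard for the label, or an
    evaluable test result are excluded and counted in ``n_excluded``.
    """
    dx_col = diagnosis_column(diagnosis_label)
    if dx_col not in records.columns:
        raise EstimationError(f"no diagnosis column {dx_col!r} for label "
                              f"{diagnosis_label!r}")
    result = evaluate_test(records, test, score_col=score_col)
    observed = records[dx_col].notna()
    mod_col = module_column(diagnosis_label)
    if mod_col in records.columns:
        observed &= records[mod_col] == 1
    weight = records[weight_col]
    usable = observed & result.notna() & weight.notna()
    n_excluded = int((weight.notna() & ~usable).sum())
    if not usable.any():
        if test.rule == "score_threshold" and not (weight.notna() & records[score_col].notna()).any():
            raise EstimationError("threshold test: all scores missing")
        raise EstimationError("no evaluable records for this test and diagnosis")

    dx = records.loc[usable, dx_col].to_numpy() > 0
    pos = result[usable].to_numpy() > 0
    w = weight[usable].to_numpy()
    return TwoByTwoWeighted(
        tp=float(w[dx & pos].sum()), fp=float(w[~dx & pos].sum()),
        fn=float(w[dx & ~pos].sum()), tn=float(w[~dx & ~pos].sum()),
        raw_tp=int((dx & pos).sum()), raw_fp=int((~dx & pos).sum()),
        raw_fn=int((dx & ~pos).sum()), raw_tn=int((~dx & ~pos).sum()),
        n_excluded=n_excluded,
    )


def accuracy_from_2x2(table: TwoByTwoWeighted) -> AccuracyEstimates:
    """Point estimates of Se, Sp, PPV, NPV, likelihood ratios and prevalence.

    Empty disease margins are errors (Se/Sp undefined); an empty test margin
    only leaves the corresponding predictive value NaN, so extreme cut-offs
    still report Se = 1 / Sp = 0 (or Se = 0 / Sp = 1).
    """
    if table.tp + table.fn <= 0:
        raise EstimationError("empty diseased margin (tp + fn = 0)")
    if table.fp + table.tn <= 0:
        raise EstimationError("empty non-diseased margin (fp + tn = 0)")
    se = table.tp / (table.tp + table.fn)
    sp = table.tn / (table.fp + table.tn)
    ppv = table.tp / (table.tp + table.fp) if table.tp + table.fp > 0 else math.nan
    npv = table.tn / (table.fn + table.tn) if table.fn + table.tn > 0 else math.nan
    lr_pos_infinite = sp >= 1.0
    lr_pos = math.inf if lr_pos_infinite else se / (1.0 - sp)
    lr_neg = (1.0 - se) / sp if sp > 0 else math.inf
    prevalence = (table.tp + table.fn) / table.total
    return AccuracyEstimates(se, sp, ppv, npv, lr_pos, lr_neg, prevalence,
                             lr_pos_infinite=lr_pos_infinite)


# ---------------------------------------------------------------------------
# prevalence and bootstrap


def weighted_prevalence(
    records: pd.DataFrame,
    diagnosis_label: str,
    weight_col: str = "design_weight",
) -> float:
    """Weighted prevalence over records with the label's gold standard observed."""
    dx_col = diagnosis_column(diagnosis_label)
    observed = records[dx_col].notna() & records[weight_col].notna()
    mod_col = module_column(diagnosis_label)
    if mod_col in records.columns:
        observed &= records[mod_col] == 1
    if not observed.any():
        raise EstimationError(f"diagnosis {diagnosis_label!r} never observed")
    w = records.loc[observed, weight_col].to_numpy()
    d = records.loc[observed, dx_col].to_numpy().astype(float)
    return float((w * d).sum() / w.sum())


def bootstrap_ci(
    records: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], float],
    B: int = 1000,
    seed: int = 0,
    stratum_col: str = "stratum",
    alpha: float = 0.05,
    max_failure_fraction: float = 0.01,
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for any record-set estimator.

    Resamples records with replacement within each screening stratum, keeping
    stratum sizes at their observed values and each record's weight attached.
    """
    if B < 200:
        raise BootstrapError(f"B must be >= 200, got {B}")
    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero((records[stratum_col] == h).to_numpy())
              for h in records[stratum_col].unique()]
    values = np.empty(B)
    failures = 0
    for b in range(B):
        idx = np.concatenate([g[rng.integers(0, len(g), len(g))] for g in groups])
        try:
            values[b] = estimator(records.iloc[idx])
        except EstimationError:
            values[b] = np.nan
            failures += 1
    if failures > max_failure_fraction * B:
        raise BootstrapError(
            f"estimator failed on {failures}/{B} bootstrap replicates")
    ok = values[~np.isnan(values)]
    low, high = np.percentile(ok, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(low), float(high)


def prevalence_estimates(
    records: pd.DataFrame,
    diagnosis_labels: list[str],
    weight_col: str = "design_weight",
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Weighted prevalence with stratified-bootstrap CI, one row per label."""
    rows = []
    for i, label in enumerate(diagnosis_labels):
        point = weighted_prevalence(records, label, weight_col)
        low, high = bootstrap_ci(
            records, lambda d, lab=label: weighted_prevalence(d, lab, weight_col),
            B=B, seed=seed + i)
        rows.append({"diagnosis": label, "prevalence": point,
                     "ci_low": low, "ci_high": high, "B": B})
    return pd.DataFrame(rows)


def estimate_accuracy(
    records: pd.DataFrame,
    test: TestDefinition,
    diagnosis_label: str,
    weight_col: str = "design_weight",
    score_col: str = "total_score",
    B: int = 1000,
    seed: int = 0,
) -> tuple[TwoByTwoWeighted, AccuracyEstimates]:
    """Full accuracy report for one test: point estimates plus bootstrap CIs."""
    table = weighted_2x2(records, test, diagnosis_label, weight_col, score_col)
    point = accuracy_from_2x2(table)
    cis: dict[str, tuple[float, float]] = {}
    fields = ("sensitivity", "specificity", "ppv", "npv", "prevalence")

    def field_estimator(name: str) -> Callable[[pd.DataFrame], float]:
        def est(d: pd.DataFrame) -> float:
            t = weighted_2x2(d, test, diagnosis_label, weight_col, score_col)
            return getattr(accuracy_from_2x2(t), name)
        return est

    for i, name in enumerate(fields):
        cis[name] = bootstrap_ci(records, field_estimator(name), B=B, seed=seed + i)
    est_with_ci = AccuracyEstimates(
        point.sensitivity, point.specificity, point.ppv, point.npv,
        point.lr_pos, point.lr_neg, point.prevalence,
        lr_pos_infinite=point.lr_pos_infinite, ci=cis)
    return table, est_with_ci


# ---------------------------------------------------------------------------
# report rounding (half away from zero, matching printed precision)


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (printed-report convention)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
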