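"""Design arithmetic and simulation-based power for a planned two-phase study.

The planning model: screen ``n_screen`` women with a binary screen of assumed
sensitivity/specificity against a reference diagnosis of assumed prevalence;
a fraction consent; all screen-positives (or a stated fraction) and a small
fraction of screen-negatives are interviewed.  Expected phase-two yields and
case counts follow in closed form from Bayes' rule.  CI widths of the
design-weighted sensitivity/specificity estimators and the power of a
cases-only comparison of two instrument sensitivities are obtained by
simulation, mirroring how the source design was justified.

Expected interview counts can be given directly (``planned_n_pos`` /
``planned_n_neg``): a study protocol typically fixes round per-stratum
targets and quotes the implied sampling fractions only approximately, and
the expected-case arithmetic is then driven by the planned counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .accuracy import bootstrap_ci
from .exceptions import ConfigurationError, EstimationError

TEST_SPECS = ("one_sample_vs_reference", "two_sample_independent")


@dataclass(frozen=True)
class DesignConfig:
    """Assumed population and design parameters for a planned study.

    Defaults are the source study's design assumptions: 6000 screened,
    9% depression, screen sensitivity 0.95 / specificity 0.89, 66% consent,
    sampling fractions 0.54 (screen-positive) and 0.06 (screen-negative),
    index instrument sensitivity 0.80 / specificity 0.71, comparator
    sensitivity 0.65.
    """

    n_screen: int = 6000
    prevalence: float = 0.09
    screen_sens: float = 0.95
    screen_spec: float = 0.89
    consent_rate: float = 0.66
    sample_fraction_pos: float = 0.54
    sample_fraction_neg: float = 0.06
    planned_n_pos: int | None = None
    planned_n_neg: int | None = None
    assumed_index_sens: float = 0.80
    assumed_index_spec: float = 0.71
    comparator_sens: float = 0.65
    alpha: float = 0.05
    replicates: int = 200
    bootstrap_B: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence", "screen_sens", "screen_spec", "consent_rate",
                     "sample_fraction_pos", "sample_fraction_neg",
                     "assumed_index_sens", "assumed_index_spec",
                     "comparator_sens", "alpha"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(
                    f"{name} must be in [0, 1], got {value!r}")
        if self.n_screen < 1:
            raise ConfigurationError("n_screen must be >= 1")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")


def paper_design(**overrides) -> DesignConfig:
    """The published design: planned phase-two targets of 400 W+ and 200 W-."""
    overrides.setdefault("planned_n_pos", 400)
    overrides.setdefault("planned_n_neg", 200)
    return DesignConfig(**overrides)


@dataclass(frozen=True)
class YieldReport:
    """Closed-form expected phase-two yields; no simulation involved."""

    expected_n_pos: float
    expected_n_neg: float
    expected_cases: float
    p_screen_pos: float
    p_disease_given_pos: float
    p_disease_given_neg: float

    @property
    def rounded(self) -> tuple[int, int, int]:
        return (round(self.expected_n_pos), round(self.expected_n_neg),
                round(self.expected_cases))


def expected_yield(config: DesignConfig) -> YieldReport:
    """Expected interviewed counts per stratum and expected diseased interviewees.

    P(screen+) = pi*Se + (1-pi)*(1-Sp); stratum yields are n_screen * P(stratum)
    * consent * sampling fraction unless planned per-stratum interview counts
    are given, in which case those planned counts drive the expected-case
    arithmetic: E[cases] = n_pos*P(D|screen+) + n_neg*P(D|screen-).
    """
    pi = config.prevalence
    p_pos = pi * config.screen_sens + (1.0 - pi) * (1.0 - config.screen_spec)
    p_d_pos = (pi * config.screen_sens / p_pos) if p_pos > 0 else 0.0
    p_d_neg = (pi * (1.0 - config.screen_sens) / (1.0 - p_pos)) if p_pos < 1 else 0.0
    n_pos = (config.planned_n_pos if config.planned_n_pos is not None
             else config.n_screen * p_pos * config.consent_rate
             * config.sample_fraction_pos)
    n_neg = (config.planned_n_neg if config.planned_n_neg is not None
             else config.n_screen * (1.0 - p_pos) * config.consent_rate
             * config.sample_fraction_neg)
    cases = n_pos * p_d_pos + n_neg * p_d_neg
    return YieldReport(float(n_pos), float(n_neg), float(cases),
                       p_pos, p_d_pos, p_d_neg)


@dataclass(frozen=True)
class PowerReport:
    expected_n_pos: float
    expected_n_neg: float
    expected_cases: float
    ci_width_sens: float | None = None
    ci_width_spec: float | None = None
    power: float | None = None
    mc_se: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 0
    n_dropped: int = 0


# ---------------------------------------------------------------------------
# simulation


def _simulate_one_study(config: DesignConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One replicate two-phase study as a minimal record frame.

    Counts are drawn hierarchically (binomial frame composition, binomial
    selection, hypergeometric disease counts among interviewees, binomial
    index-test outcomes), which is distributionally identical to per-woman
    simulation but much faster.
    """
    n = config.n_screen
    n_d = rng.binomial(n, config.prevalence)
    pos_d = rng.binomial(n_d, config.screen_sens)
    pos_nd = rng.binomial(n - n_d, 1.0 - config.screen_spec)
    frame = {"positive": (pos_d + pos_nd, pos_d),
             "negative": (n - pos_d - pos_nd, n_d - pos_d)}
    rows = []
    for stratum, fraction in (("positive", config.sample_fraction_pos),
                              ("negative", config.sample_fraction_neg)):
        n_frame, n_frame_d = frame[stratum]
        n_int = rng.binomial(n_frame, fraction * config.consent_rate)
        if n_int == 0 or n_frame == 0:
            continue
        d_int = rng.hypergeometric(n_frame_d, n_frame - n_frame_d, n_int)
        test_d = rng.binomial(d_int, config.assumed_index_sens)
        test_nd = rng.binomial(n_int - d_int, 1.0 - config.assumed_index_spec)
        weight = n_frame / n_int
        for dx, test_pos, count in ((1, 1, test_d), (1, 0, d_int - test_d),
                                    (0, 1, test_nd),
                                    (0, 0, n_int - d_int - test_nd)):
            if count:
                rows.extend([{"stratum": stratum, "dx": dx,
                              "index_pos": test_pos, "weight": weight}] * count)
    return pd.DataFrame(rows)


def _weighted_se(d: pd.DataFrame) -> float:
    cases = d[d["dx"] == 1]
    denom = cases["weight"].sum()
    if denom == 0:
        raise EstimationError("replicate has no diseased interviewees")
    return float((cases["weight"] * cases["index_pos"]).sum() / denom)


def _weighted_sp(d: pd.DataFrame) -> float:
    ctrl = d[d["dx"] == 0]
    denom = ctrl["weight"].sum()
    if denom == 0:
        raise EstimationError("replicate has no non-diseased interviewees")
    return float((ctrl["weight"] * (1 - ctrl["index_pos"])).sum() / denom)


def simulate_ci_width(config: DesignConfig) -> PowerReport:
    """Mean bootstrap percentile CI widths for weighted Se and Sp.

    Per replicate a whole two-phase study is drawn, weighted Se/Sp computed,
    and their stratified-bootstrap percentile CIs recorded.  Replicates with
    no diseased (or no non-diseased) interviewees are dropped and counted;
    more than 5% dropped is an error.
    """
    if config.bootstrap_B < 200:
        raise ConfigurationError("bootstrap_B must be >= 200")
    rng = np.random.default_rng(config.seed)
    widths_se, widths_sp = [], []
    dropped = 0
    for r in range(config.replicates):
        study = _simulate_one_study(config, rng)
        if study.empty or study["dx"].nunique() < 2:
            dropped += 1
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            lo, hi = bootstrap_ci(study, _weighted_se, B=config.bootstrap_B,
                                  seed=sub_seed)
            lo2, hi2 = bootstrap_ci(study, _weighted_sp, B=config.bootstrap_B,
                                    seed=sub_seed + 1)
        except EstimationError:
            dropped += 1
            continue
        widths_se.append(hi - lo)
        widths_sp.append(hi2 - lo2)
    if dropped > 0.05 * config.replicates:
        raise EstimationError(
            f"{dropped}/{config.replicates} replicates dropped (zero-case yields)")
    y = expected_yield(config)
    widths_se_arr = np.asarray(widths_se)
    widths_sp_arr = np.asarray(widths_sp)
    return PowerReport(
        expected_n_pos=y.expected_n_pos, expected_n_neg=y.expected_n_neg,
        expected_cases=y.expected_cases,
        ci_width_sens=float(widths_se_arr.mean()),
        ci_width_spec=float(widths_sp_arr.mean()),
        mc_se={"ci_width_sens": float(widths_se_arr.std(ddof=1)
                                      / math.sqrt(len(widths_se_arr))),
               "ci_width_spec": float(widths_sp_arr.std(ddof=1)
                                      / math.sqrt(len(widths_sp_arr)))},
        n_replicates=len(widths_se_arr), n_dropped=dropped)


def _binom_reject_table(n: int, p0: float, alpha: float) -> np.ndarray:
    """reject[k] = two-sided exact binomial test of H0: p = p0 rejects at alpha."""
    return np.array([
        stats.binomtest(k, n, p0).pvalue < alpha for k in range(n + 1)])


def simulate_power(
    config: DesignConfig,
    test_spec: str = "one_sample_vs_reference",
    n_cases: int | None = None,
    replicates: int | None = None,
) -> PowerReport:
    """Simulated power of the cases-only sensitivity comparison.

    ``one_sample_vs_reference``: per replicate draw the index test on
    ``n_cases`` diseased women at the assumed sensitivity and apply the exact
    binomial two-sided test against the comparator sensitivity (a
    conservative, cases-only analysis).  ``two_sample_independent``: draw
    both instruments on independent case groups of the same size and apply a
    two-proportion z-test.
    """
    if test_spec not in TEST_SPECS:
        raise EstimationError(f"unknown test_spec {test_spec!r}; "
                              f"choose from {TEST_SPECS}")
    replicates = replicates if replicates is not None else config.replicates
    y = expected_yield(config)
    n = n_cases if n_cases is not None else round(y.expected_cases)
    rng = np.random.default_rng(config.seed)
    if test_spec == "one_sample_vs_reference":
        reject = _binom_reject_table(n, config.comparator_sens, config.alpha)
        draws = rng.binomial(n, config.assumed_index_sens, size=replicates)
        rejections = reject[draws]
    else:
        x1 = rng.binomial(n, config.assumed_index_sens, size=replicates)
        x2 = rng.binomial(n, config.comparator_sens, size=replicates)
        p1, p2 = x1 / n, x2 / n
        pooled = (x1 + x2) / (2 * n)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * 2 / n)
        z = np.where(np.isfinite(z), z, 0.0)
        rejections = np.abs(z) > stats.norm.ppf(1 - config.alpha / 2)
    power = float(rejections.mean())
    mc_se = math.sqrt(max(power * (1 - power), 1e-12) / replicates)
    return PowerReport(
        expected_n_pos=y.expected_n_pos, expected_n_neg=y.expected_n_neg,
        expected_cases=y.expected_cases, power=power,
        mc_se={"power": mc_se}, n_replicates=replicates)
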