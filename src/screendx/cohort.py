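"""Synthetic screened-cohort generator.

Emulates the structure of a two-phase antenatal screening study: a large
population answers a binary two-item depression screen (the Whooley
questions) at their booking appointment; a 10-item questionnaire (EPDS-like,
items 0-3, total 0-30) and gold-standard diagnostic labels exist for every
woman, with missingness injected so the downstream imputation and
inverse-probability-weighting stages have something real to correct.

The questionnaire score is generated from a binormal latent model:
controls ~ N(0, 1), cases ~ N(mu1 + covariate shifts, sigma1), mapped to the
0-30 ordinal scale by a fixed monotone discretisation.  This matches the
binormal ROC-GLM fitted downstream, so parameter-recovery tests have a
closed-form truth: with controls standard normal the ROC of the latent score
is ROC(t) = Phi(a + b*Phi^-1(t)) with a = mu/sigma1, b = 1/sigma1 and
AUC = Phi(mu / sqrt(1 + sigma1^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError

# ---------------------------------------------------------------------------
# configuration

ETHNICITY_LEVELS = ["eth_1", "eth_2", "eth_3", "eth_4", "eth_5"]
INCOME_LEVELS = ["inc_1", "inc_2", "inc_3", "inc_4", "inc_5"]
EDUCATION_LEVELS = ["edu_1", "edu_2", "edu_3"]
EMPLOYMENT_LEVELS = ["employed", "not_employed"]
MODE_LEVELS = ["paper", "tablet"]

#: fixed monotone discretisation of the latent scale: score = clip(round(A + B*x), 0, 30).
#: A=7 puts the control median at 7; B=4 gives a control IQR of about 4.3-9.7, so the
#: oversampled high-scoring screen-positives pull the observed sample IQR up towards
#: the 4-13 seen in the real cohort.
LATENT_TO_SCORE_OFFSET = 7.0
LATENT_TO_SCORE_SCALE = 4.0


@dataclass(frozen=True)
class CovariateEffects:
    """Shifts of the *case* latent mean; controls are never shifted.

    ``age_slope`` is per decade of age, centred at ``age_center`` years, so a
    negative slope makes the score less discriminating in older women.
    Categorical effects are offsets per level (reference level 0).
    """

    age_slope: float = -0.35
    age_center: float = 30.0
    ethnicity: dict[str, float] = field(default_factory=dict)
    income: dict[str, float] = field(default_factory=dict)
    education: dict[str, float] = field(default_factory=dict)
    interpreter: float = 0.5
    mode: float = 0.0


@dataclass(frozen=True)
class MissingnessConfig:
    """Item-level MCAR plus MAR gold-standard module missingness.

    Module response is logistic in the (complete-data) questionnaire total,
    ethnicity and employment -- the same predictors the IPW stage must
    recover.  Defaults give ~96% module completion.
    """

    item_missing_p: float = 0.005
    help_missing_p: float = 0.02
    module_intercept: float = 4.5
    module_total_coef: float = -0.06
    module_ethnicity: dict[str, float] = field(default_factory=lambda: {
        "eth_2": -0.3, "eth_3": -0.5, "eth_4": -0.2, "eth_5": -0.4,
    })
    module_employment_coef: float = 0.4


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for one screened population.

    Defaults reproduce the structure of the real cohort: ~10,000 screened,
    depression prevalence 11%, any-disorder 27%, a screen with sensitivity
    0.41 / specificity 0.95 against depression (hence ~9% screen-positive),
    and a latent binormal score with AUC ~0.89 for depression.
    """

    n_screen: int = 10_000
    prevalence: dict[str, float] = field(default_factory=lambda: {
        "depression": 0.11, "anxiety": 0.15, "any_disorder": 0.27,
    })
    reference_label: str = "depression"
    screen_sens: float = 0.41
    screen_spec: float = 0.95
    # screen-positive pattern: P(yes to both | positive), P(q1 only | positive)
    p_both_given_pos: float = 0.45
    p_q1_only_given_pos: float = 0.30
    # help question (asked only of screen-positives)
    p_help_case: float = 0.18
    p_help_noncase: float = 0.02
    item_count: int = 10
    mu1: float = 1.735       # case latent mean at reference covariates; AUC ~ 0.89
    sigma1: float = 1.0      # case latent SD (controls fixed at N(0,1))
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    consent_rate: float = 0.35
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    # covariate distributions (study-realistic defaults; not published values)
    age_range: tuple[float, float] = (16.0, 45.0)
    ethnicity_probs: tuple[float, ...] = (0.35, 0.30, 0.15, 0.12, 0.08)
    income_probs: tuple[float, ...] = (0.25, 0.25, 0.20, 0.18, 0.12)
    education_probs: tuple[float, ...] = (0.30, 0.40, 0.30)
    employment_p: float = 0.60
    interpreter_p: float = 0.07
    mode_tablet_p: float = 0.17


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0) or not np.isfinite(p):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {p!r}")


def validate_config(config: CohortConfig) -> None:
    """Raise :class:`ConfigurationError` on any invalid parameter."""
    if config.n_screen < 1:
        raise ConfigurationError(f"n_screen must be >= 1, got {config.n_screen}")
    if config.item_count <= 0:
        raise ConfigurationError(f"item_count must be positive, got {config.item_count}")
    if config.sigma1 <= 0:
        raise ConfigurationError(f"sigma1 must be > 0, got {config.sigma1}")
    for name in ("screen_sens", "screen_spec", "consent_rate", "p_both_given_pos",
                 "p_q1_only_given_pos", "p_help_case", "p_help_noncase",
                 "employment_p", "interpreter_p", "mode_tablet_p"):
        _check_prob(name, getattr(config, name))
    if config.p_both_given_pos + config.p_q1_only_given_pos > 1.0 + 1e-12:
        raise ConfigurationError("screen-positive pattern probabilities exceed 1")
    for label, p in config.prevalence.items():
        _check_prob(f"prevalence[{label}]", p)
    if config.reference_label not in config.prevalence:
        raise ConfigurationError(
            f"reference_label {config.reference_label!r} has no prevalence entry")
    components = {k: v for k, v in config.prevalence.items() if k != "any_disorder"}
    if "any_disorder" in config.prevalence and components:
        p_any = config.prevalence["any_disorder"]
        if p_any < max(components.values()) - 1e-12:
            raise ConfigurationError(
                "any_disorder prevalence must be >= every component prevalence")
        p_union = 1.0 - float(np.prod([1.0 - v for v in components.values()]))
        if p_any < p_union - 1e-9:
            raise ConfigurationError(
                f"any_disorder prevalence {p_any} is below the union of independent "
                f"components ({p_union:.4f}); no residual disorder probability exists")
    _check_prob("item_missing_p", config.missingness.item_missing_p)
    _check_prob("help_missing_p", config.missingness.help_missing_p)
    for name in ("ethnicity_probs", "income_probs", "education_probs"):
        probs = getattr(config, name)
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ConfigurationError(f"{name} must be nonnegative and sum to 1")


def config_from_roc_params(
    alpha0: float,
    alpha1: float,
    age_slope: float = 0.0,
    **overrides,
) -> CohortConfig:
    """Build a config whose latent score follows ROC(t) = Phi(a0 + a1*Phi^-1(t) + b*Z).

    The binormal correspondence is mu1 = alpha0/alpha1, sigma1 = 1/alpha1 and
    latent covariate shift = beta/alpha1 (age slope per decade).
    """
    if alpha1 <= 0:
        raise ConfigurationError("alpha1 must be > 0")
    effects = CovariateEffects(age_slope=age_slope / alpha1, interpreter=0.0)
    return CohortConfig(
        mu1=alpha0 / alpha1, sigma1=1.0 / alpha1,
        covariate_effects=effects, **overrides)


# ---------------------------------------------------------------------------
# generation


def discretise_latent(latent: np.ndarray) -> np.ndarray:
    """Fixed monotone map from the latent scale to the 0-30 ordinal score."""
    raw = np.floor(LATENT_TO_SCORE_OFFSET + LATENT_TO_SCORE_SCALE * np.asarray(latent) + 0.5)
    return np.clip(raw, 0, 30).astype(int)


def case_latent_shift(config: CohortConfig, frame: pd.DataFrame) -> np.ndarray:
    """Deterministic covariate shift of the case latent mean for each record."""
    eff = config.covariate_effects
    shift = eff.age_slope * (frame["age"].to_numpy() - eff.age_center) / 10.0
    for col, table in (("ethnicity", eff.ethnicity), ("income", eff.income),
                       ("education", eff.education)):
        if table:
            shift = shift + frame[col].map(lambda v: table.get(v, 0.0)).to_numpy()
    shift = shift + eff.interpreter * frame["interpreter"].to_numpy()
    shift = shift + eff.mode * (frame["mode"] == MODE_LEVELS[1]).to_numpy()
    return shift


def _residual_any_prob(config: CohortConfig) -> float:
    """P(extra disorder) so the union of independent components hits any_disorder."""
    components = [v for k, v in config.prevalence.items() if k != "any_disorder"]
    if "any_disorder" not in config.prevalence:
        return 0.0
    p_any = config.prevalence["any_disorder"]
    p_union = 1.0 - float(np.prod([1.0 - v for v in components])) if components else 0.0
    if p_union >= 1.0:
        return 0.0
    return max(0.0, (p_any - p_union) / (1.0 - p_union))


def generate_population(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Generate one screened population as a DataFrame, one row per woman.

    Deterministic given (config, seed): all draws come from a single seeded
    Generator in a fixed column order.  Besides the canonical cohort columns
    the frame carries ``latent_score`` (the pre-discretisation latent value,
    NaN-free) and ``total_score`` (sum of items when all are observed).
    """
    validate_config(config)
    rng = np.random.default_rng(seed)
    n = config.n_screen
    m = config.missingness

    df = pd.DataFrame({"id": [f"W{i + 1:06d}" for i in range(n)]})
    df["age"] = np.round(rng.uniform(*config.age_range, size=n), 1)
    df["ethnicity"] = rng.choice(ETHNICITY_LEVELS, size=n, p=config.ethnicity_probs)
    df["income"] = rng.choice(INCOME_LEVELS, size=n, p=config.income_probs)
    df["education"] = rng.choice(EDUCATION_LEVELS, size=n, p=config.education_probs)
    df["employment"] = np.where(rng.random(n) < config.employment_p,
                                EMPLOYMENT_LEVELS[0], EMPLOYMENT_LEVELS[1])
    df["interpreter"] = (rng.random(n) < config.interpreter_p).astype(int)
    df["mode"] = np.where(rng.random(n) < config.mode_tablet_p,
                          MODE_LEVELS[1], MODE_LEVELS[0])

    # diagnoses: independent components plus a residual so the "any disorder"
    # union matches its configured prevalence
    component_labels = [k for k in config.prevalence if k != "any_disorder"]
    any_flag = np.zeros(n, dtype=bool)
    for label in component_labels:
        flag = rng.random(n) < config.prevalence[label]
        df[f"dx_{label}"] = flag.astype(int)
        any_flag |= flag
    if "any_disorder" in config.prevalence:
        other = rng.random(n) < _residual_any_prob(config)
        any_flag |= other
        df["dx_any"] = any_flag.astype(int)

    # screen: sensitivity/specificity against the reference diagnosis, then the
    # positive pattern split across (both, q1 only, q2 only)
    ref = df[f"dx_{config.reference_label}"].to_numpy().astype(bool)
    p_positive = np.where(ref, config.screen_sens, 1.0 - config.screen_spec)
    positive = rng.random(n) < p_positive
    u = rng.random(n)
    both = positive & (u < config.p_both_given_pos)
    q1_only = positive & ~both & (u < config.p_both_given_pos + config.p_q1_only_given_pos)
    q2_only = positive & ~both & ~q1_only
    df["screen_q1"] = (both | q1_only).astype(int)
    df["screen_q2"] = (both | q2_only).astype(int)
    df["stratum"] = np.where(positive, "positive", "negative")

    # help question: defined only for screen-positives, occasionally missing
    p_help = np.where(ref, config.p_help_case, config.p_help_noncase)
    help_q = np.where(rng.random(n) < p_help, 1.0, 0.0)
    help_q[~positive] = np.nan
    help_q[positive & (rng.random(n) < m.help_missing_p)] = np.nan
    df["help_q"] = help_q

    # latent score: controls N(0,1); cases N(mu1 + shift(Z), sigma1)
    shift = case_latent_shift(config, df)
    mean = np.where(ref, config.mu1 + shift, 0.0)
    sd = np.where(ref, config.sigma1, 1.0)
    latent = rng.normal(mean, sd)
    df["latent_score"] = latent
    total = discretise_latent(latent)
    total = np.minimum(total, 3 * config.item_count)

    # spread the total across items (each 0-3): base level plus a random
    # allocation of the remainder, so item patterns vary across women
    items = np.tile((total // config.item_count)[:, None], (1, config.item_count))
    remainder = total % config.item_count
    bump_order = np.argsort(rng.random((n, config.item_count)), axis=1)
    bump = bump_order < remainder[:, None]
    items = (items + bump).astype(float)

    item_missing = rng.random((n, config.item_count)) < m.item_missing_p
    items[item_missing] = np.nan
    for j in range(config.item_count):
        df[f"item_{j + 1}"] = items[:, j]
    df["total_score"] = np.where(item_missing.any(axis=1), np.nan, total.astype(float))

    df["consented"] = (rng.random(n) < config.consent_rate).astype(int)

    # MAR gold-standard module missingness: logistic in the complete-data
    # questionnaire total, ethnicity and employment; one draw per module
    lin = (m.module_intercept
           + m.module_total_coef * total
           + df["ethnicity"].map(lambda v: m.module_ethnicity.get(v, 0.0)).to_numpy()
           + m.module_employment_coef
           * (df["employment"] == EMPLOYMENT_LEVELS[0]).to_numpy())
    p_observed = 1.0 / (1.0 + np.exp(-lin))
    df["module_observed_depression"] = (rng.random(n) < p_observed).astype(int)
    df["module_observed_any"] = (rng.random(n) < p_observed).astype(int)

    return df


# ---------------------------------------------------------------------------
# closed-form truth for recovery tests


def empirical_roc_truth(
    config: CohortConfig,
    t_grid: np.ndarray | None = None,
    covariate_shift: float = 0.0,
) -> dict:
    """Exact binormal ROC of the generating model on the latent scale.

    At covariate shift z the case latent is N(mu1 + z, sigma1), controls
    N(0, 1), so ROC(t) = Phi(a + b*Phi^-1(t)) with a = (mu1 + z)/sigma1,
    b = 1/sigma1, and AUC = Phi((mu1 + z)/sqrt(1 + sigma1^2)).  No simulation;
    the discretised 0-30 score has slightly lower AUC because of ties.
    """
    validate_config(config)
    if t_grid is None:
        t_grid = np.arange(0.01, 1.0, 0.01)
    t_grid = np.asarray(t_grid, dtype=float)
    mu = config.mu1 + covariate_shift
    a = mu / config.sigma1
    b = 1.0 / config.sigma1
    roc = stats.norm.cdf(a + b * stats.norm.ppf(t_grid))
    auc = float(stats.norm.cdf(mu / np.sqrt(1.0 + config.sigma1 ** 2)))
    return {"auc": auc, "t": t_grid, "roc": roc, "alpha0": a, "alpha1": b}


def with_overrides(config: CohortConfig, **kwargs) -> CohortConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **kwargs)
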