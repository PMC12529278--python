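"""Synthetic reproductive-history survey generator.

Emulates the statistical structure of a retrospective pregnancy-history survey
in which self-reported event counts are subject to underreporting:

* respondent level — a true event count drawn from a zero-inflated Poisson
  with covariate-dependent rate ``lambda = exp(beta.X)`` per year of exposure
  and inflation probability ``phi = logistic(delta.Z)``, binomially thinned by
  a covariate-dependent reporting probability ``pi = logistic(gamma.W)``;
* pregnancy level — per-woman pregnancy sequences whose outcomes (live birth /
  miscarriage / abortion) follow a random-intercept multinomial logit with
  live birth as reference, with running bookkeeping of prior miscarriages and
  parity.

A ``frailty_sd > 0`` switches on a shared woman-level normal term that enters
both the number of pregnancies and the miscarriage linear predictor, creating
the unobserved-heterogeneity coupling that makes a naive (no-random-effect)
risk model attribute miscarriage risk to prior miscarriage history.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from ._design import INTERCEPT, linear_predictor

OUTCOMES = ("miscarriage", "abortion", "live_birth")
NONREF_OUTCOMES = ("miscarriage", "abortion")

RESPONDENT_BASE_COLUMNS = ["woman_id", "y_reported", "y_true", "t_exposure", "weight"]
PREGNANCY_BASE_COLUMNS = ["woman_id", "pregnancy_index", "outcome"]

# Ages (years) used to construct exposure time: interview age minus the
# earlier of menarche and first intercourse.  Discrete stand-in distributions
# of realistic location and spread; the survey concept fixes the definition,
# not these marginals.
_MENARCHE_AGES = np.arange(11, 17)
_MENARCHE_P = np.array([0.05, 0.15, 0.30, 0.30, 0.15, 0.05])
_FIRSTSEX_AGES = np.arange(15, 26)
_FIRSTSEX_P = np.array([0.04, 0.08, 0.14, 0.18, 0.16, 0.12, 0.09, 0.07, 0.05, 0.04, 0.03])
_INTERVIEW_AGES = np.arange(25, 50)


def _validate_marginal(name: str, marginal: Mapping[str, float]) -> None:
    probs = np.array(list(marginal.values()), dtype=float)
    if np.any(probs < 0):
        raise ValueError(f"negative category probability in marginal {name!r}")
    if abs(probs.sum() - 1.0) > 1e-12:
        raise ValueError(
            f"category probabilities for {name!r} sum to {probs.sum()!r}, not 1"
        )


@dataclass
class SimConfig:
    """Full parameterization of the synthetic survey.

    Coefficient mappings are keyed by term name (``"intercept"`` or
    ``"covariate[category]"``); covariates referenced by any equation must
    have an entry in ``covariate_marginals``.  Category order (and hence the
    reference level) is canonical where declared in the design module, else
    sorted — it never depends on mapping insertion order.
    """

    n_women: int
    seed: int
    beta_count: dict[str, float]
    delta_zero: dict[str, float]
    gamma_report: dict[str, float]
    covariate_marginals: dict[str, dict[str, float]]
    outcome_coefs: dict[str, dict[str, float]]
    re_sd: dict[str, float] = field(default_factory=lambda: {k: 0.0 for k in NONREF_OUTCOMES})
    frailty_sd: float = 0.0
    mean_pregnancies: float = 2.2
    preg_zero_inflation: float = 0.12
    fixed_exposure: float | None = None

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        if self.frailty_sd < 0:
            raise ValueError("frailty_sd must be >= 0")
        for k, sd in self.re_sd.items():
            if sd < 0:
                raise ValueError(f"re_sd[{k!r}] must be >= 0")
        for k in self.outcome_coefs:
            if k not in NONREF_OUTCOMES:
                raise ValueError(f"outcome_coefs key {k!r} not a non-reference outcome")
        for name, marginal in self.covariate_marginals.items():
            _validate_marginal(name, marginal)
        if self.fixed_exposure is not None and self.fixed_exposure <= 0:
            raise ValueError("fixed_exposure must be positive")

    # category order is canonical where declared, else sorted — never the
    # mapping's insertion order, which serialization may not preserve
    @property
    def orders(self) -> dict[str, list[str]]:
        from ._design import category_order

        return {c: category_order(c, m.keys())
                for c, m in self.covariate_marginals.items()}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _draw_covariates(
    rng: np.random.Generator,
    n: int,
    marginals: Mapping[str, Mapping[str, float]],
    names: list[str],
) -> pd.DataFrame:
    """Independent draws from the declared category marginals."""
    cols = {}
    for name in names:
        marginal = marginals[name]
        cats = list(marginal)
        p = np.array(list(marginal.values()), dtype=float)
        cols[name] = rng.choice(cats, size=n, p=p / p.sum())
    return pd.DataFrame(cols, index=range(n))


def _equation_covariates(*coef_dicts: Mapping[str, float]) -> list[str]:
    covs: set[str] = set()
    for coefs in coef_dicts:
        covs |= {t.split("[", 1)[0] for t in coefs if t != INTERCEPT}
    return sorted(covs)


def _exposure_years(rng: np.random.Generator, n: int) -> np.ndarray:
    menarche = rng.choice(_MENARCHE_AGES, size=n, p=_MENARCHE_P)
    first_sex = rng.choice(_FIRSTSEX_AGES, size=n, p=_FIRSTSEX_P / _FIRSTSEX_P.sum())
    interview = rng.choice(_INTERVIEW_AGES, size=n)
    t = interview - np.minimum(menarche, first_sex)
    return np.maximum(t, 0.5).astype(float)


def simulate_respondents(config: SimConfig) -> pd.DataFrame:
    """One row per woman: reported count, simulation-truth count, exposure.

    Generative steps per woman i: covariates from marginals; lambda_i =
    exp(beta.X_i); phi_i = logistic(delta.Z_i); pi_i = logistic(gamma.W_i);
    Y*_i = 0 with probability phi_i, else Poisson(lambda_i t_i);
    Y_i ~ Binomial(Y*_i, pi_i).  Columns lambda_true/phi_true/pi_true carry
    the generator truth for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n = config.n_women
    covs = _equation_covariates(config.beta_count, config.delta_zero, config.gamma_report)
    df = _draw_covariates(rng, n, config.covariate_marginals, covs)
    orders = config.orders

    lam = np.exp(linear_predictor(df, config.beta_count, orders, "count linear predictor"))
    phi = expit(linear_predictor(df, config.delta_zero, orders, "zero-inflation linear predictor"))
    pi = expit(linear_predictor(df, config.gamma_report, orders, "reporting linear predictor"))

    if config.fixed_exposure is not None:
        t = np.full(n, float(config.fixed_exposure))
    else:
        t = _exposure_years(rng, n)

    not_inflated = rng.random(n) >= phi
    y_true = np.where(not_inflated, rng.poisson(lam * t), 0)
    y_rep = rng.binomial(y_true, pi)
    weight = rng.gamma(shape=4.0, scale=0.25, size=n)

    out = pd.DataFrame(
        {
            "woman_id": np.arange(1, n + 1),
            "y_reported": y_rep.astype(int),
            "y_true": y_true.astype(int),
            "t_exposure": t,
            "weight": weight,
        }
    )
    out = pd.concat([out, df], axis=1)
    out["lambda_true"] = lam
    out["phi_true"] = phi
    out["pi_true"] = pi
    return out


def _softmax3(eta1: float, eta2: float) -> np.ndarray:
    m = max(eta1, eta2, 0.0)
    w = np.array([np.exp(eta1 - m), np.exp(eta2 - m), np.exp(-m)])
    return w / w.sum()


_PRIOR_CATS = np.array(["0", "1", "2_plus"])


def _capped_cat(count: int) -> str:
    return _PRIOR_CATS[min(count, 2)]


def simulate_pregnancies(config: SimConfig) -> pd.DataFrame:
    """Per-woman pregnancy sequences with multinomial-logit outcomes.

    The number of pregnancies is zero-inflated Poisson around
    ``mean_pregnancies``; with ``frailty_sd > 0`` a shared normal frailty
    scales the pregnancy rate and shifts the miscarriage linear predictor,
    while the per-outcome random intercepts u_ik ~ N(0, re_sd_k^2) act on the
    outcome equations only.  prior_miscarriages and parity_at_start are
    recomputed from the simulated history before each pregnancy.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n = config.n_women
    orders = config.orders

    referenced = set(_equation_covariates(*config.outcome_coefs.values()))
    history_covs = {"prior_miscarriages", "parity_at_start", "age_group_at_start"}
    available = set(config.covariate_marginals)
    # always carry the standard pregnancy-record covariates when marginals exist
    woman_covs = sorted(
        ((referenced | (_PREG_WOMAN_LEVEL & available)) - history_covs - _PREGNANCY_LEVEL)
    )
    missing = [c for c in woman_covs if c not in available]
    if missing:
        raise ValueError(f"outcome covariates without marginals: {missing}")
    drawn_per_woman = woman_covs
    preg_level = sorted((referenced | available) & _PREGNANCY_LEVEL)
    use_age = "age_group_at_start" in (referenced | available)

    base = _draw_covariates(rng, n, config.covariate_marginals, drawn_per_woman)

    frailty = rng.normal(0.0, config.frailty_sd, size=n) if config.frailty_sd > 0 else np.zeros(n)
    u = {k: rng.normal(0.0, config.re_sd.get(k, 0.0), size=n) for k in NONREF_OUTCOMES}

    # history length: ZIP sharing the frailty (log-rate shift), mean-preserving
    lam_preg = config.mean_pregnancies * np.exp(frailty - config.frailty_sd**2 / 2)
    n_preg = np.where(rng.random(n) < config.preg_zero_inflation, 0, rng.poisson(lam_preg))

    age_order = (list(config.covariate_marginals.get("age_group_at_start", {}))
                 or CANONICAL_AGE_SEQUENCE)
    age_seq = [c for c in CANONICAL_AGE_SEQUENCE if c in age_order] or list(age_order)

    # precompute coefficient lookups once; evaluate per pregnancy on a dict row
    coef_terms = {k: dict(config.outcome_coefs.get(k, {})) for k in NONREF_OUTCOMES}

    rows: list[dict] = []
    for i in range(n):
        if n_preg[i] == 0:
            continue
        woman = {c: base.at[i, c] for c in drawn_per_woman}
        # age at first pregnancy from its marginal (or default early adult)
        if "age_group_at_start" in config.covariate_marginals:
            m = config.covariate_marginals["age_group_at_start"]
            start = rng.choice(list(m), p=np.array(list(m.values())))
            age_idx = age_seq.index(start) if start in age_seq else 0
        else:
            age_idx = 0
        n_misc = 0
        n_birth = 0
        for j in range(1, int(n_preg[i]) + 1):
            row = dict(woman)
            row["prior_miscarriages"] = _capped_cat(n_misc)
            row["parity_at_start"] = _capped_cat(n_birth)
            if use_age:
                row["age_group_at_start"] = age_seq[min(age_idx, len(age_seq) - 1)]
            for c in preg_level:
                m = config.covariate_marginals[c]
                row[c] = rng.choice(list(m), p=np.array(list(m.values())))
            eta = {}
            for k in NONREF_OUTCOMES:
                eta[k] = _eta_from_row(row, coef_terms[k]) + u[k][i]
            eta["miscarriage"] += frailty[i]
            p = _softmax3(eta["miscarriage"], eta["abortion"])
            outcome = OUTCOMES[rng.choice(3, p=p)]
            if outcome == "miscarriage":
                n_misc += 1
            elif outcome == "live_birth":
                n_birth += 1
            rows.append(
                {"woman_id": i + 1, "pregnancy_index": j, "outcome": outcome, **row}
            )
            age_idx += int(rng.random() < 0.45)
    return pd.DataFrame(rows)


CANONICAL_AGE_SEQUENCE = ["below_20", "20_24", "25_29", "30_34", "35_39", "40_plus"]

_PREGNANCY_LEVEL = {"financial_situation", "relationship", "work_issues"}
_PREG_WOMAN_LEVEL = {"cohort", "education", "bmi_category", "religion_importance",
                     "born_mainland"}


def _eta_from_row(row: Mapping[str, str], coefs: Mapping[str, float]) -> float:
    eta = float(coefs.get(INTERCEPT, 0.0))
    for term, b in coefs.items():
        if term == INTERCEPT:
            continue
        cov, cat = term[:-1].split("[", 1)
        if str(row[cov]) == cat:
            eta += float(b)
    if not np.isfinite(eta):
        bad = [t for t, b in coefs.items() if not np.isfinite(b)]
        raise ValueError(f"non-finite outcome linear predictor; offending coefficients: {bad}")
    return eta


def fecond_like_preset(n_women: int = 4000, seed: int = 0) -> SimConfig:
    """Default configuration loosely calibrated to the French survey setting.

    Targets: average miscarriage reporting probability ~0.92 with a higher
    rate among tertiary-educated women; miscarriage share of pregnancy
    outcomes ~14%, abortion ~10%; covariate marginals loosely matching the
    survey's descriptive distributions.  Reporting covariates (marital status,
    health, income) are excluded from the count equation, and count covariates
    (parity, smoking, BMI, infertility treatment) from the reporting equation
    — the exclusion restrictions the fitted model relies on.
    """
    marginals = {
        "education": {"below_tertiary": 0.729, "tertiary": 0.271},
        "age_group_survey": {"26_49": 0.80, "15_25": 0.20},
        "parity_survey": {"0": 0.30, "1": 0.25, "2_plus": 0.45},
        "infertility_treatment": {"no": 0.90, "yes": 0.10},
        "ever_smoked": {"no": 0.55, "yes": 0.45},
        "bmi_category": {"18.5_24.9": 0.626, "below_18.5": 0.062,
                         "25_29.9": 0.225, "30_plus": 0.087},
        "marital_status": {"married": 0.55, "not_married": 0.45},
        "health": {"good": 0.85, "not_good": 0.15},
        "income": {"below_1500": 0.25, "1500_2499": 0.30,
                   "2500_3499": 0.25, "3500_plus": 0.20},
        # pregnancy-table covariates
        "age_group_at_start": {"25_29": 0.363, "below_20": 0.085, "20_24": 0.279,
                               "30_34": 0.194, "35_39": 0.067, "40_plus": 0.012},
        "financial_situation": {"no_issues": 0.505, "tight": 0.347, "difficult": 0.148},
        "relationship": {"stable": 0.858, "unstable": 0.142},
        "work_issues": {"no": 0.869, "yes": 0.131},
        "cohort": {"1961_69": 0.468, "1970_79": 0.424, "1980_85": 0.108},
        "born_mainland": {"yes": 0.821, "no": 0.179},
        "religion_importance": {"not_important": 0.395, "not_really": 0.314,
                                "important": 0.291},
    }
    beta_count = {
        "intercept": -4.0,
        "education[tertiary]": 0.05,
        "age_group_survey[15_25]": -0.55,
        "parity_survey[1]": 0.35,
        "parity_survey[2_plus]": 0.55,
        "infertility_treatment[yes]": 0.60,
        "ever_smoked[yes]": 0.15,
        "bmi_category[30_plus]": 0.20,
    }
    delta_zero = {
        "intercept": -1.9,
        "education[tertiary]": 0.2,
    }
    gamma_report = {
        "intercept": 5.4,
        "education[tertiary]": 3.0,
        "marital_status[not_married]": 0.5,
        "health[not_good]": 1.0,
        "income[1500_2499]": -1.4,
        "income[2500_3499]": -5.5,
        "income[3500_plus]": -0.3,
    }
    outcome_coefs = {
        "miscarriage": {
            "intercept": -2.04,
            "age_group_at_start[below_20]": 0.10,
            "age_group_at_start[20_24]": 0.00,
            "age_group_at_start[30_34]": 0.15,
            "age_group_at_start[35_39]": 0.70,
            "age_group_at_start[40_plus]": 1.45,
            "cohort[1980_85]": 0.35,
            "work_issues[yes]": -0.45,
        },
        "abortion": {
            "intercept": -2.45,
            "age_group_at_start[below_20]": 0.90,
            "age_group_at_start[20_24]": 0.35,
            "relationship[unstable]": 0.80,
            "financial_situation[difficult]": 0.40,
        },
    }
    return SimConfig(
        n_women=n_women,
        seed=seed,
        beta_count=beta_count,
        delta_zero=delta_zero,
        gamma_report=gamma_report,
        covariate_marginals=marginals,
        outcome_coefs=outcome_coefs,
        re_sd={"miscarriage": 0.6, "abortion": 0.4},
        frailty_sd=0.0,
    )


def frailty_scenario(n_women: int = 1200, seed: int = 17) -> SimConfig:
    """Preset with a shared woman-level frailty coupling history and risk.

    The frailty (SD 1.0) raises both the number of pregnancies and the
    miscarriage linear predictor, while the true prior-miscarriage coefficient
    is zero.  A naive no-random-effect risk model then attributes miscarriage
    risk to prior miscarriage history; a random-intercept model attenuates
    that association.  The baseline miscarriage intercept is lowered so the
    marginal outcome shares stay plausible despite the heterogeneity, and the
    mean history length is raised to give within-woman replication.
    """
    cfg = fecond_like_preset(n_women=n_women, seed=seed)
    cfg.frailty_sd = 1.0
    cfg.mean_pregnancies = 3.0
    cfg.re_sd = {"miscarriage": 0.0, "abortion": 0.0}
    cfg.outcome_coefs = {
        k: dict(v) for k, v in cfg.outcome_coefs.items()
    }
    cfg.outcome_coefs["miscarriage"]["intercept"] = -2.7
    return cfg


def write_respondents(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with documented header: base columns first, covariates after."""
    covs = [c for c in df.columns if c not in RESPONDENT_BASE_COLUMNS
            and c not in ("lambda_true", "phi_true", "pi_true")]
    truth = [c for c in ("lambda_true", "phi_true", "pi_true") if c in df.columns]
    df[RESPONDENT_BASE_COLUMNS + covs + truth].to_csv(path, index=False)


def write_pregnancies(df: pd.DataFrame, path: str | Path) -> None:
    covs = [c for c in df.columns if c not in PREGNANCY_BASE_COLUMNS]
    df[PREGNANCY_BASE_COLUMNS + covs].to_csv(path, index=False)
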