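"""Categorical design-matrix construction shared by the simulator and the models.

All model equations operate on dummy-coded categorical covariates plus an
intercept.  Coefficients are addressed by *term name*: ``"intercept"`` or
``"<covariate>[<category>]"`` for every non-reference category.  The reference
category is the first level in the covariate's declared order; a term that is
absent from a coefficient mapping has coefficient zero.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

INTERCEPT = "intercept"

# Category orders used throughout: first level is the reference.  These mirror
# the display order of the survey's descriptive table; covariates not listed
# here fall back to sorted order.
CANONICAL_ORDERS: dict[str, list[str]] = {
    "age_group_at_start": ["25_29", "below_20", "20_24", "30_34", "35_39", "40_plus"],
    "prior_miscarriages": ["0", "1", "2_plus"],
    "parity_at_start": ["0", "1", "2_plus"],
    "financial_situation": ["no_issues", "tight", "difficult"],
    "relationship": ["stable", "unstable"],
    "work_issues": ["no", "yes"],
    "bmi_category": ["18.5_24.9", "below_18.5", "25_29.9", "30_plus"],
    "cohort": ["1961_69", "1970_79", "1980_85"],
    "education": ["below_tertiary", "tertiary"],
    "born_mainland": ["yes", "no"],
    "religion_importance": ["not_important", "not_really", "important"],
    "age_group_survey": ["26_49", "15_25"],
    "parity_survey": ["0", "1", "2_plus"],
    "infertility_treatment": ["no", "yes"],
    "ever_smoked": ["no", "yes"],
    "marital_status": ["married", "not_married"],
    "health": ["good", "not_good"],
    "income": ["below_1500", "1500_2499", "2500_3499", "3500_plus"],
}


def term_name(covariate: str, category: str) -> str:
    return f"{covariate}[{category}]"


def category_order(covariate: str, values: Iterable[str]) -> list[str]:
    """Deterministic category order for a covariate.

    Canonical orders are used where declared; otherwise categories sort
    lexicographically so the design is invariant to row order.
    """
    observed = set(map(str, values))
    if covariate in CANONICAL_ORDERS:
        order = [c for c in CANONICAL_ORDERS[covariate] if c in observed]
        extra = sorted(observed - set(order))
        return order + extra
    return sorted(observed)


def infer_orders(df: pd.DataFrame, covariates: Sequence[str]) -> dict[str, list[str]]:
    return {c: category_order(c, df[c].astype(str)) for c in covariates}


def design_terms(covariates: Sequence[str], orders: Mapping[str, Sequence[str]]) -> list[str]:
    """Ordered term names: intercept, then non-reference dummies per covariate."""
    terms = [INTERCEPT]
    for cov in covariates:
        for cat in list(orders[cov])[1:]:
            terms.append(term_name(cov, cat))
    return terms


def build_design(
    df: pd.DataFrame,
    covariates: Sequence[str],
    orders: Mapping[str, Sequence[str]],
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix (intercept first) with fixed category orders.

    Raises ``ValueError`` naming any category in ``df`` that is absent from the
    declared order (an "unseen category" at prediction time).
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    terms = [INTERCEPT]
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"covariate column {cov!r} not in data")
        order = [str(c) for c in orders[cov]]
        values = df[cov].astype(str).to_numpy()
        unseen = set(values) - set(order)
        if unseen:
            raise ValueError(
                f"unseen categor{'ies' if len(unseen) > 1 else 'y'} "
                f"{sorted(unseen)} in covariate {cov!r}"
            )
        for cat in order[1:]:
            cols.append((values == cat).astype(float))
            terms.append(term_name(cov, cat))
    return np.column_stack(cols), terms


def coef_vector(coefs: Mapping[str, float], terms: Sequence[str]) -> np.ndarray:
    """Map a {term: coefficient} dict onto the ordered term list.

    Missing terms default to zero; a term in ``coefs`` that the design does not
    produce is an error (it would be silently ignored otherwise).
    """
    unknown = set(coefs) - set(terms)
    if unknown:
        raise ValueError(f"coefficient terms not in design: {sorted(unknown)}; "
                         f"design terms are {list(terms)}")
    return np.array([float(coefs.get(t, 0.0)) for t in terms])


def linear_predictor(
    df: pd.DataFrame,
    coefs: Mapping[str, float],
    orders: Mapping[str, Sequence[str]],
    name: str = "linear predictor",
) -> np.ndarray:
    """Evaluate intercept + dummy terms for the covariates referenced in ``coefs``."""
    covs = sorted({t.split("[", 1)[0] for t in coefs if t != INTERCEPT})
    X, terms = build_design(df, covs, orders)
    eta = X @ coef_vector(coefs, terms)
    if not np.all(np.isfinite(eta)):
        bad = [t for t in coefs if not np.isfinite(coefs[t])]
        raise ValueError(f"non-finite {name}; offending coefficients: {bad or 'data-driven'}")
    return eta
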