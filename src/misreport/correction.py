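"""Prevalence correction of a reported outcome distribution.

If outcome k is reported with probability r_k, the reported share s_k
understates outcomes with low reporting.  Dividing each share by its
reporting rate and renormalizing,

    corrected_k = (s_k / r_k) / sum_j (s_j / r_j) * 100,

recovers the distribution of experienced outcomes under the assumption that
underreporting removes events but never reclassifies them.  Outcomes absent
from the rate vector are assumed fully reported (rate 100%).  Rates are
accepted in percent; rounding to one decimal happens only at display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeDistribution",
    "RateVector",
    "correct_distribution",
    "tabulate_outcomes",
    "uncorrect_distribution",
]


@dataclass
class OutcomeDistribution:
    """Outcome shares in percent, in a fixed label order."""

    labels: list[str]
    shares: np.ndarray  # percent
    total_pregnancies: int | None = None

    def __post_init__(self) -> None:
        self.shares = np.asarray(self.shares, dtype=float)
        if len(self.labels) != self.shares.size:
            raise ValueError("labels and shares differ in length")
        if np.any(self.shares < 0):
            raise ValueError("shares must be nonnegative")
        total = float(self.shares.sum())
        # tolerate one-decimal rounding of published tables
        if abs(total - 100.0) > 0.15:
            raise ValueError(f"shares sum to {total}, not 100")

    def rounded(self) -> dict[str, float]:
        """Display form: one decimal, as published tables print shares."""
        return {lab: round(float(s), 1) for lab, s in zip(self.labels, self.shares)}

    def as_series(self) -> pd.Series:
        return pd.Series(self.shares, index=self.labels, name="share_pct")


@dataclass
class RateVector:
    """Per-outcome reporting rates in percent, each in (0, 100]."""

    rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lab, r in self.rates.items():
            if not (0 < r <= 100):
                raise ValueError(f"reporting rate for {lab!r} must be in (0, 100], got {r}")

    def rate_for(self, label: str) -> float:
        return float(self.rates.get(label, 100.0))


def correct_distribution(reported: OutcomeDistribution, rates: RateVector) -> OutcomeDistribution:
    """Adjust reported shares by outcome-specific reporting rates.

    Full precision is kept internally; use :meth:`OutcomeDistribution.rounded`
    for the one-decimal display form.  Unknown labels in the rate vector are
    an error (a silently ignored rate is almost certainly a typo).
    """
    extra = set(rates.rates) - set(reported.labels)
    if extra:
        raise ValueError(f"rate labels not in distribution: {sorted(extra)}")
    r = np.array([rates.rate_for(lab) for lab in reported.labels])
    if np.any(r <= 0):
        raise ValueError("reporting rates must be positive")
    scaled = reported.shares / (r / 100.0)
    corrected = scaled / scaled.sum() * 100.0
    return OutcomeDistribution(
        labels=list(reported.labels),
        shares=corrected,
        total_pregnancies=reported.total_pregnancies,
    )


def uncorrect_distribution(corrected: OutcomeDistribution, rates: RateVector) -> OutcomeDistribution:
    """Inverse of :func:`correct_distribution` (multiply by rates, renormalize)."""
    r = np.array([rates.rate_for(lab) for lab in corrected.labels])
    scaled = corrected.shares * (r / 100.0)
    return OutcomeDistribution(
        labels=list(corrected.labels),
        shares=scaled / scaled.sum() * 100.0,
        total_pregnancies=corrected.total_pregnancies,
    )


def tabulate_outcomes(
    pregnancies: pd.DataFrame,
    by: str | None = None,
    order: list[str] | None = None,
) -> OutcomeDistribution | dict[str, OutcomeDistribution]:
    """Outcome shares (percent) from a pregnancy table, optionally by subgroup."""
    if len(pregnancies) == 0:
        raise ValueError("empty pregnancy table")

    def _one(df: pd.DataFrame) -> OutcomeDistribution:
        counts = df["outcome"].value_counts()
        labels = order or sorted(counts.index)
        n = counts.reindex(labels).fillna(0).to_numpy(dtype=float)
        return OutcomeDistribution(
            labels=list(labels),
            shares=n / n.sum() * 100.0,
            total_pregnancies=int(n.sum()),
        )

    if by is None:
        return _one(pregnancies)
    out: dict[str, OutcomeDistribution] = {}
    for level, sub in pregnancies.groupby(pregnancies[by].astype(str), sort=True):
        if len(sub) == 0:  # pragma: no cover
            warnings.warn(f"empty subgroup {level!r} omitted", stacklevel=2)
            continue
        out[str(level)] = _one(sub)
    return out


def correction_table(
    reported: OutcomeDistribution, rates: RateVector
) -> pd.DataFrame:
    """Three-column table: reported share, reporting rate, corrected share."""
    corrected = correct_distribution(reported, rates)
    return pd.DataFrame(
        {
            "outcome": reported.labels,
            "reported_pct": np.round(reported.shares, 1),
            "reporting_rate_pct": [rates.rate_for(lab) for lab in reported.labels],
            "corrected_pct": np.round(corrected.shares, 1),
        }
    )


def write_correction_table(reported: OutcomeDistribution, rates: RateVector,
                           path: str | Path) -> None:
    correction_table(reported, rates).to_csv(path, index=False)
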