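"""Binomially-thinned zero-inflated Poisson (BT-ZIP) reporting model.

Self-reported lifetime event counts in retrospective surveys suffer two kinds
of underreporting: some respondents report zero events despite having
experienced them (excess zeros), and others report a positive but too-small
count.  The BT-ZIP model captures both.  The true count Y* follows a
zero-inflated Poisson,

    P(Y* = 0)     = phi + (1 - phi) exp(-lambda t)
    P(Y* = y), y>0 = (1 - phi) (lambda t)^y exp(-lambda t) / y!

with rate lambda = exp(beta.X) per year of exposure t and inflation
probability phi = logistic(delta.Z).  Each true event is independently
reported with probability pi = logistic(gamma.W) (binomial thinning,
Y = pi o Y*), so the observed count follows ZIP(pi lambda t, phi) exactly —
the closed form this module maximizes.  All three coefficient vectors are
estimated jointly by maximum likelihood; identification of pi separately from
lambda rests on exclusion restrictions between X and W, which
:meth:`BTZIPSpec.validate` checks.

Average reporting rates (mean of predicted pi over respondents, in percent)
and their delta-method standard errors are the model's headline summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln
from statsmodels.tools.numdiff import approx_hess

from ._design import build_design, coef_vector, infer_orders

logger = logging.getLogger(__name__)


class IdentificationWarning(UserWarning):
    """Raised when the spec offers no exclusion restriction between the
    count and reporting equations, so pi and lambda are separated only by
    functional form."""


class SampleSizeWarning(UserWarning):
    """Fewer than ~10 observations per free coefficient."""


# ---------------------------------------------------------------------------
# probability kernels


def _check_y_phi(y, phi):
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a nonnegative integer")
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("phi must lie in [0, 1]")


def zip_logpmf(y, lambda_t, phi):
    """Log pmf of the zero-inflated Poisson.

    ``-inf`` is a valid return (e.g. phi = 1 with y > 0).  Vectorized;
    broadcasting follows numpy rules.
    """
    y = np.asarray(y)
    lambda_t = np.asarray(lambda_t, dtype=float)
    phi = np.asarray(phi, dtype=float)
    _check_y_phi(y, phi)
    if np.any(lambda_t <= 0):
        raise ValueError("lambda*t must be positive")
    return _zip_logpmf_core(y, lambda_t, phi)


def _zip_logpmf_core(y, lambda_t, phi):
    with np.errstate(divide="ignore"):
        log_phi = np.log(phi)
        log1m_phi = np.log1p(-phi)
    # y = 0: log(phi + (1-phi) e^{-lt}) via logaddexp for stability
    zero_branch = np.logaddexp(log_phi, log1m_phi - lambda_t)
    # y > 0: log(1-phi) + y log(lt) - lt - log y!
    with np.errstate(divide="ignore", invalid="ignore"):
        pos_branch = log1m_phi + y * np.log(lambda_t) - lambda_t - gammaln(y + 1)
    pos_branch = np.where((lambda_t == 0) & (y > 0), -np.inf, pos_branch)
    return np.where(y == 0, zero_branch, pos_branch)


def observed_logpmf(y, lambda_t, phi, pi):
    """Log pmf of the reported count Y = pi o Y*, Y* ~ ZIP(lambda t, phi).

    Binomial thinning of a (zero-inflated) Poisson is again (zero-inflated)
    Poisson with thinned mean, so this is exactly ``zip_logpmf(y, pi *
    lambda_t, phi)``; the identity is enforced against the explicit
    ZIP x Binomial convolution in the test suite.
    """
    y = np.asarray(y)
    pi = np.asarray(pi, dtype=float)
    phi = np.asarray(phi, dtype=float)
    lambda_t = np.asarray(lambda_t, dtype=float)
    _check_y_phi(y, phi)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must lie in [0, 1]")
    if np.any(lambda_t <= 0):
        raise ValueError("lambda*t must be positive")
    return _zip_logpmf_core(y, pi * lambda_t, phi)


# ---------------------------------------------------------------------------
# model specification and fit containers


@dataclass
class BTZIPSpec:
    """Covariate lists for the three equations; each includes an intercept."""

    count_covariates: list[str] = field(default_factory=list)
    zero_covariates: list[str] = field(default_factory=list)
    report_covariates: list[str] = field(default_factory=list)

    def all_covariates(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in (*self.count_covariates, *self.zero_covariates, *self.report_covariates):
            seen.setdefault(c, None)
        return list(seen)

    def validate(self, data: pd.DataFrame) -> None:
        missing = [c for c in self.all_covariates() if c not in data.columns]
        if missing:
            raise KeyError(f"spec covariates not in data: {missing}")
        count, report = set(self.count_covariates), set(self.report_covariates)
        if not (count - report) and not (report - count):
            warnings.warn(
                "count and reporting equations share the same covariate set; "
                "the reporting probability is separated from the count rate "
                "only by functional form (no exclusion restriction)",
                IdentificationWarning,
                stacklevel=2,
            )


@dataclass
class BTZIPFit:
    """Maximum-likelihood fit of the BT-ZIP model."""

    beta: dict[str, float]
    delta: dict[str, float]
    gamma: dict[str, float]
    vcov: np.ndarray
    loglik: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    n_starts_used: int
    spec: BTZIPSpec
    orders: dict[str, list[str]]
    term_names: dict[str, list[str]]  # keys: count, zero, report
    n_dropped: int = 0

    @property
    def n_params(self) -> int:
        return len(self.beta) + len(self.delta) + len(self.gamma)

    def params(self) -> np.ndarray:
        return np.concatenate(
            [
                [self.beta[t] for t in self.term_names["count"]],
                [self.delta[t] for t in self.term_names["zero"]],
                [self.gamma[t] for t in self.term_names["report"]],
            ]
        )

    def to_json(self, path: str | Path) -> None:
        d = {
            "beta": self.beta,
            "delta": self.delta,
            "gamma": self.gamma,
            "vcov": np.asarray(self.vcov).tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "spec": dataclasses.asdict(self.spec),
            "orders": self.orders,
            "term_names": self.term_names,
            "n_dropped": self.n_dropped,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BTZIPFit":
        d = json.loads(Path(path).read_text())
        d["spec"] = BTZIPSpec(**d["spec"])
        d["vcov"] = np.asarray(d["vcov"])
        return cls(**d)


# ---------------------------------------------------------------------------
# likelihood


def _designs(data: pd.DataFrame, spec: BTZIPSpec, orders: Mapping[str, Sequence[str]]):
    Xc, tc = build_design(data, spec.count_covariates, orders)
    Xz, tz = build_design(data, spec.zero_covariates, orders)
    Xr, tr = build_design(data, spec.report_covariates, orders)
    return (Xc, Xz, Xr), {"count": tc, "zero": tz, "report": tr}


def _split(params: np.ndarray, terms: Mapping[str, Sequence[str]]):
    p1 = len(terms["count"])
    p2 = p1 + len(terms["zero"])
    return params[:p1], params[p1:p2], params[p2:]


def _loglik_core(params, y, t, Xc, Xz, Xr, terms):
    beta, delta, gamma = _split(params, terms)
    lam_t = np.exp(Xc @ beta) * t
    phi = expit(Xz @ delta)
    pi = expit(Xr @ gamma)
    mu = pi * lam_t
    with np.errstate(divide="ignore"):
        log_phi = np.log(phi)
        log1m_phi = np.log1p(-phi)
    zero_branch = np.logaddexp(log_phi, log1m_phi - mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos_branch = log1m_phi + y * np.log(mu) - mu - gammaln(y + 1)
    ll = np.where(y == 0, zero_branch, pos_branch)
    return float(np.sum(ll))


def total_loglik(
    data: pd.DataFrame,
    spec: BTZIPSpec,
    params: np.ndarray,
    orders: Mapping[str, Sequence[str]] | None = None,
) -> float:
    """Joint log-likelihood of reported counts under the BT-ZIP model.

    ``params`` concatenates (beta, delta, gamma) in design-term order.
    Rows with nonpositive exposure are rejected, not silently dropped.
    """
    t = data["t_exposure"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError(f"{int(np.sum(t <= 0))} rows with nonpositive exposure")
    orders = orders or infer_orders(data, spec.all_covariates())
    (Xc, Xz, Xr), terms = _designs(data, spec, orders)
    params = np.asarray(params, dtype=float)
    n_expected = sum(len(v) for v in terms.values())
    if params.size != n_expected:
        raise ValueError(f"expected {n_expected} parameters, got {params.size}")
    y = data["y_reported"].to_numpy(dtype=float)
    return _loglik_core(params, y, t, Xc, Xz, Xr, terms)


# ---------------------------------------------------------------------------
# fitting


def complete_cases(data: pd.DataFrame, covariates: Sequence[str]) -> tuple[pd.DataFrame, int]:
    """Drop rows with nonpositive exposure or missing analysis variables."""
    cols = ["y_reported", "t_exposure", *covariates]
    ok = data["t_exposure"].to_numpy(dtype=float) > 0
    ok &= data[cols].notna().all(axis=1).to_numpy()
    dropped = int((~ok).sum())
    if dropped:
        logger.info("complete-case filter: excluded %d of %d rows", dropped, len(data))
    return data.loc[ok].reset_index(drop=True), dropped


def fit(
    data: pd.DataFrame,
    spec: BTZIPSpec,
    *,
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 2000,
) -> BTZIPFit:
    """Maximum-likelihood fit by quasi-Newton from multiple starts.

    The null start sets every coefficient to zero except the count intercept,
    initialized at log(mean(y)/mean(t)); the remaining starts perturb it with
    seeded N(0, 0.5) noise.  The best optimum over starts is kept;
    non-convergence is recorded on the fit, never raised.  The covariance is
    the inverse of the numerically differentiated observed Hessian.
    """
    spec.validate(data)
    data, n_dropped = complete_cases(data, spec.all_covariates())
    orders = infer_orders(data, spec.all_covariates())
    (Xc, Xz, Xr), terms = _designs(data, spec, orders)
    y = data["y_reported"].to_numpy(dtype=float)
    t = data["t_exposure"].to_numpy(dtype=float)
    n = len(data)
    p = sum(len(v) for v in terms.values())
    if n < 10 * p:
        warnings.warn(
            f"only {n} observations for {p} coefficients (< 10 per coefficient)",
            SampleSizeWarning,
            stacklevel=2,
        )

    def nll(params: np.ndarray) -> float:
        v = _loglik_core(params, y, t, Xc, Xz, Xr, terms)
        return np.inf if not np.isfinite(v) else -v

    base = np.zeros(p)
    mean_rate = max(np.mean(y) / np.mean(t), 1e-8)
    base[0] = np.log(mean_rate)

    rng = np.random.default_rng(seed)
    starts = [base] + [base + rng.normal(0.0, 0.5, size=p) for _ in range(n_starts - 1)]

    best = None
    messages = []
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        messages.append(str(res.message))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            "all optimizer starts failed: " + "; ".join(dict.fromkeys(messages))
        )
    # polish the winning start so the optimum is insensitive to row order
    polish = optimize.minimize(
        nll, best.x, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-9},
    )
    if np.isfinite(polish.fun) and polish.fun <= best.fun:
        best = polish

    params = best.x
    loglik = -float(best.fun)
    converged = bool(best.success)

    vcov = np.full((p, p), np.nan)
    try:
        H = approx_hess(params, nll)
        H = (H + H.T) / 2
        vcov = np.linalg.pinv(H)
        vcov = (vcov + vcov.T) / 2
        # saturated reporting cells make the Hessian near-singular; clip the
        # resulting small negative eigenvalues so vcov stays PSD
        w, V = np.linalg.eigh(vcov)
        if np.any(w < 0):
            vcov = (V * np.clip(w, 0.0, None)) @ V.T
    except Exception:  # pragma: no cover - degenerate Hessian
        converged = False

    beta, delta, gamma = _split(params, terms)
    return BTZIPFit(
        beta=dict(zip(terms["count"], map(float, beta))),
        delta=dict(zip(terms["zero"], map(float, delta))),
        gamma=dict(zip(terms["report"], map(float, gamma))),
        vcov=vcov,
        loglik=loglik,
        aic=-2 * loglik + 2 * p,
        bic=-2 * loglik + p * np.log(n),
        n_obs=n,
        converged=converged,
        n_starts_used=len(starts),
        spec=spec,
        orders=orders,
        term_names=terms,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# prediction and reporting-rate summaries


def predict_rates(fit_: BTZIPFit, data: pd.DataFrame) -> pd.DataFrame:
    """Per-row (lambda_i, phi_i, pi_i) under the fitted coefficients."""
    (Xc, Xz, Xr), terms = _designs(data, fit_.spec, fit_.orders)
    lam = np.exp(Xc @ coef_vector(fit_.beta, terms["count"]))
    phi = expit(Xz @ coef_vector(fit_.delta, terms["zero"]))
    pi = expit(Xr @ coef_vector(fit_.gamma, terms["report"]))
    # probabilities live in the open interval; keep float saturation out
    one_minus = np.nextafter(1.0, 0.0)
    phi = np.clip(phi, np.nextafter(0.0, 1.0), one_minus)
    pi = np.clip(pi, np.nextafter(0.0, 1.0), one_minus)
    return pd.DataFrame({"lambda_i": lam, "phi_i": phi, "pi_i": pi}, index=data.index)


@dataclass
class ReportingRateTable:
    """Average predicted reporting rates (percent) with delta-method SEs."""

    rows: pd.DataFrame  # columns: subgroup, rate_pct, se_pct, n

    def formatted(self) -> pd.DataFrame:
        out = self.rows.copy()
        out["rate_pct"] = out["rate_pct"].round(1)
        out["se_pct"] = out["se_pct"].round(2)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.formatted().to_csv(path, index=False)


def _mean_pi_and_se(fit_: BTZIPFit, data: pd.DataFrame) -> tuple[float, float]:
    (Xc, Xz, Xr), terms = _designs(data, fit_.spec, fit_.orders)
    gamma = coef_vector(fit_.gamma, terms["report"])
    pi = expit(Xr @ gamma)
    mean_pi = float(np.mean(pi))
    # gradient of mean(pi) w.r.t. the full (beta, delta, gamma) vector
    p = fit_.n_params
    g = np.zeros(p)
    offset = len(terms["count"]) + len(terms["zero"])
    g[offset:] = (pi * (1 - pi)) @ Xr / len(data)
    var = float(g @ fit_.vcov @ g)
    se = np.sqrt(max(var, 0.0))
    return mean_pi, se


def average_reporting_rate(
    fit_: BTZIPFit,
    data: pd.DataFrame,
    by: str | None = None,
) -> ReportingRateTable:
    """Average predicted reporting rate in percent, overall or by subgroup.

    The average is the arithmetic mean of logistic(gamma.W_i) over rows;
    the standard error is by the delta method, sandwiching the gradient of
    that mean with the coefficient covariance.
    """
    records = []
    mean_pi, se = _mean_pi_and_se(fit_, data)
    records.append({"subgroup": "Average", "rate_pct": 100 * mean_pi,
                    "se_pct": 100 * se, "n": len(data)})
    if by is not None:
        if by not in data.columns:
            raise KeyError(f"subgroup variable {by!r} not in data")
        for level, sub in data.groupby(data[by].astype(str), sort=True):
            if len(sub) == 0:  # pragma: no cover - groupby drops empties
                warnings.warn(f"empty subgroup {level!r} omitted", stacklevel=2)
                continue
            m, s = _mean_pi_and_se(fit_, sub)
            records.append({"subgroup": f"{by}={level}", "rate_pct": 100 * m,
                            "se_pct": 100 * s, "n": len(sub)})
    return ReportingRateTable(rows=pd.DataFrame.from_records(records))
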