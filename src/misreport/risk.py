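"""Multilevel multinomial logistic regression of pregnancy outcome.

Each pregnancy j of woman i ends in one of three outcomes — miscarriage,
abortion, or live birth (the reference).  With eta_ij,ref = 0 and, for each
non-reference outcome k,

    eta_ijk = beta_0k + beta_k . X_ij + u_ik,      u_ik ~ N(0, sigma_uk^2),

the outcome probabilities are P(Y_ij = k) = exp(eta_ijk) / sum_l exp(eta_ijl).
The woman-level random intercepts u_ik absorb time-invariant unobserved
heterogeneity shared across a woman's pregnancies; contrasting fits with and
without them shows whether an apparent effect of reproductive history (e.g.
prior miscarriages) survives once that heterogeneity is modelled.

Inference is Bayesian: weakly informative Normal(0, 5^2) priors on fixed
effects and half-Student-t(3, 2.5) priors on the random-intercept SDs, with
separate sigma_u and independent u's per non-reference outcome.  Sampling is
by adaptive Metropolis-within-Gibbs — scalar random-walk updates for fixed
effects and log-SDs, a vectorized per-woman update for the random intercepts
— with proposal scales adapted during warmup only, so the post-warmup chain
is a valid time-homogeneous Markov chain.  The no-random-effect variant also
computes a maximum-a-posteriori point estimate by direct optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from ._design import build_design, infer_orders

__all__ = [
    "MNLSpec",
    "MNLFit",
    "outcome_probs",
    "conditional_loglik",
    "fit_mcmc",
    "fit_no_re",
    "predict_probabilities",
]

REFERENCE = "live_birth"
NONREF = ("miscarriage", "abortion")


class ConvergenceWarning(UserWarning):
    """Split-Rhat above 1.05 or effective sample size below 100."""


def outcome_probs(eta_1: float, eta_2: float) -> np.ndarray:
    """Probabilities of (outcome 1, outcome 2, reference) given linear
    predictors, with the reference's predictor fixed at zero.

    Overflow-safe for arbitrarily large |eta|; the triple always sums to 1.
    Accepts arrays broadcast against each other; the outcome axis is last.
    """
    eta_1 = np.asarray(eta_1, dtype=float)
    eta_2 = np.asarray(eta_2, dtype=float)
    if not (np.all(np.isfinite(eta_1)) and np.all(np.isfinite(eta_2))):
        raise ValueError("linear predictors must be finite")
    eta = np.stack(np.broadcast_arrays(eta_1, eta_2, np.zeros_like(eta_1)), axis=-1)
    eta = eta - eta.max(axis=-1, keepdims=True)
    w = np.exp(eta)
    return w / w.sum(axis=-1, keepdims=True)


@dataclass
class MNLSpec:
    """Model specification and sampler settings."""

    covariates: list[str]
    outcomes: tuple[str, ...] = ("miscarriage", "abortion", "live_birth")
    reference: str = REFERENCE
    include_random_effects: bool = True
    prior_sd_fixed: float = 5.0
    sigma_prior_df: float = 3.0
    sigma_prior_scale: float = 2.5
    chains: int = 4
    iterations: int = 6000
    warmup: int | None = None  # default: half of iterations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference not in self.outcomes:
            raise ValueError(f"reference {self.reference!r} not among outcomes")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for split-Rhat")
        if self.warmup is None:
            self.warmup = self.iterations // 2
        if not (0 < self.warmup < self.iterations):
            raise ValueError("need 0 < warmup < iterations")

    @property
    def nonref(self) -> list[str]:
        return [o for o in self.outcomes if o != self.reference]


@dataclass
class MNLFit:
    """Posterior draws and diagnostics.

    ``beta`` has shape (chains, draws, K, p) for K non-reference outcomes and
    p design terms; ``sigma_u`` (chains, draws, K); ``log_post`` (chains,
    draws).  ``summary()`` flattens chains.
    """

    beta: np.ndarray
    sigma_u: np.ndarray
    log_post: np.ndarray
    term_names: list[str]
    outcome_names: list[str]
    spec: MNLSpec
    orders: dict[str, list[str]]
    diagnostics: pd.DataFrame  # parameter, rhat, ess
    diagnostics_ok: bool
    map_estimate: dict[str, np.ndarray] | None = None  # no-RE fits only

    def param_labels(self) -> list[str]:
        labels = [
            f"{out}:{t}" for k, out in enumerate(self.outcome_names)
            for t in self.term_names
        ]
        if self.spec.include_random_effects:
            labels += [f"sigma_u[{out}]" for out in self.outcome_names]
        return labels

    def flat_beta(self) -> np.ndarray:
        """(total draws, K, p) with chains stacked."""
        c, d, K, p = self.beta.shape
        return self.beta.reshape(c * d, K, p)

    def flat_sigma(self) -> np.ndarray:
        c, d, K = self.sigma_u.shape
        return self.sigma_u.reshape(c * d, K)

    def posterior_mean_beta(self) -> pd.DataFrame:
        m = self.flat_beta().mean(axis=0)
        return pd.DataFrame(m.T, index=self.term_names, columns=self.outcome_names)

    def summary(self) -> pd.DataFrame:
        rows = []
        flat = self.flat_beta()
        for k, out in enumerate(self.outcome_names):
            for j, t in enumerate(self.term_names):
                draws = flat[:, k, j]
                rows.append(_summary_row(f"{out}:{t}", draws))
        if self.spec.include_random_effects:
            fs = self.flat_sigma()
            for k, out in enumerate(self.outcome_names):
                rows.append(_summary_row(f"sigma_u[{out}]", fs[:, k]))
        table = pd.DataFrame(rows)
        return table.merge(self.diagnostics, on="parameter", how="left")

    def to_csv(self, path: str | Path) -> None:
        self.summary().to_csv(path, index=False)


def _summary_row(name: str, draws: np.ndarray) -> dict:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {
        "parameter": name,
        "mean": float(draws.mean()),
        "sd": float(draws.std(ddof=1)),
        "q2.5": float(lo),
        "q97.5": float(hi),
    }


# ---------------------------------------------------------------------------
# likelihood pieces


def _encode(pregnancies: pd.DataFrame, spec: MNLSpec,
            orders: Mapping[str, Sequence[str]] | None = None):
    present = set(pregnancies["outcome"].astype(str))
    missing_out = [o for o in spec.outcomes if o not in present]
    nonref_present = [o for o in spec.nonref if o in present]
    if len(present) < 2 or not nonref_present:
        raise ValueError(
            f"degenerate outcome distribution: only {sorted(present)} present "
            f"(missing {missing_out})"
        )
    na = pregnancies[spec.covariates].isna().any(axis=1)
    if na.any():
        first = pregnancies.index[na][0]
        raise ValueError(f"missing covariate value at row {first}")
    orders = orders or infer_orders(pregnancies, spec.covariates)
    X, terms = build_design(pregnancies, spec.covariates, orders)
    code = {o: k for k, o in enumerate(spec.nonref)}
    code[spec.reference] = len(spec.nonref)
    y = pregnancies["outcome"].astype(str).map(code)
    if y.isna().any():
        bad = sorted(set(pregnancies["outcome"].astype(str)) - set(code))
        raise ValueError(f"unknown outcome labels: {bad}")
    woman_ids, woman_idx = np.unique(pregnancies["woman_id"].to_numpy(), return_inverse=True)
    return X, terms, y.to_numpy(dtype=int), woman_ids, woman_idx, orders


def _loglik_eta(eta: np.ndarray, y: np.ndarray) -> float:
    """Sum of log multinomial probabilities; eta is (n, K) for the
    non-reference outcomes, the reference's predictor is 0."""
    full = np.concatenate([eta, np.zeros((eta.shape[0], 1))], axis=1)
    denom = logsumexp(full, axis=1)
    num = full[np.arange(len(y)), y]
    return float(np.sum(num - denom))


def conditional_loglik(
    pregnancies: pd.DataFrame,
    spec: MNLSpec,
    beta: Mapping[str, Mapping[str, float]] | np.ndarray,
    u: Mapping | None = None,
) -> float:
    """Log-likelihood given fixed effects and (optional) per-woman effects.

    ``beta`` maps outcome -> {term: coefficient} (or a (K, p) array in design
    order); ``u`` maps outcome -> {woman_id: u_ik}.  Every pregnancy's woman
    must have a u entry when ``u`` is given.
    """
    X, terms, y, woman_ids, woman_idx, _ = _encode(pregnancies, spec)
    K = len(spec.nonref)
    if isinstance(beta, np.ndarray):
        B = np.asarray(beta, dtype=float).reshape(K, len(terms))
    else:
        B = np.zeros((K, len(terms)))
        for k, out in enumerate(spec.nonref):
            coefs = dict(beta.get(out, {}))
            unknown = set(coefs) - set(terms)
            if unknown:
                raise ValueError(f"unknown terms for {out!r}: {sorted(unknown)}")
            B[k] = [coefs.get(t, 0.0) for t in terms]
    eta = X @ B.T
    if u is not None:
        for k, out in enumerate(spec.nonref):
            uk = u.get(out, {})
            missing = [w for w in woman_ids if w not in uk]
            if missing:
                raise ValueError(f"missing random effect for woman {missing[0]!r}")
            eta[:, k] += np.array([uk[w] for w in woman_ids])[woman_idx]
    return _loglik_eta(eta, y)


# ---------------------------------------------------------------------------
# priors


def _log_prior_beta(B: np.ndarray, sd: float) -> float:
    return float(-0.5 * np.sum(B**2) / sd**2)


def _log_prior_sigma(sigma: np.ndarray, df: float, scale: float) -> float:
    # half-Student-t density up to a constant
    return float(np.sum(-(df + 1) / 2 * np.log1p((sigma / scale) ** 2 / df)))


# ---------------------------------------------------------------------------
# sampler


def _run_chain(
    rng: np.random.Generator,
    X: np.ndarray,
    y: np.ndarray,
    woman_idx: np.ndarray,
    n_women: int,
    spec: MNLSpec,
    with_re: bool,
    start_beta: np.ndarray,
    n_keep: int,
    n_warmup: int,
):
    n, p = X.shape
    K = len(spec.nonref)
    counts_by_outcome = [(y == k) for k in range(K)]

    B = start_beta.copy()
    u = np.zeros((K, n_women))
    log_sigma = np.full(K, np.log(0.5))

    eta = X @ B.T + u[:, woman_idx].T
    num_mask = [np.flatnonzero(counts_by_outcome[k]) for k in range(K)]

    # proposal scales, adapted during warmup only
    s_beta = np.full((K, p), 0.1)
    s_u = np.full(K, 0.5)
    s_sigma = np.full(K, 0.3)
    s_scale = np.full(K, 0.3)

    betas = np.empty((n_keep, K, p))
    sigmas = np.empty((n_keep, K))
    lps = np.empty(n_keep)

    def row_logdenom(e1, e2):
        # log(1 + e^{e1} + e^{e2}) stable
        m = np.maximum(np.maximum(e1, e2), 0.0)
        return m + np.log(np.exp(e1 - m) + np.exp(e2 - m) + np.exp(-m))

    if K != 2:
        raise NotImplementedError("sampler assumes two non-reference outcomes")
    e_cols = [eta[:, k].copy() for k in range(K)]
    denom = row_logdenom(e_cols[0], e_cols[1])

    def total_numerator():
        s = 0.0
        for k in range(K):
            s += float(e_cols[k][num_mask[k]].sum())
        return s

    numerator = total_numerator()
    sigma = np.exp(log_sigma)

    it_total = spec.iterations
    for it in range(it_total):
        in_warmup = it < n_warmup
        adapt_w = 1.0 / np.sqrt(it + 1.0)

        # --- fixed effects, scalar random-walk per coefficient
        for k in range(K):
            xk = e_cols[k]
            other = e_cols[1 - k]
            for j in range(p):
                db = s_beta[k, j] * rng.standard_normal()
                new_col = xk + X[:, j] * db
                new_denom = row_logdenom(new_col, other) if k == 0 else row_logdenom(other, new_col)
                d_num = float((new_col[num_mask[k]] - xk[num_mask[k]]).sum())
                d_den = float((new_denom - denom).sum())
                d_prior = -0.5 * ((B[k, j] + db) ** 2 - B[k, j] ** 2) / spec.prior_sd_fixed**2
                if np.log(rng.random()) < d_num - d_den + d_prior:
                    B[k, j] += db
                    e_cols[k] = new_col
                    xk = new_col
                    denom = new_denom
                    numerator += d_num
                    acc = 1.0
                else:
                    acc = 0.0
                if in_warmup:
                    s_beta[k, j] = np.exp(
                        np.log(s_beta[k, j]) + adapt_w * (acc - 0.44)
                    )

        if with_re:
            # --- random intercepts, vectorized over women
            for k in range(K):
                du = s_u[k] * rng.standard_normal(n_women)
                xk = e_cols[k]
                other = e_cols[1 - k]
                new_col = xk + du[woman_idx]
                new_denom = row_logdenom(new_col, other) if k == 0 else row_logdenom(other, new_col)
                d_row = (np.where(counts_by_outcome[k], new_col - xk, 0.0)
                         - (new_denom - denom))
                d_by_woman = np.bincount(woman_idx, weights=d_row, minlength=n_women)
                d_prior = -0.5 * ((u[k] + du) ** 2 - u[k] ** 2) / sigma[k] ** 2
                accept = np.log(rng.random(n_women)) < d_by_woman + d_prior
                if np.any(accept):
                    u[k, accept] += du[accept]
                    row_acc = accept[woman_idx]
                    xk = np.where(row_acc, new_col, xk)
                    e_cols[k] = xk
                    denom = row_logdenom(e_cols[0], e_cols[1])
                    numerator = total_numerator()
                if in_warmup:
                    s_u[k] = np.exp(np.log(s_u[k]) + adapt_w * (accept.mean() - 0.44))

            # --- joint scale move (u_k, sigma_k) -> (c u_k, c sigma_k): moves
            # along the funnel direction the conditional updates cannot; the
            # N(0, sigma^2) prior term on u is invariant under the rescaling
            for k in range(K):
                dlc = s_scale[k] * rng.standard_normal()
                c = np.exp(dlc)
                new_ls = log_sigma[k] + dlc
                new_s = np.exp(new_ls)
                xk = e_cols[k]
                other = e_cols[1 - k]
                new_col = xk + (c - 1.0) * u[k][woman_idx]
                new_denom = row_logdenom(new_col, other) if k == 0 else row_logdenom(other, new_col)
                d_num = float((new_col[num_mask[k]] - xk[num_mask[k]]).sum())
                d_den = float((new_denom - denom).sum())
                d_prior = (
                    _log_prior_sigma(np.array([new_s]), spec.sigma_prior_df,
                                     spec.sigma_prior_scale)
                    - _log_prior_sigma(np.array([sigma[k]]), spec.sigma_prior_df,
                                       spec.sigma_prior_scale)
                    + dlc  # Jacobian of the half-t density on the log scale
                )
                if np.log(rng.random()) < d_num - d_den + d_prior:
                    u[k] *= c
                    log_sigma[k] = new_ls
                    sigma[k] = new_s
                    e_cols[k] = new_col
                    denom = new_denom
                    numerator += d_num
                    acc = 1.0
                else:
                    acc = 0.0
                if in_warmup:
                    s_scale[k] = np.exp(np.log(s_scale[k]) + adapt_w * (acc - 0.44))

            # --- log-sigma random walk
            for k in range(K):
                dls = s_sigma[k] * rng.standard_normal()
                new_ls = log_sigma[k] + dls
                new_s = np.exp(new_ls)
                ssq = float(np.sum(u[k] ** 2))
                cur = (-n_women * log_sigma[k] - 0.5 * ssq / sigma[k] ** 2
                       + _log_prior_sigma(np.array([sigma[k]]), spec.sigma_prior_df,
                                          spec.sigma_prior_scale) + log_sigma[k])
                new = (-n_women * new_ls - 0.5 * ssq / new_s**2
                       + _log_prior_sigma(np.array([new_s]), spec.sigma_prior_df,
                                          spec.sigma_prior_scale) + new_ls)
                if np.log(rng.random()) < new - cur:
                    log_sigma[k] = new_ls
                    sigma[k] = new_s
                    acc = 1.0
                else:
                    acc = 0.0
                if in_warmup:
                    s_sigma[k] = np.exp(np.log(s_sigma[k]) + adapt_w * (acc - 0.44))

        if not in_warmup:
            idx = it - n_warmup
            betas[idx] = B
            sigmas[idx] = sigma if with_re else np.zeros(K)
            lp = numerator - float(denom.sum()) + _log_prior_beta(B, spec.prior_sd_fixed)
            if with_re:
                lp += float(np.sum(-np.log(sigma)[:, None] - 0.5 * (u / sigma[:, None]) ** 2))
                lp += _log_prior_sigma(sigma, spec.sigma_prior_df, spec.sigma_prior_scale)
            lps[idx] = lp

    return betas, sigmas, lps


def _diagnostics(beta: np.ndarray, sigma: np.ndarray, term_names, outcome_names,
                 with_re: bool) -> tuple[pd.DataFrame, bool]:
    data = {}
    for k, out in enumerate(outcome_names):
        for j, t in enumerate(term_names):
            data[f"{out}:{t}"] = beta[:, :, k, j]
    if with_re:
        for k, out in enumerate(outcome_names):
            data[f"sigma_u[{out}]"] = sigma[:, :, k]
    idata = az.from_dict(posterior={k: v for k, v in data.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = [
        {"parameter": name, "rhat": float(rhat[name].values), "ess": float(ess[name].values)}
        for name in data
    ]
    table = pd.DataFrame(rows)
    ok = bool((table["rhat"] <= 1.05).all() and (table["ess"] >= 100).all())
    return table, ok


def fit_mcmc(pregnancies: pd.DataFrame, spec: MNLSpec) -> MNLFit:
    """Sample the joint posterior of fixed effects, random intercepts and
    their SDs by adaptive Metropolis-within-Gibbs.

    Chains run sequentially from a common MAP-free start (zeros, with
    intercepts at the empirical log-odds); draws after warmup are returned.
    Poor diagnostics set ``diagnostics_ok=False`` and emit a
    :class:`ConvergenceWarning` — the fit is always returned.
    """
    X, terms, y, woman_ids, woman_idx, orders = _encode(pregnancies, spec)
    K = len(spec.nonref)
    n_women = len(woman_ids)
    with_re = spec.include_random_effects

    # empirical log-odds start for intercepts
    start = np.zeros((K, len(terms)))
    n_ref = max(int(np.sum(y == K)), 1)
    for k in range(K):
        start[k, 0] = np.log(max(int(np.sum(y == k)), 1) / n_ref)

    n_keep = spec.iterations - spec.warmup
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    all_beta = np.empty((spec.chains, n_keep, K, len(terms)))
    all_sigma = np.empty((spec.chains, n_keep, K))
    all_lp = np.empty((spec.chains, n_keep))
    for c in range(spec.chains):
        rng = np.random.default_rng(seeds[c])
        b, s, lp = _run_chain(rng, X, y, woman_idx, n_women, spec, with_re,
                              start, n_keep, spec.warmup)
        all_beta[c], all_sigma[c], all_lp[c] = b, s, lp

    diag, ok = _diagnostics(all_beta, all_sigma, terms, spec.nonref, with_re)
    if not ok:
        bad = diag.loc[(diag["rhat"] > 1.05) | (diag["ess"] < 100), "parameter"].tolist()
        warnings.warn(
            f"MCMC diagnostics flagged parameters: {bad}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return MNLFit(
        beta=all_beta,
        sigma_u=all_sigma,
        log_post=all_lp,
        term_names=terms,
        outcome_names=spec.nonref,
        spec=spec,
        orders=orders,
        diagnostics=diag,
        diagnostics_ok=ok,
    )


def _neg_log_posterior_nore(flat: np.ndarray, X, y, K, p, prior_sd):
    B = flat.reshape(K, p)
    eta = X @ B.T
    ll = _loglik_eta(eta, y)
    return -(ll + _log_prior_beta(B, prior_sd))


def map_estimate_nore(pregnancies: pd.DataFrame, spec: MNLSpec,
                      method: str = "L-BFGS-B") -> dict[str, np.ndarray]:
    """Maximum-a-posteriori fixed effects for the no-random-effect model."""
    X, terms, y, _, _, _ = _encode(pregnancies, spec)
    K, p = len(spec.nonref), len(terms)
    x0 = np.zeros(K * p)
    res = optimize.minimize(
        _neg_log_posterior_nore, x0, args=(X, y, K, p, spec.prior_sd_fixed),
        method=method, options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10}
        if method == "L-BFGS-B" else {"maxiter": 5000},
    )
    return {"beta": res.x.reshape(K, p), "neg_log_post": float(res.fun),
            "success": bool(res.success), "terms": terms}


def fit_no_re(pregnancies: pd.DataFrame, spec: MNLSpec) -> MNLFit:
    """No-random-effect variant: same sampler with u fixed at zero, plus a
    MAP point estimate by direct optimization (stored on the fit)."""
    spec_nore = MNLSpec(
        covariates=list(spec.covariates),
        outcomes=spec.outcomes,
        reference=spec.reference,
        include_random_effects=False,
        prior_sd_fixed=spec.prior_sd_fixed,
        sigma_prior_df=spec.sigma_prior_df,
        sigma_prior_scale=spec.sigma_prior_scale,
        chains=spec.chains,
        iterations=spec.iterations,
        warmup=spec.warmup,
        seed=spec.seed,
    )
    fit = fit_mcmc(pregnancies, spec_nore)
    fit.map_estimate = map_estimate_nore(pregnancies, spec_nore)
    return fit


def predict_probabilities(
    fit: MNLFit,
    profile: Mapping[str, str],
    data: pd.DataFrame,
    *,
    n_u: int = 200,
    max_draws: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Marginally standardized outcome probabilities for a covariate profile.

    For each posterior draw, the profile variables are fixed on every observed
    covariate row, probabilities are averaged over rows and over Monte-Carlo
    draws of the random intercepts (n_u per posterior draw, using that draw's
    sigma_u); the 95% interval is the 2.5/97.5 percentile across posterior
    draws.  Returns one row per outcome (non-reference outcomes then the
    reference).
    """
    unknown = [c for c in profile if c not in fit.orders]
    if unknown:
        raise KeyError(f"profile variables not in model: {unknown}")
    mod = data.copy()
    for c, v in profile.items():
        if str(v) not in [str(x) for x in fit.orders[c]]:
            raise ValueError(f"unseen category {v!r} for profile variable {c!r}")
        mod[c] = v
    X, _ = build_design(mod, fit.spec.covariates, fit.orders)

    rng = np.random.default_rng(seed)
    flat_b = fit.flat_beta()
    flat_s = fit.flat_sigma()
    n_total = flat_b.shape[0]
    if n_total > max_draws:
        idx = rng.choice(n_total, size=max_draws, replace=False)
        idx.sort()
        flat_b, flat_s = flat_b[idx], flat_s[idx]

    K = len(fit.outcome_names)
    with_re = fit.spec.include_random_effects
    per_draw = np.empty((flat_b.shape[0], K + 1))
    for d in range(flat_b.shape[0]):
        eta = X @ flat_b[d].T  # (n, K)
        if with_re and np.any(flat_s[d] > 0):
            u = rng.standard_normal((n_u, K)) * flat_s[d]
            e = eta[None, :, :] + u[:, None, :]
            probs = outcome_probs(e[..., 0], e[..., 1])
            per_draw[d] = probs.mean(axis=(0, 1))
        else:
            probs = outcome_probs(eta[:, 0], eta[:, 1])
            per_draw[d] = probs.mean(axis=0)

    labels = list(fit.outcome_names) + [fit.spec.reference]
    lo, hi = np.percentile(per_draw, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "outcome": labels,
            "probability": per_draw.mean(axis=0),
            "q2.5": lo,
            "q97.5": hi,
        }
    )
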