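"""Global Gaussian-mixture fitting of lifetime distributions across conditions.

All conditions are fit jointly: component means and widths are shared,
only the per-condition amplitudes differ — the hypothesis being that the
same conformational states (compact/open) are populated to different
degrees in each membrane environment. Fitting is expectation-maximization
over the unbinned per-bunch lifetime estimates (histograms are display
only), with multi-start initialization. The component count is chosen by
the Bayesian Information Criterion

    BIC = -2 ln L + p ln n

with p the free-parameter count (2k shared + (k-1) amplitudes per
condition) and n the total bunch count across conditions; component
separation is quantified by Ashman's D,

    D_ij = |mu_i - mu_j| / sqrt((sigma_i^2 + sigma_j^2) / 2),

where D > 2 indicates well-separated components. EGF-induced amplitude
changes and one-way ANOVA condition comparisons are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "GaussianMixtureModel",
    "ConditionComparison",
    "fit_global_mixture",
    "bic_value",
    "select_k",
    "ashman_d",
    "egf_amplitude_change",
    "anova_pair",
]

SIGMA_FLOOR = 0.01  # ns; guards EM against degenerate component collapse


@dataclass
class GaussianMixtureModel:
    k: int
    means: np.ndarray
    sigmas: np.ndarray
    weights: dict[str, np.ndarray]  # per-condition amplitudes, sum to 1
    log_likelihood: float
    n_total: int
    converged: bool
    n_iter: int
    data: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def n_conditions(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return 2 * self.k + (self.k - 1) * self.n_conditions

    @property
    def bic(self) -> float:
        return bic_value(self.log_likelihood, self.n_params, self.n_total)

    @property
    def ashman_d(self) -> np.ndarray:
        return ashman_d(self.means, self.sigmas)

    def open_fraction(self, condition: str) -> float:
        """Amplitude of the open (largest-mean) component, as a fraction."""
        return float(self.weights[condition][-1])


def bic_value(log_likelihood: float, n_params: int, n: int) -> float:
    """Bayesian Information Criterion, -2 ln L + p ln n."""
    return -2.0 * log_likelihood + n_params * np.log(n)


def ashman_d(means: Sequence[float], sigmas: Sequence[float]) -> np.ndarray:
    """Pairwise Ashman's D matrix (symmetric, zero diagonal)."""
    mu = np.asarray(means, dtype=float)
    sg = np.asarray(sigmas, dtype=float)
    diff = np.abs(mu[:, None] - mu[None, :])
    pooled = np.sqrt(0.5 * (sg[:, None] ** 2 + sg[None, :] ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(pooled > 0, diff / pooled, 0.0)
    np.fill_diagonal(D, 0.0)
    return D


def _log_norm_pdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    # x: (n,), mu/sigma: (k,) -> (n, k)
    z = (x[:, None] - mu[None, :]) / sigma[None, :]
    return -0.5 * z**2 - np.log(sigma[None, :]) - 0.5 * np.log(2 * np.pi)


def _em(
    data: Mapping[str, np.ndarray],
    means: np.ndarray,
    sigmas: np.ndarray,
    weights: Mapping[str, np.ndarray],
    sigma_floor: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, dict, float, bool, int]:
    k = len(means)
    means = means.copy()
    sigmas = np.maximum(sigmas, sigma_floor)
    weights = {c: np.asarray(w, float).copy() for c, w in weights.items()}
    ll_old = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        num_mu = np.zeros(k)
        num_var = np.zeros(k)
        denom = np.zeros(k)
        ll = 0.0
        resp_by_cond = {}
        for cond, x in data.items():
            log_r = _log_norm_pdf(x, means, sigmas) + np.log(
                np.maximum(weights[cond], 1e-300)
            )
            norm = logsumexp(log_r, axis=1)
            ll += norm.sum()
            r = np.exp(log_r - norm[:, None])
            resp_by_cond[cond] = r
            num_mu += r.T @ x
            denom += r.sum(axis=0)
        # EM guarantee: the observed-data log-likelihood never decreases
        assert ll >= ll_old - 1e-6 * max(1.0, abs(ll_old)), "EM log-likelihood decreased"
        for cond, x in data.items():
            r = resp_by_cond[cond]
            weights[cond] = r.mean(axis=0)
        mu_new = num_mu / np.maximum(denom, 1e-300)
        for cond, x in data.items():
            num_var += (resp_by_cond[cond] * (x[:, None] - mu_new[None, :]) ** 2).sum(axis=0)
        sg_new = np.sqrt(num_var / np.maximum(denom, 1e-300))
        means, sigmas = mu_new, np.maximum(sg_new, sigma_floor)
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    # sort components by mean, permuting weights accordingly
    order = np.argsort(means)
    means = means[order]
    sigmas = sigmas[order]
    weights = {c: w[order] for c, w in weights.items()}
    return means, sigmas, weights, float(ll_old), converged, it


def fit_global_mixture(
    lifetime_sets: Mapping[str, Sequence[float]],
    k: int,
    n_starts: int = 20,
    seed: int = 0,
    sigma_floor: float = SIGMA_FLOOR,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> GaussianMixtureModel:
    """Fit a shared-component Gaussian mixture jointly over conditions.

    Runs ``n_starts`` seeded EM starts (means from jittered pooled
    quantiles, uniform-Dirichlet amplitudes) and keeps the best by joint
    log-likelihood. Deterministic given ``seed``.
    """
    if k not in (1, 2, 3):
        raise ValueError("component count k must be 1, 2 or 3")
    data = {c: np.asarray(x, dtype=float) for c, x in lifetime_sets.items()}
    if not data:
        raise ValueError("need at least one condition")
    for cond, x in data.items():
        if x.size < 10 * k:
            raise ValueError(f"condition {cond!r} has {x.size} values; need >= {10 * k}")
    pooled = np.concatenate(list(data.values()))
    n_total = pooled.size
    base_means = np.quantile(pooled, (np.arange(k) + 0.5) / k)
    base_sigma = pooled.std() / max(k, 1)

    # short EM burst per start, then refine the best start to convergence
    best = None
    rng = np.random.default_rng(seed)
    for _ in range(n_starts):
        means0 = np.sort(base_means + rng.normal(0, pooled.std() / 4, size=k))
        sigmas0 = np.full(k, base_sigma) * rng.uniform(0.5, 1.5)
        weights0 = {c: rng.dirichlet(np.ones(k) * 5) for c in data}
        result = _em(data, means0, sigmas0, weights0, sigma_floor, tol, max_iter=25)
        if best is None or result[3] > best[3]:
            best = result
    means, sigmas, weights, ll, converged, n_iter = _em(
        data, best[0], best[1], best[2], sigma_floor, tol, max_iter
    )
    return GaussianMixtureModel(
        k=k,
        means=means,
        sigmas=sigmas,
        weights=weights,
        log_likelihood=ll,
        n_total=int(n_total),
        converged=converged,
        n_iter=n_iter,
        data=data,
    )


def select_k(models: Sequence[GaussianMixtureModel]) -> GaussianMixtureModel:
    """Pick the minimum-BIC model; ties break toward fewer components.

    All candidates must be fit on identical data (same conditions and
    sample counts), else BIC values are not comparable.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least two candidate models")
    ref = models[0]
    for m in models[1:]:
        same = set(m.data) == set(ref.data) and all(
            m.data[c].size == ref.data[c].size and np.allclose(m.data[c], ref.data[c])
            for c in ref.data
        )
        if not same:
            raise ValueError("models were fitted on differing data")
    return min(models, key=lambda m: (round(m.bic, 12), m.k))


# ---------------------------------------------------------------------------
# Condition comparisons


@dataclass
class ConditionComparison:
    condition_minus_egf: str
    condition_plus_egf: str
    open_fraction_minus_egf: float  # percent
    open_fraction_plus_egf: float   # percent
    delta: float                    # percentage points
    delta_se: float                 # percentage points, from observed information
    anova_f: float
    anova_p: float
    df: tuple[int, int]
    significant: bool


def _pack_params(model: GaussianMixtureModel) -> tuple[np.ndarray, list[str]]:
    theta = list(model.means) + list(model.sigmas)
    conds = list(model.weights)
    for c in conds:
        theta.extend(model.weights[c][:-1])
    return np.array(theta, dtype=float), conds


def _loglik_at(theta: np.ndarray, model: GaussianMixtureModel, conds: list[str]) -> float:
    k = model.k
    means = theta[:k]
    # clamp rather than reject so finite differences stay finite at the
    # boundary of the simplex / positive-sigma region
    sigmas = np.maximum(theta[k : 2 * k], 1e-6)
    ll = 0.0
    pos = 2 * k
    for c in conds:
        w_head = theta[pos : pos + k - 1]
        w = np.append(w_head, 1.0 - w_head.sum())
        w = np.clip(w, 1e-12, 1.0)
        pos += k - 1
        x = model.data[c]
        log_r = _log_norm_pdf(x, means, sigmas) + np.log(np.maximum(w, 1e-300))
        ll += logsumexp(log_r, axis=1).sum()
    return ll


def observed_information_weight_se(model: GaussianMixtureModel) -> dict[str, float]:
    """Standard error of each condition's open-component amplitude from the
    observed information (numerical Hessian of the joint log-likelihood)."""
    theta0, conds = _pack_params(model)
    n = len(theta0)
    h = 1e-4 * np.maximum(np.abs(theta0), 0.05)
    hess = np.zeros((n, n))
    f0 = _loglik_at(theta0, model, conds)
    for i in range(n):
        for j in range(i, n):
            ei, ej = np.zeros(n), np.zeros(n)
            ei[i], ej[j] = h[i], h[j]
            fpp = _loglik_at(theta0 + ei + ej, model, conds)
            fpm = _loglik_at(theta0 + ei - ej, model, conds)
            fmp = _loglik_at(theta0 - ei + ej, model, conds)
            fmm = _loglik_at(theta0 - ei - ej, model, conds)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    hess = np.nan_to_num(hess, nan=0.0, posinf=0.0, neginf=0.0)
    try:
        cov = np.linalg.pinv(-hess)
    except np.linalg.LinAlgError:
        return {c: float("nan") for c in conds}
    k = model.k
    out = {}
    for ci, c in enumerate(conds):
        idx = 2 * k + ci * (k - 1)
        head = cov[idx : idx + k - 1, idx : idx + k - 1]
        # open weight = 1 - sum(head weights): var = 1' Cov 1
        out[c] = float(np.sqrt(max(head.sum(), 0.0)))
    return out


def egf_amplitude_change(
    model: GaussianMixtureModel,
    pairs: Sequence[tuple[str, str]],
) -> list[ConditionComparison]:
    """Tabulate the EGF-induced change in the open-state amplitude.

    ``pairs`` lists (condition without EGF, condition with EGF); delta is
    the open-component amplitude difference in percentage points, with an
    observed-information standard error, plus a one-way ANOVA of the two
    conditions' lifetime values.
    """
    for minus, plus in pairs:
        for c in (minus, plus):
            if c not in model.weights:
                raise ValueError(f"condition {c!r} not present in the model")
    ses = observed_information_weight_se(model) if model.k >= 2 else {
        c: 0.0 for c in model.weights
    }
    out = []
    for minus, plus in pairs:
        w_minus = model.open_fraction(minus) * 100
        w_plus = model.open_fraction(plus) * 100
        f, p, df = anova_pair(model.data[minus], model.data[plus])
        out.append(
            ConditionComparison(
                condition_minus_egf=minus,
                condition_plus_egf=plus,
                open_fraction_minus_egf=w_minus,
                open_fraction_plus_egf=w_plus,
                delta=w_plus - w_minus,
                delta_se=float(np.hypot(ses[minus], ses[plus])) * 100,
                anova_f=f,
                anova_p=p,
                df=df,
                significant=p <= 1e-3,
            )
        )
    return out


def anova_pair(*samples: Sequence[float]) -> tuple[float, float, tuple[int, int]]:
    """Classical one-way ANOVA across >= 2 groups.

    Returns (F, p, (df_between, df_within)); significance in the pipeline
    is called at p <= 0.001.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(s, dtype=float) for s in samples]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least two values")
    f, p = stats.f_oneway(*groups)
    n = sum(g.size for g in groups)
    df = (len(groups) - 1, n - len(groups))
    if not np.isfinite(f):  # identical constant groups
        f, p = 0.0, 1.0
    return float(f), float(p), df


def comparisons_table(comparisons: Sequence[ConditionComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition_minus_egf": [c.condition_minus_egf for c in comparisons],
            "condition_plus_egf": [c.condition_plus_egf for c in comparisons],
            "open_pct_minus_egf": [c.open_fraction_minus_egf for c in comparisons],
            "open_pct_plus_egf": [c.open_fraction_plus_egf for c in comparisons],
            "delta_points": [c.delta for c in comparisons],
            "delta_se_points": [c.delta_se for c in comparisons],
            "anova_f": [c.anova_f for c in comparisons],
            "anova_p": [c.anova_p for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    )
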