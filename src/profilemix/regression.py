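"""External variables and latent class membership.

Two routes are provided:

* :func:`fit_concomitant` — one-step (simultaneous) latent class
  regression: class proportions become multinomial-logit functions of
  covariates, pi_c(x_i) = exp(g_c0 + g_c' x_i) / sum_k exp(...), and the
  mixture and logit coefficients are estimated jointly by EM. The
  one-step route avoids the attenuation bias of classify-then-regress.
* :func:`external_binary_by_class` — the multiple-imputation fallback:
  the distribution of a binary external variable (e.g. diagnosis) across
  classes, pooled over posterior-probability assignment draws with
  Rubin's rules. This is robust when regression degenerates (perfect
  prediction of a class by the outcome).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import IndicatorMatrix
from .lpa import (
    EMError,
    FittedModel,
    ModelSpec,
    ParameterSet,
    m_step,
)
from .mi import draw_class_assignments, pool_rubin
from .multistart import align_classes

__all__ = [
    "CovariateModel",
    "fit_concomitant",
    "stability_under_covariates",
    "external_binary_by_class",
]


@dataclass
class CovariateModel:
    """Multinomial-logit coefficients for class membership.

    ``coefficients[c - shift]`` holds (intercept, slopes...) for each
    non-reference class c, contrasting it against ``reference_class``
    (whose row is identically zero and omitted). Wald inference with
    normal critical values.
    """

    reference_class: int
    class_indices: list          # non-reference classes, row order
    covariate_names: list        # ["intercept", ...]
    coefficients: np.ndarray     # (C-1, p+1)
    standard_errors: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, c in enumerate(self.class_indices):
            for q, name in enumerate(self.covariate_names):
                rows.append({
                    "class": c, "term": name,
                    "estimate": self.coefficients[r, q],
                    "se": self.standard_errors[r, q],
                    "z": self.wald_z[r, q],
                    "p": self.p_values[r, q],
                    "ci_low": self.ci_low[r, q],
                    "ci_high": self.ci_high[r, q],
                })
        return pd.DataFrame(rows)


def _class_probs(gamma: np.ndarray, X1: np.ndarray, C: int,
                 reference: int) -> np.ndarray:
    """Per-subject class probabilities from logit coefficients.

    gamma: (C-1, p+1) for non-reference classes; X1: (n, p+1) with
    leading 1s column.
    """
    n = X1.shape[0]
    eta = np.zeros((n, C))
    rows = [c for c in range(C) if c != reference]
    eta[:, rows] = X1 @ gamma.T
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=1, keepdims=True)


def _fit_weighted_multinomial(
    tau: np.ndarray, X1: np.ndarray, reference: int,
    gamma0: np.ndarray | None = None,
    max_iter: int = 50, tol: float = 1e-10,
) -> np.ndarray:
    """Newton maximization of sum_i sum_c tau_ic log pi_c(x_i) over gamma.

    The objective is concave; a ridge of 1e-8 stabilizes the Hessian.
    Raises on divergence (separation).
    """
    n, C = tau.shape
    q = X1.shape[1]
    rows = [c for c in range(C) if c != reference]
    K = len(rows)
    gamma = np.zeros((K, q)) if gamma0 is None else gamma0.copy()
    for _ in range(max_iter):
        P = _class_probs(gamma, X1, C, reference)
        grad = ((tau - P)[:, rows].T @ X1).reshape(-1)  # (K*q,)
        H = np.zeros((K * q, K * q))
        for a in range(K):
            ca = rows[a]
            for b in range(K):
                cb = rows[b]
                w = P[:, ca] * ((ca == cb) - P[:, cb])
                H[a * q:(a + 1) * q, b * q:(b + 1) * q] = (X1 * w[:, None]).T @ X1
        H += 1e-8 * np.eye(K * q)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise EMError(f"singular Hessian in concomitant M-step: {exc}")
        # damped Newton: halve until the objective does not decrease
        obj0 = float((tau * np.log(np.maximum(P, 1e-300))).sum())
        scale = 1.0
        for _ in range(30):
            cand = gamma + scale * step.reshape(K, q)
            Pc = _class_probs(cand, X1, C, reference)
            if float((tau * np.log(np.maximum(Pc, 1e-300))).sum()) >= obj0 - 1e-12:
                break
            scale /= 2.0
        gamma = gamma + scale * step.reshape(K, q)
        if np.abs(gamma).max() > 50:
            raise EMError(
                "diverging logit coefficients (|gamma| > 50): a covariate "
                "separates a class perfectly; use the MI route "
                "(external_binary_by_class) instead"
            )
        if np.abs(grad).max() < tol * n:
            break
    return gamma


def _concomitant_loglik(data, params, gamma, X1, reference) -> float:
    """Observed loglik with subject-specific class probabilities."""
    from scipy.special import logsumexp

    P = _class_probs(gamma, X1, params.C, reference)
    dev = data.values[:, None, :] - params.means[None, :, :]
    quad = (dev * dev / params.variances).sum(axis=2)
    logdet = np.log(2 * np.pi * params.variances).sum()
    lw = np.log(np.maximum(P, 1e-300)) - 0.5 * (logdet + quad)
    return float(logsumexp(lw, axis=1).sum())


def fit_concomitant(
    data: IndicatorMatrix,
    spec: ModelSpec,
    covariates: np.ndarray | pd.DataFrame | None,
    init: ParameterSet,
    reference_class: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[FittedModel, CovariateModel]:
    """One-step EM for the mixture with covariate-dependent proportions.

    The E-step uses pi_c(x_i); the M-step updates measurement parameters
    (means under all spec restrictions, pooled variances) by weighted
    moments and the logit coefficients by Newton iterations on the
    posterior-weighted multinomial likelihood. Standard errors for gamma
    come from the numerically differentiated observed information of the
    full loglikelihood, holding measurement parameters at their MLE.
    With zero covariates the model collapses to the plain mixture.
    """
    if covariates is None:
        covariates = np.empty((data.n, 0))
    if isinstance(covariates, pd.DataFrame):
        cov_names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cov_names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] != data.n:
        raise ValueError("covariates and data disagree on n")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be complete (no missing values)")

    C = spec.n_classes
    if reference_class is None:
        reference_class = spec.fixed_indices[0] if spec.fixed_classes else 0
    X1 = np.hstack([np.ones((data.n, 1)), X])
    q = X1.shape[1]
    rows = [c for c in range(C) if c != reference_class]

    from .lpa import VARIANCE_FLOOR_FRACTION

    floor = VARIANCE_FLOOR_FRACTION * data.values.var(axis=0, ddof=0)
    params = init
    gamma = np.zeros((C - 1, q))
    # seed intercepts from the init proportions so the p=0 case starts at
    # the plain model's logits
    with np.errstate(divide="ignore"):
        logits = np.log(init.proportions)
    gamma[:, 0] = logits[rows] - logits[reference_class]

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        P = _class_probs(gamma, X1, C, reference_class)
        # E-step with subject-specific priors
        dev = data.values[:, None, :] - params.means[None, :, :]
        quad = (dev * dev / params.variances).sum(axis=2)
        logdet = np.log(2 * np.pi * params.variances).sum()
        lw = np.log(np.maximum(P, 1e-300)) - 0.5 * (logdet + quad)
        from scipy.special import logsumexp

        norm_i = logsumexp(lw, axis=1, keepdims=True)
        tau = np.exp(lw - norm_i)
        ll = float(norm_i.sum())
        if np.isnan(ll):
            raise EMError(f"NaN loglikelihood at iteration {n_iter}")
        if ll < prev_ll - 1e-9:
            raise EMError(
                f"loglikelihood decreased at iteration {n_iter} "
                f"({prev_ll:.8f} -> {ll:.8f})"
            )
        if np.isfinite(prev_ll) and abs(ll - prev_ll) / max(abs(prev_ll), 1.0) < tol:
            converged = True
            break
        prev_ll = ll
        ms = m_step(data, tau, spec, prev=params, variance_floor=floor)
        gamma = _fit_weighted_multinomial(tau, X1, reference_class, gamma0=gamma,
                                          max_iter=5)
        params = ParameterSet(
            proportions=np.maximum(tau.mean(axis=0), 1e-300)
            / np.maximum(tau.mean(axis=0), 1e-300).sum(),
            means=ms.means, variances=ms.variances,
        )

    # recompute posteriors and LL at the final parameter values
    P = _class_probs(gamma, X1, C, reference_class)
    dev = data.values[:, None, :] - params.means[None, :, :]
    quad = (dev * dev / params.variances).sum(axis=2)
    logdet = np.log(2 * np.pi * params.variances).sum()
    lw = np.log(np.maximum(P, 1e-300)) - 0.5 * (logdet + quad)
    from scipy.special import logsumexp

    norm_i = logsumexp(lw, axis=1, keepdims=True)
    tau = np.exp(lw - norm_i)
    ll = float(norm_i.sum())
    fitted = FittedModel(
        spec=spec, params=params, loglik=ll, posteriors=tau,
        n_iter=n_iter, converged=converged,
        boundary_flag=bool(np.any(params.proportions < 1e-4)),
    )

    # observed information for gamma by central-difference Hessian
    flat = gamma.reshape(-1)
    m = flat.size
    h = 1e-4

    def f(v):
        return _concomitant_loglik(data, params, v.reshape(gamma.shape),
                                   X1, reference_class)

    H = np.zeros((m, m))
    for a in range(m):
        for b in range(a, m):
            ea = np.zeros(m); ea[a] = h
            eb = np.zeros(m); eb[b] = h
            fpp = f(flat + ea + eb)
            fpm = f(flat + ea - eb)
            fmp = f(flat - ea + eb)
            fmm = f(flat - ea - eb)
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    info = -H
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(gamma.shape)
    except np.linalg.LinAlgError:
        se = np.full(gamma.shape, np.nan)

    z = np.divide(gamma, se, out=np.full(gamma.shape, np.nan), where=se > 0)
    pvals = 2 * norm.sf(np.abs(z))
    cov_model = CovariateModel(
        reference_class=reference_class,
        class_indices=rows,
        covariate_names=["intercept"] + cov_names,
        coefficients=gamma,
        standard_errors=se,
        wald_z=z,
        p_values=pvals,
        ci_low=gamma - 1.96 * se,
        ci_high=gamma + 1.96 * se,
    )
    return fitted, cov_model


def stability_under_covariates(model_without: FittedModel,
                               model_with: FittedModel,
                               flag_distance: float = 0.25) -> pd.DataFrame:
    """Compare class structure with and without concomitant covariates.

    Classes are aligned by mean profile; each row reports the profile
    distance and proportion shift. A distance above ``flag_distance``
    flags a class whose measurement structure (not merely its size)
    moved when covariates were added — the warning sign the diagnostic
    exists for.
    """
    a, b = model_without, model_with
    perm = align_classes(a.params, b.params, a.spec.fixed_indices)
    pb = b.params.permuted(list(perm))
    rows = []
    for c in range(a.params.C):
        dist = float(np.sqrt(((a.params.means[c] - pb.means[c]) ** 2).sum()))
        rows.append({
            "class": c,
            "matched_class": int(perm[c]),
            "profile_distance": dist,
            "proportion_without": float(a.params.proportions[c]),
            "proportion_with": float(pb.proportions[c]),
            "proportion_shift": float(pb.proportions[c] - a.params.proportions[c]),
            "flagged": dist > flag_distance,
        })
    return pd.DataFrame(rows)


def external_binary_by_class(
    binary: np.ndarray,
    posteriors: np.ndarray,
    D: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Class-wise proportion of a binary external variable, MI-pooled.

    Per draw, subjects are assigned to classes from their posteriors and
    the within-class proportion of 1s is recorded with its binomial
    variance p(1−p)/m; draws are pooled with Rubin's rules. Classes
    empty in every draw yield NaN rows.
    """
    y = np.asarray(binary, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binary variable must contain only 0 and 1")
    tau = np.asarray(posteriors, dtype=float)
    if y.shape[0] != tau.shape[0]:
        raise ValueError("binary vector and posteriors disagree on n")
    C = tau.shape[1]
    rng = np.random.default_rng(seed)
    means = np.full((D, C), np.nan)
    wvars = np.full((D, C), np.nan)
    sizes = np.zeros((D, C))
    for d in range(D):
        z = draw_class_assignments(tau, seed=int(rng.integers(2**31)))
        for c in range(C):
            mask = z == c
            m = int(mask.sum())
            sizes[d, c] = m
            if m >= 1:
                p = float(y[mask].mean())
                means[d, c] = p
                wvars[d, c] = p * (1 - p) / m
    rows = []
    for c in range(C):
        ok = np.isfinite(means[:, c])
        if ok.sum() < 2:
            rows.append({
                "class_index": c, "pooled_proportion": np.nan,
                "ci_low": np.nan, "ci_high": np.nan,
                "n_draws_used": int(ok.sum()),
                "mean_class_size": float(sizes[:, c].mean()),
            })
            continue
        est = pool_rubin(
            means[:, c], wvars[:, c], class_index=c, indicator="binary",
            mean_class_size=float(sizes[ok, c].mean()),
        )
        rows.append({
            "class_index": c,
            "pooled_proportion": est.pooled_mean,
            "within_var": est.within_var,
            "between_var": est.between_var,
            "total_var": est.total_var,
            "ci_low": max(est.ci_low, 0.0),
            "ci_high": min(est.ci_high, 1.0),
            "n_draws_used": est.n_draws_used,
            "mean_class_size": est.mean_class_size,
        })
    return pd.DataFrame(rows)
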