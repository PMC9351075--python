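"""Restricted Gaussian profile mixture: model, EM, and parameter counting.

The model is a finite mixture of multivariate normals with conditionally
independent indicators and pooled (class-invariant) variances:

    f(y_i) = sum_c  pi_c  prod_j  N(y_ij; mu_cj, sigma_j^2)

Two kinds of mean restrictions are supported, both aimed at conserving
free parameters in small samples:

* **fixed classes** — an entire class mean vector pinned to constants
  (e.g. a "low average" reference class at −0.5 on every z-scored
  indicator and a "high average" class at +0.5);
* **equality groups** — one indicator's mean tied to be equal across a
  set of classes (never across indicators).

Restrictions enter only in the M-step; the E-step and likelihood are
those of the unrestricted mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .data import IndicatorMatrix

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "FittedModel",
    "loglik",
    "e_step",
    "m_step",
    "fit_em",
    "count_parameters",
    "apply_restrictions",
    "two_reference_spec",
    "EMError",
]

# Relative variance floor: sigma_j^2 is never allowed below
# VARIANCE_FLOOR_FRACTION * sample variance of indicator j. Prevents the
# unbounded-likelihood spikes a Gaussian mixture exhibits when a class
# collapses onto a handful of points.
VARIANCE_FLOOR_FRACTION = 1e-4

# A class proportion below this is treated as a boundary (near-empty class).
PI_BOUNDARY = 1e-4


class EMError(RuntimeError):
    """EM failure: divergence, underflow, or invalid inputs."""


@dataclass(frozen=True)
class ModelSpec:
    """Class count plus mean-restriction structure.

    ``fixed_classes`` maps class indices to full J-vectors of constants.
    ``equality_groups`` is a sequence of ``(indicator_index, class_indices)``
    pairs; each ties one indicator's mean across the listed classes.
    Variances are always pooled: one sigma_j^2 per indicator, shared by
    all classes.
    """

    n_classes: int
    fixed_classes: tuple = ()
    equality_groups: tuple = ()
    variance_structure: str = "pooled"

    def __post_init__(self):
        object.__setattr__(self, "fixed_classes", tuple(
            (int(c), tuple(float(v) for v in vec)) for c, vec in self.fixed_classes
        ))
        object.__setattr__(self, "equality_groups", tuple(
            (int(j), tuple(sorted(int(c) for c in cls))) for j, cls in self.equality_groups
        ))
        C = self.n_classes
        if C < 1:
            raise ValueError("n_classes must be >= 1")
        if self.variance_structure != "pooled":
            raise ValueError("only pooled variances are supported")
        fixed_idx = [c for c, _ in self.fixed_classes]
        if len(set(fixed_idx)) != len(fixed_idx):
            raise ValueError("fixed class indices must be distinct")
        if any(c < 0 or c >= C for c in fixed_idx):
            raise ValueError("fixed class index out of range")
        seen = set()
        for j, cls in self.equality_groups:
            if len(cls) < 2:
                raise ValueError("equality group must tie at least 2 classes")
            for c in cls:
                if c < 0 or c >= C:
                    raise ValueError("equality group class index out of range")
                if c in fixed_idx:
                    raise ValueError(
                        f"class {c} is fixed; its means cannot also be tied"
                    )
                if (j, c) in seen:
                    raise ValueError(f"cell (indicator {j}, class {c}) tied twice")
                seen.add((j, c))
        if C == 1 and (self.fixed_classes or self.equality_groups):
            raise ValueError("a 1-class model admits no restrictions")

    @property
    def fixed_indices(self) -> tuple:
        return tuple(c for c, _ in self.fixed_classes)

    def validate_J(self, J: int) -> None:
        for c, vec in self.fixed_classes:
            if len(vec) != J:
                raise ValueError(
                    f"fixed class {c} has {len(vec)} means for {J} indicators"
                )
        for j, _ in self.equality_groups:
            if j < 0 or j >= J:
                raise ValueError("equality group indicator index out of range")

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "fixed_classes": {str(c): list(v) for c, v in self.fixed_classes},
            "equality_groups": [
                {"indicator": j, "classes": list(cls)}
                for j, cls in self.equality_groups
            ],
            "variance_structure": self.variance_structure,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            n_classes=int(d["n_classes"]),
            fixed_classes=tuple(
                (int(c), tuple(v)) for c, v in d.get("fixed_classes", {}).items()
            ),
            equality_groups=tuple(
                (g["indicator"], tuple(g["classes"]))
                for g in d.get("equality_groups", [])
            ),
            variance_structure=d.get("variance_structure", "pooled"),
        )


def two_reference_spec(n_classes: int, J: int,
                       low: float = -0.5, high: float = 0.5) -> ModelSpec:
    """Spec with two fully fixed reference classes at constant low / high means.

    Class 0 is the low reference, class 1 the high reference; remaining
    classes are free. This is the workhorse restriction for small-sample
    profile models: the two-class version estimates only one proportion
    and the J pooled variances.
    """
    if n_classes < 2:
        raise ValueError("reference-class spec needs at least 2 classes")
    return ModelSpec(
        n_classes=n_classes,
        fixed_classes=((0, (low,) * J), (1, (high,) * J)),
    )


@dataclass
class ParameterSet:
    """Mixture parameters: proportions pi, class means mu, pooled variances."""

    proportions: np.ndarray  # (C,)
    means: np.ndarray        # (C, J)
    variances: np.ndarray    # (J,)

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.asarray(self.variances, dtype=float)
        if abs(self.proportions.sum() - 1.0) > 1e-10:
            raise ValueError("class proportions must sum to 1")
        if np.any(self.proportions < 0):
            raise ValueError("class proportions must be nonnegative")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")
        if self.means.shape != (self.C, self.J):
            raise ValueError("means must be C × J")

    @property
    def C(self) -> int:
        return self.proportions.shape[0]

    @property
    def J(self) -> int:
        return self.variances.shape[0]

    def permuted(self, perm: Sequence[int]) -> "ParameterSet":
        perm = list(perm)
        return ParameterSet(
            proportions=self.proportions[perm],
            means=self.means[perm],
            variances=self.variances.copy(),
        )

    def to_dict(self) -> dict:
        return {
            "proportions": self.proportions.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(np.array(d["proportions"]), np.array(d["means"]),
                   np.array(d["variances"]))


@dataclass
class FittedModel:
    """EM output: spec, parameters, loglikelihood, posteriors, diagnostics."""

    spec: ModelSpec
    params: ParameterSet
    loglik: float
    posteriors: np.ndarray  # (n, C)
    n_iter: int
    converged: bool
    boundary_flag: bool = False

    @property
    def n(self) -> int:
        return self.posteriors.shape[0]

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "boundary_flag": self.boundary_flag,
        }


def apply_restrictions(means: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Overwrite fixed cells with their constants; equalize tied cells.

    Tied cells are set to their plain average — used only to make start
    values feasible; the M-step computes the proper weighted pooled value.
    """
    out = means.copy()
    for c, vec in spec.fixed_classes:
        out[c, :] = vec
    for j, cls in spec.equality_groups:
        out[list(cls), j] = out[list(cls), j].mean()
    return out


def _log_densities(y: np.ndarray, params: ParameterSet) -> np.ndarray:
    """(n, C) matrix of log pi_c + log f_c(y_i), computed in the log domain."""
    var = params.variances  # (J,)
    # (n, C, J) squared deviations scaled by variances
    dev = y[:, None, :] - params.means[None, :, :]
    quad = (dev * dev / var).sum(axis=2)
    logdet = np.log(2 * np.pi * var).sum()
    logphi = -0.5 * (logdet + quad)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.proportions)
    return logpi[None, :] + logphi


def _posteriors_and_ll(y: np.ndarray, params: ParameterSet):
    """Fused E-step: (tau, loglik) from one pass over the log densities."""
    lw = _log_densities(y, params)
    m = lw.max(axis=1, keepdims=True)
    ex = np.exp(lw - m)
    s = ex.sum(axis=1, keepdims=True)
    ll = float((m[:, 0] + np.log(s[:, 0])).sum())
    return ex / s, ll


def loglik(data: IndicatorMatrix, params: ParameterSet) -> float:
    """Observed-data loglikelihood, with per-observation log-sum-exp."""
    if data.J != params.J:
        raise ValueError("data and parameters disagree on indicator count")
    lw = _log_densities(data.values, params)
    return float(logsumexp(lw, axis=1).sum())


def e_step(data: IndicatorMatrix, params: ParameterSet) -> np.ndarray:
    """Posterior membership probabilities tau_ic; rows sum to 1."""
    if np.any(params.proportions <= 0):
        raise EMError("e_step requires strictly positive class proportions")
    lw = _log_densities(data.values, params)
    norm = logsumexp(lw, axis=1, keepdims=True)
    if not np.all(np.isfinite(norm)):
        raise EMError(
            "zero total density for some observation even in the log domain; "
            "check for degenerate variances"
        )
    return np.exp(lw - norm)


def m_step(
    data: IndicatorMatrix,
    posteriors: np.ndarray,
    spec: ModelSpec,
    prev: ParameterSet | None = None,
    variance_floor: np.ndarray | float = 1e-10,
) -> ParameterSet:
    """Weighted-moment updates under the spec's restrictions.

    Free means are posterior-weighted averages; fixed cells are set to
    their constants; an equality group's shared value pools the weighted
    sums across its classes. Pooled variances average squared deviations
    over all classes (denominator n) and are floored. A numerically empty
    class keeps its previous mean row when ``prev`` is given.
    """
    y = data.values
    n, J = y.shape
    tau = np.asarray(posteriors, dtype=float)
    if tau.shape[0] != n:
        raise ValueError("posteriors and data disagree on n")
    if not np.allclose(tau.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    C = tau.shape[1]

    weight = tau.sum(axis=0)                      # (C,)
    pi = weight / n
    empty = weight < 1e-10
    safe_w = np.where(empty, 1.0, weight)
    means = (tau.T @ y) / safe_w[:, None]
    if np.any(empty) and prev is not None:
        means[empty, :] = prev.means[empty, :]

    for j, cls in spec.equality_groups:
        idx = list(cls)
        num = float((tau[:, idx] * y[:, [j]]).sum())
        den = float(tau[:, idx].sum())
        if den > 1e-10:
            means[idx, j] = num / den
    for c, vec in spec.fixed_classes:
        means[c, :] = vec

    dev = y[:, None, :] - means[None, :, :]
    var = (tau[:, :, None] * dev * dev).sum(axis=(0, 1)) / n
    var = np.maximum(var, variance_floor)

    # guard against zero proportions breaking the next E-step
    pi = np.maximum(pi, 1e-300)
    pi = pi / pi.sum()
    return ParameterSet(proportions=pi, means=means, variances=var)


def fit_em(
    data: IndicatorMatrix,
    spec: ModelSpec,
    init: ParameterSet,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> FittedModel:
    """Run EM from one start until the relative LL change drops below tol.

    The loglikelihood is monotone non-decreasing across iterations (a
    decrease beyond 1e-9 slack raises, since it indicates a coding or
    numerical fault, not a modelling outcome). The returned model's
    ``loglik`` and ``posteriors`` are recomputed at the final parameters,
    and all restrictions hold exactly in the result.
    """
    spec.validate_J(data.J)
    if init.C != spec.n_classes or init.J != data.J:
        raise ValueError("init dimensions do not match spec/data")
    sample_var = data.values.var(axis=0, ddof=0)
    floor = VARIANCE_FLOOR_FRACTION * sample_var

    if spec.n_classes == 1:
        # closed form: the MLE is the sample mean and population-style variance
        mu = data.values.mean(axis=0, keepdims=True)
        var = np.maximum(sample_var, floor)
        params = ParameterSet(np.array([1.0]), mu, var)
        ll = loglik(data, params)
        tau = np.ones((data.n, 1))
        return FittedModel(spec, params, ll, tau, n_iter=1, converged=True,
                           boundary_flag=bool(np.any(var <= floor)))

    if np.any(init.proportions <= 0):
        raise EMError("initial class proportions must be strictly positive")
    params = init
    y = data.values
    prev_ll = -np.inf
    prev_delta = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        tau, ll = _posteriors_and_ll(y, params)
        if np.isnan(ll):
            raise EMError(
                f"loglikelihood became NaN at iteration {n_iter}; "
                f"params: {params.to_dict()}"
            )
        if ll < prev_ll - 1e-9:
            raise EMError(
                f"loglikelihood decreased at iteration {n_iter} "
                f"({prev_ll:.10f} -> {ll:.10f})"
            )
        if np.isfinite(prev_ll):
            # Aitken-accelerated stopping: project the asymptotic LL from
            # the contraction rate and stop when the projected remaining
            # gain is below tol (relative to |LL|). A plain change-based
            # rule fires prematurely on the near-flat saddle ridges that
            # collapsed-class starts crawl along.
            delta = ll - prev_ll
            thr = tol * max(abs(ll), 1.0)
            if delta <= 1e-13 * max(abs(ll), 1.0):
                converged = True
                break
            # only trust the contraction estimate once two consecutive
            # steps are small; a single tiny step after a large jump says
            # nothing about whether EM is on a plateau or at a maximum
            if delta < thr and prev_delta < thr:
                rate = delta / prev_delta
                if rate < 0.999:
                    gain = delta * rate / (1.0 - rate)
                    if gain < thr:
                        converged = True
                        break
            prev_delta = delta
        prev_ll = ll
        params = m_step(data, tau, spec, prev=params, variance_floor=floor)

    tau, ll = _posteriors_and_ll(y, params)
    boundary = bool(
        np.any(params.variances <= floor * (1 + 1e-12))
        or np.any(params.proportions < PI_BOUNDARY)
    )
    return FittedModel(spec, params, ll, tau, n_iter=n_iter,
                       converged=converged, boundary_flag=boundary)


def count_parameters(spec: ModelSpec, J: int) -> int:
    """Number of freely estimated parameters.

    k = free mean cells + J pooled variances + (C − 1) proportions.
    A fully fixed class contributes no free mean cells; an equality group
    of size g contributes one shared cell instead of g.
    """
    spec.validate_J(J)
    C = spec.n_classes
    free_means = C * J - J * len(spec.fixed_classes)
    for _, cls in spec.equality_groups:
        free_means -= len(cls) - 1
    return free_means + J + (C - 1)
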