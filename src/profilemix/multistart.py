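"""Multistart EM and mode diagnostics.

Mixture loglikelihood surfaces are routinely multimodal, and in small
samples the number of local maxima ("modes") that random starts reach —
and the share of starts reaching the best one — is itself a key
diagnostic of estimation quality. This module runs many random starts,
groups the converged solutions into modes up to class relabelling, and
tallies starts per mode.

Two solutions belong to the same mode when their loglikelihoods agree
within ``ll_tol`` *and* their parameters agree within ``param_tol``
(max-abs difference) after optimal class alignment; grouping is the
transitive closure of that relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data import IndicatorMatrix
from .lpa import (
    EMError,
    FittedModel,
    ModelSpec,
    ParameterSet,
    apply_restrictions,
    fit_em,
)

__all__ = [
    "ModeGroup",
    "MultistartResult",
    "generate_starts",
    "run_multistart",
    "group_modes",
    "align_classes",
]

DEFAULT_LL_TOL = 0.01
DEFAULT_PARAM_TOL = 0.05


@dataclass
class ModeGroup:
    """One local maximum: its best member and the starts that reached it."""

    representative: FittedModel
    loglik: float
    n_starts: int
    members: list  # start indices

    def to_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "n_starts": self.n_starts,
            "members": list(self.members),
            "representative": self.representative.to_dict(),
        }


@dataclass
class MultistartResult:
    """Modes sorted by descending loglikelihood, plus start-value tallies."""

    modes: list
    n_starts_total: int
    n_failed: int
    seed: int
    start_scheme: str = "seeded-partition+dirichlet"

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def best(self) -> FittedModel:
        return self.modes[0].representative

    @property
    def top_mode_fraction(self) -> float:
        return self.modes[0].n_starts / self.n_starts_total

    def to_dict(self) -> dict:
        return {
            "n_starts_total": self.n_starts_total,
            "n_failed": self.n_failed,
            "n_modes": self.n_modes,
            "seed": self.seed,
            "start_scheme": self.start_scheme,
            "top_mode_fraction": self.top_mode_fraction,
            "modes": [m.to_dict() for m in self.modes],
        }


def generate_starts(
    data: IndicatorMatrix,
    spec: ModelSpec,
    n_starts: int,
    seed: int,
) -> list:
    """Random classification-style start values.

    Each start draws C distinct subjects as seeds, partitions all
    subjects to their nearest seed, and initializes free class means at
    the partition's group means with variances at the pooled
    within-group column variances (one k-means-style classification
    step). Fixed and tied mean cells are then overwritten per the spec,
    and proportions come from a flat Dirichlet. Starting from group
    means with within-group spread — rather than raw seed rows with the
    total column variance — keeps starts dispersed while avoiding the
    near-uniform posteriors that drive EM onto the collapsed-classes
    ridge.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    C = spec.n_classes
    if data.n < C:
        raise ValueError(f"need at least C={C} subjects, got n={data.n}")
    spec.validate_J(data.J)
    rng = np.random.default_rng(seed)
    y = data.values
    col_var = np.maximum(y.var(axis=0, ddof=0), 1e-12)
    starts = []
    for _ in range(n_starts):
        rows = rng.choice(data.n, size=C, replace=False)
        seeds = y[rows]
        d = ((y[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        labels = d.argmin(axis=1)
        means = seeds.copy()
        wss = np.zeros(data.J)
        for c in range(C):
            mask = labels == c
            if mask.any():
                means[c] = y[mask].mean(axis=0)
                wss += ((y[mask] - means[c]) ** 2).sum(axis=0)
        var = np.maximum(wss / data.n, 1e-3 * col_var)
        means = apply_restrictions(means, spec)
        pi = rng.dirichlet(np.ones(C))
        pi = np.maximum(pi, 1e-6)
        pi = pi / pi.sum()
        starts.append(ParameterSet(pi, means, var))
    return starts


def align_classes(params_a: ParameterSet, params_b: ParameterSet,
                  fixed_indices: tuple = ()) -> np.ndarray:
    """Permutation mapping classes of ``params_b`` onto ``params_a``.

    Minimizes the total squared distance between mean profiles,
    sum_c ||mu_a[c] − mu_b[perm[c]]||², solved exactly as an assignment
    problem. Fixed reference classes are constrained to map to
    themselves. Returns ``perm`` such that ``params_b.permuted(perm)``
    is aligned with ``params_a``.
    """
    if params_a.C != params_b.C or params_a.J != params_b.J:
        raise ValueError("parameter sets have mismatched dimensions")
    C = params_a.C
    free = [c for c in range(C) if c not in fixed_indices]
    perm = np.arange(C)
    if free:
        diff = params_a.means[free][:, None, :] - params_b.means[free][None, :, :]
        cost = (diff * diff).sum(axis=2)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            perm[free[r]] = free[c]
    return perm


def _same_mode(a: FittedModel, b: FittedModel, ll_tol: float,
               param_tol: float) -> bool:
    if abs(a.loglik - b.loglik) > ll_tol:
        return False
    perm = align_classes(a.params, b.params, a.spec.fixed_indices)
    pb = b.params.permuted(perm)
    diff = max(
        float(np.abs(a.params.means - pb.means).max()),
        float(np.abs(a.params.proportions - pb.proportions).max()),
        float(np.abs(a.params.variances - pb.variances).max()),
    )
    return diff <= param_tol


def group_modes(
    solutions: list,
    ll_tol: float = DEFAULT_LL_TOL,
    param_tol: float = DEFAULT_PARAM_TOL,
    start_indices: list | None = None,
) -> list:
    """Group converged solutions into modes (transitive closure), best first."""
    if not solutions:
        raise ValueError("group_modes needs at least one solution")
    if start_indices is None:
        start_indices = list(range(len(solutions)))
    # sort by LL so candidate pairs are adjacent; union-find for closure
    order = sorted(range(len(solutions)), key=lambda i: -solutions[i].loglik)
    parent = list(range(len(solutions)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for pos, i in enumerate(order):
        for jpos in range(pos + 1, len(order)):
            j = order[jpos]
            if solutions[i].loglik - solutions[j].loglik > ll_tol:
                break  # sorted: no later solution can be within ll_tol
            if find(i) == find(j):
                continue
            if _same_mode(solutions[i], solutions[j], ll_tol, param_tol):
                union(i, j)

    groups: dict = {}
    for i in range(len(solutions)):
        groups.setdefault(find(i), []).append(i)
    modes = []
    for members in groups.values():
        best = max(members, key=lambda i: solutions[i].loglik)
        modes.append(ModeGroup(
            representative=solutions[best],
            loglik=solutions[best].loglik,
            n_starts=len(members),
            members=sorted(start_indices[i] for i in members),
        ))
    modes.sort(key=lambda m: -m.loglik)
    return modes


def canonical_class_order(model: FittedModel) -> np.ndarray:
    """Presentation order: fixed classes first as declared, then free
    classes by descending proportion."""
    fixed = list(model.spec.fixed_indices)
    free = [c for c in range(model.params.C) if c not in fixed]
    free.sort(key=lambda c: -model.params.proportions[c])
    return np.array(fixed + free)


def run_multistart(
    data: IndicatorMatrix,
    spec: ModelSpec,
    n_starts: int = 1000,
    seed: int = 0,
    ll_tol: float = DEFAULT_LL_TOL,
    param_tol: float = DEFAULT_PARAM_TOL,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> MultistartResult:
    """Fit ``n_starts`` random starts and group the solutions into modes.

    Starts that raise (NaN likelihood) or fail to converge within
    ``max_iter`` count as failures; modes partition the remainder.
    """
    starts = generate_starts(data, spec, n_starts, seed)
    solutions, indices = [], []
    n_failed = 0
    for idx, init in enumerate(starts):
        try:
            fit = fit_em(data, spec, init, tol=tol, max_iter=max_iter)
        except EMError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        solutions.append(fit)
        indices.append(idx)
    if not solutions:
        raise EMError(f"all {n_starts} starts failed for C={spec.n_classes}")
    modes = group_modes(solutions, ll_tol, param_tol, start_indices=indices)
    return MultistartResult(
        modes=modes,
        n_starts_total=n_starts,
        n_failed=n_failed,
        seed=seed,
    )
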