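"""Fit indices, model comparison, stability diagnostics, and interpretation aids.

No single statistic is trusted to select the number of classes. The
reporting surface here deliberately puts loglikelihood, AIC, BIC,
relative entropy, convergence quality, class proportions and residual
variance side by side and leaves the selection to the analyst; the
:func:`compare_models` table never declares a winner.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import IndicatorMatrix
from .lpa import FittedModel, ModelSpec, ParameterSet, count_parameters
from .multistart import MultistartResult, run_multistart

__all__ = [
    "aic",
    "bic",
    "relative_entropy",
    "residual_variance_fractions",
    "high_posterior_fraction",
    "FitReport",
    "fit_report",
    "compare_models",
    "sensitivity_grid",
    "track_class_evolution",
    "back_transform",
]


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k − 2·LL."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return 2.0 * k - 2.0 * loglik


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion, k·ln(n) − 2·LL."""
    if k < 0 or n < 1:
        raise ValueError("need k >= 0 and n >= 1")
    return k * math.log(n) - 2.0 * loglik


def relative_entropy(posteriors: np.ndarray) -> float:
    """Relative entropy of the classification, E = 1 − H(tau)/(n ln C).

    1 means perfectly crisp posterior classification, 0 means the
    posteriors are uninformative (uniform). For a 1-class model the
    quantity is undefined and NaN is returned (fit tables leave the
    entry blank).
    """
    tau = np.asarray(posteriors, dtype=float)
    n, C = tau.shape
    if C == 1:
        return math.nan
    if not np.allclose(tau.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(tau > 0, -tau * np.log(tau), 0.0).sum()
    return 1.0 - h / (n * math.log(C))


def residual_variance_fractions(model: FittedModel,
                                data: IndicatorMatrix) -> np.ndarray:
    """Pooled residual variance as a fraction of each indicator's variance.

    Computed as sigma_hat_j^2 / sample variance (ddof=1) of indicator j;
    on standardized data this is simply sigma_hat_j^2. Values near 1 mean
    the class structure explains little of that indicator.
    """
    sample_var = data.values.var(axis=0, ddof=1)
    return model.params.variances / sample_var


def high_posterior_fraction(posteriors: np.ndarray,
                            threshold: float = 0.8) -> float:
    """Fraction of subjects whose largest membership probability exceeds
    ``threshold`` — a plain summary of classification crispness."""
    tau = np.asarray(posteriors, dtype=float)
    C = tau.shape[1]
    if not (1.0 / C < threshold < 1.0):
        warnings.warn(
            f"threshold {threshold} outside (1/C, 1) is uninformative",
            stacklevel=2,
        )
    return float((tau.max(axis=1) > threshold).mean())


@dataclass
class FitReport:
    """One model's full evaluation row."""

    n_classes: int
    k: int
    loglik: float
    aic: float
    bic: float
    entropy: float
    class_proportions: np.ndarray
    residual_variance_fraction: np.ndarray
    high_posterior_fraction: float
    boundary_flag: bool
    n: int
    n_modes: int | None = None
    top_mode_fraction: float | None = None

    def to_row(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "k": self.k,
            "n_modes": self.n_modes,
            "top_mode_fraction": self.top_mode_fraction,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "entropy": self.entropy,
            "min_proportion": float(np.min(self.class_proportions)),
            "max_proportion": float(np.max(self.class_proportions)),
            "high_posterior_fraction": self.high_posterior_fraction,
            "boundary_flag": self.boundary_flag,
        }


def fit_report(model: FittedModel, data: IndicatorMatrix,
               multistart: MultistartResult | None = None) -> FitReport:
    """Assemble the evaluation quantities for one fitted model."""
    k = count_parameters(model.spec, data.J)
    ll = model.loglik
    n = data.n
    return FitReport(
        n_classes=model.spec.n_classes,
        k=k,
        loglik=ll,
        aic=aic(ll, k),
        bic=bic(ll, k, n),
        entropy=relative_entropy(model.posteriors),
        class_proportions=model.params.proportions.copy(),
        residual_variance_fraction=residual_variance_fractions(model, data),
        high_posterior_fraction=high_posterior_fraction(model.posteriors)
        if model.posteriors.shape[1] > 1 else 1.0,
        boundary_flag=model.boundary_flag,
        n=n,
        n_modes=multistart.n_modes if multistart is not None else None,
        top_mode_fraction=multistart.top_mode_fraction
        if multistart is not None else None,
    )


def compare_models(reports: list) -> pd.DataFrame:
    """Side-by-side table of fit reports; never declares a single winner.

    Rows are ordered by class count regardless of input order, so the
    table is invariant to how the models were supplied.
    """
    ns = {r.n for r in reports}
    if len(ns) > 1:
        raise ValueError(f"models were fitted on different sample sizes: {ns}")
    rows = [r.to_row() for r in reports]
    df = pd.DataFrame(rows).sort_values(["n_classes", "k"]).reset_index(drop=True)
    return df


def sweep_classes(
    data: IndicatorMatrix,
    class_range,
    n_starts: int = 1000,
    seed: int = 0,
    spec_factory=None,
    **ms_kwargs,
):
    """Multistart fits over a range of class counts.

    ``spec_factory(C, J)`` builds the spec per class count (default:
    unrestricted). Returns (list of FitReport, list of MultistartResult).
    """
    from .lpa import ModelSpec as _MS

    if spec_factory is None:
        spec_factory = lambda C, J: _MS(n_classes=C)  # noqa: E731
    reports, results = [], []
    for offset, C in enumerate(class_range):
        spec = spec_factory(C, data.J)
        ms = run_multistart(data, spec, n_starts=n_starts,
                            seed=seed + offset, **ms_kwargs)
        reports.append(fit_report(ms.best, data, ms))
        results.append(ms)
    return reports, results


def sensitivity_grid(
    data: IndicatorMatrix,
    base_spec: ModelSpec,
    reference_levels: list,
    n_starts: int = 1000,
    seed: int = 0,
    **ms_kwargs,
) -> pd.DataFrame:
    """Refit the two-reference-class model over a grid of reference means.

    Each level ``(low, high)`` replaces the constants of the two fixed
    classes (all indicators set to the same value within a class) and the
    full multistart analysis is repeated. Well-chosen reference values
    should beat grossly misspecified ones on AIC and BIC; levels where
    every start fails are reported as no-convergence rows rather than
    raised.
    """
    if len(base_spec.fixed_classes) != 2:
        raise ValueError("sensitivity grid requires a spec with two fixed classes")
    from .lpa import EMError

    (c_lo, _), (c_hi, _) = base_spec.fixed_classes
    rows = []
    for offset, (low, high) in enumerate(reference_levels):
        spec = ModelSpec(
            n_classes=base_spec.n_classes,
            fixed_classes=((c_lo, (low,) * data.J), (c_hi, (high,) * data.J)),
            equality_groups=base_spec.equality_groups,
        )
        row = {"low": low, "high": high,
               "k": count_parameters(spec, data.J)}
        try:
            ms = run_multistart(data, spec, n_starts=n_starts,
                                seed=seed + offset, **ms_kwargs)
        except EMError:
            row.update({"converged": False, "n_modes": None,
                        "top_mode_fraction": None, "loglik": None,
                        "aic": None, "bic": None, "entropy": None})
            rows.append(row)
            continue
        rep = fit_report(ms.best, data, ms)
        row.update({
            "converged": True,
            "n_modes": ms.n_modes,
            "top_mode_fraction": ms.top_mode_fraction,
            "loglik": rep.loglik,
            "aic": rep.aic,
            "bic": rep.bic,
            "entropy": rep.entropy,
        })
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StabilityMap:
    """Matched classes and proportion trajectories across model sizes."""

    matches: pd.DataFrame      # per consecutive pair: class match + distance
    proportions: pd.DataFrame  # matched-proportion trajectory table


def track_class_evolution(models: list) -> StabilityMap:
    """Trace how classes persist as the class count grows.

    For each consecutive pair of models (sorted by C), classes of the
    smaller model are matched to classes of the larger one by mean-profile
    distance; the output records each match's distance and how matched
    classes' proportions drift. A recurring class whose proportion shrinks
    as new classes appear is the signature of subjects peeling off into
    the new classes.
    """
    models = sorted(models, key=lambda m: m.spec.n_classes)
    match_rows = []
    # chain matches so classes can be traced from the smallest model up
    labels = {0: {c: c for c in range(models[0].params.C)}}
    for step in range(len(models) - 1):
        a, b = models[step], models[step + 1]
        Ca, Cb = a.params.C, b.params.C
        diff = a.params.means[:, None, :] - b.params.means[None, :, :]
        cost = np.sqrt((diff * diff).sum(axis=2))
        from scipy.optimize import linear_sum_assignment

        rows_i, cols_i = linear_sum_assignment(cost)
        labels[step + 1] = {}
        for r, c in zip(rows_i, cols_i):
            match_rows.append({
                "from_C": Ca, "to_C": Cb,
                "class_small": int(r), "class_large": int(c),
                "distance": float(cost[r, c]),
                "proportion_small": float(a.params.proportions[r]),
                "proportion_large": float(b.params.proportions[c]),
            })
            labels[step + 1][c] = labels[step].get(r)
        for c in range(Cb):
            labels[step + 1].setdefault(c, None)

    prop_rows = []
    for step, model in enumerate(models):
        row = {"n_classes": model.spec.n_classes}
        for c in range(model.params.C):
            lineage = labels[step].get(c)
            key = f"class_{lineage}" if lineage is not None else f"new_at_C{model.spec.n_classes}_{c}"
            row[key] = float(model.params.proportions[c])
        prop_rows.append(row)
    return StabilityMap(
        matches=pd.DataFrame(match_rows),
        proportions=pd.DataFrame(prop_rows),
    )


def back_transform(params: ParameterSet, data: IndicatorMatrix) -> pd.DataFrame:
    """Map standardized class means back to the raw metric, with percentiles.

    Each cell reports mu_cj · SD_j + mean_j and the normal-CDF percentile
    100·Phi(z). Percentiles assume norm-referenced standardized scores and
    are interpretive aids, not inferential quantities.
    """
    if data.raw_means is None or data.raw_sds is None:
        raise ValueError(
            "data carries no raw-scale moments; standardize() records them"
        )
    rows = []
    for c in range(params.C):
        for j, name in enumerate(data.indicator_names):
            z = params.means[c, j]
            rows.append({
                "class": c,
                "indicator": name,
                "z_mean": z,
                "raw_mean": z * data.raw_sds[j] + data.raw_means[j],
                "percentile": 100.0 * norm.cdf(z),
            })
    return pd.DataFrame(rows)
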