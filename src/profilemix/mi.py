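"""Multiple-imputation extension of a fitted class structure to new indicators.

Once a class structure has been established on a well-understood primary
indicator set, secondary indicators (e.g. resting EEG band powers) can be
profiled by class without refitting a joint mixture — which in small
samples tends to be unstable and lets the new indicators overpower the
established structure. Instead, subjects are repeatedly assigned to
classes by sampling from their posterior membership probabilities; each
draw yields per-class means and standard errors for the secondary
indicators, and the D draws are combined with Rubin's rules so the final
intervals reflect both class-membership uncertainty and sampling error
of the means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .data import IndicatorMatrix

__all__ = [
    "PooledEstimate",
    "draw_class_assignments",
    "imputation_estimates",
    "pool_rubin",
    "extend_model",
    "theta_beta_ratios",
]

DEFAULT_N_IMPUTATIONS = 20


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of one (class, indicator) mean across draws.

    total variance T = W̄ + (1 + 1/D)·B, where W̄ is the average
    within-draw variance of the mean and B the between-draw variance of
    the draw means. The 95% interval uses a t reference with
    Barnard–Rubin small-sample degrees of freedom.
    """

    class_index: int
    indicator: str
    pooled_mean: float
    within_var: float
    between_var: float
    total_var: float
    dof: float
    ci_low: float
    ci_high: float
    n_draws_used: int
    mean_class_size: float


def draw_class_assignments(posteriors: np.ndarray, seed: int) -> np.ndarray:
    """Sample one class per subject from its posterior membership row.

    A subject with posterior 0.90 for a class lands in that class in
    about 90% of draws; one-hot posteriors make the draw deterministic.
    """
    tau = np.asarray(posteriors, dtype=float)
    if not np.allclose(tau.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(tau, axis=1)
    u = rng.random(tau.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def imputation_estimates(
    secondary: IndicatorMatrix, assignments: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class means and squared standard errors for one assignment draw.

    Returns ``(means, var_of_mean, class_sizes)`` each of shape (C, J2) /
    (C, J2) / (C,). A class that is empty — or has a single member, whose
    standard error is undefined — gets NaN entries for that draw.
    """
    y = secondary.values
    n, J2 = y.shape
    z = np.asarray(assignments)
    if z.shape[0] != n:
        raise ValueError("assignments and secondary data disagree on n")
    means = np.full((n_classes, J2), np.nan)
    var_of_mean = np.full((n_classes, J2), np.nan)
    sizes = np.zeros(n_classes)
    for c in range(n_classes):
        mask = z == c
        m = int(mask.sum())
        sizes[c] = m
        if m >= 1:
            means[c] = y[mask].mean(axis=0)
        if m >= 2:
            s2 = y[mask].var(axis=0, ddof=1)
            var_of_mean[c] = s2 / m
    return means, var_of_mean, sizes


def pool_rubin(
    draw_means: np.ndarray,
    draw_vars: np.ndarray,
    class_index: int,
    indicator: str,
    mean_class_size: float,
    ci_level: float = 0.95,
) -> PooledEstimate:
    """Combine one (class, indicator) mean across imputation draws.

    ``draw_means``/``draw_vars`` are 1-d arrays over draws; NaN draws
    (class empty or singleton in that draw) are dropped and the usable
    count reported. Degrees of freedom follow the Barnard–Rubin
    small-sample adjustment, with the complete-data dof taken as the
    average class size minus one.
    """
    ok = np.isfinite(draw_means) & np.isfinite(draw_vars)
    means = np.asarray(draw_means, dtype=float)[ok]
    wvars = np.asarray(draw_vars, dtype=float)[ok]
    D = means.size
    if D < 2:
        raise ValueError(
            f"class {class_index}, indicator {indicator!r}: only {D} usable "
            "draws; need at least 2 to apply Rubin's rules"
        )
    qbar = float(means.mean())
    wbar = float(wvars.mean())
    b = float(means.var(ddof=1))
    total = wbar + (1.0 + 1.0 / D) * b

    nu_com = max(mean_class_size - 1.0, 1.0)
    if b > 0 and total > 0:
        lam = (1.0 + 1.0 / D) * b / total
        nu_old = (D - 1) / lam**2
        nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
        if nu_obs > 0:
            dof = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
        else:
            # lam = 1: variance entirely between draws; classical MI dof
            dof = nu_old
    else:
        # no between-draw variation: plain t interval on the within part
        dof = nu_com
    half = float(t_dist.ppf(0.5 + ci_level / 2.0, dof)) * np.sqrt(total)
    return PooledEstimate(
        class_index=class_index,
        indicator=indicator,
        pooled_mean=qbar,
        within_var=wbar,
        between_var=b,
        total_var=total,
        dof=float(dof),
        ci_low=qbar - half,
        ci_high=qbar + half,
        n_draws_used=D,
        mean_class_size=mean_class_size,
    )


def extend_model(
    secondary: IndicatorMatrix,
    posteriors: np.ndarray,
    D: int = DEFAULT_N_IMPUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Class profiles of secondary indicators via D imputation draws.

    Returns one row per (class, indicator) with the pooled mean, the
    Rubin variance decomposition, and a 95% interval.
    """
    tau = np.asarray(posteriors, dtype=float)
    if tau.shape[0] != secondary.n:
        raise ValueError("secondary data and posteriors disagree on subjects")
    C = tau.shape[1]
    J2 = secondary.J
    all_means = np.empty((D, C, J2))
    all_vars = np.empty((D, C, J2))
    all_sizes = np.empty((D, C))
    rng = np.random.default_rng(seed)
    for d in range(D):
        z = draw_class_assignments(tau, seed=int(rng.integers(2**31)))
        all_means[d], all_vars[d], all_sizes[d] = imputation_estimates(
            secondary, z, C
        )
    rows = []
    for c in range(C):
        for j, name in enumerate(secondary.indicator_names):
            est = pool_rubin(
                all_means[:, c, j], all_vars[:, c, j],
                class_index=c, indicator=name,
                mean_class_size=float(all_sizes[:, c].mean()),
            )
            rows.append(est.__dict__)
    return pd.DataFrame(rows)


def theta_beta_ratios(
    power: pd.DataFrame,
    theta: str = "theta",
    low_beta: str = "low_beta",
    high_beta: str = "high_beta",
) -> pd.DataFrame:
    """Per-subject log theta:beta power ratios.

    Computed from raw (untransformed) absolute band powers and then
    log-transformed: ratio 1 pairs theta with low beta, ratio 2 with
    high beta. The pairing is configurable via the column-name
    arguments, since band labelling conventions differ.
    """
    for col in (theta, low_beta, high_beta):
        if col not in power.columns:
            raise ValueError(f"band {col!r} not in power table")
        if (power[col] <= 0).any():
            raise ValueError(f"non-positive raw power in band {col!r}")
    return pd.DataFrame({
        "theta_beta_1": np.log(power[theta] / power[low_beta]),
        "theta_beta_2": np.log(power[theta] / power[high_beta]),
    }, index=power.index)
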