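"""End-to-end workflow orchestration with a reproducibility manifest.

The pipeline runs the full small-sample profile-analysis workflow:
preprocessing, an unrestricted class-count sweep, restricted
re-estimation with two reference classes, a reference-mean sensitivity
grid, a multi-criteria selection report (no automatic winner), and the
optional secondary-indicator extension and external-variable analyses.
Every run directory carries a manifest recording inputs, seeds, and
package version so any exported number can be recomputed.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import read_indicator_csv, standardize
from .lpa import ModelSpec, two_reference_spec
from .evaluation import compare_models, sensitivity_grid, sweep_classes
from .mi import extend_model

from .regression import external_binary_by_class

logger = logging.getLogger("profilemix")

__all__ = ["RunConfig", "run_pipeline", "load_model_spec", "save_model_spec"]

DEFAULT_SENSITIVITY_LEVELS = [(-0.5, 0.5), (0.0, 1.0), (-1.0, 1.0),
                              (-2.0, 2.0), (-2.0, -1.0)]


@dataclass
class RunConfig:
    """Inputs and settings for one pipeline run. Seed is mandatory."""

    data_path: str
    out_dir: str
    seed: int
    secondary_path: str | None = None
    binary_path: str | None = None
    class_range: tuple = (1, 8)
    restricted_range: tuple = (2, 7)
    reference_low: float = -0.5
    reference_high: float = 0.5
    sensitivity_levels: list = field(
        default_factory=lambda: list(DEFAULT_SENSITIVITY_LEVELS))
    n_starts: int = 1000
    n_imputations: int = 20
    ll_tol: float = 0.01
    param_tol: float = 0.05
    standardize_input: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError(
                "a seed is required: every stochastic stage (start values, "
                "imputation draws) must be reproducible"
            )


def load_model_spec(path) -> ModelSpec:
    """Read a ModelSpec from YAML or JSON."""
    text = Path(path).read_text()
    d = yaml.safe_load(text)
    return ModelSpec.from_dict(d)


def save_model_spec(spec: ModelSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict()))


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    A stage that fails leaves earlier outputs in place and records the
    failure in the manifest rather than discarding the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "inputs": {"data": str(config.data_path),
                   "secondary": config.secondary_path,
                   "binary": config.binary_path},
        "settings": {
            "class_range": list(config.class_range),
            "restricted_range": list(config.restricted_range),
            "reference": [config.reference_low, config.reference_high],
            "sensitivity_levels": [list(t) for t in config.sensitivity_levels],
            "n_starts": config.n_starts,
            "n_imputations": config.n_imputations,
            "ll_tol": config.ll_tol,
            "param_tol": config.param_tol,
            "entropy_formula": "1 - sum(-tau ln tau) / (n ln C)",
            "start_scheme": "seeded-partition+dirichlet",
        },
        "stages": {},
    }

    def record(stage, status, **extra):
        manifest["stages"][stage] = {"status": status, **extra}
        _write_json(out / "manifest.json", manifest)

    data = read_indicator_csv(config.data_path)
    if config.standardize_input:
        data = standardize(data)
    record("preprocess", "ok", provenance=data.log)

    best_restricted = None
    ms_kwargs = dict(n_starts=config.n_starts, ll_tol=config.ll_tol,
                     param_tol=config.param_tol)

    try:
        lo, hi = config.class_range
        reports, _ = sweep_classes(data, range(lo, hi + 1), seed=config.seed,
                                   **ms_kwargs)
        sweep_df = compare_models(reports)
        sweep_df.to_csv(out / "sweep_unrestricted.csv", index=False)
        record("unrestricted_sweep", "ok", n_rows=len(sweep_df))
    except Exception as exc:  # noqa: BLE001 — manifest records the failure
        logger.exception("unrestricted sweep failed")
        record("unrestricted_sweep", "failed", error=str(exc))

    try:
        lo, hi = config.restricted_range
        factory = lambda C, J: two_reference_spec(  # noqa: E731
            C, J, config.reference_low, config.reference_high)
        reports, results = sweep_classes(
            data, range(lo, hi + 1), seed=config.seed + 1000,
            spec_factory=factory, **ms_kwargs)
        rest_df = compare_models(reports)
        rest_df.to_csv(out / "sweep_restricted.csv", index=False)
        # the multi-criteria report names each criterion's favourite and
        # flags disagreement; it never auto-selects
        best = {
            "aic_best_C": int(rest_df.loc[rest_df.aic.idxmin(), "n_classes"]),
            "bic_best_C": int(rest_df.loc[rest_df.bic.idxmin(), "n_classes"]),
            "entropy_best_C": int(
                rest_df.loc[rest_df.entropy.idxmax(), "n_classes"]),
            "convergence_best_C": int(
                rest_df.loc[rest_df.top_mode_fraction.idxmax(), "n_classes"]),
        }
        best["criteria_agree"] = len(set(best.values())) == 1
        _write_json(out / "selection_report.json", best)
        # keep the best-AIC restricted model for downstream stages
        idx = int(rest_df.aic.idxmin())
        best_restricted = results[idx].best
        record("restricted_sweep", "ok", n_rows=len(rest_df), **best)
    except Exception as exc:  # noqa: BLE001
        logger.exception("restricted sweep failed")
        record("restricted_sweep", "failed", error=str(exc))

    try:
        C_sens = best_restricted.spec.n_classes if best_restricted is not None \
            else max(config.restricted_range[0], 5)
        base = two_reference_spec(C_sens, data.J, config.reference_low,
                                  config.reference_high)
        sens = sensitivity_grid(data, base, config.sensitivity_levels,
                                n_starts=config.n_starts,
                                seed=config.seed + 2000,
                                ll_tol=config.ll_tol,
                                param_tol=config.param_tol)
        sens.to_csv(out / "sensitivity.csv", index=False)
        record("sensitivity", "ok", n_rows=len(sens))
    except Exception as exc:  # noqa: BLE001
        logger.exception("sensitivity grid failed")
        record("sensitivity", "failed", error=str(exc))

    if config.secondary_path and best_restricted is not None:
        try:
            secondary = read_indicator_csv(config.secondary_path)
            if config.standardize_input:
                secondary = standardize(secondary)
            ext = extend_model(secondary, best_restricted.posteriors,
                               D=config.n_imputations,
                               seed=config.seed + 3000)
            ext.to_csv(out / "extension.csv", index=False)
            record("extension", "ok", n_rows=len(ext))
        except Exception as exc:  # noqa: BLE001
            logger.exception("MI extension failed")
            record("extension", "failed", error=str(exc))

    if config.binary_path and best_restricted is not None:
        try:
            bin_df = pd.read_csv(config.binary_path, index_col=0)
            ext = external_binary_by_class(
                bin_df.iloc[:, 0].to_numpy(), best_restricted.posteriors,
                D=config.n_imputations, seed=config.seed + 4000)
            ext.to_csv(out / "external_binary.csv", index=False)
            record("external_binary", "ok", n_rows=len(ext))
        except Exception as exc:  # noqa: BLE001
            logger.exception("external binary analysis failed")
            record("external_binary", "failed", error=str(exc))

    if best_restricted is not None:
        _write_json(out / "best_restricted_model.json",
                    best_restricted.to_dict())
        np.savetxt(out / "best_restricted_posteriors.csv",
                   best_restricted.posteriors, delimiter=",")
    return out
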