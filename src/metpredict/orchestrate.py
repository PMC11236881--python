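"""End-to-end pipeline: configuration and the full model-comparison run.

Produces, for every requested (model, n_sc, prediction mode) combination, a
leave-one-location-out CV result, collected into a single comparison table
(one row per combination: MSEPD, mean rank correlation and its standard
error) written as CSV and JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .datatypes import MODEL_CATALOGUE, CVResult
from .io import (
    convert_means_to_tonnes,
    drop_genotypes_without_pedigree,
    read_ec_table,
    read_means,
    read_pedigree,
    read_plot_data,
)
from .kinship import numerator_relationship
from .predict import cross_validate_model
from .stage1 import ConvergenceError, FitControls, fit_stage1

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full comparison run.

    Exactly one of ``plots`` (Stage I input) or ``means`` (Stage II input)
    must be given. Unknown keys in a config file are rejected.
    """

    plots: Optional[str] = None
    means: Optional[str] = None
    pedigree: Optional[str] = None
    ec: Optional[str] = None
    models: list[str] = field(default_factory=lambda: list(MODEL_CATALOGUE))
    n_sc: list[int] = field(default_factory=lambda: [1])
    fa_order: Optional[int] = None          # None -> AIC path over FA(1..3)
    prediction_modes: list[str] = field(default_factory=lambda: ["main_effect"])
    max_iter: int = 2000
    seed: int = 0
    strict: bool = False
    outdir: str = "results"

    def __post_init__(self) -> None:
        if (self.plots is None) == (self.means is None):
            raise ValueError("give exactly one of 'plots' or 'means'")
        unknown = [m for m in self.models if m not in MODEL_CATALOGUE]
        if unknown:
            raise ValueError(f"unknown model id(s): {unknown}")
        if any(n not in (0, 1, 2) for n in self.n_sc):
            raise ValueError("n_sc entries must be 0, 1 or 2")
        bad = [m for m in self.prediction_modes
               if m not in ("main_effect", "main_plus_avg_interaction")]
        if bad:
            raise ValueError(f"unknown prediction mode(s): {bad}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _needs_sc(model_id: str) -> bool:
    return MODEL_CATALOGUE[model_id][2]


def run_full_comparison(config: RunConfig) -> pd.DataFrame:
    """Run the requested model suite under leave-one-location-out CV.

    Returns the comparison table and writes ``comparison.csv`` /
    ``comparison.json`` under ``config.outdir``. Failures of individual
    cells are reported in the table and do not stop the run unless
    ``config.strict``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    controls = FitControls(max_iter=config.max_iter)
    if config.plots is not None:
        trials = read_plot_data(config.plots)
        log.info("Stage I: fitting %d locations", len(trials))
        _, mean_sets = fit_stage1(trials, controls)
    else:
        mean_sets = convert_means_to_tonnes(read_means(config.means), "t/ha")
    A = None
    if config.pedigree is not None:
        A = numerator_relationship(read_pedigree(config.pedigree))
        mean_sets, dropped = drop_genotypes_without_pedigree(mean_sets, A)
        if dropped:
            log.info("dropped between stages (no pedigree): %s", dropped)
    ec = read_ec_table(config.ec) if config.ec is not None else None

    rows = []
    results: list[CVResult] = []
    for model_id in config.models:
        sc_counts = [n for n in config.n_sc if n > 0] if _needs_sc(model_id) else [0]
        for n_sc in sc_counts:
            for mode in config.prediction_modes:
                label = f"{model_id}/nsc={n_sc}/{mode}"
                try:
                    if _needs_sc(model_id) and ec is None:
                        raise ValueError("model needs an EC table")
                    if MODEL_CATALOGUE[model_id][0] == "kinship" and A is None:
                        raise ValueError("model needs a pedigree")
                    res = cross_validate_model(
                        mean_sets, model_id, n_sc=n_sc,
                        fa_order=config.fa_order, prediction_mode=mode,
                        A=A, ec=ec, controls=controls, strict=config.strict)
                except (ConvergenceError, ValueError) as e:
                    if config.strict:
                        raise
                    log.error("cell %s failed: %s", label, e)
                    rows.append({"model": model_id, "n_sc": n_sc, "mode": mode,
                                 "msepd": float("nan"), "mean_rho": float("nan"),
                                 "se_rho": float("nan"), "failed_folds": "ALL",
                                 "error": str(e)})
                    continue
                results.append(res)
                rows.append({"model": model_id, "n_sc": n_sc, "mode": mode,
                             "msepd": res.msepd, "mean_rho": res.mean_rho,
                             "se_rho": res.se_rho,
                             "failed_folds": ",".join(res.failed_folds),
                             "error": ""})
                log.info("%s: MSEPD=%.5f mean_rho=%.4f (se %.3f)",
                         label, res.msepd, res.mean_rho, res.se_rho)
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "comparison.csv", index=False)
    with open(outdir / "comparison.json", "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)
    return table
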