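"""Orchestration of the full simulation study: generate, fit, evaluate.

For every condition x replication, one dataset is generated, the two models of
interest are fitted to it (traits+ERS "ignoring faking" and traits+ERS+faking
"accounting for faking"), MAP scores are computed, and recovery statistics are
appended to a tidy results table.  Runs are resumable: replications whose
result file already exists are skipped.
"""

from __future__ import annotations

import json
import logging
import platform
import zlib
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import StudyConfig
from .estimate import FitOptions, build_weight_matrices, fit, score_map
from .evaluate import correlation_bias, correlation_rmse, generalized_eta_squared, person_recovery
from .simulate import (
    SimulationCondition,
    enumerate_design,
    make_model_spec,
    simulate_dataset,
)

__all__ = ["run_replication", "run_study", "effect_size_table"]

logger = logging.getLogger("mnrm.study")

MODEL_LABELS = ("ignoring_faking", "accounting_faking")


def _fit_options(cfg: StudyConfig, seed: int) -> FitOptions:
    f = cfg.fit
    return FitOptions(
        algorithm=f.algorithm,
        n_burnin=f.n_burnin,
        mh_draws=f.mh_draws,
        tol=f.tol,
        window=f.window,
        max_cycles=f.max_cycles,
        quad_nodes=f.quad_nodes,
        loglik_mc_draws=f.loglik_mc_draws,
        seed=seed,
    )


def run_replication(
    condition: SimulationCondition,
    master_seed: int,
    weight_noise_scale: float = 0.5,
    fit_options: Optional[Dict[str, FitOptions]] = None,
) -> List[Dict]:
    """Simulate one replication, fit both models, return tidy result rows."""
    responses, truth = simulate_dataset(condition, master_seed)
    rep = condition.replication or 0
    seed_base = zlib.crc32(f"{master_seed}|{condition.label()}".encode()) % (2 ** 31)
    rows: List[Dict] = []
    traits = list(range(5))
    for label in MODEL_LABELS:
        include_faking = label == "accounting_faking"
        spec = make_model_spec(
            condition.items_per_trait, include_ers=True, include_faking=include_faking
        )
        weights = build_weight_matrices(
            spec,
            trajectories=dict(zip(spec.item_ids, truth.trajectories)),
            noise_scale=weight_noise_scale if include_faking else 0.0,
            seed=seed_base + rep,
        )
        opts = (fit_options or {}).get(label) or FitOptions(seed=seed_base + rep + 1)
        result = fit(responses, spec, weights, options=opts)
        theta = score_map(responses, result)
        rec = person_recovery(
            theta.values[:, traits], truth.persons.values[:, traits]
        )
        rows.append(
            {
                "composition": condition.composition_id,
                "items_per_trait": condition.items_per_trait,
                "n_persons": condition.n_persons,
                "ers_present": condition.ers_present,
                "faking_impact": condition.faking_impact,
                "replication": rep,
                "model": label,
                "mean_recovery_r": rec.mean_back_transformed,
                "mean_recovery_z": float(rec.fisher_z.mean()),
                "bias_rep": correlation_bias(result.sigma, truth.latent.covariance),
                "rmse_rep": correlation_rmse(result.sigma, truth.latent.covariance),
                "loglik": result.loglik,
                "n_params": result.n_params,
                "converged": result.converged,
            }
        )
    return rows


def run_study(cfg: StudyConfig) -> Path:
    """Run the configured design; returns the output directory.

    Results are written per replication (JSON) so interrupted runs resume
    without recomputation, then aggregated into ``results.csv``.  Partial
    failures are logged and the run continues.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "effective_config.json").write_text(cfg.model_dump_json(indent=1))
    (out / "environment.json").write_text(
        json.dumps(
            {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "master_seed": cfg.master_seed,
            },
            indent=1,
        )
    )
    runs = enumerate_design(
        compositions=cfg.compositions,
        items_per_trait=cfg.items_per_trait,
        sample_sizes=cfg.sample_sizes,
        ers_levels=cfg.ers_levels,
        faking_impacts=cfg.faking_impacts,
        replications=cfg.replications,
    )
    failures = 0
    for condition in runs:
        rep_file = out / f"{condition.label()}.json"
        if rep_file.exists():
            logger.info("skipping completed %s", rep_file.name)
            continue
        try:
            opts = {
                label: _fit_options(cfg, cfg.master_seed + i)
                for i, label in enumerate(MODEL_LABELS)
            }
            rows = run_replication(
                condition,
                cfg.master_seed,
                weight_noise_scale=cfg.weight_noise_scale,
                fit_options=opts,
            )
            rep_file.write_text(json.dumps(rows, indent=1))
        except Exception:  # noqa: BLE001 - study runs continue past failures
            failures += 1
            logger.exception("replication %s failed", condition.label())
    all_rows: List[Dict] = []
    for f in sorted(out.glob("comp*.json")):
        all_rows.extend(json.loads(f.read_text()))
    if all_rows:
        pd.DataFrame(all_rows).to_csv(out / "results.csv", index=False)
    if failures:
        logger.warning("%d replications failed", failures)
    (out / "summary.json").write_text(
        json.dumps({"n_runs": len(runs), "n_failures": failures}, indent=1)
    )
    return out


def effect_size_table(results: pd.DataFrame, dv: str = "mean_recovery_z") -> pd.Series:
    """Generalized eta-squared per effect of the mixed factorial design."""
    between = [
        c
        for c in (
            "composition",
            "items_per_trait",
            "n_persons",
            "ers_present",
            "faking_impact",
        )
        if results[c].nunique() > 1
    ]
    return generalized_eta_squared(
        results, dv=dv, between=between, within="model", subject="replication"
    )
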