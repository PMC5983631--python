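"""End-to-end orchestration: fit -> scan -> cluster -> screen -> concurrent.

The stage parameters default to the standard screening constants: over/under folds 4
and 0.25, effective-pair threshold 0.9, fit acceptance r^2 0.95, three
enzyme groups, four metabolite clusters (so a singleton like PEP can
split off), integrator tolerances 1e-6/1e-9.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .calibration import fit_vmax
from .errors import DataError
from .gmea import (
    cluster_groups,
    concurrent_modification,
    effective_pairs,
    modification_scan,
)
from .io import (
    load_observed_profiles,
    load_protein_table,
    packaged_protein_table,
    read_model_config,
    write_json,
    write_profiles,
    write_reduction_matrix,
)
from .network import build_model, simulate_profiles
from .proteomics import select_candidates, time_average_ratios
from .synthetic import SyntheticSpec, generate_model, generate_profiles, soybean_network

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("floodmet")


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full pipeline run."""

    model_config: str | None = None  # None -> packaged soybean network
    profiles: str | None = None  # None -> synthetic profiles from the model
    protein_tables: tuple = ()  # empty -> packaged Tables fixture
    out_dir: str = "floodmet_run"
    over_fold: float = 4.0
    under_fold: float = 0.25
    effective_threshold: float = 0.9
    r2_accept: float = 0.95
    k_enzymes: int = 3
    k_metabolites: int = 4
    vmax_bounds: tuple = (1.0 / 50.0, 50.0)
    n_restarts: int = 5
    rtol: float = 1e-6
    atol: float = 1e-9
    noise_cv: float = 0.05
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write results + a machine-readable manifest.

    Outputs in ``out_dir``: fit.json, profiles_fitted.csv,
    reduction_matrix.csv + reduction_direction.csv, grouping.json,
    effective_pairs.json, time_average_ratios.csv, candidates.json,
    concurrent.json and manifest.json.  A stage failure is recorded in
    the manifest and re-raised; completed outputs stay on disk.
    Deterministic for a fixed seed and config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "floodmet",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.digest(),
        "stages": {},
    }

    def done(stage, **info):
        manifest["stages"][stage] = {"status": "ok", **info}
        write_json(manifest, out / "manifest.json")
        log.info("[%s] done %s", stage, info)

    try:
        # --- inputs -------------------------------------------------------
        if config.model_config:
            model = read_model_config(config.model_config)
        else:
            model = build_model(soybean_network())
        spec = SyntheticSpec(seed=config.seed, noise_cv=config.noise_cv)
        if config.profiles:
            observed = load_observed_profiles(config.profiles)
        else:
            observed = generate_profiles(model, spec)
        done("inputs", n_pools=len(model.pools), n_reactions=len(model.reactions),
             n_observations=len(observed.data))

        # --- fit ----------------------------------------------------------
        fit = fit_vmax(
            model, observed, bounds=config.vmax_bounds, seed=config.seed,
            n_restarts=config.n_restarts, rtol=config.rtol, atol=config.atol,
        )
        fitted = fit.fitted_model
        write_json(fit.to_dict() | {"r2_accept": config.r2_accept,
                                    "accepted": fit.r2 >= config.r2_accept},
                   out / "fit.json")
        write_profiles(simulate_profiles(fitted), out / "profiles_fitted.csv")
        done("fit", r2=fit.r2, accepted=bool(fit.r2 >= config.r2_accept))

        # --- scan ---------------------------------------------------------
        matrix = modification_scan(fitted, config.over_fold, config.under_fold)
        write_reduction_matrix(matrix, out / "reduction_matrix.csv",
                               out / "reduction_direction.csv")
        pairs = effective_pairs(matrix, config.effective_threshold)
        write_json({"threshold": config.effective_threshold,
                    "pairs": sorted(map(list, pairs))}, out / "effective_pairs.json")
        done("scan", shape=list(matrix.values.shape), n_effective_pairs=len(pairs))

        # --- cluster ------------------------------------------------------
        grouping = cluster_groups(matrix, config.k_enzymes, config.k_metabolites)
        write_json(grouping.to_dict(), out / "grouping.json")
        done("cluster", enzyme_groups={k: len(v) for k, v in grouping.enzyme_groups.items()})

        # --- screen -------------------------------------------------------
        if config.protein_tables:
            table = load_protein_table(*config.protein_tables)
        else:
            table = packaged_protein_table()
        ratios = time_average_ratios(table)
        ratios.table.to_csv(out / "time_average_ratios.csv")
        candidates = select_candidates(ratios, grouping)
        write_json(candidates.to_dict(), out / "candidates.json")
        done("screen", candidates=candidates.reactions)

        # --- concurrent ---------------------------------------------------
        if not candidates.members:
            raise DataError("screen selected no candidates; concurrent stage undefined")
        report = concurrent_modification(fitted, candidates)
        write_json(report.to_dict(), out / "concurrent.json")
        done("concurrent", average_reduction_ratio=report.average_reduction_ratio,
             n_reduced=len(report.reduced_set))
    except Exception as exc:
        stage = "inputs"
        for name in ("inputs", "fit", "scan", "cluster", "screen", "concurrent"):
            if name not in manifest["stages"]:
                stage = name
                break
        manifest["stages"][stage] = {"status": "failed", "error": str(exc),
                                     "error_type": type(exc).__name__}
        write_json(manifest, out / "manifest.json")
        raise
    return out
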