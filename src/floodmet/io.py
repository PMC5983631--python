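"""File formats: model configs (JSON/TOML), tidy CSV tables, result JSON.

Observed soybean flooding metabolite profiles are deposited at
"proteome.dc.affrc.go.jp/Soybean/metabo/metabolism_tbl.html" (and the
proteomics at ProteomeXchange PXD005680); this package never downloads
them — ``load_observed_profiles`` reads the same tidy CSV layout from a
local path, and the synthetic module generates stand-ins.

CSV dialect: comma-separated, UTF-8, mandatory header row, "." decimal
separator.  Floats in JSON are written with 12 significant digits.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ExperimentalProfileSet, FitResult
from .errors import ConfigError, DataError
from .gmea import ClusterGrouping, ConcurrentReport, ReductionMatrix
from .network import MetabolicModel, TemporalProfile, build_model
from .proteomics import CandidateSet, ProteinRatioTable, TimeAverageRatios

__all__ = [
    "read_model_config",
    "write_model_config",
    "load_observed_profiles",
    "write_profiles",
    "load_protein_table",
    "packaged_protein_table",
    "write_reduction_matrix",
    "read_reduction_matrix",
    "write_json",
    "round_floats",
]

#: where the deposited metabolite tables live (documentation only)
DEPOSITED_PROFILE_URL = "proteome.dc.affrc.go.jp/Soybean/metabo/metabolism_tbl.html"


def round_floats(obj, sig: int = 12):
    """Recursively format floats to ``sig`` significant digits for JSON."""
    if isinstance(obj, dict):
        return {k: round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(obj, path):
    Path(path).write_text(json.dumps(round_floats(obj), indent=1) + "\n")


def read_model_config(path) -> MetabolicModel:
    """Read and validate a model config (JSON or TOML by suffix)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"model config not found: {path}")
    try:
        if path.suffix.lower() == ".toml":
            config = tomllib.loads(path.read_text())
        else:
            config = json.loads(path.read_text())
    except (json.JSONDecodeError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"{path}: cannot parse: {exc}") from exc
    try:
        return build_model(config)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_model_config(model: MetabolicModel, path):
    """Serialise a model to a JSON config; inverse of read_model_config."""
    config = {
        "pools": [
            {
                "id": p.id,
                "name": p.name,
                "initial_amount": p.initial_amount,
                "is_target_fitting": p.is_target_fitting,
                "role": p.role,
            }
            for p in model.pools.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "enzyme_name": r.enzyme_name,
                "substrates": [[p, c] for p, c in r.substrates],
                "products": [[p, c] for p, c in r.products],
                "km": dict(r.km),
                "vmax": r.vmax,
                "pathway": r.pathway,
                "modifiable": r.modifiable,
            }
            for r in model.reactions.values()
        ],
        "horizon_days": model.horizon_days,
        "output_grid": list(model.output_grid),
    }
    write_json(config, path)


def load_observed_profiles(path) -> ExperimentalProfileSet:
    """Read observed metabolite profiles from tidy CSV.

    Columns: condition, metabolite, day, amount (nmol/g DW).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"profile file not found: {path}")
    table = pd.read_csv(path)
    return ExperimentalProfileSet(data=table)


def write_profiles(profiles, path):
    """Write profiles (TemporalProfile or ExperimentalProfileSet) as tidy CSV."""
    if isinstance(profiles, TemporalProfile):
        table = profiles.to_tidy()
    else:
        table = profiles.data
    table.to_csv(path, index=False)


def load_protein_table(*paths) -> ProteinRatioTable:
    """Read one or more protein ratio CSVs and concatenate them."""
    frames = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise DataError(f"protein table not found: {path}")
        frames.append(pd.read_csv(path))
    return ProteinRatioTable(data=pd.concat(frames, ignore_index=True))


def packaged_protein_table() -> ProteinRatioTable:
    """The packaged per-reaction abundance-ratio fixture (all four conditions)."""
    import importlib.resources as resources

    root = resources.files("floodmet.data")
    frames = [
        pd.read_csv(root.joinpath(name).open())
        for name in ("protein_ratios_flooded.csv", "protein_ratios_tolerant.csv")
    ]
    return ProteinRatioTable(data=pd.concat(frames, ignore_index=True))


def write_reduction_matrix(matrix: ReductionMatrix, values_path, direction_path=None):
    matrix.values.to_csv(values_path)
    if direction_path is not None:
        matrix.direction.to_csv(direction_path)


def read_reduction_matrix(values_path, direction_path=None) -> ReductionMatrix:
    values = pd.read_csv(values_path, index_col=0)
    values.index.name, values.columns.name = "reaction", "metabolite"
    if direction_path is not None:
        direction = pd.read_csv(direction_path, index_col=0)
        direction.index.name, direction.columns.name = "reaction", "metabolite"
    else:
        direction = values.map(lambda _: "over")
    return ReductionMatrix(values=values, direction=direction)


def fit_result_json(result: FitResult) -> dict:
    return result.to_dict()


def grouping_json(grouping: ClusterGrouping) -> dict:
    return grouping.to_dict()


def candidates_json(candidates: CandidateSet) -> dict:
    return candidates.to_dict()


def concurrent_json(report: ConcurrentReport) -> dict:
    return report.to_dict()


def time_average_csv(ratios: TimeAverageRatios, path):
    ratios.table.to_csv(path)
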