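"""Synthetic ground-truth models, metabolite time courses and protein tables.

Every pipeline stage can be exercised without the deposited study data:
``generate_model`` draws a kinetically randomised model on either the
full soybean topology or a small linear-chain toy; ``generate_profiles``
turns a model into noisy observed time courses (multiplicative lognormal
noise, sampled on days 1–4, matching a 1–4-day flooding design with the
day-0 state known); ``generate_protein_table`` builds an abundance-ratio
table in which chosen candidate reactions carry the flood-tolerant
signature (protein maintained in U, A and M relative to F) and all other
reactions are guaranteed to fail the screen filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .network import MetabolicModel, build_model, simulate_profiles
from .calibration import ExperimentalProfileSet
from .gmea import ClusterGrouping
from .proteomics import PROTEIN_CONDITIONS, ProteinRatioTable

__all__ = [
    "SyntheticSpec",
    "generate_model",
    "generate_profiles",
    "generate_protein_table",
    "soybean_network",
]

AMOUNT_FLOOR = 1e-6


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    noise_cv is the coefficient of variation of multiplicative lognormal
    observation noise on metabolite amounts (default 0.05, a stand-in
    for unknown biological variance); tolerant_effect is the fold by
    which planted candidate proteins track the unstressed rather than
    the flooded level (>= 1); n_timepoints post-treatment observations
    per condition.
    """

    seed: int = 0
    network_size: str = "soybean"
    noise_cv: float = 0.05
    tolerant_effect: float = 2.0
    n_timepoints: int = 4
    replicates: int = 1

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ParameterError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.tolerant_effect < 1:
            raise ParameterError(
                f"tolerant_effect must be >= 1, got {self.tolerant_effect}"
            )
        if self.network_size not in ("soybean", "toy"):
            raise ParameterError(f"unknown network_size {self.network_size!r}")
        if self.n_timepoints < 1 or self.replicates < 1:
            raise ParameterError("n_timepoints and replicates must be >= 1")


def soybean_network() -> dict:
    """Parsed packaged soybean network config (synthetic parameterization)."""
    import importlib.resources as resources
    import json

    ref = resources.files("floodmet.data").joinpath("soybean_network_synthetic.json")
    return json.loads(ref.read_text())


def _toy_config(rng: np.random.Generator) -> dict:
    """A small source -> A -> B -> C -> sink chain, all pools targets."""
    inits = {"A": 50.0, "B": 30.0, "C": 20.0}
    pools = [
        {"id": p, "name": p, "initial_amount": v, "is_target_fitting": True}
        for p, v in inits.items()
    ]
    reactions = [
        {"id": "SRC", "enzyme_name": "source", "substrates": [], "products": [["A", 1.0]],
         "km": {}, "vmax": 100.0, "pathway": "linker", "modifiable": False},
        {"id": "T1", "enzyme_name": "A to B", "substrates": [["A", 1.0]],
         "products": [["B", 1.0]], "km": {"A": 50.0}, "vmax": 200.0,
         "pathway": "glycolysis", "modifiable": True},
        {"id": "T2", "enzyme_name": "B to C", "substrates": [["B", 1.0]],
         "products": [["C", 1.0]], "km": {"B": 30.0}, "vmax": 190.0,
         "pathway": "glycolysis", "modifiable": True},
        {"id": "SINK", "enzyme_name": "C sink", "substrates": [["C", 1.0]],
         "products": [], "km": {"C": 100.0}, "vmax": 500.0,
         "pathway": "linker", "modifiable": False},
    ]
    return {"pools": pools, "reactions": reactions, "horizon_days": 4.0}


def generate_model(spec: SyntheticSpec) -> MetabolicModel:
    """Draw a ground-truth model on the requested topology.

    Km values are redrawn log-uniformly over [0.1, 10] x the substrate's
    initial amount, Vmax log-uniformly over [0.5, 5] x the carbohydrate
    source flux; boundary source rates stay at their configured values
    so the scale of the system is anchored.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    config = soybean_network() if spec.network_size == "soybean" else _toy_config(rng)
    inits = {p["id"]: max(p["initial_amount"], 1.0) for p in config["pools"]}
    sources = [r for r in config["reactions"] if not r["substrates"]]
    source_flux = max(r["vmax"] for r in sources) if sources else 100.0
    for rxn in config["reactions"]:
        if not rxn["substrates"]:
            continue  # keep boundary source rates fixed
        rxn["vmax"] = float(source_flux * 10.0 ** rng.uniform(np.log10(0.5), np.log10(5.0)))
        rxn["km"] = {
            pid: float(inits[pid] * 10.0 ** rng.uniform(-1.0, 1.0))
            for pid, _ in rxn["substrates"]
        }
    return build_model(config)


def generate_profiles(
    model: MetabolicModel, spec: SyntheticSpec, condition: str = "flooded"
) -> ExperimentalProfileSet:
    """Simulate the model and observe it with multiplicative noise.

    Samples days 1..n_timepoints, multiplies each amount by a lognormal
    factor with the requested CV (noise_cv = 0 reproduces the simulation
    exactly), floors amounts at 1e-6 so the log transform stays defined.
    """
    rng = np.random.default_rng(spec.seed + 1)
    profile = simulate_profiles(model, condition=condition)
    days = np.arange(1.0, spec.n_timepoints + 1.0)
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    rows = []
    for metabolite in model.pool_ids:
        sim = np.interp(days, profile.days, profile.amount(metabolite))
        for _rep in range(spec.replicates):
            if sigma > 0:
                noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=days.size))
            else:
                noise = np.ones_like(days)
            for day, amount in zip(days, np.maximum(sim * noise, AMOUNT_FLOOR)):
                rows.append(
                    {
                        "condition": condition,
                        "metabolite": metabolite,
                        "day": float(day),
                        "amount": float(amount),
                    }
                )
    return ExperimentalProfileSet(data=pd.DataFrame(rows))


def generate_protein_table(
    spec: SyntheticSpec,
    grouping: ClusterGrouping | None = None,
    planted_candidates=(),
    reactions=None,
) -> ProteinRatioTable:
    """Build a protein ratio table with planted flood-tolerance candidates.

    Flooded (F) ratios wander near 1.  For each planted candidate the U,
    A and M series are the F level scaled by ~tolerant_effect, rescaled
    so each condition's time average is exactly its drawn effect (> 1
    when tolerant_effect > 1).  Every non-candidate has its U series
    forced below the F average, so only planted reactions can pass the
    all-three-ratios > 1 screen filter.
    """
    rng = np.random.default_rng(spec.seed + 2)
    if reactions is None:
        if grouping is not None:
            reactions = sorted(
                (r for ms in grouping.enzyme_groups.values() for r in ms),
                key=lambda r: (len(r), r),
            )
        else:
            reactions = [
                r["id"] for r in soybean_network()["reactions"] if r["modifiable"]
            ]
    planted = set(planted_candidates)
    unknown = planted - set(reactions)
    if unknown:
        raise ParameterError(f"planted candidates not in reaction set: {sorted(unknown)}")
    n = spec.n_timepoints
    rows = []

    def emit(rid, cond, series):
        rows.append(
            {"reaction_id": rid, "protein_id": f"SYN.{rid}", "description": "synthetic",
             "condition": cond, "time_point": 0, "time_label": "baseline", "ratio": 1.0}
        )
        for t, v in enumerate(series, start=1):
            rows.append(
                {"reaction_id": rid, "protein_id": f"SYN.{rid}",
                 "description": "synthetic", "condition": cond, "time_point": t,
                 "time_label": f"t{t}", "ratio": float(max(v, 1e-6))}
            )

    for rid in reactions:
        f_series = np.exp(rng.normal(0.0, 0.15, size=n))
        f_mean = float(f_series.mean())
        emit(rid, "F", f_series)
        if rid in planted:
            for cond in ("U", "A", "M"):
                effect = spec.tolerant_effect ** rng.uniform(0.8, 1.2)
                raw = f_mean * np.exp(rng.normal(0.0, 0.1, size=n))
                series = raw * (effect * f_mean / raw.mean())
                emit(rid, cond, series)
        else:
            # U held strictly below the flooded average: filter must fail
            u_series = f_series * rng.uniform(0.4, 0.95)
            emit(rid, "U", u_series)
            for cond in ("A", "M"):
                emit(rid, cond, np.exp(rng.normal(0.0, 0.3, size=n)))
    return ProteinRatioTable(data=pd.DataFrame(rows))
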