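"""Metabolic network data model and Michaelis–Menten ODE simulation.

The network is a set of metabolite pools (amounts in nmol per g dry
weight) coupled by irreversible enzyme reactions.  Each reaction follows
an irreversible Michaelis–Menten rate law; a reaction with several
substrates multiplies the saturation terms:

    v = Vmax * prod_s  S_s / (Km_s + S_s)

A reaction with no substrates is a constant boundary source (v = Vmax);
a reaction with no products drains to a boundary sink.  Time is measured
in days after stress onset; the default horizon is 4 days sampled every
half day, matching a 1–4-day flooding design.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigError, LookupError_, ParameterError, SimulationError

__all__ = [
    "MetabolitePool",
    "ReactionSpec",
    "MetabolicModel",
    "ModificationScenario",
    "TemporalProfile",
    "mm_rate",
    "build_model",
    "apply_modification",
    "simulate_profiles",
    "accumulation_auc",
    "DEFAULT_GRID",
]

#: default output grid, days after stress onset
DEFAULT_GRID = tuple(np.arange(0.0, 4.0 + 1e-9, 0.5))

PATHWAYS = ("glycolysis", "fermentation", "tca", "gaba_shunt", "linker")
ROLES = ("internal", "boundary_source", "boundary_sink")


@dataclass(frozen=True)
class MetabolitePool:
    """A metabolite pool.

    Parameters
    ----------
    id : str
        Short symbol, e.g. ``"G6P"``.
    name : str
        Human-readable name.
    initial_amount : float
        Amount at day 0, nmol per g dry weight; must be >= 0.
    is_target_fitting : bool
        Whether the pool is one of the fitting-target metabolites whose
        simulated trajectory is calibrated against observed data.
    role : str
        ``internal``, ``boundary_source`` or ``boundary_sink``.
    """

    id: str
    name: str = ""
    initial_amount: float = 0.0
    is_target_fitting: bool = False
    role: str = "internal"

    def __post_init__(self):
        if self.initial_amount < 0:
            raise ConfigError(
                f"pool {self.id!r}: initial_amount must be >= 0, "
                f"got {self.initial_amount}"
            )
        if self.role not in ROLES:
            raise ConfigError(f"pool {self.id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class ReactionSpec:
    """An irreversible Michaelis–Menten reaction.

    ``substrates`` and ``products`` are tuples of ``(pool_id, stoich)``;
    ``km`` maps each substrate pool id to its Michaelis constant (same
    unit as pool amounts).  ``vmax`` is in nmol/g DW per day.
    """

    id: str
    enzyme_name: str = ""
    substrates: tuple = ()
    products: tuple = ()
    km: dict = field(default_factory=dict)
    vmax: float = 1.0
    pathway: str = "linker"
    modifiable: bool = False

    def __post_init__(self):
        object.__setattr__(self, "substrates", tuple((str(p), float(c)) for p, c in self.substrates))
        object.__setattr__(self, "products", tuple((str(p), float(c)) for p, c in self.products))
        if self.vmax <= 0:
            raise ConfigError(f"reaction {self.id!r}: vmax must be > 0, got {self.vmax}")
        if self.pathway not in PATHWAYS:
            raise ConfigError(f"reaction {self.id!r}: unknown pathway {self.pathway!r}")
        for pool_id, _ in self.substrates:
            if pool_id not in self.km:
                raise ConfigError(
                    f"reaction {self.id!r}: missing km for substrate {pool_id!r}"
                )
            if self.km[pool_id] <= 0:
                raise ConfigError(
                    f"reaction {self.id!r}: km for {pool_id!r} must be > 0, "
                    f"got {self.km[pool_id]}"
                )


@dataclass(frozen=True)
class ModificationScenario:
    """Vmax fold multipliers applied to named reactions.

    Reactions not listed keep fold 1 (wild type).  Overexpression is a
    fold > 1, suppression a fold in (0, 1).
    """

    folds: dict = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        for rid, fold in self.folds.items():
            if fold <= 0:
                raise ParameterError(
                    f"scenario {self.label!r}: fold for {rid!r} must be > 0, got {fold}"
                )


@dataclass
class MetabolicModel:
    """Pools + reactions + simulation horizon.

    ``pools`` and ``reactions`` are insertion-ordered dicts keyed by id.
    """

    pools: dict
    reactions: dict
    horizon_days: float = 4.0
    output_grid: tuple = DEFAULT_GRID

    # -- structure queries -------------------------------------------------
    @property
    def pool_ids(self):
        return list(self.pools)

    @property
    def modifiable_reactions(self):
        return [r.id for r in self.reactions.values() if r.modifiable]

    @property
    def target_pools(self):
        return [p.id for p in self.pools.values() if p.is_target_fitting]

    def initial_state(self):
        return np.array([p.initial_amount for p in self.pools.values()], float)

    def validate(self):
        """Check the MetabolicModel invariants; raise ConfigError on failure."""
        for rxn in self.reactions.values():
            for pool_id, _ in rxn.substrates + rxn.products:
                if pool_id not in self.pools:
                    raise ConfigError(
                        f"reaction {rxn.id!r} references undefined pool {pool_id!r}"
                    )
        g = nx.Graph()
        g.add_nodes_from(self.pools)
        for rxn in self.reactions.values():
            members = [p for p, _ in rxn.substrates + rxn.products]
            for a, b in zip(members, members[1:]):
                g.add_edge(a, b)
        if len(self.pools) > 1 and not nx.is_connected(g):
            parts = sorted(len(c) for c in nx.connected_components(g))
            raise ConfigError(
                f"stoichiometric graph is not connected (component sizes {parts})"
            )
        return self

    def copy(self):
        return copy.deepcopy(self)

    # -- compiled arrays for the ODE right-hand side -----------------------
    def _compiled(self):
        """Flat arrays for a vectorised rate evaluation.

        Each reaction owns a contiguous segment of (pool index, Km)
        entries; substrate-free boundary sources get one dummy entry
        (index -1) whose saturation term is fixed at 1, so a single
        ``multiply.reduceat`` yields every reaction's saturation product.
        """
        index = {pid: i for i, pid in enumerate(self.pools)}
        rxns = list(self.reactions.values())
        n_pools, n_rxn = len(index), len(rxns)
        stoich = np.zeros((n_pools, n_rxn))
        vmax = np.empty(n_rxn)
        sub_idx, km_flat, starts = [], [], []
        for j, rxn in enumerate(rxns):
            vmax[j] = rxn.vmax
            starts.append(len(sub_idx))
            if rxn.substrates:
                for pool_id, coef in rxn.substrates:
                    stoich[index[pool_id], j] -= coef
                    sub_idx.append(index[pool_id])
                    km_flat.append(rxn.km[pool_id])
            else:
                sub_idx.append(-1)
                km_flat.append(1.0)
            for pool_id, coef in rxn.products:
                stoich[index[pool_id], j] += coef
        return (
            stoich,
            vmax,
            np.array(sub_idx, int),
            np.array(km_flat, float),
            np.array(starts, int),
        )


def mm_rate(vmax, km_per_substrate, substrate_amounts):
    """Irreversible Michaelis–Menten rate with multiplicative saturation.

    Parameters
    ----------
    vmax : float
        Maximal rate, > 0.
    km_per_substrate : sequence of float
        One Michaelis constant per substrate, all > 0.
    substrate_amounts : sequence of float
        Current substrate amounts, all >= 0; same length as the Km list.

    Returns
    -------
    float
        ``vmax * prod_s S_s / (Km_s + S_s)``, bounded by [0, vmax] and
        monotone nondecreasing in each substrate amount.
    """
    if vmax <= 0:
        raise ParameterError(f"vmax must be > 0, got {vmax}")
    km = np.atleast_1d(np.asarray(km_per_substrate, float))
    s = np.atleast_1d(np.asarray(substrate_amounts, float))
    if km.shape != s.shape:
        raise ParameterError("km and substrate lists differ in length")
    if np.any(km <= 0):
        raise ParameterError("all km must be > 0")
    if np.any(s < 0):
        raise ParameterError("substrate amounts must be >= 0")
    return float(vmax * np.prod(s / (km + s)))


def build_model(network_config: dict) -> MetabolicModel:
    """Materialise a :class:`MetabolicModel` from a parsed config mapping.

    The config has a ``pools`` array and a ``reactions`` array whose
    entries mirror the :class:`MetabolitePool` / :class:`ReactionSpec`
    fields; ``horizon_days`` and ``output_grid`` are optional.
    """
    if not isinstance(network_config, dict):
        raise ConfigError("network config must be a mapping")
    for key in ("pools", "reactions"):
        if key not in network_config or not isinstance(network_config[key], list):
            raise ConfigError(f"network config must contain a {key!r} array")

    pools = {}
    for i, entry in enumerate(network_config["pools"]):
        try:
            pool = MetabolitePool(**entry)
        except TypeError as exc:
            raise ConfigError(f"/pools/{i}: {exc}") from exc
        if pool.id in pools:
            raise ConfigError(f"/pools/{i}: duplicate pool id {pool.id!r}")
        pools[pool.id] = pool

    reactions = {}
    for i, entry in enumerate(network_config["reactions"]):
        entry = dict(entry)
        entry["substrates"] = [tuple(x) for x in entry.get("substrates", [])]
        entry["products"] = [tuple(x) for x in entry.get("products", [])]
        try:
            rxn = ReactionSpec(**entry)
        except TypeError as exc:
            raise ConfigError(f"/reactions/{i}: {exc}") from exc
        if rxn.id in reactions:
            raise ConfigError(f"/reactions/{i}: duplicate reaction id {rxn.id!r}")
        reactions[rxn.id] = rxn

    model = MetabolicModel(
        pools=pools,
        reactions=reactions,
        horizon_days=float(network_config.get("horizon_days", 4.0)),
        output_grid=tuple(network_config.get("output_grid", DEFAULT_GRID)),
    )
    return model.validate()


def apply_modification(
    model: MetabolicModel, scenario: ModificationScenario
) -> MetabolicModel:
    """Return a new model with each listed reaction's Vmax multiplied by its fold.

    Over/under-expression of an enzyme is mimicked by scaling the Vmax of
    its reaction; the input model is left untouched.
    """
    for rid in scenario.folds:
        if rid not in model.reactions:
            raise LookupError_(f"scenario {scenario.label!r}: unknown reaction {rid!r}")
    new_reactions = {}
    for rid, rxn in model.reactions.items():
        fold = scenario.folds.get(rid, 1.0)
        new_reactions[rid] = replace(rxn, vmax=rxn.vmax * fold) if fold != 1.0 else rxn
    return MetabolicModel(
        pools=dict(model.pools),
        reactions=new_reactions,
        horizon_days=model.horizon_days,
        output_grid=model.output_grid,
    )


@dataclass
class TemporalProfile:
    """Simulated or observed metabolite amounts on a day grid.

    ``amounts`` is a DataFrame indexed by day with one column per pool.
    """

    amounts: pd.DataFrame
    condition: str = "flooded"

    @property
    def days(self):
        return self.amounts.index.to_numpy(float)

    def amount(self, pool_id):
        if pool_id not in self.amounts.columns:
            raise LookupError_(f"pool {pool_id!r} not in profile")
        return self.amounts[pool_id].to_numpy(float)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format view with columns condition, metabolite, day, amount."""
        long = self.amounts.reset_index(names="day").melt(
            id_vars="day", var_name="metabolite", value_name="amount"
        )
        long.insert(0, "condition", self.condition)
        return long[["condition", "metabolite", "day", "amount"]]


def simulate_profiles(
    model: MetabolicModel,
    initial_state=None,
    horizon: float | None = None,
    condition: str = "flooded",
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> TemporalProfile:
    """Integrate the network ODEs and sample the output grid.

    Uses a stiff-capable solver (LSODA) at rtol 1e-6 / atol 1e-9; Km
    values can span orders of magnitude.  Tiny negative excursions from
    integration error are clipped to 0 in the output.
    """
    if horizon is None:
        horizon = model.horizon_days
    if horizon <= 0:
        raise ParameterError(f"horizon must be > 0, got {horizon}")
    y0 = (
        model.initial_state()
        if initial_state is None
        else np.asarray(initial_state, float)
    )
    if y0.shape != (len(model.pools),) or np.any(y0 < 0):
        raise ParameterError("initial_state must be nonnegative, one value per pool")

    stoich, vmax, sub_idx, km_flat, starts = model._compiled()
    dummy = sub_idx < 0

    def rhs(_t, y):
        s = np.maximum(y[sub_idx], 0.0)
        sat = s / (km_flat + s)
        sat[dummy] = 1.0  # substrate-free boundary source
        return stoich @ (vmax * np.multiply.reduceat(sat, starts))

    grid = np.asarray([d for d in model.output_grid if d <= horizon + 1e-12], float)
    if grid.size < 2:
        grid = np.array([0.0, horizon])
    sol = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        y0,
        method="LSODA",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SimulationError(f"integration failed at t={last:.4g}: {sol.message}", last)
    amounts = pd.DataFrame(
        np.maximum(sol.y.T, 0.0), index=pd.Index(sol.t, name="day"),
        columns=list(model.pools),
    )
    return TemporalProfile(amounts=amounts, condition=condition)


def accumulation_auc(profile: TemporalProfile, pool_id) -> float:
    """Area under a pool's temporal profile (amount x days), trapezoidal.

    This is the accumulation measure behind the reduction-ratio
    statistic; exact for piecewise-linear profiles.
    """
    y = profile.amount(pool_id)
    if len(y) < 2:
        raise ParameterError("profile needs at least 2 grid points for an area")
    return float(np.trapezoid(y, profile.days))
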