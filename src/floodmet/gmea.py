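"""Genetic modification effectiveness analysis (GMEA).

Each modifiable enzyme is virtually over-expressed (4x Vmax) and
suppressed (0.25x Vmax); for every fitting-target metabolite the
accumulation reduction ratio

    ratio = AUC(modified profile) / AUC(unmodified profile)

is computed over the shared 0–4-day output grid, and per cell the
smaller of the two directions is kept (ties go to over-expression).
The resulting enzymes x metabolites matrix is clustered hierarchically
(centroid linkage, Euclidean distance, raw ratios) into enzyme groups
E1..Ek and metabolite groups M1..Mk plus singletons; cells below 0.9
are flagged as effective enzyme–metabolite pairs.

A concurrent scenario applies several candidate folds in one
simulation; its effect is 1 minus the average reduction ratio over the
target metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import LookupError_, NumericalError, ParameterError
from .network import (
    MetabolicModel,
    ModificationScenario,
    TemporalProfile,
    accumulation_auc,
    apply_modification,
    simulate_profiles,
)

__all__ = [
    "ReductionMatrix",
    "ClusterGrouping",
    "ConcurrentReport",
    "reduction_ratio",
    "modification_scan",
    "cluster_groups",
    "effective_pairs",
    "concurrent_modification",
]

OVER_FOLD = 4.0
UNDER_FOLD = 0.25
EFFECTIVE_THRESHOLD = 0.9


@dataclass
class ReductionMatrix:
    """Accumulation reduction ratios, reactions x metabolites.

    ``values``: DataFrame, rows = modifiable reaction ids, columns =
    target metabolite ids.  ``direction``: same shape, "over"/"under",
    recording which fold produced each (min-selected) cell.
    """

    values: pd.DataFrame
    direction: pd.DataFrame
    over_fold: float = OVER_FOLD
    under_fold: float = UNDER_FOLD

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ParameterError("reduction ratios must be >= 0")
        if not self.values.index.equals(self.direction.index) or not (
            self.values.columns.equals(self.direction.columns)
        ):
            raise ParameterError("values and direction must share index/columns")

    @property
    def reactions(self):
        return list(self.values.index)

    @property
    def metabolites(self):
        return list(self.values.columns)


def _auc_vector(profile: TemporalProfile, pools):
    return np.array([accumulation_auc(profile, p) for p in pools])


def reduction_ratio(
    model: MetabolicModel,
    scenario: ModificationScenario,
    pool_id: str,
    baseline_profile: TemporalProfile | None = None,
) -> float:
    """AUC ratio (modified / unmodified) of one metabolite under a scenario.

    Both areas are measured over the identical output grid and horizon;
    a ratio below 1 means the modification reduces accumulation.
    """
    if pool_id not in model.pools:
        raise LookupError_(f"unknown pool {pool_id!r}")
    base = baseline_profile or simulate_profiles(model)
    denom = accumulation_auc(base, pool_id)
    if denom == 0:
        raise NumericalError(
            f"unmodified AUC of {pool_id!r} is 0; reduction ratio undefined"
        )
    modified = simulate_profiles(apply_modification(model, scenario))
    return float(accumulation_auc(modified, pool_id) / denom)


def modification_scan(
    model: MetabolicModel,
    over_fold: float = OVER_FOLD,
    under_fold: float = UNDER_FOLD,
) -> ReductionMatrix:
    """Scan every modifiable enzyme at the over- and under-expression folds.

    Per (enzyme, metabolite) cell the smaller reduction ratio of the two
    directions is selected and the direction recorded; equal ratios are
    recorded as "over".
    """
    if over_fold <= 0 or under_fold <= 0:
        raise ParameterError("folds must be > 0")
    reactions = model.modifiable_reactions
    if not reactions:
        raise ParameterError("model has no modifiable reactions to scan")
    targets = model.target_pools
    baseline = simulate_profiles(model)
    base_auc = _auc_vector(baseline, targets)
    if np.any(base_auc == 0):
        zero = [t for t, a in zip(targets, base_auc) if a == 0]
        raise NumericalError(f"unmodified AUC is 0 for {zero}; scan undefined")

    values = np.empty((len(reactions), len(targets)))
    direction = np.empty((len(reactions), len(targets)), dtype=object)
    for i, rid in enumerate(reactions):
        try:
            over = simulate_profiles(
                apply_modification(model, ModificationScenario({rid: over_fold}))
            )
            under = simulate_profiles(
                apply_modification(model, ModificationScenario({rid: under_fold}))
            )
        except NumericalError as exc:
            raise NumericalError(f"scan failed for reaction {rid!r}: {exc}") from exc
        r_over = _auc_vector(over, targets) / base_auc
        r_under = _auc_vector(under, targets) / base_auc
        take_under = r_under < r_over  # tie -> over
        values[i] = np.where(take_under, r_under, r_over)
        direction[i] = np.where(take_under, "under", "over")
    idx = pd.Index(reactions, name="reaction")
    cols = pd.Index(targets, name="metabolite")
    return ReductionMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        direction=pd.DataFrame(direction, index=idx, columns=cols),
        over_fold=over_fold,
        under_fold=under_fold,
    )


@dataclass
class ClusterGrouping:
    """Partitions of enzymes and metabolites from hierarchical clustering.

    ``enzyme_groups`` maps labels E1..Ek to reaction id lists (E1 is the
    group with the smallest mean reduction ratio, i.e. the strongest
    reducers).  ``metabolite_groups`` maps M1..Mk to metabolite lists,
    ordered the same way; clusters beyond the k largest stay as
    singleton groups labelled by the metabolite id (the place a lone
    metabolite such as PEP can occupy).
    """

    enzyme_groups: dict
    metabolite_groups: dict
    enzyme_linkage: np.ndarray | None = None
    metabolite_linkage: np.ndarray | None = None

    def group_of_reaction(self, rid):
        for label, members in self.enzyme_groups.items():
            if rid in members:
                return label
        raise LookupError_(f"reaction {rid!r} not in any enzyme group")

    def group_of_metabolite(self, mid):
        for label, members in self.metabolite_groups.items():
            if mid in members:
                return label
        raise LookupError_(f"metabolite {mid!r} not in any metabolite group")

    def to_dict(self):
        return {
            "enzyme_groups": {k: list(v) for k, v in self.enzyme_groups.items()},
            "metabolite_groups": {
                k: list(v) for k, v in self.metabolite_groups.items()
            },
        }


def _cluster_axis(matrix: np.ndarray, items, k: int, prefix: str, n_major: int):
    """Centroid-linkage clusters of matrix rows; labels ordered by mean value.

    The ``n_major`` largest clusters get ``prefix``1..``prefix``n labels
    (ascending mean cell value = strongest effect first); smaller
    clusters become singleton-style groups labelled by their members.
    """
    if k < 1 or k > len(items):
        raise ParameterError(
            f"cluster count {k} invalid for {len(items)} items"
        )
    if k == len(items):
        assignments = np.arange(1, k + 1)
        linkage = None
    else:
        linkage = hierarchy.linkage(matrix, method="centroid", metric="euclidean")
        assignments = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    clusters = {}
    for item, c in zip(items, assignments):
        clusters.setdefault(int(c), []).append(item)
    means = {
        c: float(matrix[[items.index(i) for i in members]].mean())
        for c, members in clusters.items()
    }
    # majors: largest clusters (ties broken by mean then first member)
    order_major = sorted(
        clusters, key=lambda c: (-len(clusters[c]), means[c], clusters[c][0])
    )
    majors = sorted(order_major[:n_major], key=lambda c: (means[c], clusters[c][0]))
    groups = {}
    for rank, c in enumerate(majors, start=1):
        groups[f"{prefix}{rank}"] = clusters[c]
    for c in sorted(set(clusters) - set(majors), key=lambda c: clusters[c][0]):
        members = clusters[c]
        label = members[0] if len(members) == 1 else "+".join(members)
        groups[label] = members
    return groups, linkage


def cluster_groups(
    matrix: ReductionMatrix, k_enzymes: int = 3, k_metabolites: int = 4
) -> ClusterGrouping:
    """Cluster the reduction matrix into enzyme and metabolite groups.

    Agglomerative centroid linkage on Euclidean distances of the raw
    ratio vectors (rows for enzymes, columns for metabolites), cut at
    ``k_enzymes`` / ``k_metabolites`` clusters.  The metabolite cut
    keeps the three largest clusters as M1–M3 and leaves the rest as
    singleton groups.
    """
    vals = matrix.values.to_numpy(float)
    if np.isnan(vals).any():
        raise ParameterError("reduction matrix has missing cells")
    enzyme_groups, enz_link = _cluster_axis(
        vals, matrix.reactions, k_enzymes, "E", n_major=k_enzymes
    )
    met_groups, met_link = _cluster_axis(
        vals.T, matrix.metabolites, k_metabolites, "M", n_major=min(3, k_metabolites)
    )
    return ClusterGrouping(
        enzyme_groups=enzyme_groups,
        metabolite_groups=met_groups,
        enzyme_linkage=enz_link,
        metabolite_linkage=met_link,
    )


def effective_pairs(matrix: ReductionMatrix, threshold: float = EFFECTIVE_THRESHOLD):
    """All (reaction, metabolite) pairs with reduction ratio strictly below threshold."""
    if not 0 < threshold <= 1:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    mask = matrix.values < threshold
    return {
        (rid, mid)
        for rid in matrix.reactions
        for mid in matrix.metabolites
        if mask.at[rid, mid]
    }


@dataclass
class ConcurrentReport:
    """Per-metabolite outcome of a concurrent multi-enzyme modification."""

    ratios: dict
    reduced_set: list
    average_reduction_ratio: float
    effect: float
    scenario: ModificationScenario = field(default=None)

    def to_dict(self):
        return {
            "ratios": {k: float(v) for k, v in self.ratios.items()},
            "reduced_set": list(self.reduced_set),
            "average_reduction_ratio": float(self.average_reduction_ratio),
            "effect": float(self.effect),
            "folds": dict(self.scenario.folds) if self.scenario else {},
        }


def concurrent_modification(model: MetabolicModel, candidate_folds) -> ConcurrentReport:
    """Simulate all candidate Vmax folds in a single concurrent scenario.

    ``candidate_folds`` maps reaction id -> fold (a ``CandidateSet``
    from the proteomic screen exposes ``.folds``).  Reports the
    per-target reduction ratios, the metabolites reduced (ratio < 1),
    their arithmetic mean over all targets, and effect = 1 - mean.
    """
    folds = dict(getattr(candidate_folds, "folds", candidate_folds))
    scenario = ModificationScenario(folds=folds, label="concurrent")
    targets = model.target_pools
    baseline = simulate_profiles(model)
    base_auc = _auc_vector(baseline, targets)
    if np.any(base_auc == 0):
        zero = [t for t, a in zip(targets, base_auc) if a == 0]
        raise NumericalError(f"unmodified AUC is 0 for {zero}")
    modified = simulate_profiles(apply_modification(model, scenario))
    ratios = dict(zip(targets, _auc_vector(modified, targets) / base_auc))
    reduced = [m for m in targets if ratios[m] < 1.0]
    avg = float(np.mean([ratios[m] for m in targets]))
    return ConcurrentReport(
        ratios={k: float(v) for k, v in ratios.items()},
        reduced_set=reduced,
        average_reduction_ratio=avg,
        effect=1.0 - avg,
        scenario=scenario,
    )
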