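"""Proteomics-guided candidate selection.

Protein abundance per reaction is expressed as a ratio to a shared
2-day-old unstressed baseline, for four conditions: U (unstressed wild
type), F (flooded wild type), A (ABA-treated flooded) and M
(flood-tolerant mutant, flooded), each observed at four post-treatment
time points.  Per reaction the time-averaged condition ratios U/F, A/F
and M/F are formed from the four post-treatment points (the shared
baseline of 1 is excluded).  Candidate flood-tolerance enzymes are the
reactions whose protein stayed high in all tolerant-like conditions
(U/F > 1 and A/F > 1 and M/F > 1), thinned to at most one per enzyme
group (the filtered reaction with the largest M/F wins; ties break on
A/F, then reaction id), and each candidate's over-expression fold is
its M/F ratio truncated to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import DataError, ParameterError
from .gmea import ClusterGrouping

__all__ = [
    "ProteinRatioTable",
    "TimeAverageRatios",
    "CandidateSet",
    "time_average_ratios",
    "cluster_protein_profiles",
    "select_candidates",
    "fold_from_ratio",
    "PROTEIN_CONDITIONS",
]

PROTEIN_CONDITIONS = ("U", "F", "A", "M")
N_TIMEPOINTS = 4


@dataclass
class ProteinRatioTable:
    """Tidy protein abundance ratios.

    Columns: reaction_id, protein_id, description, condition (U/F/A/M),
    time_point (0 = baseline, 1..4 = post-treatment), time_label, ratio.
    The baseline row of every (reaction, condition) series is 1 by
    definition; each condition must carry the four post-treatment
    points.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"reaction_id", "condition", "time_point", "ratio"}
        missing = required - set(self.data.columns)
        if missing:
            raise DataError(f"protein table missing columns {sorted(missing)}")
        if (self.data["ratio"] <= 0).any():
            bad = self.data.loc[self.data["ratio"] <= 0].iloc[0]
            raise DataError(
                f"ratios must be > 0; got {bad['ratio']} for "
                f"{bad['reaction_id']} ({bad['condition']})"
            )
        unknown = set(self.data["condition"]) - set(PROTEIN_CONDITIONS)
        if unknown:
            raise DataError(f"unknown conditions {sorted(unknown)}")
        base = self.data[self.data["time_point"] == 0]
        if not np.allclose(base["ratio"], 1.0):
            raise DataError("baseline (time_point 0) ratios must equal 1")

    @property
    def reactions(self):
        return sorted(set(self.data["reaction_id"]))

    def series(self, reaction_id: str, condition: str) -> np.ndarray:
        """Post-treatment ratio series (time points 1..4) for one condition."""
        sub = self.data[
            (self.data["reaction_id"] == reaction_id)
            & (self.data["condition"] == condition)
            & (self.data["time_point"] > 0)
        ].sort_values("time_point")
        if len(sub) != N_TIMEPOINTS:
            raise DataError(
                f"reaction {reaction_id!r}, condition {condition!r}: expected "
                f"{N_TIMEPOINTS} post-treatment points, found {len(sub)}"
            )
        return sub["ratio"].to_numpy(float)


@dataclass
class TimeAverageRatios:
    """Per-reaction time-average condition ratios U/F, A/F, M/F."""

    table: pd.DataFrame  # index reaction_id; columns u_over_f, a_over_f, m_over_f

    def triplet(self, reaction_id: str):
        row = self.table.loc[reaction_id]
        return float(row["u_over_f"]), float(row["a_over_f"]), float(row["m_over_f"])

    @property
    def reactions(self):
        return list(self.table.index)


def time_average_ratios(table: ProteinRatioTable) -> TimeAverageRatios:
    """Mean post-treatment abundance per condition, then U/F, A/F, M/F."""
    rows = {}
    for rid in table.reactions:
        means = {}
        for cond in PROTEIN_CONDITIONS:
            means[cond] = float(np.mean(table.series(rid, cond)))
        if means["F"] <= 0:
            raise DataError(f"reaction {rid!r}: flooded average is 0")
        rows[rid] = {
            "u_over_f": means["U"] / means["F"],
            "a_over_f": means["A"] / means["F"],
            "m_over_f": means["M"] / means["F"],
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "reaction_id"
    return TimeAverageRatios(table=out.sort_index())


def cluster_protein_profiles(table: ProteinRatioTable, k: int) -> dict:
    """Hierarchical clustering of per-reaction log2 abundance profiles.

    The profile vector concatenates the four post-treatment log2 ratios
    of conditions U, F, A, M (16 values); centroid linkage on Euclidean
    distances, cut at ``k`` clusters.  Returns cluster id -> reactions.
    """
    reactions = table.reactions
    if k < 1 or k > len(reactions):
        raise ParameterError(f"k={k} invalid for {len(reactions)} reactions")
    vectors = np.array(
        [
            np.log2(np.concatenate([table.series(r, c) for c in PROTEIN_CONDITIONS]))
            for r in reactions
        ]
    )
    if k == len(reactions):
        assignments = np.arange(1, k + 1)
    else:
        linkage = hierarchy.linkage(vectors, method="centroid", metric="euclidean")
        assignments = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    clusters = {}
    for rid, c in zip(reactions, assignments):
        clusters.setdefault(int(c), []).append(rid)
    return clusters


@dataclass
class CandidateSet:
    """Selected flood-tolerance candidate reactions with assigned folds.

    ``members`` is an ordered list of (reaction_id, enzyme_group,
    fold); ``trace`` records the filter decision for every screened
    reaction.
    """

    members: list = field(default_factory=list)
    trace: dict = field(default_factory=dict)

    @property
    def folds(self) -> dict:
        return {rid: fold for rid, _, fold in self.members}

    @property
    def reactions(self) -> list:
        return [rid for rid, _, _ in self.members]

    def to_dict(self):
        return {
            "members": [
                {"reaction_id": r, "enzyme_group": g, "fold": float(f)}
                for r, g, f in self.members
            ],
            "trace": dict(self.trace),
        }


def fold_from_ratio(m_over_f: float) -> float:
    """Truncate an M/F time-average ratio to one decimal for use as a Vmax fold.

    Truncation (floor at 0.1 resolution), not rounding: 3.23 -> 3.2,
    1.81 -> 1.8, 1.67 -> 1.6.
    """
    if m_over_f <= 0:
        raise ParameterError(f"ratio must be > 0, got {m_over_f}")
    return math.floor(m_over_f * 10.0 + 1e-9) / 10.0


def select_candidates(
    ratios: TimeAverageRatios, grouping: ClusterGrouping
) -> CandidateSet:
    """Filter + per-group selection of flood-tolerance candidates.

    Step 1 keeps reactions with U/F > 1, A/F > 1 and M/F > 1 (protein
    maintained in every tolerant-like condition).  Step 2 keeps, within
    each enzyme group, the filtered reaction with the largest M/F
    (tie-break: larger A/F, then lexicographically smaller id), so the
    candidate set spans the enzyme groups with at most one member each.
    Folds are the truncated M/F ratios.  An empty result is legitimate.
    """
    trace = {}
    passed = []
    for rid in ratios.reactions:
        u, a, m = ratios.triplet(rid)
        if u > 1 and a > 1 and m > 1:
            try:
                group = grouping.group_of_reaction(rid)
            except Exception:
                trace[rid] = "passed filter but has no enzyme-group assignment"
                continue
            passed.append((rid, group, u, a, m))
            trace[rid] = f"passed filter (U/F={u:.3g}, A/F={a:.3g}, M/F={m:.3g}), group {group}"
        else:
            trace[rid] = (
                f"failed filter (U/F={u:.3g}, A/F={a:.3g}, M/F={m:.3g}): "
                "needs all three > 1"
            )
    winners = {}
    for rid, group, _u, a, m in sorted(passed, key=lambda t: (-t[4], -t[3], t[0])):
        winners.setdefault(group, (rid, m))
    members = []
    for group in sorted(winners):
        rid, m = winners[group]
        members.append((rid, group, fold_from_ratio(m)))
        trace[rid] += "; selected for group " + group
    for rid, group, _u, _a, _m in passed:
        if all(rid != r for r, _, _ in members):
            trace[rid] += f"; outcompeted within group {group}"
    members.sort(key=lambda t: t[1])
    return CandidateSet(members=members, trace=trace)
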