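"""Vmax calibration against observed metabolite time courses.

Fitted-model agreement is scored by r^2 — the squared Pearson
correlation between log10-transformed simulated and observed amounts of
the fitting-target metabolites, pooled over metabolites and days (the
scatter-plot-with-fit-line reading).  An r^2 of at least 0.95 is the
conventional acceptance level for the calibrated model.

Vmax values are optimised jointly on a log10 scale by bounded local
least squares with seeded multi-start restarts; Km values stay fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, FitError, ParameterError
from .network import MetabolicModel, TemporalProfile, simulate_profiles

__all__ = [
    "ExperimentalProfileSet",
    "FitResult",
    "log_fit_r2",
    "fit_vmax",
]

CONDITIONS = ("flooded", "unstressed")
_FLOOR = 1e-9  # guard for log10 of a simulated amount clipped at zero


@dataclass
class ExperimentalProfileSet:
    """Observed metabolite amounts, tidy: condition, metabolite, day, amount.

    Amounts must be strictly positive so the log transform is defined;
    zeros are rejected at construction.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"condition", "metabolite", "day", "amount"}
        missing = required - set(self.data.columns)
        if missing:
            raise DataError(f"profile table missing columns {sorted(missing)}")
        if (self.data["amount"] <= 0).any():
            bad = self.data.loc[self.data["amount"] <= 0].iloc[0]
            raise DataError(
                "observed amounts must be > 0 for the log transform; "
                f"got {bad['amount']} for {bad['metabolite']} "
                f"({bad['condition']}, day {bad['day']})"
            )
        unknown = set(self.data["condition"]) - set(CONDITIONS)
        if unknown:
            raise DataError(f"unknown conditions {sorted(unknown)}")

    def conditions(self):
        return sorted(set(self.data["condition"]))

    def subset(self, condition: str) -> pd.DataFrame:
        sub = self.data[self.data["condition"] == condition]
        if sub.empty:
            raise DataError(f"no observations for condition {condition!r}")
        return sub

    def metabolites(self, condition: str):
        return sorted(set(self.subset(condition)["metabolite"]))


def _paired_logs(simulated: TemporalProfile, observed, condition, targets=None):
    """Log10 pairs of (simulated, observed) at matching (metabolite, day)."""
    if isinstance(observed, ExperimentalProfileSet):
        table = observed.subset(condition)
    else:
        table = observed
    sim_days = simulated.days
    sims, obss = [], []
    for metabolite, group in table.groupby("metabolite"):
        if targets is not None and metabolite not in targets:
            continue
        if metabolite not in simulated.amounts.columns:
            continue
        sim_y = simulated.amount(metabolite)
        interp = np.interp(group["day"].to_numpy(float), sim_days, sim_y)
        sims.append(np.log10(np.maximum(interp, _FLOOR)))
        obss.append(np.log10(group["amount"].to_numpy(float)))
    if not sims:
        raise DataError("no overlapping (metabolite, day) pairs to compare")
    return np.concatenate(sims), np.concatenate(obss)


def log_fit_r2(
    simulated: TemporalProfile,
    observed,
    condition: str = "flooded",
    targets=None,
) -> float:
    """Squared Pearson correlation of log10 simulated vs observed amounts.

    Pairs are pooled over all fitting-target metabolites and observation
    days (simulated values linearly interpolated to the observed days).
    """
    sim, obs = _paired_logs(simulated, observed, condition, targets)
    if sim.size < 2:
        raise DataError("need at least 2 paired points for r^2")
    if np.ptp(sim) == 0 or np.ptp(obs) == 0:
        raise DataError("zero variance in log amounts; r^2 undefined")
    r = stats.pearsonr(sim, obs).statistic
    return float(r * r)


@dataclass
class FitResult:
    """Outcome of a Vmax calibration.

    ``vmax_estimates`` covers every reaction (fitted ones updated, the
    rest at their input values); ``r2`` is the pooled log-scale score of
    the fitted model; ``fitted_model`` is the calibrated model itself.
    """

    vmax_estimates: dict
    r2: float
    converged: bool
    n_points: int
    seed: int
    loss: float = math.nan
    initial_loss: float = math.nan
    fitted_model: MetabolicModel | None = None
    free_reactions: list = field(default_factory=list)

    def to_dict(self):
        return {
            "vmax_estimates": {k: float(v) for k, v in self.vmax_estimates.items()},
            "r2": float(self.r2),
            "converged": bool(self.converged),
            "n_points": int(self.n_points),
            "seed": int(self.seed),
            "loss": float(self.loss),
            "initial_loss": float(self.initial_loss),
            "free_reactions": list(self.free_reactions),
        }


def _model_with_vmax(model, free_ids, log_folds):
    from .network import ModificationScenario, apply_modification

    folds = {rid: float(10.0 ** lf) for rid, lf in zip(free_ids, log_folds)}
    return apply_modification(model, ModificationScenario(folds=folds, label="fit"))


def fit_vmax(
    model: MetabolicModel,
    observed: ExperimentalProfileSet,
    bounds=(1.0 / 50.0, 50.0),
    seed: int = 0,
    condition: str = "flooded",
    free_reactions=None,
    n_restarts: int = 5,
    max_nfev: int | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> FitResult:
    """Calibrate Vmax values to observed time courses.

    Minimises the sum of squared log10 residuals over all fitting-target
    (metabolite, day) pairs of the chosen condition.  The decision
    variables are log10 fold changes of Vmax relative to the model's
    initial values, bounded by ``bounds`` (default 1/50 .. 50-fold).
    ``n_restarts`` seeded restarts start from log-uniform perturbations
    of the initial Vmax vector (the first restart starts unperturbed).

    By default only the modifiable reactions are free; pass
    ``free_reactions`` to fit a different subset (e.g. linkers too).
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if lo <= 0 or hi < lo:
        raise ParameterError(f"bounds must satisfy 0 < lo <= hi, got {bounds}")
    free_ids = list(free_reactions) if free_reactions is not None else model.modifiable_reactions
    for rid in free_ids:
        if rid not in model.reactions:
            raise ParameterError(f"unknown reaction {rid!r} in free_reactions")
    targets = set(model.target_pools)
    missing = [
        m for m in targets if m not in set(observed.subset(condition)["metabolite"])
    ]
    if missing:
        raise DataError(
            f"observed data lacks fitting-target metabolites {sorted(missing)}"
        )

    table = observed.subset(condition)
    obs_cache = table[table["metabolite"].isin(targets)]
    n_points = len(obs_cache)

    def residuals(log_folds):
        candidate = _model_with_vmax(model, free_ids, log_folds)
        try:
            profile = simulate_profiles(candidate, rtol=rtol, atol=atol)
        except Exception:
            return np.full(n_points, 1e3)
        sim, obs = _paired_logs(profile, obs_cache, condition, targets)
        return sim - obs

    rng = np.random.default_rng(seed)
    llo, lhi = math.log10(lo), math.log10(hi)
    x0 = np.zeros(len(free_ids))
    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.uniform(llo / 4.0, lhi / 4.0, size=len(free_ids)))

    initial_loss = float(np.sum(residuals(x0) ** 2))
    best = None
    any_success = False
    if not free_ids:
        best = (initial_loss, x0, True)
    if llo == lhi:  # degenerate bounds pin every fold
        x_fixed = np.full(len(free_ids), llo)
        best = (float(np.sum(residuals(x_fixed) ** 2)), x_fixed, True)
        any_success, starts = True, []
    for start in starts:
        try:
            sol = optimize.least_squares(
                residuals,
                start,
                bounds=(llo, lhi),
                method="trf",
                max_nfev=max_nfev,
                xtol=1e-10,
            )
        except Exception:
            continue
        any_success = any_success or sol.success
        if best is None or sol.cost * 2 < best[0]:
            best = (float(sol.cost * 2), sol.x, bool(sol.success))
        if best[0] < 1e-12:
            break
    if best is None:
        raise FitError("optimiser failed on all restarts", best_result=None)

    loss, x_best, success = best
    # never accept a fit worse than the starting point (when it is feasible)
    if loss > initial_loss and llo <= 0.0 <= lhi:
        loss, x_best, success = initial_loss, x0, False
    fitted = _model_with_vmax(model, free_ids, x_best)
    profile = simulate_profiles(fitted, rtol=rtol, atol=atol)
    r2 = log_fit_r2(profile, obs_cache, condition, targets)
    estimates = {rid: rxn.vmax for rid, rxn in fitted.reactions.items()}
    result = FitResult(
        vmax_estimates=estimates,
        r2=r2,
        converged=bool(success and any_success),
        n_points=n_points,
        seed=int(seed),
        loss=loss,
        initial_loss=initial_loss,
        fitted_model=fitted,
        free_reactions=free_ids,
    )
    if not any_success and free_ids:
        raise FitError("optimiser reported failure on all restarts", best_result=result)
    return result
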