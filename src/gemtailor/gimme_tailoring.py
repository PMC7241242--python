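"""GIMME context-specific model extraction and threshold calibration.

The tailoring LP minimizes sum(weight * |v|) subject to steady state,
bounds, and the biomass flux held at or above a fraction (default 90%)
of the parent model's optimum. Reactions whose expression falls below
the threshold are penalized by (threshold - expression); reactions above
threshold or without expression carry zero weight. Removed reactions are
those with positive weight and no flux in the LP solution; weighted
reactions that still carry flux are recorded as reinserted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from gemtailor.expression_context import (
    ContextKey,
    ExpressionSeries,
    map_expression_to_reactions,
    pooled_reaction_values,
    quantile_threshold,
)
from gemtailor.flux_analysis import ZERO_TOL, FluxSolution, fba
from gemtailor.model_core import MetabolicModel, stoichiometric_matrix

#: Tiny uniform cost on total split flux added to the GIMME LP objective.
#: It breaks ties among penalty-equal optima (there are many: any flux
#: routing through zero-weight reactions is penalty-free) so solutions
#: are reproducible. Too small to trade against any real penalty.
FLUX_TIE_BREAK = 1e-8


class GimmeInfeasibleError(RuntimeError):
    pass


class InternalConsistencyError(RuntimeError):
    pass


@dataclass
class GimmeWeights:
    """Per-reaction penalties x = max(0, threshold - expression)."""

    weights: Dict[str, float]
    threshold: float
    quantile: Optional[float] = None

    def weight(self, rxn_id: str) -> float:
        return self.weights.get(rxn_id, 0.0)


def gimme_weights(
    rxn_expr: Mapping[str, float],
    threshold: float,
    quantile: Optional[float] = None,
) -> GimmeWeights:
    """Penalty weights from mapped expression values and a threshold.

    Reactions absent from ``rxn_expr`` (no gene association or no
    coverage) get weight zero.
    """
    if not math.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    weights = {
        rxn_id: threshold - value
        for rxn_id, value in rxn_expr.items()
        if value < threshold
    }
    return GimmeWeights(weights=weights, threshold=threshold, quantile=quantile)


def gimme_lp(
    model: MetabolicModel,
    weights: GimmeWeights,
    objective_fraction: float = 0.9,
    parent_optimum: Optional[float] = None,
) -> FluxSolution:
    """Solve the GIMME LP on the parent model.

    |v| is realized by splitting every reaction into forward/backward
    non-negative parts sharing the same weight. Returns a FluxSolution
    whose ``objective_value`` is the penalty sum(weight * |v|) and whose
    ``biomass`` is the achieved objective flux.
    """
    if parent_optimum is None:
        base = fba(model)
        if base.status != "optimal":
            raise GimmeInfeasibleError(f"parent model FBA is {base.status}")
        parent_optimum = base.objective_value
    target = objective_fraction * parent_optimum

    n = len(model.reactions)
    S = stoichiometric_matrix(model)
    lower = np.array([r.lower_bound for r in model.reactions])
    upper = np.array([r.upper_bound for r in model.reactions])
    c_obj = np.array([r.objective_coefficient for r in model.reactions])
    w = np.array([weights.weight(r.id) for r in model.reactions])

    # v = vf - vb, vf in [max(l,0), max(u,0)], vb in [max(-u,0), max(-l,0)]
    bounds_f = list(zip(np.maximum(lower, 0.0), np.maximum(upper, 0.0)))
    bounds_b = list(zip(np.maximum(-upper, 0.0), np.maximum(-lower, 0.0)))
    cost = np.concatenate([w, w]) + FLUX_TIE_BREAK
    A_eq = np.hstack([S, -S])
    A_ub = -np.concatenate([c_obj, -c_obj])[None, :]
    res = linprog(
        cost,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=np.array([-target]),
        bounds=bounds_f + bounds_b,
        method="highs",
    )
    if res.status != 0:
        raise GimmeInfeasibleError(
            f"GIMME LP infeasible at objective fraction {objective_fraction} "
            f"(target biomass {target:.6g})"
        )
    v = res.x[:n] - res.x[n:]
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, v)}
    penalty = float(np.sum(w * np.abs(v)))
    return FluxSolution(
        fluxes=fluxes,
        objective_value=penalty,
        status="optimal",
        biomass=float(c_obj @ v),
    )


@dataclass
class ContextGEM:
    """Sub-model extracted for one (condition, day) context."""

    model: MetabolicModel
    context: ContextKey
    kept_reactions: Set[str]
    removed_reactions: Set[str]
    reinserted_reactions: Set[str]
    gimme_objective: float
    biomass_rate: float
    threshold: Optional[float] = None
    quantile: Optional[float] = None

    @property
    def label(self) -> str:
        return f"{self.context.condition}_day{self.context.day}"


def extract_context_gem(
    model: MetabolicModel,
    weights: GimmeWeights,
    gimme_solution: FluxSolution,
    context: ContextKey,
    objective_fraction: float = 0.9,
    zero_tol: float = ZERO_TOL,
    parent_optimum: Optional[float] = None,
) -> ContextGEM:
    """Build the context GEM from a GIMME solution.

    Keeps zero-weight reactions plus weighted reactions carrying flux
    (recorded as reinserted); removes the rest; prunes orphan
    metabolites. The sub-model must reach the biomass target — anything
    else indicates misconfigured tolerances.
    """
    kept: Set[str] = set()
    removed: Set[str] = set()
    reinserted: Set[str] = set()
    for rxn in model.reactions:
        carries = abs(gimme_solution.fluxes.get(rxn.id, 0.0)) > zero_tol
        if weights.weight(rxn.id) <= 0.0:
            kept.add(rxn.id)
        elif carries:
            kept.add(rxn.id)
            reinserted.add(rxn.id)
        else:
            removed.add(rxn.id)

    sub = MetabolicModel(id=f"{model.id}__{context.condition}_day{context.day}")
    sub.reactions = [r for r in model.copy().reactions if r.id in kept]
    used = {m for r in sub.reactions for m in r.stoichiometry}
    sub.metabolites = [m for m in model.copy().metabolites if m.id in used]
    sub.compartments = {
        cid: name
        for cid, name in model.compartments.items()
        if any(m.compartment == cid for m in sub.metabolites)
    }

    sol = fba(sub)
    biomass = sol.objective_value if sol.status == "optimal" else 0.0
    if parent_optimum is None:
        parent = fba(model)
        parent_optimum = parent.objective_value if parent.status == "optimal" else 0.0
    floor = objective_fraction * parent_optimum
    if sol.status != "optimal" or biomass < floor - 1e-6 * max(1.0, abs(floor)):
        raise InternalConsistencyError(
            f"context GEM {context} reaches biomass {biomass:.6g} < target {floor:.6g}; "
            "check zero-flux tolerance configuration"
        )
    return ContextGEM(
        model=sub,
        context=context,
        kept_reactions=kept,
        removed_reactions=removed,
        reinserted_reactions=reinserted,
        gimme_objective=gimme_solution.objective_value,
        biomass_rate=float(biomass),
        threshold=weights.threshold,
        quantile=weights.quantile,
    )


# ---------------------------------------------------------------------------
# Growth data
# ---------------------------------------------------------------------------


@dataclass
class GrowthSeries:
    """Fresh weight per (condition, day), in grams."""

    table: pd.DataFrame  # columns: condition, day, fresh_weight_g

    def __post_init__(self):
        required = {"condition", "day", "fresh_weight_g"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"growth table lacks columns {sorted(missing)}")
        if (self.table["fresh_weight_g"] <= 0).any():
            raise ValueError("fresh weights must be strictly positive")

    @property
    def conditions(self) -> List[str]:
        return sorted(self.table["condition"].unique())

    def fresh_weight(self, condition: str, day: int) -> float:
        rows = self.table[
            (self.table["condition"] == condition) & (self.table["day"] == day)
        ]
        if rows.empty:
            raise KeyError(f"no fresh weight for ({condition}, day {day})")
        return float(rows["fresh_weight_g"].iloc[0])

    @classmethod
    def from_tsv(cls, path: str) -> "GrowthSeries":
        return cls(table=pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fresh_weight_rate(growth: GrowthSeries) -> pd.DataFrame:
    """Per-interval rate of fresh weight increase, Delta FW / Delta t.

    Computed over consecutive recorded days per condition; a gap larger
    than one day still yields a rate (over the actual Delta t) but is
    flagged.
    """
    rows = []
    for condition in growth.conditions:
        sub = growth.table[growth.table["condition"] == condition].sort_values("day")
        days = list(sub["day"].astype(int))
        weights = list(sub["fresh_weight_g"].astype(float))
        if len(days) < 2:
            raise ValueError(f"condition {condition!r} has fewer than two days")
        for (d0, w0), (d1, w1) in zip(zip(days, weights), zip(days[1:], weights[1:])):
            dt = d1 - d0
            rows.append({
                "condition": condition,
                "day_start": d0,
                "day_end": d1,
                "rate_g_per_day": (w1 - w0) / dt,
                "gap_flagged": dt != 1,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Threshold sweep and calibration
# ---------------------------------------------------------------------------


@dataclass
class TailoringReport:
    """Per-quantile sweep outcomes and the selected threshold."""

    entries: List[dict]
    selected_quantile: float
    selected_threshold: float
    similarity_metric: str = "pearson_r (ties: min-max scaled RMSE, then lower quantile)"
    quantile_convention: str = "pooled reaction-mapped values, linear interpolation"
    objective_fraction: float = 0.9

    def entry(self, q: float) -> dict:
        for rec in self.entries:
            if abs(rec["quantile"] - q) < 1e-12:
                return rec
        raise KeyError(f"no sweep entry for quantile {q}")

    def to_json(self, path: str) -> None:
        payload = {
            "selected_quantile": self.selected_quantile,
            "selected_threshold": self.selected_threshold,
            "similarity_metric": self.similarity_metric,
            "quantile_convention": self.quantile_convention,
            "objective_fraction": self.objective_fraction,
            "entries": [
                {
                    **rec,
                    "biomass": {f"{c}_day{d}": v for (c, d), v in rec["biomass"].items()},
                }
                for rec in self.entries
            ],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)

    def scores_tsv(self, path: str) -> None:
        with open(path, "w") as handle:
            handle.write("# similarity: %s\n" % self.similarity_metric)
            handle.write("quantile\tthreshold\tscore\trmse\tvalid\n")
            for rec in self.entries:
                handle.write(
                    "%.2f\t%.10g\t%s\t%s\t%s\n"
                    % (
                        rec["quantile"],
                        rec["threshold"],
                        "%.10g" % rec["score"] if rec["valid"] else "NA",
                        "%.10g" % rec["rmse"] if rec["valid"] else "NA",
                        int(rec["valid"]),
                    )
                )


def _aligned_series(
    biomass: Mapping[ContextKey, float],
    rates: pd.DataFrame,
) -> Tuple[np.ndarray, np.ndarray]:
    """Pair each interval's growth rate with the biomass at its end day."""
    sim, obs = [], []
    for condition in sorted(rates["condition"].unique()):
        sub = rates[rates["condition"] == condition].sort_values("day_end")
        for row in sub.itertuples(index=False):
            key = ContextKey(condition, int(row.day_end))
            if key in biomass:
                sim.append(biomass[key])
                obs.append(row.rate_g_per_day)
    return np.asarray(sim), np.asarray(obs)


def _minmax(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    return (x - x.min()) / span if span > 0 else np.zeros_like(x)


def trajectory_similarity(
    biomass: Mapping[ContextKey, float],
    rates: pd.DataFrame,
) -> Tuple[float, float]:
    """(Pearson r, min-max scaled RMSE) of simulated vs observed patterns."""
    sim, obs = _aligned_series(biomass, rates)
    if sim.size < 3 or np.ptp(sim) == 0 or np.ptp(obs) == 0:
        return math.nan, math.nan
    r = float(np.corrcoef(sim, obs)[0, 1])
    rmse = float(np.sqrt(np.mean((_minmax(sim) - _minmax(obs)) ** 2)))
    return r, rmse


def tailor_all(
    model: MetabolicModel,
    expr: ExpressionSeries,
    growth: GrowthSeries,
    q_grid: Sequence[float],
    objective_fraction: float = 0.9,
    zero_tol: float = ZERO_TOL,
) -> Tuple[List[ContextGEM], TailoringReport]:
    """Sweep threshold quantiles, score each against the growth trajectory,
    and return the context GEMs tailored at the best quantile.

    A quantile at which any context is infeasible is recorded as invalid
    and skipped. The winner maximizes Pearson correlation between the
    simulated biomass trajectory and the fresh-weight-increase rate
    trajectory (both concatenated over conditions in day order); ties go
    to the smaller min-max-scaled RMSE, then to the smaller quantile.
    """
    if len(q_grid) == 0:
        raise ValueError("quantile grid is empty")
    parent = fba(model)
    if parent.status != "optimal":
        raise GimmeInfeasibleError(f"global model FBA is {parent.status}")
    z_star = parent.objective_value

    contexts = expr.contexts
    mapped = {
        ctx: map_expression_to_reactions(model, expr.gene_values(ctx))
        for ctx in contexts
    }
    pooled = pooled_reaction_values(model, expr)
    rates = fresh_weight_rate(growth)

    def tailor_at(q: float, threshold: float) -> List[ContextGEM]:
        gems = []
        for ctx in contexts:
            weights = gimme_weights(mapped[ctx], threshold, quantile=q)
            sol = gimme_lp(model, weights, objective_fraction, parent_optimum=z_star)
            gems.append(
                extract_context_gem(
                    model, weights, sol, ctx,
                    objective_fraction=objective_fraction,
                    zero_tol=zero_tol,
                    parent_optimum=z_star,
                )
            )
        return gems

    entries: List[dict] = []
    for q in q_grid:
        threshold = quantile_threshold(pooled, q)
        record = {"quantile": float(q), "threshold": threshold, "valid": False,
                  "score": math.nan, "rmse": math.nan, "biomass": {}}
        try:
            gems = tailor_at(q, threshold)
        except GimmeInfeasibleError as exc:
            record["error"] = str(exc)
            entries.append(record)
            continue
        biomass = {g.context: g.biomass_rate for g in gems}
        score, rmse = trajectory_similarity(biomass, rates)
        record.update(biomass=biomass, score=score, rmse=rmse, valid=True)
        entries.append(record)

    feasible = [rec for rec in entries if rec["valid"]]
    if not feasible:
        raise GimmeInfeasibleError("every quantile in the grid was infeasible")
    # NaN scores (flat trajectories) never beat a finite score but remain
    # selectable when nothing else is on offer (e.g. a one-quantile grid).
    def sort_key(rec):
        score = rec["score"] if math.isfinite(rec["score"]) else -math.inf
        rmse = rec["rmse"] if math.isfinite(rec["rmse"]) else math.inf
        return (-score, rmse, rec["quantile"])

    best = sorted(feasible, key=sort_key)[0]
    gems = tailor_at(best["quantile"], best["threshold"])
    report = TailoringReport(
        entries=entries,
        selected_quantile=best["quantile"],
        selected_threshold=best["threshold"],
        objective_fraction=objective_fraction,
    )
    return gems, report
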