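"""FBA, norm-regularized FBA, flux-sums, deletion and insertion screens.

Linear programs are solved with scipy's HiGHS backend. The regularized
variant uses a two-stage scheme: an LP fixes the optimal objective Z*,
then a strictly convex QP picks, among the alternate optima satisfying
c'v >= Z*(1 - 1e-6), the flux vector of minimal squared Euclidean norm.
The QP solution is polished against its KKT system so repeated runs are
numerically reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from gemtailor.model_core import MetabolicModel, Reaction, stoichiometric_matrix

#: |v| above this counts as "carries flux".
ZERO_TOL = 1e-9

#: Relative slack allowed on the optimum in the second (QP) stage;
#: mirrors a 1e-6 norm-regularization weight on the LP objective.
MIN_NORM_SLACK = 1e-6

_STATUS = {0: "optimal", 1: "undefined", 2: "infeasible", 3: "unbounded", 4: "undefined"}


@dataclass
class FluxSolution:
    fluxes: Dict[str, float]
    objective_value: float
    status: str
    biomass: Optional[float] = None

    def flux(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as handle:
            handle.write("# status=%s objective=%.12g\n" % (self.status, self.objective_value))
            handle.write("reaction_id\tflux\n")
            for rxn_id, value in self.fluxes.items():
                handle.write(f"{rxn_id}\t{value:.12g}\n")


@dataclass
class DeletionResult:
    reaction_id: str
    objective_after_deletion: float
    essentiality_class: str  # no_effect | reduced | lethal


def _lp_arrays(model: MetabolicModel):
    S = stoichiometric_matrix(model)
    lower = np.array([r.lower_bound for r in model.reactions])
    upper = np.array([r.upper_bound for r in model.reactions])
    c = np.array([r.objective_coefficient for r in model.reactions])
    return S, lower, upper, c


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximize the objective flux subject to S v = 0 and bounds."""
    if model.objective_reaction_id is None:
        raise ValueError("model has no objective reaction")
    S, lower, upper, c = _lp_arrays(model)
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lower, upper)),
        method="highs",
    )
    status = _STATUS.get(res.status, "undefined")
    if status != "optimal":
        return FluxSolution(fluxes={}, objective_value=math.nan, status=status)
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    objective = float(c @ res.x)
    return FluxSolution(fluxes=fluxes, objective_value=objective, status="optimal",
                        biomass=objective)


def _polish_min_norm(x, S, lower, upper, c, target) -> Optional[np.ndarray]:
    """Exact KKT solve on the active set identified by the iterative QP."""
    n = x.size
    act_tol = 1e-7
    fixed = np.zeros(n, dtype=bool)
    fixed_vals = np.zeros(n)
    at_lower = np.isfinite(lower) & (np.abs(x - lower) < act_tol)
    at_upper = np.isfinite(upper) & (np.abs(x - upper) < act_tol)
    fixed |= at_lower
    fixed_vals[at_lower] = lower[at_lower]
    fixed |= at_upper
    fixed_vals[at_upper] = upper[at_upper]
    free = ~fixed
    if not free.any():
        candidate = fixed_vals
    else:
        rows = [S[:, free]]
        rhs = [-S[:, fixed] @ fixed_vals[fixed]]
        if c @ x <= target + 1e-6 * max(1.0, abs(target)):
            rows.append(c[free][None, :])
            rhs.append(np.array([target - c[fixed] @ fixed_vals[fixed]]))
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        # min ||x_free||^2 s.t. A x_free = b  ->  x_free = A' (A A')^+ b
        lam, *_ = np.linalg.lstsq(A @ A.T, b, rcond=None)
        candidate = fixed_vals.copy()
        candidate[free] = A.T @ lam
    ok = (
        np.all(candidate >= lower - 1e-7)
        and np.all(candidate <= upper + 1e-7)
        and np.max(np.abs(S @ candidate)) < 1e-6
        and c @ candidate >= target - 1e-6 * max(1.0, abs(target))
        and candidate @ candidate <= x @ x + 1e-6
    )
    return np.clip(candidate, lower, upper) if ok else None


def fba_min_norm(model: MetabolicModel, exclude_exchanges: bool = False) -> FluxSolution:
    """FBA followed by squared-norm minimization over the optimal face.

    ``exclude_exchanges`` drops single-metabolite (boundary) reactions
    from the norm, for callers reading "internal flux" narrowly.
    """
    base = fba(model)
    if base.status != "optimal":
        return base
    S, lower, upper, c = _lp_arrays(model)
    z_star = base.objective_value
    target = z_star * (1.0 - MIN_NORM_SLACK) if z_star >= 0 else z_star * (1.0 + MIN_NORM_SLACK)

    weights = np.ones(len(model.reactions))
    if exclude_exchanges:
        for j, rxn in enumerate(model.reactions):
            if len(rxn.stoichiometry) == 1:
                weights[j] = 0.0

    x0 = np.array([base.fluxes[r.id] for r in model.reactions])

    def objective(v):
        return float(v @ (weights * v))

    def gradient(v):
        return 2.0 * weights * v

    def hessian(v):
        return 2.0 * np.diag(weights)

    S_qp = S[np.any(S != 0.0, axis=1)]  # orphan metabolites add zero rows
    constraints = [
        LinearConstraint(S_qp, 0.0, 0.0),
        LinearConstraint(c[None, :], target, np.inf),
    ]
    res = minimize(
        objective,
        x0,
        jac=gradient,
        hess=hessian,
        bounds=Bounds(lower, upper),
        constraints=constraints,
        method="trust-constr",
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000, "verbose": 0},
    )
    x = res.x
    if not np.all(weights == 1.0):
        polished = None  # KKT polish below assumes the full-norm objective
    else:
        polished = _polish_min_norm(x, S, lower, upper, c, target)
    if polished is not None:
        x = polished
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, x)}
    return FluxSolution(
        fluxes=fluxes,
        objective_value=float(c @ x),
        status="optimal",
        biomass=float(c @ x),
    )


def flux_sum(solution: FluxSolution, model: MetabolicModel, metabolite_id: str) -> float:
    """Half the absolute stoichiometry-weighted flux through a metabolite."""
    model.get_metabolite(metabolite_id)  # raises KeyError if unknown
    total = 0.0
    for rxn in model.reactions:
        coef = rxn.stoichiometry.get(metabolite_id)
        if coef is not None:
            total += abs(coef * solution.fluxes.get(rxn.id, 0.0))
    return 0.5 * total


def single_reaction_deletion(
    model: MetabolicModel,
    rel_tol: float = 1e-6,
    lethal_frac: float = 1e-3,
) -> List[DeletionResult]:
    """Delete (zero-bound) each reaction in turn and re-run FBA.

    Classes relative to the wild-type optimum Z: ``no_effect`` when the
    deleted optimum is within ``rel_tol`` of Z, ``lethal`` when it falls
    to ``lethal_frac * Z`` or below (or the problem goes infeasible),
    ``reduced`` otherwise.
    """
    wild = fba(model)
    if wild.status != "optimal":
        raise ValueError(f"wild-type model is {wild.status}, cannot screen deletions")
    z_wt = wild.objective_value
    results: List[DeletionResult] = []
    for rxn in model.reactions:
        saved = (rxn.lower_bound, rxn.upper_bound)
        rxn.lower_bound = rxn.upper_bound = 0.0
        try:
            sol = fba(model)
        finally:
            rxn.lower_bound, rxn.upper_bound = saved
        z_del = sol.objective_value if sol.status == "optimal" else 0.0
        scale = max(1.0, abs(z_wt))
        if z_del >= z_wt - rel_tol * scale:
            klass = "no_effect"
        elif z_del <= lethal_frac * max(z_wt, 0.0) + rel_tol * scale:
            klass = "lethal"
        else:
            klass = "reduced"
        results.append(DeletionResult(rxn.id, float(z_del), klass))
    return results


def insert_reaction_and_evaluate(
    model: MetabolicModel,
    reaction: Reaction,
    new_metabolites=(),
    replace: bool = False,
) -> Tuple[float, float]:
    """Objective before and after adding ``reaction`` (model untouched).

    Metabolites referenced by the reaction but absent from the model must
    be supplied via ``new_metabolites``. An existing reaction id is an
    error unless ``replace`` is set.
    """
    before = fba(model)
    z_before = before.objective_value if before.status == "optimal" else 0.0

    trial = model.copy()
    ids = {r.id for r in trial.reactions}
    if reaction.id in ids:
        if not replace:
            raise ValueError(
                f"reaction {reaction.id!r} already present (pass replace=True to override)"
            )
        trial.reactions = [r for r in trial.reactions if r.id != reaction.id]
    known = {m.id for m in trial.metabolites}
    for met in new_metabolites:
        if met.id not in known:
            trial.metabolites.append(met)
            known.add(met.id)
    missing = [m for m in reaction.stoichiometry if m not in known]
    if missing:
        raise ValueError(
            f"reaction {reaction.id!r} references unknown metabolites {missing}; "
            "pass them via new_metabolites"
        )
    trial.reactions.append(reaction)
    after = fba(trial)
    z_after = after.objective_value if after.status == "optimal" else 0.0
    return float(z_before), float(z_after)
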