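"""Cross-context comparison: flux/flux-sum matrices, fold-changes,
profile clustering, occurrence percentages, and model census tables.

"Flux size" means |v| throughout: signed ratios would be ill-defined for
direction reversals, which are instead reported separately. Missing
matrix entries (reaction or metabolite absent from a context GEM) are
filled with one-tenth of the global minimum positive magnitude; zero
entries of present items are floored to the same value so every
fold-change is finite. Both kinds of substitution are tracked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from gemtailor.expression_context import ContextKey
from gemtailor.flux_analysis import ZERO_TOL, FluxSolution, flux_sum
from gemtailor.gimme_tailoring import ContextGEM
from gemtailor.model_core import MetabolicModel


@dataclass
class FluxMatrix:
    """Contexts x items magnitude matrix with fill bookkeeping."""

    values: pd.DataFrame            # index: ContextKey tuples; columns: item ids
    imputed_mask: pd.DataFrame      # item absent from the context GEM
    floored_mask: pd.DataFrame      # item present but carrying (numerical) zero
    fill_value: float

    @property
    def fill_mask(self) -> pd.DataFrame:
        return self.imputed_mask | self.floored_mask

    def to_tsv(self, path: str) -> None:
        frame = self.values.copy()
        frame.index = [f"{c}_day{d}" for c, d in frame.index]
        with open(path, "w") as handle:
            handle.write(f"# fill_value={self.fill_value:.12g} (min positive magnitude / 10)\n")
            frame.to_csv(handle, sep="\t", index_label="context")


@dataclass
class FoldChangeTable:
    """log2(drought/control) per item per day, with the |log2FC|>1 flag."""

    values: pd.DataFrame            # index: day; columns: item ids
    flagged: pd.DataFrame           # |log2 fc| > log2(factor)
    imputed: pd.DataFrame           # either side imputed/floored
    factor: float = 2.0
    numerator: str = "drought"
    denominator: str = "control"

    def flagged_items(self) -> List[str]:
        """Items flagged on at least one day."""
        mask = self.flagged.any(axis=0)
        return [item for item in self.values.columns if mask[item]]

    def to_long_tsv(self, path: str) -> None:
        with open(path, "w") as handle:
            handle.write(
                f"# log2({self.numerator}/{self.denominator}); "
                f"flagged = |log2fc| > {math.log2(self.factor):g}\n"
            )
            handle.write("day\titem\tlog2fc\tflagged\timputed\n")
            for day in self.values.index:
                for item in self.values.columns:
                    handle.write(
                        "%s\t%s\t%.10g\t%d\t%d\n"
                        % (day, item, self.values.at[day, item],
                           bool(self.flagged.at[day, item]),
                           bool(self.imputed.at[day, item]))
                    )


@dataclass
class ClusterAssignment:
    labels: Dict[str, int]
    linkage_matrix: np.ndarray
    cut_distance: float
    singletons: List[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, cluster: int) -> List[str]:
        return sorted(i for i, c in self.labels.items() if c == cluster)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as handle:
            handle.write(f"# average linkage, 1 - Pearson r, cut at {self.cut_distance}\n")
            handle.write("item\tcluster\n")
            for item in sorted(self.labels, key=lambda i: (self.labels[i], i)):
                handle.write(f"{item}\t{self.labels[item]}\n")


def _assemble_matrix(
    entries: Mapping[ContextKey, Mapping[str, float]],
    memberships: Mapping[ContextKey, Set[str]],
    zero_tol: float,
) -> FluxMatrix:
    contexts = sorted(memberships, key=lambda c: (c.condition, c.day))
    items = sorted(set().union(*memberships.values()))
    index = pd.MultiIndex.from_tuples(contexts, names=["condition", "day"])
    values = pd.DataFrame(0.0, index=index, columns=items)
    imputed = pd.DataFrame(False, index=index, columns=items)
    floored = pd.DataFrame(False, index=index, columns=items)

    for ctx in contexts:
        present = memberships[ctx]
        row = entries[ctx]
        for item in items:
            if item in present:
                mag = abs(row.get(item, 0.0))
                if mag <= zero_tol:
                    floored.at[ctx, item] = True
                    mag = 0.0
                values.at[ctx, item] = mag
            else:
                imputed.at[ctx, item] = True

    positives = values.values[values.values > 0]
    if positives.size == 0:
        raise ValueError("all matrix entries are zero; fill value undefined")
    fill = float(positives.min()) / 10.0
    values.values[imputed.values | floored.values] = fill
    return FluxMatrix(values=values, imputed_mask=imputed, floored_mask=floored,
                      fill_value=fill)


def build_flux_matrix(
    solutions: Mapping[ContextKey, FluxSolution],
    gem_memberships: Mapping[ContextKey, Set[str]],
    zero_tol: float = ZERO_TOL,
) -> FluxMatrix:
    """Contexts x reactions matrix of |v| with missing-entry fill.

    ``gem_memberships`` gives the reaction ids present in each context's
    GEM; absent reactions are imputed with min(positive magnitudes)/10.
    """
    if not solutions:
        raise ValueError("no solutions supplied")
    entries = {ctx: sol.fluxes for ctx, sol in solutions.items()}
    return _assemble_matrix(entries, gem_memberships, zero_tol)


def flux_sum_matrix(
    solutions: Mapping[ContextKey, FluxSolution],
    models: Mapping[ContextKey, MetabolicModel],
    zero_tol: float = ZERO_TOL,
) -> FluxMatrix:
    """Contexts x metabolites matrix of flux-sums, same fill rule."""
    if not solutions:
        raise ValueError("no solutions supplied")
    entries: Dict[ContextKey, Dict[str, float]] = {}
    memberships: Dict[ContextKey, Set[str]] = {}
    for ctx, model in models.items():
        sol = solutions[ctx]
        mets = {m.id for m in model.metabolites}
        memberships[ctx] = mets
        entries[ctx] = {mid: flux_sum(sol, model, mid) for mid in mets}
    return _assemble_matrix(entries, memberships, zero_tol)


def fold_change(
    matrix: FluxMatrix,
    days: Optional[Sequence[int]] = None,
    numerator: str = "drought",
    denominator: str = "control",
    factor: float = 2.0,
) -> FoldChangeTable:
    """log2(numerator-condition / denominator-condition) per day."""
    by_day: Dict[int, Dict[str, ContextKey]] = {}
    for raw in matrix.values.index:
        ctx = ContextKey(raw[0], int(raw[1]))
        by_day.setdefault(ctx.day, {})[ctx.condition] = ctx
    if days is None:
        days = sorted(
            d for d, conds in by_day.items() if numerator in conds and denominator in conds
        )
    rows, flag_rows, imp_rows = [], [], []
    cut = math.log2(factor)
    for day in days:
        conds = by_day.get(day, {})
        if numerator not in conds or denominator not in conds:
            raise ValueError(f"day {day} lacks a {numerator}/{denominator} pair")
        num = matrix.values.loc[[conds[numerator]]].iloc[0]
        den = matrix.values.loc[[conds[denominator]]].iloc[0]
        l2 = np.log2(num / den)
        rows.append(l2)
        # the boundary case (ratio exactly = factor) counts as changed
        flag_rows.append(np.abs(l2) >= cut - 1e-12)
        imp_rows.append(
            matrix.fill_mask.loc[[conds[numerator]]].iloc[0]
            | matrix.fill_mask.loc[[conds[denominator]]].iloc[0]
        )
    values = pd.DataFrame(rows, index=pd.Index(days, name="day"))
    flagged = pd.DataFrame(flag_rows, index=values.index)
    imputed = pd.DataFrame(imp_rows, index=values.index)
    return FoldChangeTable(values=values, flagged=flagged, imputed=imputed,
                           factor=factor, numerator=numerator, denominator=denominator)


def direction_reversals(
    solutions: Mapping[ContextKey, FluxSolution],
    zero_tol: float = ZERO_TOL,
) -> pd.DataFrame:
    """Reactions whose net flux changes sign between condition pairs per day."""
    by_day: Dict[int, Dict[str, FluxSolution]] = {}
    for ctx, sol in solutions.items():
        by_day.setdefault(ctx.day, {})[ctx.condition] = sol
    rows = []
    for day, conds in sorted(by_day.items()):
        if len(conds) < 2:
            continue
        (ca, sa), (cb, sb) = sorted(conds.items())[:2]
        for rxn in set(sa.fluxes) & set(sb.fluxes):
            va, vb = sa.fluxes[rxn], sb.fluxes[rxn]
            if va * vb < 0 and abs(va) > zero_tol and abs(vb) > zero_tol:
                rows.append({"day": day, "reaction": rxn, ca: va, cb: vb})
    return pd.DataFrame(rows)


def cluster_profiles(
    profiles: pd.DataFrame,
    cut_distance: float = 0.5,
) -> ClusterAssignment:
    """Agglomerate time profiles (items x days) by correlation.

    Distance is 1 - Pearson r with average linkage, cut at
    ``cut_distance`` (r > 0.5 grouped at the default). Constant profiles
    have undefined correlation; they are forced into singleton clusters
    and reported. Labels are 1..K ordered by cluster size (descending),
    then by the smallest member id.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    items = list(profiles.index)
    X = profiles.to_numpy(dtype=float)
    constant = np.ptp(X, axis=1) == 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr = np.where(np.isfinite(corr), corr, -1.0)  # undefined -> max distance
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=cut_distance, criterion="distance")

    groups: Dict[int, List[str]] = {}
    for item, label in zip(items, raw):
        groups.setdefault(int(label), []).append(item)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    labels = {item: k + 1 for k, group in enumerate(ordered) for item in group}
    singletons = [item for item, is_const in zip(items, constant) if is_const]
    return ClusterAssignment(labels=labels, linkage_matrix=Z,
                             cut_distance=cut_distance, singletons=singletons)


def occurrence_percentage(
    context_gem: ContextGEM,
    reported: Iterable[str],
    global_model: MetabolicModel,
) -> float:
    """Share (%) of globally known reported metabolites found in the GEM.

    Reported metabolites absent from the global model are excluded from
    both numerator and denominator before the ratio is taken.
    """
    global_mets = {m.id for m in global_model.metabolites}
    considered = [m for m in dict.fromkeys(reported) if m in global_mets]
    if not considered:
        raise ValueError("no reported metabolite occurs in the global model")
    gem_mets = {m.id for m in context_gem.model.metabolites}
    present = sum(1 for m in considered if m in gem_mets)
    return 100.0 * present / len(considered)


@dataclass
class CensusTables:
    totals: pd.DataFrame          # per context: n_reactions, n_metabolites
    subsystems: pd.DataFrame      # per context x subsystem reaction counts
    condition_specific: pd.DataFrame  # per day: only-in-A / only-in-B / common
    specific_members: Dict[Tuple[int, str], Set[str]]  # (day, condition) -> rxn ids


def model_census(context_gems: Sequence[ContextGEM]) -> CensusTables:
    """Counts of reactions/metabolites/subsystem members per context, and
    per-day condition-specific membership."""
    if not context_gems:
        raise ValueError("no context GEMs supplied")
    totals_rows, subsystem_rows = [], []
    for gem in context_gems:
        totals_rows.append({
            "condition": gem.context.condition,
            "day": gem.context.day,
            "n_reactions": len(gem.model.reactions),
            "n_metabolites": len(gem.model.metabolites),
            "n_reinserted": len(gem.reinserted_reactions),
        })
        counts: Dict[str, int] = {}
        for rxn in gem.model.reactions:
            counts[rxn.subsystem or "(none)"] = counts.get(rxn.subsystem or "(none)", 0) + 1
        for subsystem, n in sorted(counts.items()):
            subsystem_rows.append({
                "condition": gem.context.condition,
                "day": gem.context.day,
                "subsystem": subsystem,
                "n_reactions": n,
            })
    totals = pd.DataFrame(totals_rows).sort_values(["condition", "day"]).reset_index(drop=True)
    subsystems = pd.DataFrame(subsystem_rows)

    by_day: Dict[int, Dict[str, ContextGEM]] = {}
    for gem in context_gems:
        by_day.setdefault(gem.context.day, {})[gem.context.condition] = gem
    spec_rows = []
    members: Dict[Tuple[int, str], Set[str]] = {}
    for day, conds in sorted(by_day.items()):
        if len(conds) != 2:
            continue
        (ca, ga), (cb, gb) = sorted(conds.items())
        ra = {r.id for r in ga.model.reactions}
        rb = {r.id for r in gb.model.reactions}
        ma = {m.id for m in ga.model.metabolites}
        mb = {m.id for m in gb.model.metabolites}
        members[(day, ca)] = ra - rb
        members[(day, cb)] = rb - ra
        spec_rows.append({
            "day": day,
            f"reactions_only_{ca}": len(ra - rb),
            f"reactions_only_{cb}": len(rb - ra),
            "reactions_common": len(ra & rb),
            f"metabolites_only_{ca}": len(ma - mb),
            f"metabolites_only_{cb}": len(mb - ma),
            "metabolites_common": len(ma & mb),
        })
    condition_specific = pd.DataFrame(spec_rows)
    return CensusTables(totals=totals, subsystems=subsystems,
                        condition_specific=condition_specific,
                        specific_members=members)
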