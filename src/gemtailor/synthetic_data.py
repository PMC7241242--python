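"""Synthetic drought scenario: toy GEM, expression series, growth data.

Everything the pipeline consumes can be generated here, with planted
ground truths recorded alongside so recovery is checkable end to end:

* a compartmentalized toy GEM (cytosol/plastid/mitochondrion/peroxisome
  plus an extracellular space) with two parallel equal-yield glycolysis
  routes, a biomass drain over three precursors, transporters without
  gene associations, and one "key" reaction (``GDH_c``) whose presence
  lifts the biomass optimum from 200/27 to 8;
* a 13-day x 2-condition x 4-replicate expression table in which the key
  gene clears the expression threshold only in late control contexts,
  cytosolic glycolysis and one essential mitochondrial gene fall under
  late drought, flavonoid-like genes rise under late drought, and a bank
  of filler genes shapes the pooled value distribution so the threshold
  sweep has an interior optimum;
* growth trajectories that track each other until the divergence day.

The planted truths (active sets, generative quantile, expected biomass)
are derived from the realized noisy values with self-contained numpy
code, independent of the pipeline's own mapping and quantile machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from gemtailor.expression_context import ContextKey, ExpressionSeries, average_replicates
from gemtailor.gimme_tailoring import GrowthSeries
from gemtailor.model_core import MetabolicModel, Metabolite, Reaction

BIOMASS_WITH_KEY = 8.0          # 20 pyruvate / 2.5 per biomass unit
BIOMASS_WITHOUT_KEY = 200.0 / 27.0  # wasteful glutamate route: 2.7 per unit


@dataclass
class ScenarioConfig:
    """Knobs of the planted scenario (documented defaults; tests cite these)."""

    days: int = 13
    conditions: Tuple[str, str] = ("control", "drought")
    replicates: int = 4
    sigma: float = 0.3                 # additive Gaussian noise, log-scale units
    onset_day: int = 11                # first day drought suppression shows
    divergence_day: int = 10           # growth rates split after this day
    base_rate: float = 0.2             # control fresh-weight gain, g/day
    drought_factor: float = 0.5        # late drought rate multiplier
    control_accel_factor: float = 1.3  # control rate multiplier, late days
    control_accel_day: int = 12        # first interval end day with acceleration
    initial_fresh_weight: float = 1.0
    high_expr: float = 9.8
    low_expr: float = 2.5
    suppressed_expr: float = 3.0
    flv_low: float = 2.8
    flv_high: float = 9.6
    key_control_profile: Dict[int, float] = field(
        default_factory=lambda: {11: 7.6, 12: 9.0, 13: 9.2}
    )
    n_filler_low: int = 47
    filler_low_range: Tuple[float, float] = (2.6, 6.0)
    n_filler_band: int = 8
    filler_band_range: Tuple[float, float] = (6.6, 8.6)
    q_grid: Tuple[float, ...] = tuple(round(0.70 + 0.01 * i, 2) for i in range(21))


def _met(mid: str, name: str, comp: str, kegg: Optional[str] = None) -> Metabolite:
    return Metabolite(id=mid, name=name, compartment=comp, external_id=kegg)


def _rxn(rid, stoich, subsystem="", gpr="", lb=0.0, ub=1000.0, obj=0.0, name=None):
    return Reaction(
        id=rid, name=name or rid, stoichiometry=dict(stoich),
        lower_bound=lb, upper_bound=ub, reversible=lb < 0,
        subsystem=subsystem, gene_association=gpr, objective_coefficient=obj,
    )


def _minimal_gem() -> MetabolicModel:
    """Four reactions, two metabolites: the parallel-pathway toy."""
    model = MetabolicModel(id="toy_minimal", compartments={"c": "cytosol"})
    model.metabolites = [_met("A_c", "A", "c"), _met("B_c", "B", "c")]
    model.reactions = [
        _rxn("EX_A", {"A_c": 1}, subsystem="exchange", ub=10.0),
        _rxn("R1", {"A_c": -1, "B_c": 1}, subsystem="core"),
        _rxn("R2", {"A_c": -1, "B_c": 1}, subsystem="core"),
        _rxn("BIO", {"B_c": -1}, subsystem="biomass", obj=1.0),
    ]
    model.validate()
    return model


#: Gene layout of the standard toy: reaction -> (combinator, genes).
#: The combinator is how the generator itself resolves multi-gene rules
#: when computing planted truths (min for complexes, max for isozymes).
STANDARD_GPR: Dict[str, Tuple[str, Tuple[str, ...]]] = {
    "HK_c": ("single", ("gGC1",)),
    "PYK_c": ("and", ("gGC2", "gGC3")),
    "T_glcp": ("single", ("gTP1",)),
    "HK_p": ("single", ("gGP1",)),
    "PYK_p": ("single", ("gGP2",)),
    "AKG_m": ("single", ("gM1",)),
    "LIP_x": ("or", ("gX1", "gX2")),
    "GDH_c": ("single", ("gKEY",)),
    "GLUALT_c": ("single", ("gALT",)),
    "FLV1_c": ("single", ("gF1",)),
    "FLV2_c": ("single", ("gF2",)),
}

#: Planted means for the always-on backbone genes (slightly staggered so
#: no two mapped values tie exactly).
_BACKBONE_MEANS = {
    "gGC1": 9.80, "gGC2": 9.72, "gGC3": 9.90, "gTP1": 9.78,
    "gGP1": 9.82, "gGP2": 9.86, "gALT": 9.76, "gX1": 9.84, "gM1": 9.80,
}

KEY_REACTION = "GDH_c"
DROUGHT_SUPPRESSED = ("gGC1", "gGC2", "gGC3", "gM1")
FLAVONOID_REACTIONS = ("FLV1_c", "FLV2_c")


def _standard_gem(cfg: ScenarioConfig) -> MetabolicModel:
    model = MetabolicModel(
        id="toy_drought",
        compartments={
            "e": "extracellular", "c": "cytosol", "p": "plastid",
            "m": "mitochondrion", "x": "peroxisome",
        },
    )
    model.metabolites = [
        _met("glc_e", "glucose", "e", "C00031"),
        _met("nh4_e", "ammonium", "e", "C01342"),
        _met("glc_c", "glucose", "c", "C00031"),
        _met("g6p_c", "glucose 6-phosphate", "c", "C00092"),
        _met("pyr_c", "pyruvate", "c", "C00022"),
        _met("akg_c", "2-oxoglutarate", "c", "C00026"),
        _met("glu_c", "glutamate", "c", "C00025"),
        _met("flv_c", "flavonoid precursor", "c"),
        _met("flv2_c", "flavonoid", "c"),
        _met("waste_c", "auxiliary drain pool", "c"),
        _met("glc_p", "glucose", "p", "C00031"),
        _met("g6p_p", "glucose 6-phosphate", "p", "C00092"),
        _met("pyr_p", "pyruvate", "p", "C00022"),
        _met("pyr_m", "pyruvate", "m", "C00022"),
        _met("akg_m", "2-oxoglutarate", "m", "C00026"),
        _met("pyr_x", "pyruvate", "x", "C00022"),
        _met("lip_x", "lipid precursor", "x"),
    ]

    def gpr(rid: str) -> str:
        if rid not in STANDARD_GPR:
            return ""
        op, genes = STANDARD_GPR[rid]
        return genes[0] if op == "single" else f" {op} ".join(genes)

    rxns = [
        _rxn("EX_glc", {"glc_e": 1}, "exchange", ub=10.0),
        _rxn("EX_nh4", {"nh4_e": 1}, "exchange"),
        _rxn("T_glc", {"glc_e": -1, "glc_c": 1}, "transport"),
        _rxn("T_nh4", {"nh4_e": -1, "nh4_c": 1}, "transport"),
        _rxn("HK_c", {"glc_c": -1, "g6p_c": 1}, "glycolysis (cytosol)", gpr("HK_c")),
        _rxn("PYK_c", {"g6p_c": -1, "pyr_c": 2}, "glycolysis (cytosol)", gpr("PYK_c")),
        _rxn("T_glcp", {"glc_c": -1, "glc_p": 1}, "transport", gpr("T_glcp")),
        _rxn("HK_p", {"glc_p": -1, "g6p_p": 1}, "glycolysis (plastid)", gpr("HK_p")),
        _rxn("PYK_p", {"g6p_p": -1, "pyr_p": 2}, "glycolysis (plastid)", gpr("PYK_p")),
        _rxn("T_pyrp", {"pyr_p": -1, "pyr_c": 1}, "transport"),
        _rxn("T_pyrm", {"pyr_c": -1, "pyr_m": 1}, "transport"),
        _rxn("AKG_m", {"pyr_m": -1, "akg_m": 1}, "TCA (mitochondrion)", gpr("AKG_m")),
        _rxn("T_akg", {"akg_m": -1, "akg_c": 1}, "transport"),
        _rxn("T_pyrx", {"pyr_c": -1, "pyr_x": 1}, "transport"),
        _rxn("LIP_x", {"pyr_x": -1, "lip_x": 1}, "lipid (peroxisome)", gpr("LIP_x")),
        _rxn("GDH_c", {"akg_c": -1, "nh4_c": -1, "glu_c": 1},
             "nitrogen assimilation", gpr("GDH_c"), name="glutamate dehydrogenase analogue"),
        _rxn("GLUALT_c", {"akg_c": -1, "nh4_c": -1, "pyr_c": -0.2, "glu_c": 1},
             "nitrogen assimilation", gpr("GLUALT_c"), name="wasteful glutamate route"),
        _rxn("FLV1_c", {"pyr_c": -1, "flv_c": 1}, "flavonoid biosynthesis", gpr("FLV1_c")),
        _rxn("FLV2_c", {"flv_c": -1, "flv2_c": 1}, "flavonoid biosynthesis", gpr("FLV2_c")),
        _rxn("SINK_flv", {"flv2_c": -1}, "exchange"),
        _rxn("SINK_waste", {"waste_c": -1}, "exchange"),
        _rxn("BIO", {"pyr_c": -1, "glu_c": -1, "lip_x": -0.5}, "biomass", obj=1.0,
             name="biomass drain"),
    ]
    model.metabolites.append(_met("nh4_c", "ammonium", "c", "C01342"))

    filler_sources = ["pyr_c", "g6p_c", "glc_c", "akg_c"]
    n_total = cfg.n_filler_low + cfg.n_filler_band
    for k in range(n_total):
        src = filler_sources[k % len(filler_sources)]
        gene = f"gFILL{k + 1:02d}"
        rxns.append(_rxn(f"AUX{k + 1:02d}", {src: -1, "waste_c": 1},
                         "auxiliary drain", gene))
    model.reactions = rxns
    model.validate()
    return model


def generate_toy_gem(seed: int, size_class: str = "standard",
                     config: Optional[ScenarioConfig] = None) -> MetabolicModel:
    """Deterministic toy GEM; ``seed`` is accepted for interface symmetry
    (the structure is fixed by the config, not sampled)."""
    if size_class == "minimal":
        return _minimal_gem()
    if size_class == "standard":
        return _standard_gem(config or ScenarioConfig())
    raise ValueError(f"unknown size_class {size_class!r}")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def gpr_map(cfg: ScenarioConfig) -> Dict[str, Tuple[str, Tuple[str, ...]]]:
    """Reaction -> (combinator, genes) for the standard toy, fillers included."""
    table = dict(STANDARD_GPR)
    for k in range(cfg.n_filler_low + cfg.n_filler_band):
        table[f"AUX{k + 1:02d}"] = ("single", (f"gFILL{k + 1:02d}",))
    return table


def _filler_means(cfg: ScenarioConfig) -> Dict[str, float]:
    lows = np.linspace(*cfg.filler_low_range, cfg.n_filler_low)
    bands = np.linspace(*cfg.filler_band_range, cfg.n_filler_band)
    means = {}
    for k, value in enumerate(list(lows) + list(bands)):
        means[f"gFILL{k + 1:02d}"] = float(value)
    return means


def planted_mean(gene: str, condition: str, day: int, cfg: ScenarioConfig) -> float:
    """The noise-free planted expression value for one (gene, context)."""
    fillers = _filler_means(cfg)
    if gene in fillers:
        return fillers[gene]
    if gene == "gKEY":
        if condition == "control" and day in cfg.key_control_profile:
            return cfg.key_control_profile[day]
        return cfg.low_expr
    if gene in ("gF1", "gF2"):
        if condition == "drought" and day >= cfg.onset_day:
            return cfg.flv_high
        return cfg.flv_low
    if gene == "gX2":
        return 2.2
    if gene in _BACKBONE_MEANS:
        base = _BACKBONE_MEANS[gene]
        if gene in DROUGHT_SUPPRESSED and condition == "drought" and day >= cfg.onset_day:
            return cfg.suppressed_expr + (0.2 if gene == "gM1" else 0.0)
        return base
    raise KeyError(f"no planted profile for gene {gene!r}")


def _all_genes(cfg: ScenarioConfig) -> List[str]:
    genes = sorted(_BACKBONE_MEANS) + ["gKEY", "gF1", "gF2", "gX2"]
    genes += sorted(_filler_means(cfg))
    return genes


@dataclass
class SyntheticExpression:
    """Raw replicate-level table plus its sample sheet."""

    table: pd.DataFrame         # genes x samples
    sample_sheet: pd.DataFrame  # sample_id, condition, day, replicate

    def series(self) -> ExpressionSeries:
        return average_replicates(self.table, self.sample_sheet)

    def write(self, table_path: str, sheet_path: str) -> None:
        self.table.to_csv(table_path, sep="\t", index_label="gene")
        self.sample_sheet.to_csv(sheet_path, sep="\t", index=False)


def generate_expression_series(
    seed: int,
    gem: MetabolicModel,
    days: int = 13,
    conditions: Sequence[str] = ("control", "drought"),
    replicates: int = 4,
    config: Optional[ScenarioConfig] = None,
) -> SyntheticExpression:
    """Replicate-level expression table with planted context patterns."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if not any(r.gene_association for r in gem.reactions):
        raise ValueError("the GEM carries no gene associations to emulate")
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng([int(seed), 101])
    genes = _all_genes(cfg)

    columns, meta = [], []
    for condition in conditions:
        for day in range(1, days + 1):
            for rep in range(1, replicates + 1):
                columns.append(f"{condition}_d{day:02d}_r{rep}")
                meta.append((condition, day, rep))
    means = np.array([
        [planted_mean(g, cond, day, cfg) for (cond, day, _rep) in meta]
        for g in genes
    ])
    noise = rng.normal(0.0, cfg.sigma, size=means.shape)
    table = pd.DataFrame(means + noise, index=pd.Index(genes, name="gene"),
                         columns=columns)
    sheet = pd.DataFrame(
        [{"sample_id": s, "condition": c, "day": d, "replicate": r}
         for s, (c, d, r) in zip(columns, meta)]
    )
    return SyntheticExpression(table=table, sample_sheet=sheet)


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------


def generate_growth_series(
    seed: int,
    days: int = 13,
    config: Optional[ScenarioConfig] = None,
) -> GrowthSeries:
    """Fresh-weight trajectories: shared early, split after the divergence
    day (drought slows; control modestly accelerates on the last days so
    the late-control biomass lift is echoed in the observations)."""
    cfg = config or ScenarioConfig()
    rows = []
    for condition in cfg.conditions:
        weight = cfg.initial_fresh_weight
        rows.append({"condition": condition, "day": 1, "fresh_weight_g": weight})
        for day in range(2, days + 1):
            rate = cfg.base_rate
            if condition == "drought" and day > cfg.divergence_day:
                rate = cfg.base_rate * cfg.drought_factor
            elif condition == "control" and day >= cfg.control_accel_day:
                rate = cfg.base_rate * cfg.control_accel_factor
            weight += rate
            rows.append({"condition": condition, "day": day,
                         "fresh_weight_g": round(weight, 9)})
    return GrowthSeries(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Whole scenario with planted truths
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScenario:
    gem: MetabolicModel
    expression: SyntheticExpression
    growth: GrowthSeries
    truths: dict
    config: ScenarioConfig
    seed: int

    def write(self, directory: str) -> Dict[str, str]:
        """Emit the pipeline-consumable files; returns name -> path."""
        from gemtailor.model_core import write_gem

        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gem": str(out / "gem.xml"),
            "expression": str(out / "expression.tsv"),
            "sample_sheet": str(out / "sample_sheet.tsv"),
            "growth": str(out / "growth.tsv"),
            "truths": str(out / "truths.json"),
        }
        write_gem(self.gem, paths["gem"])
        self.expression.write(paths["expression"], paths["sample_sheet"])
        self.growth.to_tsv(paths["growth"])
        payload = dict(self.truths)
        payload["seed"] = self.seed
        payload["active_reactions"] = {
            f"{c}_day{d}": sorted(v)
            for (c, d), v in self.truths["active_reactions"].items()
        }
        with open(paths["truths"], "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
        return paths


def _realized_context_means(expr: SyntheticExpression) -> Dict[ContextKey, Dict[str, float]]:
    """Replicate averages recomputed directly from the raw table."""
    sheet = expr.sample_sheet
    out: Dict[ContextKey, Dict[str, float]] = {}
    for (condition, day), group in sheet.groupby(["condition", "day"]):
        cols = list(group["sample_id"])
        means = expr.table[cols].to_numpy().mean(axis=1)
        out[ContextKey(str(condition), int(day))] = dict(zip(expr.table.index, means))
    return out


def _combine(op: str, values: List[float]) -> float:
    if op == "and":
        return min(values)
    if op == "or":
        return max(values)
    return values[0]


def generate_scenario(
    seed: int,
    size_class: str = "standard",
    config: Optional[ScenarioConfig] = None,
) -> SyntheticScenario:
    """Full scenario with planted truths derived from the realized data.

    The generative quantile is the smallest grid quantile whose pooled
    threshold exceeds the realized key-gene average at (control, day 11):
    exactly there the key reaction flips from three late-control days to
    the planted two, matching the growth trajectory's acceleration.
    """
    cfg = config or ScenarioConfig()
    gem = generate_toy_gem(seed, size_class, cfg)
    expression = generate_expression_series(
        seed, gem, cfg.days, cfg.conditions, cfg.replicates, cfg
    )
    growth = generate_growth_series(seed, cfg.days, cfg)

    ctx_means = _realized_context_means(expression)
    mapped: Dict[ContextKey, Dict[str, float]] = {}
    for ctx, gene_vals in ctx_means.items():
        vals = {}
        for rid, (op, genes) in gpr_map(cfg).items():
            vals[rid] = _combine(op, [gene_vals[g] for g in genes])
        mapped[ctx] = vals

    pooled = np.sort(np.concatenate([list(v.values()) for v in mapped.values()]))
    key_day11 = ctx_means[ContextKey("control", cfg.onset_day)]["gKEY"]
    thresholds = {q: float(np.quantile(pooled, q)) for q in cfg.q_grid}
    q_gen = None
    for q in sorted(cfg.q_grid):
        if thresholds[q] > key_day11:
            q_gen = q
            break
    if q_gen is None:
        raise RuntimeError(
            "planted scenario failed: no grid quantile clears the key gene's "
            "day-11 control value; adjust the filler configuration"
        )
    t_gen = thresholds[q_gen]

    no_gene = {r.id for r in gem.reactions if not r.gene_association}
    active: Dict[ContextKey, Set[str]] = {}
    biomass: Dict[ContextKey, float] = {}
    for ctx, vals in mapped.items():
        kept = set(no_gene) | {rid for rid, v in vals.items() if v > t_gen}
        # the lone pyruvate->2-oxoglutarate step is essential: GIMME must
        # reinsert it whenever its gene dips below threshold
        kept.add("AKG_m")
        active[ctx] = kept
        biomass[ctx] = BIOMASS_WITH_KEY if KEY_REACTION in kept else BIOMASS_WITHOUT_KEY

    late_days = [d for d in range(1, cfg.days + 1) if d >= cfg.onset_day]
    truths = {
        "key_reaction": KEY_REACTION,
        "key_gene": "gKEY",
        "generative_quantile": q_gen,
        "generative_threshold": t_gen,
        "key_day11_control_mean": float(key_day11),
        "divergence_day": cfg.divergence_day,
        "onset_day": cfg.onset_day,
        "late_days": late_days,
        "key_reaction_contexts": [
            ["control", d] for d in sorted(cfg.key_control_profile)
            if ContextKey("control", d) in active
            and KEY_REACTION in active[ContextKey("control", d)]
        ],
        "drought_only_late_reactions": sorted(FLAVONOID_REACTIONS),
        "biomass_with_key": BIOMASS_WITH_KEY,
        "biomass_without_key": BIOMASS_WITHOUT_KEY,
        "active_reactions": active,
        "expected_biomass": {f"{c}_day{d}": v for (c, d), v in biomass.items()},
        "sigma": cfg.sigma,
    }
    return SyntheticScenario(gem=gem, expression=expression, growth=growth,
                             truths=truths, config=cfg, seed=int(seed))
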