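"""Expression tables: replicate averaging, reaction mapping, thresholds."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from gemtailor._gpr import GprParseError, evaluate_gpr, parse_gpr
from gemtailor.model_core import MetabolicModel


class ContextKey(NamedTuple):
    """One (condition, day) cell of the experimental design."""

    condition: str
    day: int


@dataclass
class ExpressionSeries:
    """Replicate-averaged gene expression per (condition, day) context.

    ``values`` is a genes x contexts frame whose columns are a
    (condition, day) MultiIndex. Missing entries are NaN, never silently
    zero.
    """

    values: pd.DataFrame

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def contexts(self) -> List[ContextKey]:
        return [ContextKey(cond, int(day)) for cond, day in self.values.columns]

    def gene_values(self, context: ContextKey) -> Dict[str, float]:
        """Per-gene values for one context; genes missing there are dropped."""
        col = self.values[(context.condition, context.day)]
        return {g: float(v) for g, v in col.items() if not pd.isna(v)}

    def to_tsv(self, path: str) -> None:
        frame = self.values.copy()
        frame.columns = [f"{c}_day{d}" for c, d in frame.columns]
        frame.to_csv(path, sep="\t", index_label="gene")


def read_expression_table(path: str) -> pd.DataFrame:
    """Genes-as-rows, samples-as-columns TSV/CSV (delimiter sniffed)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_sample_sheet(path: str) -> pd.DataFrame:
    """TSV with columns sample_id, condition, day, replicate."""
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "day", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path!r} lacks columns {sorted(missing)}")
    return sheet


def average_replicates(table: pd.DataFrame, sample_sheet: pd.DataFrame) -> ExpressionSeries:
    """Arithmetic mean over replicates for every (condition, day) context.

    A gene missing (NaN) in some replicates is averaged over the
    remaining ones; missing in all replicates of a context leaves NaN.
    """
    sheet_samples = set(sample_sheet["sample_id"])
    table_samples = set(table.columns)
    orphans = sorted(table_samples - sheet_samples)
    if orphans:
        raise ValueError(f"samples absent from the sample sheet: {orphans}")
    ghosts = sorted(sheet_samples - table_samples)
    if ghosts:
        contexts = sample_sheet[sample_sheet["sample_id"].isin(ghosts)][["condition", "day"]]
        listing = sorted({(c, int(d)) for c, d in contexts.itertuples(index=False)})
        raise ValueError(
            f"sample sheet samples missing from the table: {ghosts} (contexts {listing})"
        )

    columns: Dict[ContextKey, pd.Series] = {}
    grouped = sample_sheet.groupby(["condition", "day"], sort=True)
    for (condition, day), group in grouped:
        samples = list(group["sample_id"])
        if not samples:
            raise ValueError(f"context ({condition}, {day}) has zero samples")
        columns[ContextKey(str(condition), int(day))] = table[samples].mean(axis=1)

    frame = pd.DataFrame(columns)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["condition", "day"])
    frame = frame.sort_index(axis=1)
    return ExpressionSeries(values=frame)


def map_expression_to_reactions(
    model: MetabolicModel,
    gene_values: Mapping[str, float],
    and_mode=min,
    or_mode=max,
) -> Dict[str, float]:
    """One expression value per gene-associated reaction.

    AND resolves by ``and_mode`` (min), OR by ``or_mode`` (max).
    Reactions without a gene association -- or whose genes are all
    uncovered -- are absent from the result, not zero.
    """
    mapped: Dict[str, float] = {}
    for rxn in model.reactions:
        if not rxn.gene_association:
            continue
        try:
            ast = parse_gpr(rxn.gene_association)
        except GprParseError:
            continue  # unparsable rule treated as absent
        value = evaluate_gpr(ast, gene_values, and_mode=and_mode, or_mode=or_mode)
        if value is not None:
            mapped[rxn.id] = float(value)
    return mapped


def pooled_reaction_values(
    model: MetabolicModel,
    series: ExpressionSeries,
    and_mode=min,
    or_mode=max,
) -> np.ndarray:
    """All reaction-mapped values pooled over every context (threshold base)."""
    pooled: List[float] = []
    for context in series.contexts:
        pooled.extend(
            map_expression_to_reactions(
                model, series.gene_values(context), and_mode, or_mode
            ).values()
        )
    return np.asarray(pooled, dtype=float)


def quantile_threshold(values: Iterable[float], q: float) -> float:
    """q-th quantile under the sorted-array linear-interpolation convention."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a quantile of an empty value set")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile fraction must be in [0, 1], got {q}")
    return float(np.quantile(arr, q, method="linear"))
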