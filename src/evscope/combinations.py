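"""Protein co-expression pair statistics.

For each sample, the number of EVs carrying both members of each unordered
protein pair is counted; pair counts are CPM-normalized within the sample
(per million pair observations) and compared between groups with the same
adaptive two-group testing used for single proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionSet, differential_test
from .matrix import SingleEVMatrix

logger = logging.getLogger(__name__)


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) key of an unordered protein pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class CombinationTable:
    """Per-sample EV counts for each co-expressed protein pair."""

    sample_id: str
    pairs: dict[tuple[str, str], int] = field(default_factory=dict)
    cpm: dict[tuple[str, str], float] | None = None

    @property
    def total(self) -> int:
        return sum(self.pairs.values())


def count_combinations(matrix: SingleEVMatrix,
                       min_molecules: int = 1) -> CombinationTable:
    """Count EVs on which both proteins of each pair are detected.

    "Detected" means >= ``min_molecules`` molecules. Computed as the upper
    triangle of Bᵀ B for the binary detection matrix B.
    """
    B = matrix.counts.copy()
    B.data = (B.data >= min_molecules).astype(np.int64)
    B.eliminate_zeros()
    co = (B.T @ B).tocoo()
    proteins = matrix.proteins
    pairs = {}
    for i, j, v in zip(co.row, co.col, co.data):
        if i < j and v > 0:
            pairs[pair_key(proteins[i], proteins[j])] = int(v)
    return CombinationTable(matrix.sample_id, pairs)


def cpm_normalize(table: CombinationTable) -> CombinationTable:
    """Counts per million over the sample's total pair observations."""
    total = table.total
    if total == 0:
        raise ValueError(f"sample {table.sample_id}: no co-expressed pairs")
    table.cpm = {k: v / total * 1e6 for k, v in table.pairs.items()}
    return table


def combination_frame(tables: list[CombinationTable],
                      use_cpm: bool = True) -> pd.DataFrame:
    """Pair x sample table (absent pairs = 0)."""
    cols = {}
    for t in tables:
        if use_cpm:
            if t.cpm is None:
                cpm_normalize(t)
            cols[t.sample_id] = pd.Series(
                {f"{a}+{b}": v for (a, b), v in t.cpm.items()})
        else:
            cols[t.sample_id] = pd.Series(
                {f"{a}+{b}": v for (a, b), v in t.pairs.items()})
    return pd.DataFrame(cols).fillna(0.0).sort_index()


def differential_combinations(tables: list[CombinationTable],
                              groups: pd.Series, case_group: str,
                              min_samples_observed: int = 2,
                              alpha_assumption: float = 0.05) -> pd.DataFrame:
    """Two-group testing of per-pair CPM values.

    Pairs observed (count > 0) in fewer than ``min_samples_observed``
    samples are excluded and logged.
    """
    frame = combination_frame(tables, use_cpm=True)
    observed = (frame > 0).sum(axis=1)
    excluded = frame.index[observed < min_samples_observed]
    if len(excluded):
        logger.info("excluding %d pairs observed in < %d samples",
                    len(excluded), min_samples_observed)
    frame = frame.drop(index=excluded)
    expr = ExpressionSet(frame, groups.loc[frame.columns])
    # values are already per-sample CPM; test them as-is
    result = differential_test(expr, case_group,
                               alpha_assumption=alpha_assumption,
                               use_normalized=False)
    result["n_samples_observed"] = observed.loc[result.index]
    return result


def focal_partners(diff_pairs: pd.DataFrame, focal: str,
                   q_threshold: float = 0.05) -> list[str]:
    """Significant case-enriched partners of one focal protein, ordered by
    ascending q-value."""
    rows = []
    for key, row in diff_pairs.iterrows():
        a, b = str(key).split("+")
        if focal not in (a, b):
            continue
        if row.direction == "up" and row.q_value < q_threshold:
            rows.append((row.q_value, b if a == focal else a))
    return [name for _, name in sorted(rows)]
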