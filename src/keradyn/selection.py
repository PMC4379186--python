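"""AIC model selection over the scenario collection.

For least-squares fits with ``n`` observations the Akaike information
criterion of scenario ``i`` is ``AIC_i = n ln(Psi_i / n) + 2 K_i`` where
``Psi_i`` is the residual sum of squares and ``K_i`` counts the estimated
parameters (free turnover parameters plus one for the residual
variance).  Scenarios are compared through the differences
``Delta_i = AIC_i - AIC_min`` and the Akaike weights

    w_i = exp(-Delta_i / 2) / sum_r exp(-Delta_r / 2),

interpreted as the probability that scenario ``i`` is the best model of
the collection given the data.  The weights are computed in the
Delta-shifted form, which is overflow-safe.  Derived quantities: ranks
(descending weight, ties broken by ascending index), the 95% confidence
set (smallest prefix of the ranking whose weights sum to at least 0.95),
pairwise evidence ratios ``w_i / w_j = exp((AIC_j - AIC_i)/2)``, and
process-importance sums of weights over partitions of the collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from numpy.typing import NDArray

from .profiles import N_POINTS_DEFAULT
from .scenarios import build_scenario

__all__ = [
    "N_SAMPLE_DEFAULT",
    "WEIGHT_PRINT_FLOOR",
    "SelectionTable",
    "GroupImportance",
    "aic",
    "selection_from_aic",
    "akaike_table",
    "evidence_ratio",
    "group_importance",
    "standard_groupings",
]

# the sample size of the least-squares fit is the number of grid points
N_SAMPLE_DEFAULT = N_POINTS_DEFAULT

# weights below this are printed as 0 in reports (full precision is kept
# internally)
WEIGHT_PRINT_FLOOR = 1e-12


def aic(psi: float, n: int = N_SAMPLE_DEFAULT, K: int = 3) -> float:
    """Akaike criterion ``n ln(psi/n) + 2K`` for a least-squares fit."""
    if psi <= 0:
        raise ValueError("psi must be positive (a perfect fit has a "
                         "degenerate AIC and must be handled separately)")
    if n <= 0 or K < 1:
        raise ValueError("need n > 0 and K >= 1")
    return n * float(np.log(psi / n)) + 2 * K


@dataclass(frozen=True)
class SelectionTable:
    """Per-scenario AIC comparison: Delta, weight and rank columns plus
    the best index and the 95% confidence set."""

    indices: tuple[int, ...]
    K: tuple[int, ...]
    aic_values: NDArray[np.float64] = field(repr=False)
    delta: NDArray[np.float64] = field(repr=False)
    weight: NDArray[np.float64] = field(repr=False)
    rank: tuple[int, ...]
    best_index: int
    confidence_set: tuple[int, ...]

    def row(self, index: int) -> dict:
        i = self.indices.index(index)
        return {"index": index, "K": self.K[i],
                "aic": float(self.aic_values[i]),
                "delta": float(self.delta[i]),
                "weight": float(self.weight[i]), "rank": self.rank[i]}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "scenario": self.indices, "K": self.K, "AIC": self.aic_values,
            "delta": self.delta, "weight": self.weight, "rank": self.rank,
        })


def selection_from_aic(indices: Iterable[int], aic_values: Iterable[float],
                       K: Iterable[int] | None = None,
                       confidence: float = 0.95) -> SelectionTable:
    """Build the comparison table from AIC values directly (e.g. from a
    published ranking table)."""
    indices = tuple(int(i) for i in indices)
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate scenario indices")
    if len(indices) < 2:
        raise ValueError("need at least two scenarios to compare")
    aic_values = np.asarray(list(aic_values), dtype=float)
    if aic_values.shape != (len(indices),):
        raise ValueError("one AIC value per scenario index required")
    K = (tuple(int(k) for k in K) if K is not None
         else tuple(0 for _ in indices))

    delta = aic_values - aic_values.min()
    raw = np.exp(-0.5 * delta)
    weight = raw / raw.sum()

    # rank by descending weight, ties broken by ascending scenario index
    order = sorted(range(len(indices)), key=lambda i: (-weight[i], indices[i]))
    rank = [0] * len(indices)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    best_index = indices[order[0]]

    cum, conf_set = 0.0, []
    for i in order:
        conf_set.append(indices[i])
        cum += weight[i]
        if cum >= confidence:
            break
    return SelectionTable(
        indices=indices, K=K, aic_values=aic_values, delta=delta,
        weight=weight, rank=tuple(rank), best_index=best_index,
        confidence_set=tuple(conf_set))


def akaike_table(fits, n: int = N_SAMPLE_DEFAULT,
                 confidence: float = 0.95) -> SelectionTable:
    """Build the comparison table from :class:`~keradyn.fitting.FitResult`
    objects (AIC computed from each residual Psi)."""
    fits = list(fits)
    return selection_from_aic(
        indices=[f.scenario_index for f in fits],
        aic_values=[aic(f.psi, n=n, K=f.K) for f in fits],
        K=[f.K for f in fits],
        confidence=confidence)


def evidence_ratio(table: SelectionTable, i: int, j: int) -> float:
    """Evidence ratio ``w_i / w_j``, computed from the AIC difference
    ``exp((AIC_j - AIC_i)/2)`` for numerical stability."""
    ai = table.aic_values[table.indices.index(i)]
    aj = table.aic_values[table.indices.index(j)]
    return float(np.exp(0.5 * (aj - ai)))


@dataclass(frozen=True)
class GroupImportance:
    """Summed Akaike weights over a partition of the collection."""

    grouping: str
    weights: dict[str, float]

    def ordered(self) -> list[tuple[str, float]]:
        return sorted(self.weights.items(), key=lambda kv: -kv[1])


def group_importance(table: SelectionTable,
                     grouping: Mapping[int, str],
                     name: str = "grouping") -> GroupImportance:
    """Sum the Akaike weights of all scenarios sharing a label; over a
    partition of the collection the sums total 1."""
    missing = [i for i in table.indices if i not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover indices {missing}")
    sums: dict[str, float] = {}
    for idx, w in zip(table.indices, table.weight):
        label = grouping[idx]
        sums[label] = sums.get(label, 0.0) + float(w)
    return GroupImportance(grouping=name, weights=sums)


def standard_groupings(indices: Iterable[int] = range(1, 37)
                       ) -> dict[str, dict[int, str]]:
    """The partitions used to assess process importance: drift mode,
    turnover kind, assembly profile, disassembly profile, and the
    assembly x disassembly combination."""
    specs = {i: build_scenario(i) for i in indices}
    return {
        "drift": {i: s.drift for i, s in specs.items()},
        "turnover": {i: s.turnover for i, s in specs.items()},
        "assembly": {i: s.assembly for i, s in specs.items()},
        "disassembly": {i: s.disassembly for i, s in specs.items()},
        "assembly_x_disassembly": {
            i: f"{s.assembly}+{s.disassembly}" for i, s in specs.items()},
    }
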