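"""Cross-compartment concordance screen.

Finds proteins regulated beyond a linear fold threshold in the same
direction in two cell-type compartments (e.g. keratinocytes and immune
cells) for the same disease-versus-healthy contrast. "At least fourfold"
means log2 fold change >= 2 inclusively, in both compartments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import DEPResult
from .errors import ValidationError

__all__ = ["ConcordanceResult", "cross_compartment_concordance"]


@dataclass
class ConcordanceResult:
    table: pd.DataFrame       # protein, log2fc_a, log2fc_b, q_a, q_b
    fold: float
    direction: str
    require_significance: bool

    @property
    def proteins(self) -> list[str]:
        return list(self.table.index)


def cross_compartment_concordance(dep_a: DEPResult, dep_b: DEPResult,
                                  fold: float = 4.0, direction: str = "up",
                                  require_significance: bool = True,
                                  alpha: float = 0.05) -> ConcordanceResult:
    """Proteins with linear fold change >= ``fold`` in both compartments.

    The threshold is applied as log2fc >= log2(fold) (inclusive) for
    ``direction='up'``, or log2fc <= -log2(fold) for ``'down'``. With
    ``require_significance`` both q-values must additionally be below
    ``alpha``. The shared protein universe is the intersection of the two
    tables.
    """
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    if fold <= 0:
        raise ValidationError(f"fold must be > 0, got {fold}")
    shared = dep_a.table.index.intersection(dep_b.table.index)
    if len(shared) == 0:
        raise ValidationError("disjoint protein universes between compartments")
    a = dep_a.table.loc[shared]
    b = dep_b.table.loc[shared]
    cut = np.log2(fold)
    if direction == "up":
        mask = (a["log2fc"] >= cut) & (b["log2fc"] >= cut)
    else:
        mask = (a["log2fc"] <= -cut) & (b["log2fc"] <= -cut)
    if require_significance:
        mask &= (a["q_value"] < alpha) & (b["q_value"] < alpha)
    table = pd.DataFrame({
        "log2fc_a": a.loc[mask, "log2fc"],
        "log2fc_b": b.loc[mask, "log2fc"],
        "q_a": a.loc[mask, "q_value"],
        "q_b": b.loc[mask, "q_value"],
    })
    return ConcordanceResult(table=table, fold=fold, direction=direction,
                             require_significance=require_significance)
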