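"""Gene-set overrepresentation analysis (hypergeometric, BH across sets).

For a hit list of size n drawn from a measured universe of size M, a gene
set with K members in the universe and overlap k has upper-tail p-value
P(X >= k) under Hypergeometric(M, K, n); the enrichment ratio is k over
the expected overlap n*K/M. The natural universe is the set of proteins
surviving the identification filter for the cell type under study.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .diffexp import benjamini_hochberg
from .errors import ValidationError

__all__ = ["ora"]


def ora(hits, collection: dict[str, list[str]], universe) -> pd.DataFrame:
    """Overrepresentation of ``hits`` in each gene set of ``collection``.

    Returns one row per set: overlap k, set size in universe, expected
    overlap, enrichment_ratio, p_value, q_value. Set members outside the
    universe are ignored; hits must be a subset of the universe.
    """
    universe = set(universe)
    hits = set(hits)
    if not hits:
        raise ValidationError("empty hit list")
    stray = hits - universe
    if stray:
        raise ValidationError(
            f"hits outside the universe: {sorted(stray)[:5]}")
    if not collection:
        raise ValidationError("empty gene-set collection")
    M, n = len(universe), len(hits)
    rows = []
    for name, members in collection.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        k = len(in_universe & hits)
        expected = n * K / M
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append({
            "gene_set": name,
            "overlap": k,
            "set_size": K,
            "expected": expected,
            "enrichment_ratio": (k / expected) if expected > 0 else float("nan"),
            "p_value": min(p, 1.0),
        })
    table = pd.DataFrame(rows).set_index("gene_set")
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    return table.sort_values(["p_value", "enrichment_ratio"],
                             ascending=[True, False], kind="stable")
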