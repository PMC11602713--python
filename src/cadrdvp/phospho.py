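"""Phosphoproteomic post-processing.

Class-I phosphosites are those with localization probability strictly
greater than 0.75. Multiplicity variants of the same (protein, position)
are collapsed after differential testing by keeping the variant with the
larger |log2 fold change|, breaking ties by larger -log10(p) and then by
smaller multiplicity for determinism. Site-level statistics reuse the
diffexp machinery.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["classify_sites", "collapse_multiplicity", "site_log2fc_cut"]

CLASS_I_PROBABILITY = 0.75  # strict lower bound

#: default log2 fold-change cut for site-level overrepresentation input
site_log2fc_cut = 0.5


def classify_sites(table: pd.DataFrame,
                   prob_col: str = "localization_probability") -> pd.DataFrame:
    """Add a boolean ``class_i`` column (probability > 0.75, strict).

    Counts of both classes are stored in ``df.attrs``.
    """
    if prob_col not in table.columns:
        raise ValidationError(f"phosphosite table lacks column {prob_col!r}")
    prob = table[prob_col].astype(float)
    if ((prob < 0) | (prob > 1)).any():
        bad = prob[(prob < 0) | (prob > 1)]
        raise ValidationError(
            f"localization probabilities outside [0, 1]: {bad.iloc[:5].tolist()}")
    out = table.copy()
    out["class_i"] = prob > CLASS_I_PROBABILITY
    out.attrs["n_class_i"] = int(out["class_i"].sum())
    out.attrs["n_non_class_i"] = int((~out["class_i"]).sum())
    return out


def collapse_multiplicity(site_results: pd.DataFrame,
                          key_cols: tuple[str, str] = ("protein", "position"),
                          fc_col: str = "log2fc",
                          p_col: str = "p_value") -> pd.DataFrame:
    """One record per (protein, position): drop redundant multiplicity variants.

    Ranking: |log2fc| descending, then -log10(p) descending, then
    multiplicity ascending. When the two criteria disagree for a key (the
    |fc|-best variant is not the p-best one) the conflict is logged.
    """
    for col in (*key_cols, fc_col, p_col, "multiplicity"):
        if col not in site_results.columns:
            raise ValidationError(f"site table lacks column {col!r}")
    df = site_results.copy()
    df["_abs_fc"] = df[fc_col].abs()
    with np.errstate(divide="ignore"):
        df["_neglogp"] = -np.log10(df[p_col].astype(float))

    ranked = df.sort_values(by=["_abs_fc", "_neglogp", "multiplicity"],
                            ascending=[False, False, True], kind="stable")
    collapsed = ranked.drop_duplicates(subset=list(key_cols), keep="first")

    # log keys where the |fc|-best and p-best variants disagree
    best_p = (df.sort_values(by="_neglogp", ascending=False, kind="stable")
                .drop_duplicates(subset=list(key_cols), keep="first"))
    merged = collapsed.merge(best_p, on=list(key_cols),
                             suffixes=("_fc", "_p"))
    conflicts = merged[merged["_neglogp_fc"] < merged["_neglogp_p"]]
    for _, row in conflicts.iterrows():
        logger.info("multiplicity collapse conflict at %s: kept |fc|-best "
                    "variant over p-best", tuple(row[list(key_cols)]))

    collapsed = collapsed.drop(columns=["_abs_fc", "_neglogp"])
    return collapsed.reset_index(drop=True)
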