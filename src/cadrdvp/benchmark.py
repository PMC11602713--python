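"""Ground-truthed recovery benchmarks for the pipeline's inference stages.

Each scenario fixes a synthetic study design with planted truth and measures
how well a stage recovers it: type-I error of the DEP calling under the
null, sensitivity on planted fold-change modules, exactness of the
cross-compartment concordance screen, and the rank of a planted
disease-specific interaction among decoys. They are used both by the test
suite and by the reproduction script, so the measured operating
characteristics always refer to one fixed set of study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stream
from .concordance import cross_compartment_concordance
from .crosstalk import CrosstalkConfig, run_crosstalk
from .diffexp import t_test_dep
from .preprocess import average_replicates, filter_by_identification_rate
from .simulate import (CohortSimConfig, PlantedInteraction, PlantedModule,
                       generate_cohort, generate_interaction_table)

__all__ = [
    "null_dep_fraction",
    "planted_module_sensitivity",
    "concordance_recovery",
    "crosstalk_interaction_rank",
]


def null_dep_fraction(seed: int, n_proteins: int = 1000,
                      alpha: float = 0.05) -> tuple[int, int]:
    """(significant, tested) protein counts under a no-effect null cohort.

    Two cohorts, one cell type, default MNAR dropout, no planted effects;
    the t-test + BH stage should call about alpha or fewer proteins
    significant (q < alpha, no fold cut).
    """
    config = CohortSimConfig(n_proteins=n_proteins, cohorts=("healthy", "TEN"),
                             cell_types=("keratinocyte",), seed=seed)
    matrix, _ = generate_cohort(config)
    filtered = filter_by_identification_rate(average_replicates(matrix))
    dep = t_test_dep(filtered, "TEN", "healthy", alpha=alpha, fc_cut=0.0)
    q = dep.table["q_value"]
    return int((q < alpha).sum()), int(q.notna().sum())


def planted_module_sensitivity(seed: int, n_proteins: int = 300,
                               module_size: int = 50,
                               log2_effect: float = 3.0,
                               noise_sd: float = 0.5) -> tuple[int, int]:
    """(recovered, planted) counts for an interferon-signature-like module.

    ``module_size`` proteins are shifted by ``log2_effect`` in the disease
    keratinocytes of a two-cohort design with five individuals per cohort;
    recovery means an "up" DEP call (q < 0.05, log2fc >= 1).
    """
    proteins = CohortSimConfig(n_proteins=n_proteins).protein_ids()
    module = tuple(proteins[:module_size])
    config = CohortSimConfig(
        n_proteins=n_proteins, cohorts=("healthy", "TEN"),
        cell_types=("keratinocyte",), noise_sd=noise_sd, seed=seed,
        planted_modules=(PlantedModule("TEN", "keratinocyte", module,
                                       log2_effect),))
    matrix, truth = generate_cohort(config)
    filtered = filter_by_identification_rate(average_replicates(matrix))
    dep = t_test_dep(filtered, "TEN", "healthy")
    planted = [p for p in module if p in dep.table.index]
    n_up = int((dep.table.loc[planted, "call"] == "up").sum())
    return n_up, len(module)


def concordance_recovery(seed: int, n_proteins: int = 300,
                         module_size: int = 50,
                         log2_effect: float = 3.0,
                         noise_sd: float = 0.3,
                         fold: float = 4.0) -> tuple[set, set]:
    """(recovered set, planted set) of the cross-compartment screen.

    One module is planted in both keratinocytes and immune cells of the
    disease cohort and nowhere else; the fourfold both-compartments screen
    should return exactly that set. Dropout is disabled here: exact set
    equality is a property of the screen itself, whereas MNAR censoring can
    make a genuinely shifted low-abundance protein untestable (too few
    observed healthy values), which the sensitivity benchmark covers.
    """
    proteins = CohortSimConfig(n_proteins=n_proteins).protein_ids()
    module = tuple(proteins[:module_size])
    config = CohortSimConfig(
        n_proteins=n_proteins, cohorts=("healthy", "TEN"),
        noise_sd=noise_sd, seed=seed, dropout_steepness=0.0,
        planted_modules=(
            PlantedModule("TEN", "keratinocyte", module, log2_effect),
            PlantedModule("TEN", "immune", module, log2_effect)))
    matrix, _ = generate_cohort(config)
    filtered = filter_by_identification_rate(average_replicates(matrix))
    dep_ker = t_test_dep(filtered.subset_cell_type("keratinocyte"),
                         "TEN", "healthy")
    dep_imm = t_test_dep(filtered.subset_cell_type("immune"),
                         "TEN", "healthy")
    result = cross_compartment_concordance(dep_ker, dep_imm, fold=fold)
    return set(result.proteins), set(module)


@dataclass
class CrosstalkScenario:
    """One synthetic interaction screen with a single planted true positive."""

    matrix: object
    interactions: pd.DataFrame
    planted: PlantedInteraction


def _crosstalk_scenario(seed: int, n_genes: int = 120,
                        n_decoys: int = 100,
                        planted_effect: float = 2.0) -> CrosstalkScenario:
    """Build the planted-interaction recovery scenario.

    The source gene of the planted interaction is shifted by
    ``planted_effect`` in the disease (TEN) keratinocytes. Every gene also
    carries a strong (+/-1.5) effect in a second disease cohort (MPR) so it
    can pass the ANOVA/Tukey gate — without this, decoy interactions would
    be vacuously unmatched and the ranking trivial — and decoy genes get
    small (sd 0.15) random TEN effects so decoy records compete with
    realistic, nonzero disease deltas. Decoy interactions are drawn among
    genes disjoint from the planted pair.
    """
    proteins = CohortSimConfig(n_proteins=n_genes).protein_ids()
    rng = stream(seed, "benchmark.crosstalk")
    modules = []
    for gene in proteins:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for cell_type in ("keratinocyte", "immune"):
            modules.append(PlantedModule("MPR", cell_type, (gene,), 1.5 * sign))
        if gene not in proteins[:2]:
            for cell_type in ("keratinocyte", "immune"):
                modules.append(PlantedModule(
                    "TEN", cell_type, (gene,), float(rng.normal(0, 0.15))))
    planted = PlantedInteraction(
        source_gene=proteins[0], source_cell_type="keratinocyte",
        target_gene=proteins[1], target_cell_type="immune",
        effects={"TEN": planted_effect})
    config = CohortSimConfig(
        n_proteins=n_genes, cohorts=("healthy", "MPR", "TEN"),
        dropout_steepness=0.0, seed=seed,
        planted_modules=tuple(modules), planted_interactions=(planted,))
    matrix, _ = generate_cohort(config)
    decoys = generate_interaction_table(proteins[2:], planted=(),
                                        n_decoys=n_decoys, seed=seed)
    interactions = pd.concat([
        pd.DataFrame([{"source": planted.source_gene,
                       "target": planted.target_gene}]),
        decoys], ignore_index=True)
    return CrosstalkScenario(matrix=matrix, interactions=interactions,
                             planted=planted)


def crosstalk_interaction_rank(seed: int, n_genes: int = 120,
                               n_decoys: int = 100) -> int:
    """Rank (1 = best) of the planted interaction by disease delta.

    Runs the full screen (missingness filter, imputation, ANOVA/Tukey gate,
    condition averaging, directional delta scoring) and ranks the disease
    (TEN) records by D descending.
    """
    scenario = _crosstalk_scenario(seed, n_genes=n_genes, n_decoys=n_decoys)
    scores, _ = run_crosstalk(scenario.matrix, scenario.interactions,
                              config=CrosstalkConfig(imputer_seed=seed))
    ten = scores[scores["condition"] == "TEN"].sort_values(
        "disease_delta", ascending=False, kind="stable").reset_index(drop=True)
    planted = scenario.planted
    hit = ten.index[
        (ten["source_gene"] == planted.source_gene)
        & (ten["target_gene"] == planted.target_gene)
        & (ten["source_cell_type"] == planted.source_cell_type)
        & (ten["target_cell_type"] == planted.target_cell_type)]
    if len(hit) == 0:
        return len(ten) + 1  # not recovered at all
    return int(hit[0]) + 1
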