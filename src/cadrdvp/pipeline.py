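"""End-to-end orchestration from a single YAML config.

A run either loads measured tables (``inputs`` block) or simulates a cohort
(``synthetic`` block), preprocesses per cell type (log2 -> replicate
averaging -> identification-rate filter), computes disease-versus-healthy
contrasts on non-imputed data, screens cross-compartment concordance, and
scores directional cell-cell interactions. Imputation and z-scoring are
applied only on the clustering/ordination branch. Every output table is
written once into the run directory with a provenance header (stage,
parameters, seed, config hash); reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .concordance import cross_compartment_concordance
from .containers import IntensityMatrix
from .crosstalk import CrosstalkConfig, run_crosstalk
from .diffexp import hierarchical_cluster, anova_tukey, t_test_dep
from .errors import ConfigError
from .preprocess import (average_replicates, filter_by_identification_rate,
                         impute_gaussian, log2_transform, zscore)
from .simulate import (CohortSimConfig, PlantedInteraction, PlantedModule,
                       generate_cohort, generate_interaction_table)

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, stage: str, params: dict,
           seed: int, config_hash: str, index: bool = True) -> None:
    if path.exists():
        raise ConfigError(f"output {path} already exists (runs are write-once)")
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n")
        fh.write(f"# params: {json.dumps(params, sort_keys=True, default=str)}\n")
        fh.write(f"# seed: {seed}\n")
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", float_format="%.12g", index=index)


def _sim_config_from_block(block: dict, seed: int) -> CohortSimConfig:
    block = dict(block)
    modules = tuple(
        PlantedModule(cohort=m["cohort"], cell_type=m["cell_type"],
                      proteins=tuple(m["proteins"]),
                      log2_effect=float(m["log2_effect"]))
        for m in block.pop("planted_modules", []))
    interactions = tuple(
        PlantedInteraction(source_gene=i["source_gene"],
                           source_cell_type=i["source_cell_type"],
                           target_gene=i["target_gene"],
                           target_cell_type=i["target_cell_type"],
                           effects=dict(i["effects"]))
        for i in block.pop("planted_interactions", []))
    known = {f for f in CohortSimConfig.__dataclass_fields__}
    stray = set(block) - known
    if stray:
        raise ConfigError(f"unknown synthetic config fields: {sorted(stray)}")
    for key in ("cohorts", "cell_types"):
        if key in block:
            block[key] = tuple(block[key])
    return CohortSimConfig(planted_modules=modules,
                           planted_interactions=interactions,
                           seed=seed, **block)


def _load_inputs(config: dict, seed: int):
    if "synthetic" in config:
        sim = _sim_config_from_block(config["synthetic"], seed)
        matrix, truth = generate_cohort(sim)
        interactions = generate_interaction_table(
            sim.protein_ids(), planted=sim.planted_interactions,
            n_decoys=int(config.get("crosstalk", {}).get("n_decoys", 97)),
            seed=seed)
        return matrix, interactions, truth
    if "inputs" not in config:
        raise ConfigError("config needs an 'inputs' or 'synthetic' block")
    block = config["inputs"]
    for key in ("intensity", "metadata"):
        if key not in block:
            raise ConfigError(f"inputs block lacks {key!r}")
        if not Path(block[key]).exists():
            raise ConfigError(f"input path does not exist: {block[key]}")
    matrix = pio.read_intensity_matrix(
        block["intensity"], layout=block.get("layout", "wide"),
        metadata_path=block["metadata"],
        scale=block.get("scale", "log2"))
    interactions = None
    if "interactions" in block:
        if not Path(block["interactions"]).exists():
            raise ConfigError(
                f"input path does not exist: {block['interactions']}")
        interactions = pio.read_interaction_table(block["interactions"])
    return matrix, interactions, None


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Execute all configured stages; returns the results bundle."""
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "cadrdvp_run"))
    chash = _config_hash(config)
    matrix, interactions, truth = _load_inputs(config, seed)
    outdir.mkdir(parents=True, exist_ok=True)

    results: dict = {"truth": truth}

    # preprocess -----------------------------------------------------------
    pp = config.get("preprocess", {})
    if matrix.scale == "raw":
        matrix = log2_transform(matrix)
    averaged = average_replicates(matrix)
    filtered = filter_by_identification_rate(
        averaged, min_rate=float(pp.get("min_rate", 0.70)))
    results["filtered"] = filtered
    _write(filtered.values, outdir / "intensity_filtered.tsv", "preprocess",
           {"min_rate": pp.get("min_rate", 0.70)}, seed, chash)

    # diffexp per cell type, disease vs reference (non-imputed) ------------
    de = config.get("diffexp", {})
    reference = de.get("reference", "healthy")
    alpha = float(de.get("alpha", 0.05))
    fc_cut = float(de.get("fc_cut", 1.0))
    cohorts = [c for c in dict.fromkeys(filtered.samples["cohort"])
               if c != reference]
    cell_types = list(dict.fromkeys(filtered.samples["cell_type"]))
    deps: dict[tuple[str, str], object] = {}
    for cell_type in cell_types:
        sub = filtered.subset_cell_type(cell_type)
        for cohort in cohorts:
            dep = t_test_dep(sub, cohort, reference, alpha=alpha,
                             fc_cut=fc_cut,
                             contrast=f"{cohort}_vs_{reference}_{cell_type}")
            deps[(cohort, cell_type)] = dep
            _write(dep.table, outdir / f"dep_{cohort}_{cell_type}.tsv",
                   "diffexp", {"contrast": dep.contrast, "alpha": alpha,
                               "fc_cut": fc_cut}, seed, chash)
    results["deps"] = deps

    # ANOVA + clustering branch (imputed, z-scored) ------------------------
    cl = config.get("clustering", {})
    if cl.get("enabled", True):
        clusters = {}
        for cell_type in cell_types:
            sub = filtered.subset_cell_type(cell_type)
            keep = sub.values.dropna(how="all").index
            sub = sub.subset_proteins(keep)
            try:
                imputed = impute_gaussian(
                    sub, width=float(pp.get("impute", {}).get("width", 0.3)),
                    downshift=float(pp.get("impute", {}).get("downshift", 1.8)),
                    random_state=seed)
                anova = anova_tukey(imputed, groups="cohort", tukey=False)
                sig = anova.significant(alpha)
                k = int(cl.get("k", 3))
                if len(sig) >= max(k, 2):
                    scored = zscore(imputed.subset_proteins(sig))
                    clusters[cell_type] = hierarchical_cluster(scored, k=k)
                    _write(clusters[cell_type].to_frame(),
                           outdir / f"clusters_{cell_type}.tsv", "clustering",
                           {"k": k, "alpha": alpha}, seed, chash)
            except Exception as exc:  # degenerate small runs: skip, log
                logger.warning("clustering skipped for %s: %s", cell_type, exc)
        results["clusters"] = clusters

    # concordance ----------------------------------------------------------
    co = config.get("concordance", {})
    if len(cell_types) >= 2:
        ct_a, ct_b = cell_types[:2]
        conc = {}
        for cohort in cohorts:
            result = cross_compartment_concordance(
                deps[(cohort, ct_a)], deps[(cohort, ct_b)],
                fold=float(co.get("fold", 4.0)),
                require_significance=bool(co.get("require_significance", True)),
                alpha=alpha)
            conc[cohort] = result
            _write(result.table, outdir / f"concordance_{cohort}.tsv",
                   "concordance", {"fold": result.fold,
                                   "require_significance":
                                   result.require_significance},
                   seed, chash)
        results["concordance"] = conc

    # crosstalk ------------------------------------------------------------
    ct_cfg = config.get("crosstalk", {})
    if interactions is not None and ct_cfg.get("enabled", True):
        cfg = CrosstalkConfig(
            max_missing_fraction=float(ct_cfg.get("max_missing_fraction", 0.30)),
            anova_p_cut=float(ct_cfg.get("anova_p_cut", 0.01)),
            tukey_alpha=float(ct_cfg.get("tukey_alpha", 0.05)),
            min_significant_pairs=int(ct_cfg.get("min_significant_pairs", 5)),
            imputer_seed=seed,
            reference=reference)
        scores, unmatched = run_crosstalk(filtered, interactions, config=cfg)
        results["crosstalk"] = scores
        results["crosstalk_unmatched"] = unmatched
        _write(scores, outdir / "crosstalk_scores.tsv", "crosstalk",
               {"anova_p_cut": cfg.anova_p_cut,
                "min_significant_pairs": cfg.min_significant_pairs},
               seed, chash, index=False)

    results["output_dir"] = outdir
    return results
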