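"""Synthetic cohort, interaction, imaging and phosphosite data with known truth.

Emulates the statistical structure of a cell-type-resolved DIA proteomics
study of cutaneous drug reactions: log-normal protein intensities (Gaussian
on the log2 scale) with protein and sample effects, intensity-dependent
missing-not-at-random dropout, planted cohort x cell-type fold-change
modules (e.g. an interferon signature), planted directional ligand->receptor
interactions, per-cell two-channel immunofluorescence tables, microdissection
polygon contours, and phosphosite tables with localization probabilities.

The defaults mirror the emulated study design: cohorts healthy / MPR /
DRESS / TEN with five individuals each, keratinocyte and immune compartments,
biological duplicates, and roughly 10-15% MNAR missingness. Ground truth is
returned alongside every cohort so recovery can be tested without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .containers import SCALE_LOG2, IntensityMatrix
from .errors import ConfigError

__all__ = [
    "PlantedModule",
    "PlantedInteraction",
    "CohortSimConfig",
    "SimTruth",
    "generate_cohort",
    "generate_interaction_table",
    "generate_cell_feature_table",
    "generate_contours",
    "generate_phospho_table",
]


@dataclass(frozen=True)
class PlantedModule:
    """A set of proteins shifted by ``log2_effect`` in one (cohort, cell type)."""

    cohort: str
    cell_type: str
    proteins: tuple[str, ...]
    log2_effect: float


@dataclass(frozen=True)
class PlantedInteraction:
    """A directed interaction whose source gene is shifted per condition.

    ``effects`` maps cohort -> log2 shift applied to the source gene in the
    source cell type, making the interaction's directional delta
    disease-specific by construction.
    """

    source_gene: str
    source_cell_type: str
    target_gene: str
    target_cell_type: str
    effects: Mapping[str, float]


@dataclass
class CohortSimConfig:
    """Study-design and noise parameters for the synthetic cohort.

    All intensity parameters are on the log2 scale. ``dropout_midpoint`` and
    ``dropout_steepness`` parameterize logistic MNAR dropout,
    P(missing | latent x) = 1 / (1 + exp(steepness * (x - midpoint))),
    so lower-abundance proteins drop out preferentially. A steepness of 0
    disables dropout entirely.
    """

    n_proteins: int = 1000
    n_individuals_per_cohort: int = 5
    cohorts: tuple[str, ...] = ("healthy", "MPR", "DRESS", "TEN")
    cell_types: tuple[str, ...] = ("keratinocyte", "immune")
    n_replicates: int = 2
    base_mean: float = 16.0
    protein_sd: float = 2.0
    sample_sd: float = 0.25
    noise_sd: float = 0.5
    dropout_midpoint: float = 12.0
    dropout_steepness: float = 0.8
    planted_modules: tuple[PlantedModule, ...] = ()
    planted_interactions: tuple[PlantedInteraction, ...] = ()
    seed: int = 0

    def protein_ids(self) -> list[str]:
        width = len(str(self.n_proteins))
        return [f"G{i:0{width}d}" for i in range(1, self.n_proteins + 1)]

    def validate(self) -> None:
        for name in ("n_proteins", "n_individuals_per_cohort", "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("protein_sd", "sample_sd", "noise_sd", "dropout_steepness"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if "healthy" not in self.cohorts:
            raise ConfigError("cohorts must include the reference label 'healthy'")
        if len(set(self.cohorts)) != len(self.cohorts):
            raise ConfigError("cohorts contains duplicate labels")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ConfigError("cell_types contains duplicate labels")
        universe = set(self.protein_ids())
        for module in self.planted_modules:
            if module.cohort not in self.cohorts:
                raise ConfigError(f"planted_modules: unknown cohort {module.cohort!r}")
            if module.cell_type not in self.cell_types:
                raise ConfigError(
                    f"planted_modules: unknown cell type {module.cell_type!r}")
            stray = set(module.proteins) - universe
            if stray:
                raise ConfigError(
                    f"planted_modules: proteins outside universe: {sorted(stray)[:5]}")
        for inter in self.planted_interactions:
            for gene in (inter.source_gene, inter.target_gene):
                if gene not in universe:
                    raise ConfigError(
                        f"planted_interactions: gene {gene!r} outside universe")
            for ct in (inter.source_cell_type, inter.target_cell_type):
                if ct not in self.cell_types:
                    raise ConfigError(
                        f"planted_interactions: unknown cell type {ct!r}")
            for cohort in inter.effects:
                if cohort not in self.cohorts:
                    raise ConfigError(
                        f"planted_interactions: unknown cohort {cohort!r}")


@dataclass
class SimTruth:
    """Planted ground truth of one synthetic cohort."""

    true_log2fc: dict[tuple[str, str, str], float]  # (protein, cohort, cell_type)
    true_interactions: tuple[PlantedInteraction, ...]
    dropout_rate_realized: pd.Series  # per sample

    def planted_proteins(self, cohort: str, cell_type: str) -> set[str]:
        return {p for (p, coh, ct) in self.true_log2fc
                if coh == cohort and ct == cell_type}


def generate_cohort(config: CohortSimConfig) -> tuple[IntensityMatrix, SimTruth]:
    """Simulate a log2 intensity matrix plus its planted ground truth.

    The latent intensity of protein p in sample s is

        base_mean + protein_effect_p + sample_effect_s + planted(p, s) + noise,

    with planted effects added before the logistic dropout step so that
    censoring interacts with effects the way it does in real DIA data.
    """
    config.validate()
    proteins = config.protein_ids()
    n_prot = len(proteins)

    rows = []
    for cohort in config.cohorts:
        for i in range(1, config.n_individuals_per_cohort + 1):
            individual = f"{cohort}_{i:02d}"
            for cell_type in config.cell_types:
                for rep in range(1, config.n_replicates + 1):
                    rows.append({
                        "sample_id": f"{individual}_{cell_type}_r{rep}",
                        "individual": individual,
                        "cohort": cohort,
                        "cell_type": cell_type,
                        "replicate": rep,
                    })
    samples = pd.DataFrame(rows).set_index("sample_id")
    n_samp = len(samples)

    rng_protein = stream(config.seed, "cohort.protein")
    rng_sample = stream(config.seed, "cohort.sample")
    rng_noise = stream(config.seed, "cohort.noise")
    rng_dropout = stream(config.seed, "cohort.dropout")

    protein_effect = rng_protein.normal(0.0, config.protein_sd, size=n_prot)
    sample_effect = rng_sample.normal(0.0, config.sample_sd, size=n_samp)

    latent = (config.base_mean
              + protein_effect[:, None]
              + sample_effect[None, :]
              + rng_noise.normal(0.0, config.noise_sd, size=(n_prot, n_samp)))

    prot_pos = {p: i for i, p in enumerate(proteins)}
    true_log2fc: dict[tuple[str, str, str], float] = {}
    cohort_arr = samples["cohort"].to_numpy()
    ct_arr = samples["cell_type"].to_numpy()

    for module in config.planted_modules:
        if module.log2_effect == 0:
            continue
        col_mask = (cohort_arr == module.cohort) & (ct_arr == module.cell_type)
        idx = [prot_pos[p] for p in module.proteins]
        latent[np.ix_(idx, np.flatnonzero(col_mask))] += module.log2_effect
        for p in module.proteins:
            key = (p, module.cohort, module.cell_type)
            true_log2fc[key] = true_log2fc.get(key, 0.0) + module.log2_effect

    for inter in config.planted_interactions:
        row = prot_pos[inter.source_gene]
        for cohort, effect in inter.effects.items():
            if effect == 0:
                continue
            col_mask = (cohort_arr == cohort) & (ct_arr == inter.source_cell_type)
            latent[row, np.flatnonzero(col_mask)] += effect
            key = (inter.source_gene, cohort, inter.source_cell_type)
            true_log2fc[key] = true_log2fc.get(key, 0.0) + effect

    if config.dropout_steepness > 0:
        p_missing = 1.0 / (1.0 + np.exp(
            config.dropout_steepness * (latent - config.dropout_midpoint)))
        dropped = rng_dropout.random(size=latent.shape) < p_missing
    else:
        dropped = np.zeros(latent.shape, dtype=bool)

    values = pd.DataFrame(np.where(dropped, np.nan, latent),
                          index=pd.Index(proteins, name="protein"),
                          columns=samples.index)

    matrix = IntensityMatrix(values=values, samples=samples, scale=SCALE_LOG2)
    matrix.record_step("generate_cohort", seed=config.seed)
    truth = SimTruth(
        true_log2fc=true_log2fc,
        true_interactions=tuple(config.planted_interactions),
        dropout_rate_realized=pd.Series(dropped.mean(axis=0),
                                        index=samples.index, name="dropout"),
    )
    return matrix, truth


def generate_interaction_table(genes: Sequence[str],
                               planted: Sequence[PlantedInteraction] = (),
                               n_decoys: int = 97,
                               seed: int = 0) -> pd.DataFrame:
    """Directional source->target table: planted interactions plus random decoys.

    Emulates a curated ligand-receptor resource restricted to the measured
    gene universe. Directed pairs are unique; self-pairs are excluded.
    """
    genes = list(dict.fromkeys(genes))
    universe = set(genes)
    for inter in planted:
        for gene in (inter.source_gene, inter.target_gene):
            if gene not in universe:
                raise ConfigError(f"planted gene {gene!r} not in universe")
    if len(genes) < 2 and n_decoys > 0:
        raise ConfigError("need >= 2 genes to draw decoy interactions")

    pairs = list(dict.fromkeys(
        (inter.source_gene, inter.target_gene) for inter in planted))
    seen = set(pairs)
    rng = stream(seed, "interactions")
    max_pairs = len(genes) * (len(genes) - 1)
    if len(seen) + n_decoys > max_pairs:
        raise ConfigError(
            f"cannot draw {n_decoys} decoys from {max_pairs} possible pairs")
    n_target = len(pairs) + n_decoys
    while len(pairs) < n_target:
        s, t = rng.choice(len(genes), size=2, replace=False)
        pair = (genes[s], genes[t])
        if pair in seen:
            continue
        seen.add(pair)
        pairs.append(pair)
    return pd.DataFrame(pairs, columns=["source", "target"])


def generate_cell_feature_table(n_individuals_per_cohort: int,
                                cells_per_individual: int,
                                cohort_effects: Mapping[str, float],
                                seed: int = 0,
                                *,
                                stat1_base: float = 500.0,
                                hoechst_base: float = 1000.0,
                                cell_cv: float = 0.3,
                                illumination_cv: float = 0.4) -> pd.DataFrame:
    """Per-cell STAT1/Hoechst mean intensities with per-individual illumination.

    Both channels are log-normal; a per-individual illumination factor
    multiplies both channels (so the STAT1/Hoechst ratio is invariant to it),
    while the cohort effect multiplies STAT1 only.
    """
    if cells_per_individual < 1:
        raise ConfigError("cells_per_individual must be >= 1")
    if n_individuals_per_cohort < 1:
        raise ConfigError("n_individuals_per_cohort must be >= 1")
    rng = stream(seed, "cell_features")
    sigma = np.sqrt(np.log1p(cell_cv ** 2))
    ill_sigma = np.sqrt(np.log1p(illumination_cv ** 2))
    frames = []
    for cohort, effect in cohort_effects.items():
        if effect <= 0:
            raise ConfigError(f"cohort_effects[{cohort!r}] must be > 0")
        for i in range(1, n_individuals_per_cohort + 1):
            individual = f"{cohort}_{i:02d}"
            illumination = float(rng.lognormal(0.0, ill_sigma))
            stat1 = stat1_base * effect * rng.lognormal(0.0, sigma,
                                                        cells_per_individual)
            hoechst = hoechst_base * rng.lognormal(0.0, sigma,
                                                   cells_per_individual)
            frames.append(pd.DataFrame({
                "cell_id": [f"{individual}_c{j}" for j in
                            range(cells_per_individual)],
                "individual": individual,
                "cohort": cohort,
                "stat1_mean": stat1 * illumination,
                "hoechst_mean": hoechst * illumination,
            }))
    return pd.concat(frames, ignore_index=True)


def generate_contours(n: int, vertex_range: tuple[int, int],
                      area_range: tuple[float, float], seed: int = 0,
                      cell_type: str | None = None) -> list:
    """Random star-shaped simple polygons with exactly known areas.

    Vertices are angle-sorted points with random radii around the centroid,
    which guarantees a simple (non-self-intersecting) polygon; each polygon
    is then rescaled so its shoelace area equals a target drawn uniformly
    from ``area_range``.
    """
    from .imaging import Contour, shoelace_area

    vmin, vmax = vertex_range
    amin, amax = area_range
    if n < 1:
        raise ConfigError("n must be >= 1")
    if vmin < 3 or vmax < vmin:
        raise ConfigError(f"degenerate vertex_range {vertex_range}")
    if amin <= 0 or amax < amin:
        raise ConfigError(f"degenerate area_range {area_range}")
    rng = stream(seed, "contours")
    contours = []
    for i in range(n):
        n_vertices = int(rng.integers(vmin, vmax + 1))
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vertices))
        radii = rng.uniform(0.5, 1.5, size=n_vertices)
        verts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        target_area = float(rng.uniform(amin, amax))
        verts *= np.sqrt(target_area / shoelace_area(verts))
        center = rng.uniform(0, 1000, size=2)  # position on a 1 mm tile
        contours.append(Contour(vertices=verts + center, cell_type=cell_type,
                                contour_id=f"contour_{i:04d}"))
    return contours


@dataclass
class PhosphoSimConfig:
    """Parameters of the synthetic phosphosite table."""

    n_sites: int = 100
    n_samples: int = 6
    frac_low_probability: float = 0.3  # localization probability <= 0.75
    frac_multiplicity_duplicates: float = 0.2
    base_mean: float = 14.0
    site_sd: float = 1.5
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        for name in ("frac_low_probability", "frac_multiplicity_duplicates"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")


def generate_phospho_table(config: PhosphoSimConfig) -> pd.DataFrame:
    """Phosphosite rows with localization probabilities and multiplicity variants.

    A controlled fraction of sites gets localization probability <= 0.75
    (non-class-I); a controlled fraction of (protein, position) keys receives
    an extra multiplicity-2 variant, creating the redundancy the collapse
    step removes.
    """
    config.validate()
    rng = stream(config.seed, "phospho")
    residues = np.array(["S", "T", "Y"])
    n_low = int(round(config.frac_low_probability * config.n_sites))
    rows = []
    for i in range(config.n_sites):
        protein = f"P{i // 2 + 1:04d}"  # ~2 sites per protein
        position = int(rng.integers(1, 800))
        residue = str(rng.choice(residues, p=[0.75, 0.2, 0.05]))
        if i < n_low:
            prob = float(rng.uniform(0.2, 0.75))
        else:
            prob = float(rng.uniform(0.7501, 1.0))
        base = config.base_mean + rng.normal(0, config.site_sd)
        multiplicities = [1]
        if rng.random() < config.frac_multiplicity_duplicates:
            multiplicities.append(2)
        for mult in multiplicities:
            intensities = base + rng.normal(0, config.noise_sd, config.n_samples)
            row = {
                "protein": protein,
                "position": position,
                "residue": residue,
                "multiplicity": mult,
                "localization_probability": prob,
            }
            row.update({f"sample_{j + 1}": intensities[j]
                        for j in range(config.n_samples)})
            rows.append(row)
    return pd.DataFrame(rows)
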