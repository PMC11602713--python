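# cadrdvp

Cell-type-resolved spatial-proteomics analysis of cutaneous adverse drug
reactions (CADRs) — the spectrum from maculopapular rash (MPR) through DRESS
to toxic epidermal necrolysis (TEN).

Laser-microdissection proteomics yields log2 protein-intensity matrices per
cell type (keratinocytes, CD45+ immune cells, macrophage/T-cell subsets) and
cohort, with strongly intensity-dependent (MNAR) missingness. `cadrdvp`
implements the downstream analysis as a tested, reusable library for
proteomics analysts and dermatology researchers:

- **Preprocessing** — log2 transform, replicate averaging per individual and
  cell type, the 70% identification-rate filter per cell type, Perseus-style
  downshifted-Gaussian imputation
  (missing ~ N(μ<sub>s</sub> − 1.8 σ<sub>s</sub>, (0.3 σ<sub>s</sub>)²) per
  sample), and per-protein z-scoring — as sklearn-style transformers.
- **Differential expression** — per-protein Student t-tests,
  Benjamini–Hochberg FDR, DEP calling at q < 0.05 and |log2FC| ≥ 1, one-way
  ANOVA with Tukey HSD (studentized-range), hierarchical clustering of
  significant proteins.
- **Cross-compartment concordance** — proteins at least fourfold regulated
  in *both* keratinocytes and immune cells for the same disease contrast.
- **Cell–cell interaction scoring** — the directional delta screen: after a
  <30%-missingness filter, random-forest chained-equations imputation and an
  ANOVA (p < 0.01) + Tukey (≥5 pairs at 0.05) gate, each directed
  ligand→receptor pair gets Δ = I(source gene, source cell type) −
  I(target gene, target cell type) per condition and a disease-specificity
  score D = Δ<sub>disease</sub> − Δ<sub>healthy</sub>; records with D > 0
  flag disease-gained signalling.
- **Imaging quantification** — microdissection contour filtering
  (30–200 µm²), 99% vertex decimation, alternating-shape subsampling,
  per-cell STAT1/Hoechst ratio normalization with 5,000-nuclei sampling,
  and the co-culture cytotoxicity fraction.
- **Phosphoproteomics** — class-I site filtering (localization
  probability > 0.75) and multiplicity-redundancy collapse.
- **Enrichment** — hypergeometric overrepresentation with BH across sets.
- **Clinical scores** — SCORTEN with its category-wise mortality lookup,
  BSA-based SJS / SJS–TEN overlap / TEN classification, the murine clinical
  score, and one-tailed Welch t-tests.
- **Synthetic cohorts** — a generator that emulates the study design
  (log-normal intensities, logistic MNAR dropout, planted fold-change
  modules and directional interactions) with full ground truth, so every
  stage is testable without any data download.

## Worked example

```python
from cadrdvp import (CohortSimConfig, PlantedModule, generate_cohort,
                     average_replicates, filter_by_identification_rate,
                     t_test_dep, cross_compartment_concordance)

proteins = CohortSimConfig(n_proteins=400).protein_ids()
signature = tuple(proteins[:30])  # a planted interferon-like module
config = CohortSimConfig(
    n_proteins=400, cohorts=("healthy", "TEN"), seed=42,
    planted_modules=(
        PlantedModule("TEN", "keratinocyte", signature, 3.0),
        PlantedModule("TEN", "immune", signature, 3.0)))
matrix, truth = generate_cohort(config)
print(f"simulated {matrix.values.shape[0]} proteins x "
      f"{matrix.values.shape[1]} samples, "
      f"{100 * matrix.values.isna().mean().mean():.1f}% missing")

filtered = filter_by_identification_rate(average_replicates(matrix))
dep_ker = t_test_dep(filtered.subset_cell_type("keratinocyte"), "TEN", "healthy")
dep_imm = t_test_dep(filtered.subset_cell_type("immune"), "TEN", "healthy")
print("keratinocyte DEPs:", dep_ker.counts)
print("immune DEPs:      ", dep_imm.counts)

hits = cross_compartment_concordance(dep_ker, dep_imm, fold=4.0)
planted_found = len(set(hits.proteins) & set(signature))
print(f"fourfold in both compartments: {len(hits.table)} proteins "
      f"({planted_found} of {len(signature)} planted, 0 false positives)")
```

prints:

```
simulated 400 proteins x 40 samples, 9.5% missing
keratinocyte DEPs: {'up': 29, 'down': 0, 'ns': 369}
immune DEPs:       {'up': 30, 'down': 0, 'ns': 368}
fourfold in both compartments: 29 proteins (29 of 30 planted, 0 false positives)
```

The 30-protein module was planted at log2FC +3 in the disease cohort of
both compartments; the t-test/BH/fold-change chain recovers 29–30 of them
per compartment (one low-abundance member is censored by MNAR dropout in
the healthy group and becomes untestable), and the fourfold
both-compartments screen returns them with no false positives.

Clinical utilities from the shell:

```bash
cadrdvp scorten --factors '{"age_ge_40": true, "malignancy": true,
  "initial_detachment_gt_10pct": true, "glucose_gt_14mM": true}'
# {"score": 4, "predicted_mortality_pct": 58.3}
cadrdvp classify-cadr --bsa 35
# {"bsa_percent": 35.0, "classification": "TEN"}
```

An end-to-end run (`cadrdvp run --config config.yaml --out rundir`) writes
every stage's table with a provenance header (stage, parameters, seed,
config hash) and is byte-identical on rerun.

## Documentation

`docs/methods.md` describes the statistical model, every tunable threshold
with its default and rationale, what the synthetic generator does and does
not emulate, and known limitations.
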