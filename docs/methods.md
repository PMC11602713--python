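# Methods

## Data model

The central object is the `IntensityMatrix`: a proteins × samples grid of
protein-group intensities with per-sample metadata (individual, cohort,
cell type, replicate, optional spatial label for attached/detached
keratinocytes). Missingness is carried as NaN; a scale flag distinguishes
raw, log2 and z-scored values, and every processing step appends itself,
with parameters, to the matrix's provenance record. Label-free DIA
intensities are treated as log-normal: all modelling and testing happens on
the log2 scale, and the log2 fold change of a contrast is the difference of
group means of log2 intensities (not the log of the ratio of raw means).

## Preprocessing

Order matters and is enforced: log2 transform → replicate averaging →
identification-rate filter → (imputation → z-scoring, only for
clustering/ordination-style analyses). Hypothesis tests always run on
non-imputed, available-case data, because imputed values would manufacture
significance from the imputation model itself.

- **Replicate averaging** uses the available-case mean per (individual,
  cell type): a protein missing in one replicate keeps the other's value;
  missing in all replicates stays missing.
- **Identification-rate filter** (default 0.70): a protein is retained for
  a cell type iff its observed fraction reaches 70% in at least one cohort
  of that cell type. The rate is computed on replicate-level columns, since
  "identification" is a property of MS runs rather than of averaged
  profiles; whether the field convention counts runs or individuals is
  genuinely ambiguous, and the choice is recorded here. On a joint
  multi-cell-type matrix the rule is applied per cell type: blocks failing
  it are masked to missing, rows failing everywhere are dropped, and the
  per-cell-type keep table is stored in `meta['identification_keep']`.
- **Downshifted-Gaussian imputation** (width 0.3, downshift 1.8): for each
  sample column with observed mean μ and standard deviation σ (ddof = 1 —
  another unstated convention, recorded in the output metadata), missing
  cells are drawn i.i.d. from N(μ − 1.8 σ, (0.3 σ)²). This is the standard
  left-censored treatment of MNAR dropout in DIA proteomics: absent
  proteins are presumed low-abundance, so draws sit in the left tail of the
  sample's intensity distribution. Imputation is applied per averaged
  sample column (one column per individual × cell type), consistent with
  its position after replicate averaging in the processing order. Only
  previously missing cells are altered; a sample with fewer than two
  observed values has no defined σ and is an error.
- **Z-scoring** is per protein with population sd (ddof = 0, the common
  heat-map convention; configurable). Zero-variance proteins are an error
  listing the offenders.

All five steps are sklearn `TransformerMixin` estimators
(`Log2Transformer`, `ReplicateAverager`, `IdentificationRateFilter`,
`GaussianImputer`, `ProteinZScorer`) so they compose with sklearn
pipelines; the module-level functions are one-shot wrappers.

## Differential expression

Per-protein two-sided Student t-test (pooled variance; Welch available via
`equal_var=False`), available-case with a minimum of two observations per
group — below that the variance is not estimable, the p-value is reported
missing, and the protein is excluded from the multiple-testing family.
Benjamini–Hochberg q-values follow the step-up definition
q_i = min over {j : p_j ≥ p_i} of m·p_j/rank_j, clipped to 1, with a
stable sort for deterministic ties; the implementation is cross-checked in
the tests against both a literal brute-force implementation of that
definition and statsmodels. A DEP call is `up` iff q < α (default 0.05)
and log2FC ≥ 1 (twofold), symmetrically `down`.

One-way fixed-effects ANOVA uses `scipy.stats.f_oneway`; Tukey HSD adjusted
p-values are computed directly from the studentized-range distribution
(Tukey–Kramer form for unequal group sizes,
q = |m_i − m_j| / sqrt(MSE/2·(1/n_i + 1/n_j)), p = sf(q; k, N − k)) and
cross-checked against `scipy.stats.tukey_hsd` as an independent route.
Zero-centring and scaling a protein before ANOVA is an affine map and
leaves F and the Tukey p unchanged, so scaling is exposed but off by
default. Hierarchical clustering of ANOVA-significant, imputed, z-scored
proteins uses Euclidean average-linkage agglomeration cut at k clusters,
with labels canonicalized by first appearance so the partition is
deterministic and order-invariant.

## Cross-compartment concordance

For one contrast computed in two compartments, the screen returns proteins
whose linear fold change reaches the threshold (default fourfold, i.e.
log2FC ≥ 2, inclusive) in both DEP tables, intersecting the two universes.
By default both q-values must also be below α; the significance requirement
is a flag because the plain "at least fourfold in both" reading is also
legitimate, and both are reproducible.

## Cell–cell interaction screen

The joint matrix over both cell types is filtered to proteins with
strictly fewer than 30% missing values, then completed by chained-equations
iterative imputation (sklearn `IterativeImputer`) with a
`RandomForestRegressor` (30 trees by default, max 10 rounds, tolerance
1e-3 on mean absolute change — none of these is canonical, so all are
parameters). Because a forest's prediction is not range-bounded, imputed
values are clipped to the protein's observed range widened by 20% of that
range; observed cells are never altered, and the whole step is
deterministic given the seed.

Gating keeps proteins with one-way ANOVA p < 0.01 over the joint
condition × cell-type groups *and* at least five Tukey-significant pairwise
comparisons (adjusted p < 0.05). The joint grouping (rather than per cell
type) is used because the two compartments are processed together. On a
complete matrix the Tukey count is evaluated against the single critical
value q_crit = ppf(1 − 0.05; k, N − k), which is exactly equivalent to
thresholding each adjusted p and avoids thousands of slow
studentized-range tail evaluations.

Gated proteins are averaged per (condition, cell type); protein groups are
matched to interaction gene symbols by their first member
(";"-delimited), case-sensitively. For each directed interaction and each
ordered cell-type pair, Δ = I(source gene, source cell type) −
I(target gene, target cell type) per condition, and
D = Δ_condition − Δ_healthy. D of the mirrored direction is −D by
construction, and the default keep rule retains D > 0. Cell-type pairs are
listed explicitly (default: both directions between the two cell types);
self-pairs can be added but are not default, since within-compartment
signalling is not what the screen is designed to isolate.

## Imaging quantification

Contours are ordered vertex lists in µm; area is the absolute shoelace sum.
Cuttable contours are simple polygons with area between 30 and 200 µm²
inclusive ("between ... and" read inclusively); self-intersecting polygons
are rejected with a logged reason. Outline simplification removes 99% of
vertices by uniform index stride starting at vertex 0, flooring at 3
retained vertices — stride decimation is chosen over curvature-based
simplification because it is deterministic and directly testable. Note a
geometric consequence: decimating a circle to n points leaves the inscribed
regular n-gon, whose area is (n/2)r²·sin(2π/n), ~6.5% below πr² at n = 10;
membrane shapes of that vertex count cannot be decimated more faithfully.
For fragile membranes, at most every second shape in input order is
selected, randomly: a greedy pass over a seeded random permutation accepts
a contour iff neither input neighbour is already accepted, which guarantees
no adjacent pair and at most ⌈n/2⌉ selections. Input order stands in for
spatial adjacency, which the exported contour files do not carry.

Per-cell STAT1 is normalized by the same cell's Hoechst mean — the ratio
cancels any per-slide or per-cell illumination factor common to both
channels, and no additional slide factor is applied. Exactly 5,000 nuclei
are sampled per individual (individuals with fewer are excluded and
counted), and cohorts are compared by an unpaired two-sided t-test on
per-individual means, not on pooled cells, so individuals are the unit of
replication. The co-culture cytotoxicity readout is the fraction of
tracker-positive keratinocytes that are also dead-stain-positive.

## Phosphoproteomics

Class-I sites have localization probability strictly greater than 0.75.
Multiplicity variants of one (protein, position) are collapsed after
differential testing by |log2FC| descending, then −log10(p) descending,
then multiplicity ascending; when the |fc|-best and p-best variants
disagree the conflict is logged per key (the two criteria cannot always be
satisfied jointly, so |fc| is primary). The site-level fold-change cut used
to select ORA input defaults to 0.5 on the log2 scale.

## Overrepresentation

Upper-tail hypergeometric: for a hit list of size n from a universe of
size M and a set with K members in the universe, p = P(X ≥ k) with
enrichment ratio k/(nK/M), BH-corrected across sets. The natural universe
is the set of proteins surviving the identification filter for the cell
type under study — the measured background, not a genome-wide list.

## Clinical scores

SCORTEN is the count of seven binary risk factors (age ≥ 40, malignancy,
heart rate ≥ 120/min, initial detachment > 10% BSA, urea > 10 mM,
glucose > 14 mM, bicarbonate < 20 mM) with the category-wise predicted
mortality of the score's original validation cohort: 0–1 → 3.2%, 2 → 12.1%,
3 → 35.3%, 4 → 58.3%, ≥5 → 90.0%. CADR severity from detached body-surface
area: TEN strictly above 30%, SJS–TEN overlap for 10–30% inclusive, SJS
below 10% (TEN requires *exceeding* 30%, so the 30% boundary is overlap).
The murine clinical score sums three ordinal 0–3 components (oedema, rubor,
epidermal disruption) to 0–9; the enumerated 0/1/2/3 levels are the
operational definition even though the scale is sometimes described as
"four-point (0–4)". Mouse group contrasts use Welch's unequal-variance
t-test with Satterthwaite degrees of freedom, one-tailed in the stated
direction.

## Synthetic cohorts and what they do (not) show

`generate_cohort` draws latent log2 intensities
base_mean + protein_effect + sample_effect + planted(p, cohort, cell type)
+ noise, with defaults chosen to look like cell-type-resolved DIA data:
base_mean 16, protein sd 2, sample sd 0.25, residual noise sd 0.5 (log2
units), four cohorts (healthy, MPR, DRESS, TEN) × five individuals × two
cell types × two biological replicates. Dropout is logistic in the latent
intensity, P(missing) = 1/(1 + exp(steepness·(x − midpoint))) with
midpoint 12 and steepness 0.8 (≈8–12% overall missingness, concentrated in
low-abundance proteins) — the left-censoring regime that the downshifted
imputation presumes. Effects are added *before* dropout so censoring
interacts with effects as it does in real data; a steepness of zero
disables dropout entirely (the logistic value would otherwise be a flat
0.5, which models nothing useful). One integer seed fans out into named
substreams per generator, so adding a generator never shifts another's
draws, and every planted nonzero effect is recorded in the returned truth
object.

The generator emulates the statistical skeleton only: it has no
peptide-level structure, no correlated protein modules beyond the planted
ones, no batch or slide effects, and its MNAR mechanism is exactly the
logistic model. Passing recovery tests therefore demonstrates the
correctness and calibration of the analysis chain under its own
assumptions, not performance on real tissue data.

Benchmark scenarios (in `cadrdvp.benchmark`) fix the study conditions for
the operating characteristics:

- *Type-I control*: 1,000-protein null cohorts, default dropout; fraction
  of q < 0.05 calls across 20 seeds.
- *Sensitivity*: 50-protein module at log2FC +3, n = 5/cohort, noise sd
  0.5, default dropout.
- *Concordance exactness*: the module planted in both compartments, noise
  sd 0.3, dropout disabled — exact set equality is a property of the screen
  itself, whereas MNAR censoring can legitimately render a shifted
  low-abundance protein untestable (that effect is covered by the
  sensitivity benchmark).
- *Interaction ranking*: source gene +2 in disease keratinocytes; every
  gene also gets a ±1.5 effect in a second disease cohort so it can pass
  the ANOVA/Tukey gate (otherwise decoys would be vacuously unmatched and
  the ranking trivial), and decoy genes get small (sd 0.15) random disease
  effects so decoy records compete with realistic nonzero deltas. Decoy
  pairs are drawn among genes disjoint from the planted pair — an
  interaction sharing the planted source gene inherits its disease shift
  and is a true positive in all but name, not a decoy. Dropout is off in
  this scenario (the ranking property concerns the scoring, and the
  imputer is exercised by its own hold-out recovery tests).

## Numerical choices and degenerate inputs

Zero pooled spread in a t-test yields p = 1 when the means agree and p = 0
otherwise; the analogous convention applies to ANOVA and the Welch test.
BH ties are broken by stable sort. The interaction-table reader
deduplicates directed pairs with a logged warning and treats an empty table
as an error; intensity readers normalize blank/"NA"/"NaN" (and, on raw
scale, numeric 0 — configurable, since DIA export conventions differ) to a
single missing representation and fail loudly on duplicate ids with the
offender named. Floats are serialized at 12 significant digits, making
write→read an identity.

## Limitations

No moderated (empirical-Bayes) test statistics or mixed models; no
between-sample normalization (median centring, quantile) — upstream
cross-run normalization is assumed done by the search engine; no GSEA-style
weighted enrichment, only the hypergeometric ORA; the pipeline consumes
segmentation/quantification exports and protein/phosphosite tables, never
raw spectra or images. Problem sizes in the test-suite benchmarks (hundreds
to a thousand proteins, 20 seeds) are chosen as the smallest designs at
which the measured operating characteristics are stable.
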