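# Methods

`cypred` predicts continuous CYP3A4 % inhibition (percentage points, 0–100,
single-concentration HTS readout at 10 μM) from molecular structure. This
note records the models, the defaults and why they were chosen, what the
synthetic benchmark does and does not emulate, and the numerical choices a
maintainer would want to know.

## Label curation

Raw (structure, value) records are standardized (largest organic fragment by
heavy-atom count, ties broken by canonical-SMILES order; toolkit-default
charge normalization; canonicalization) and grouped by canonical SMILES.
Values are clipped into [0, 100] when they fall inside a configurable
acceptance window (default (−10, 110): mild assay overshoot is clipped,
gross errors rejected with a reason code). Replicate groups whose sample SD
exceeds `max_sd` (default 30 points; the cutoff is a package choice, exposed
as a parameter) are excluded before aggregation, so the min/max branches
cannot mask irreproducible groups.

Aggregation is piecewise on the replicate mean m: m < `lo` (default 20)
takes the group minimum (guards against spuriously high single reads);
m > `hi` (default 70) takes the maximum (preserves strong inhibition
signal); otherwise the mean. A mean exactly at a threshold falls in the
mean branch (the outer branches are defined by strict inequalities).
`run_sensitivity` re-aggregates over a (lo, hi) grid — default 10–30 × 60–80
— and reports retained counts and mean labels per cell. Replicates are
sorted before averaging so aggregation is exactly permutation-invariant in
floating point.

## Representations

* **Fingerprint**: radius-4, 2048-bit circular fingerprint (ECFP8-style).
* **Descriptors**: a pinned 12-descriptor set (MW, SLogP, TPSA, HBD, HBA,
  rotatable bonds, molar refractivity, aromatic rings, heavy atoms, ring
  count, fraction Csp3, heteroatoms). The set is deliberately small and
  named; reproducing a ~1800-descriptor union is out of scope.
* **Engineered features**: an additive log-solubility estimate (linear in
  LogP, MW, rotatable bonds, aromatic fraction — a monotone-plausible proxy,
  not a calibrated solubility model), TPSA, formal-charge patch counts,
  polar-surface fraction (TPSA / Labute ASA), motif counts from a versioned
  SMARTS catalog (benzodioxole, imidazole, pyridine, indole, piperidine,
  pyrazine, triazole, heterocyclic nitrogen, coordinating heteroatoms),
  coordinating-heteroatom fraction, aromatic-carbon ratio, Lipinski
  violation count, QED.
* **Mean training-set similarity**: mean Tanimoto of each molecule's
  fingerprint to the training references, computed with vectorized
  bit-matrix arithmetic.
* **Dual graph**: atom/bond graph plus explicit ring tensors. Ring
  perception is the smallest set of smallest rings; two rings are adjacent
  when they share at least one atom (covers fused and spiro systems). Node
  features: atomic number, formal charge, hybridization code {s, sp, sp2,
  sp3, other}, aromaticity, ring membership, attached hydrogens. Edge
  features: bond order, aromaticity, conjugation, cyclicity. Atom indices
  are 0-based throughout.

Missing/non-finite feature values become 0 with a companion `AnyMissing`
flag column.

## Ring-aware graph regressor

Each encoder layer updates, in order: (i) bond states from their endpoint
atoms, (ii) atom states from summed neighbor atoms, summed incident bonds
and the mean state of the rings containing the atom, (iii) ring states from
the mean of their member atoms. All aggregations are sums or means, so the
embedding is exactly invariant under atom relabeling. Readout is a mean
(optionally sum) over atom states; a two-layer head maps the graph embedding
to a scalar. At zero depth the embedding reduces to the readout of linearly
projected input features, which the tests exploit as a closed form.

The encoder, its gradients and the optimizer are implemented on NumPy with
a compact reverse-mode autodiff core (`_autograd.py`); sparse aggregation
operators carry the graph structure, and every op is validated against
central differences in the test suite. Training uses Adam (lr 5e-3 default),
labels standardized internally, predictions clipped to [0, 100] at reporting
time only.

**Contrastive pretraining.** Two stochastic views per molecule — atom
masking (rate 0.15), bond deletion (0.10), removal of a random connected
subgraph of ≤ 20 % of atoms — feed an InfoNCE loss over cosine
similarities with temperature 0.1; candidates are the other 2B − 1 views in
the batch. The rates and temperature are package defaults chosen as
conventional values for molecular graph contrastive learning. Rings are
stored as atom sets, so bond deletion leaves the ring tensors unchanged;
atom removal drops rings that lose atoms and rebuilds incidence/adjacency.

**Similarity-weighted manifold mixup.** Within each mini-batch, pair
similarity is S = w_g·cos(h_i, h_j) + w_y·(1 − |y_i − y_j|/R) with
w_g = w_y = 0.5 and R = 100. For each anchor the partner is sampled from its
top-k (k = 8) candidates with probability ∝ max(S, 0), uniform fallback when
none is positive. λ ~ Beta(α, α) with α = 0.5. Mixed embeddings and labels
(h̃ = λh_i + (1−λ)h_j, ỹ likewise) pass through the prediction head only and
supplement the real samples with equal weight in the squared-error loss.
With mixup disabled the loop reduces exactly to plain supervised training
(verified by a fixed-seed equivalence test). Mixup is always confined to the
training portion of a fold.

α, the similarity weights, top-k and the equal loss weighting are package
defaults where the method leaves them open; all are constructor parameters.

## Tabular block and ensembles

Components: LightGBM (`gbdt_a`), XGBoost (`gbdt_b`), and a two-hidden-layer
scikit-learn MLP with early stopping (`mlp`), all single-threaded and
seeded for determinism. A degenerate constant-label fit short-circuits to
the constant. Component predictions are combined with weights on the
probability simplex fitted by SLSQP-constrained least squares from a uniform
start; weights of components with identical predictions are equalized
afterwards (uniform tie-break over the optimal set). Because the unit
vectors are feasible, the fitted combination can never have higher RMSE than
the best single component on the fitting set.

The hybrid estimator fits the tabular block and the graph block, then fits
inter-model simplex weights on validation predictions: either a held-out
split (default 20 %) or, with `n_folds ≥ 2`, out-of-fold predictions with
fold-model averaging at inference. Test labels are never touched before
final evaluation.

**TTA.** A predictor is evaluated on the canonical SMILES plus N randomized
serializations (seeded atom-permutation renumbering; duplicates allowed) and
the predictions averaged. Default N = 8. For the graph model this is a
no-op by serialization invariance (asserted in tests); it exists for
string-sensitive predictors behind the pluggable embedding interface.

## Metrics

RMSE; NRMSE = RMSE / R with R = 100 by default (labels are clipped
percentages; the empirical max − min is exposed as an option); sample
Pearson correlation (errors on constant input); R²; and the composite

    score = 0.5 · (1 − NRMSE) + 0.5 · PCC,

equal weights by default, configurable. The fixed R = 100 convention is
validated by exact agreement (±1e-4) with all nine rows of the published
comparison table when the composite is recomputed from each row's printed
RMSE and PCC.

## Interpretation and SAR

Occlusion replaces a unit's node features with the mask token (a dedicated
channel) and records base − occluded prediction; units are single atoms or
whole rings. Masking rather than deleting keeps ring tensors and topology
valid; the divergence risk is that a masked atom still carries topology,
which deletion-based occlusion would not.

SAR statistics per motif: point-biserial correlation (population-SD form,
algebraically equal to Pearson on the 0/1 indicator — cross-checked in
tests), t-transformation p-value with significance stars (*** p < 0.001,
** p < 0.01, * p < 0.05; no multiple-testing correction by default, BH
step-up available), Cohen's d with pooled sample SD, and a percentile
bootstrap 95% CI on the mean difference (default 2000 resamples, seeded).
Spearman correlations (average ranks on ties) cover the label–descriptor
matrix.

## Synthetic benchmark

The generator emulates the statistical shape of a curated HTS inhibition
set: molecules are a neutral ring core (benzene, cyclohexane, furan,
thiophene, oxane, naphthalene) plus 0–3 substituents from a pool containing
the six SAR motif rings and eleven neutral groups, joined by single bonds at
seeded attachment points and deduplicated by canonical SMILES. Labels are

    y = clip(20 + Σ β_m·count_m + 2·SLogP + 3·aromatic_rings + N(0, σ), 0, 100)

with β = {benzodioxole +35, indole +16, pyridine +11, imidazole +9,
piperidine −5, pyrazine −1.5} and σ = 10 for the main benchmark. The motif
effects echo the direction and magnitude of reported substructure shifts for
this endpoint; the slopes encode the positive hydrophobicity/aromaticity
association. Motifs ride on substituents rather than on mutually exclusive
cores so their presences are quasi-independent and marginal SAR estimates
sit close to the planted effects. Replicates add N(0, σ) around the final
label, optionally displacing one replicate by ±50 to exercise outlier
flagging. Everything is bit-reproducible given the seed.

What the generator does **not** emulate: real assay heteroscedasticity,
floor/ceiling pile-ups beyond clipping, scaffold bias, activity cliffs, or
the label distribution of any real collection. Passing the recovery tests
shows the pipeline machinery is correct and sensitive at realistic noise,
not that real-data accuracy matches any published figure.

## Problem sizes and seeds

The end-to-end recovery check runs on 2,000 molecules, 3 folds, a
32-dimensional 2-layer encoder, 10 supervised + 2 contrastive epochs —
sizes chosen so the whole suite stays desk-scale while the planted signal
(noise ceiling PCC ≈ 0.8) remains clearly detectable; the check requires
held-out PCC ≥ 0.6, hybrid weight-set RMSE no worse than either block, and
sign recovery of every planted motif effect. The CI-coverage property for
the benzodioxole shift uses five 400-molecule repetitions. One global seed
fans out to per-stage seeds via `SeedSequence(seed, spawn_key=(stage,))`.

## Known limitations

* The encoder is a faithful ring-aware variant (bond→atom→ring update
  order, ring-average injection into atom updates); it does not replicate
  any particular attention parameterization, and the NumPy implementation
  targets desk-scale data, not GPU-scale training.
* Pretrained chemical-language-model embeddings are out of scope; the TTA
  interface accepts any string predictor as their plug-in point.
* SHAP-style attribution is delegated to external explainer libraries; the
  package ships occlusion sensitivity only.
* Fingerprint bit identities are hash-dependent; no claims are made about
  specific bit indices.
* Stereochemistry beyond toolkit defaults, InChI handling and 3D
  conformers are out of scope.
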