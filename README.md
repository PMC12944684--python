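# cypred

Hybrid graph/tabular regression of **CYP3A4 % inhibition** from molecular
structure.

CYP3A4 metabolizes a large fraction of small-molecule drugs; compounds that
inhibit it are a primary source of drug–drug interactions, so inhibition
liability is screened early and at scale. Single-concentration HTS assays
(typically 10 μM) report % inhibition in [0, 100], with replicate scatter,
floor/ceiling effects and occasional implausible values. `cypred` is a
toolkit for modeling this endpoint end to end, aimed at cheminformatics and
ADMET modelers:

* **Curation** — structure standardization and canonicalization, clipping or
  rejection of implausible values, piecewise replicate aggregation
  (mean < 20 → minimum; mean > 70 → maximum; otherwise mean), replicate
  outlier exclusion, threshold sensitivity analysis, Bemis–Murcko scaffold
  diversity counts.
* **Featurization** — radius-4 2048-bit circular fingerprints,
  a pinned physicochemical descriptor set, engineered feature axes
  (solubility/polarity, charge patches, ring-motif counts, drug-likeness),
  and a dual graph: the atom/bond graph augmented with explicit ring tensors
  (ring atom sets, node–ring incidence, ring–ring adjacency).
* **Graph model** — a ring-aware message-passing regressor
  (`RingGNNRegressor`) that updates bonds, then atoms, then rings per layer,
  with InfoNCE contrastive pretraining over augmented graph views and
  similarity-weighted manifold mixup during fine-tuning: batch pairs scored
  by S = w_g·cos(h_i, h_j) + w_y·(1 − |y_i − y_j|/R) are interpolated in
  embedding space with λ ~ Beta(α, α), and the mixed samples supplement the
  real ones through the prediction head.
* **Tabular block** — LightGBM, XGBoost and an MLP combined with weights on
  the probability simplex fitted by constrained least squares
  (`TabularEnsembleRegressor`).
* **Hybrid ensemble** — `HybridInhibitionRegressor` fits inter-model simplex
  weights on validation (or out-of-fold) predictions of the two blocks, with
  optional SMILES test-time augmentation (canonical + N randomized
  serializations, mean-pooled).
* **Evaluation** — RMSE, NRMSE, R², Pearson correlation, and the composite
  score `0.5·(1 − RMSE/R) + 0.5·PCC` with label range R = 100.
* **Interpretation** — occlusion sensitivity (atom- or ring-level feature
  masking) and per-motif SAR statistics: point-biserial correlation,
  Cohen's d, bootstrap CIs on mean inhibition differences, Spearman
  descriptor correlations.
* **Synthetic benchmarks** — a seeded fragment-grammar generator with a
  planted additive structure–activity function, so every stage is testable
  without external data.

Estimators follow scikit-learn conventions (`fit`/`predict`/`get_params`,
fitted attributes with trailing underscores) and compose with sklearn model
selection. The graph model, its gradients and optimizer run on NumPy with a
compact reverse-mode autodiff core validated against central differences.

## Worked example

```python
import numpy as np
from cypred import (GeneratorConfig, generate_molecules, plant_labels,
                    evaluate_pipeline, sar_report)

cfg = GeneratorConfig(n_molecules=400, noise_sd=10.0, seed=7)
mols = generate_molecules(cfg)
truth = plant_labels(mols, cfg)
smiles = [m.canonical for m in mols]

report, bundles, model = evaluate_pipeline(
    smiles, truth.labels, test_fraction=0.2, seed=7,
    gnn_params=dict(hidden_dim=32, n_layers=2, epochs=10, batch_size=64,
                    contrastive_epochs=2, mixup=True),
)
print(f"held-out n={report.n}  RMSE={report.rmse:.2f}  PCC={report.pcc:.3f}  "
      f"R2={report.r2:.3f}  composite={report.custom_metric:.4f}")
print("hybrid weights:", {k: round(v, 3) for k, v in model.weights_.as_dict().items()})

for r in sar_report(smiles, truth.labels, n_boot=500, seed=7)[:3]:
    print(f"{r.motif:<14} r_pb={r.r_pb:+.3f}{r.stars:<4} d={r.cohens_d:+.2f} "
          f"shift={r.mean_diff:+.1f} pp  CI95=({r.ci95[0]:.1f}, {r.ci95[1]:.1f})")
```

Output:

```
held-out n=80  RMSE=14.08  PCC=0.724  R2=0.464  composite=0.7917
hybrid weights: {'ml': 0.919, 'gnn': 0.081}
benzodioxole   r_pb=+0.632***  d=+2.48 shift=+37.1 pp  CI95=(32.4, 41.5)
imidazole      r_pb=+0.200***  d=+0.70 shift=+13.3 pp  CI95=(6.2, 20.8)
pyridine       r_pb=+0.212***  d=+0.59 shift=+11.1 pp  CI95=(7.0, 15.6)
```

The benchmark plants a benzodioxole effect of +35 points (with +16 indole,
+11 pyridine, +9 imidazole, −5 piperidine, −1.5 pyrazine) on top of
hydrophobicity and aromaticity slopes with noise SD 10; the held-out metrics
show the hybrid recovering most of the learnable signal, and the SAR table
recovers the planted shifts within their confidence intervals. At this small
demonstration size the tabular block dominates the hybrid weights; the graph
block's share grows with training-set size.

## Command line

```bash
cypred --seed 7 make-benchmark --n 2000 --replicates 2 --out bench/
cypred --seed 7 curate --in bench/raw.csv --out curated.csv \
       --sens-lo 10:30:5 --sens-hi 60:80:5 --sensitivity-out sensitivity.csv
cypred featurize --in curated.csv --out features.csv --graphs-out graphs.jsonl
cypred --seed 7 train-hybrid --labels curated.csv --out model.joblib
cypred --seed 7 predict --model model.joblib --in curated.csv --tta 8 --out preds.csv
cypred evaluate --pred preds.csv --truth curated.csv --range 100 --out report.json
cypred explain --model model.joblib --in probe.csv --unit atom --out attributions.jsonl
cypred --seed 7 sar --curated curated.csv --out sar.csv
```

## Documentation

See `docs/methods.md` for the model and procedure details, parameter
defaults and their rationale, what the synthetic generator does and does not
emulate, numerical choices, and known limitations.
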