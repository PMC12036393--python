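# mirv

Quantifying **intertumor heterogeneity** in multi-metastatic cancer patients
from lesion-level CT radiomic feature tables.

Radiomic analyses usually score one tumor per patient, but metastatic patients
carry several lesions whose imaging phenotypes can diverge — and divergent
lesions tend to respond divergently to systemic therapy. This package scores
that divergence per patient as **MIRV (Measured Intrapatient Radiomic
Variability)** and links it to treatment response and survival. It is aimed at
imaging researchers who already have a lesion × feature table from an extractor
such as PyRadiomics (plus lesion volumes and clinical endpoints) and want a
reproducible heterogeneity → response → survival analysis without touching the
underlying DICOM.

## The method

For each patient with lesions L₁ … Lₙ (n ≥ 2), represented by reduced,
cohort-z-scored radiomic feature vectors, MIRV summarises the most divergent
lesion pair under two complementary metrics:

```
MIRV max Distance       = max over i<j of  d_Euclidean(L_i, L_j)
MIRV max Dissimilarity  = max over i<j of  1 − cos(L_i, L_j)
```

Euclidean distance responds to both magnitude and direction of feature
differences; cosine dissimilarity only to differences in feature *pattern*.
Before scoring, the feature panel is reduced in three ordered stages on the
pooled lesion matrix: drop features with sample variance strictly below the
median variance; drop volume surrogates (|Spearman ρ| vs baseline volume
> 0.1); greedily drop redundant features (pairwise |ρ| > 0.7, keep-first).

Downstream analyses:

* **Volumetric response** — percent volume change per lesion between baseline
  and first follow-up; per-patient response range; the binary
  **tumor-specific response classification** (Complete Tumor Response iff
  every lesion shrank ≥ 33%);
* **Associations** — Spearman correlations among MIRV, response, ctDNA
  positivity and three baseline-volume controls (range / SD / total), with
  Benjamini–Hochberg FDR per matrix;
* **Survival** — multivariable Cox model (Efron ties) with MIRV, age,
  performance status, tumor burden, histology and RECIST, optional
  MIRV × histology interaction, and per-histology Kaplan–Meier / log-rank
  subgroups with median-dichotomized MIRV.

Because real multi-metastatic trial cohorts are access-restricted, the package
includes a synthetic-cohort generator with known ground truth (per-patient
heterogeneity σ_p driving lesion feature dispersion, heterogeneity-linked
lesion response, histology-confined survival effects), so the whole pipeline
is testable end to end. See `docs/methods.md` for the generative model.

## Worked example

```bash
cat > run.yaml <<EOF
simulate:
  n_patients: 120
EOF
mirv run --config run.yaml --seed 17 --out-dir mirv_out
```

This simulates a 120-patient cohort (320 lesions, 14 features), reduces the
panel to 4 features (the manifest itemises every removal: two near-constant
columns, two volume proxies, duplicated columns, and low-variance signal
features), scores MIRV, classifies response, and runs both statistical arms.
Key lines of the printed stage summary:

```
"reduce":   {"n_features_in": 14, "n_features_out": 4, ...}
"response": {"complete_response_rate": 0.475, "n_patients": 120}
"survival": {"n": 120, "n_events": 97, "n_subgroups_tested": 3}
```

`mirv_out/mirv.csv` holds one row per patient with both maxima and the argmax
lesion pairs:

```
patient_id,n_lesions,mirv_max_distance,mirv_max_dissimilarity,argmax_pair_distance,...
P0000,2,0.9115450201981945,0.19930778071161315,L00|L01,...
P0001,2,3.2763719323738707,1.0479399849675992,L00|L01,...
```

and `mirv_out/associations_volumetric.csv` the FDR-adjusted association
matrix. On this run the heterogeneity score is negatively associated with
Complete Tumor Response (ρ = −0.23, q = 0.020) and positively with the
response range (ρ = 0.36, q = 0.00016) while remaining only weakly tied to
baseline tumor burden — the qualitative pattern the method is designed to
expose: heterogeneous patients respond non-uniformly, independent of tumor
size.

Each subcommand (`simulate`, `validate`, `reduce`, `score`, `response`,
`associate`, `survival`) is also available standalone; `manifest.json` records
every analysis parameter, seed and per-stage count, and a rerun with the same
config and seed reproduces every output byte-identically.

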