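# rsoct

Multimodal discrimination of colorectal tumor tissue from two endoscopic
fiber-probe modalities — Raman spectroscopy (RS) and optical coherence
tomography (OCT) — with per-sample evidence fusion by Bayes' rule.

The package is aimed at biophotonics / biomedical-optics groups who collect
hierarchical measurement data (subjects → biopsy samples → repeated
measurements) from two complementary modalities and want a leakage-free,
subject-wise validated pipeline from raw measurements to per-sample disease
probabilities. Because such clinical datasets are rarely public, a synthetic
cohort generator with known ground truth is part of the package and drives
all automated checks.

## The method

**Per-record classification.** Raman spectra are preprocessed (cosmic-spike
removal, wavenumber calibration, intensity-response correction, batch SVD
denoising, asymmetric-least-squares baseline removal with λ = 10³,
p = 10⁻⁵, EMSC, area normalization) and reduced to the wavenumber regions
where a per-channel Welch t-test separates the classes at p < 10⁻¹⁰. OCT
enface images are described by four texture blocks (oriented Gabor bank,
multi-scale LBP, LPQ, GLCM). Each modality gets a linear discriminant
classifier on PCA scores, tuned (solver × tolerance grid, AUC-ROC merit) by
*nested leave-one-subject-out cross-validation* and evaluated by pooled
held-out ROC.

**Per-sample fusion.** Every measurement is treated as an independent binary
diagnostic test at a fixed threshold with operating point (TPR, FPR).
Starting from a prior tumor probability of 0.5, a sample's posterior is
updated once per record:

    positive:  p' = TPR·p / (TPR·p + FPR·(1−p))
    negative:  p' = 1 − (1−FPR)(1−p) / ((1−FPR)(1−p) + (1−TPR)·p)

i.e. posterior odds = prior odds × likelihood ratio, so the result is
order-invariant. Sample-level ROC curves are reported for RS-only, OCT-only
and fused modes, with Youden, confirmatory (FPR ≤ 0.1) and screening
(TPR ≥ 0.9) operating points.

## Worked example

Run the full pipeline on a small synthetic cohort (10 subjects, 22 biopsy
samples, ~110 records per modality, 96-px enface images):

```bash
cat > demo.yaml <<'YAML'
cohort:
  n_subjects: 10
  n_healthy_samples: 8
  n_tumor_samples: 14
  mean_rs_records_per_sample: 4.5
  mean_oct_records_per_sample: 5.0
oct_image_side: 96
seed: 7
YAML
rsoct run-all --config demo.yaml --out runs/demo
```

prints:

```json
{
 "n_oct_records": 109,
 "n_rs_records": 108,
 "oct_decision_threshold": 0.586569795820747,
 "oct_record_auc": 0.7665165165165164,
 "oct_youden_threshold": 0.586569795820747,
 "rs_decision_threshold": 0.6963606806883273,
 "rs_record_auc": 0.7222222222222223,
 "rs_selected_regions": 0,
 "rs_youden_threshold": 0.6963606806883273,
 "sample_auc_OCT": 0.875,
 "sample_auc_RS": 0.8660714285714286,
 "sample_auc_RS+OCT": 0.8928571428571428,
 "seed": 7
}
```

Reading this: each modality alone classifies individual measurements
imperfectly (record-level AUC ≈ 0.72–0.77 — tumor biopsies contain
healthy-like measurement sites, so record labels are intrinsically noisy).
At this small cohort size no wavenumber channel clears the strict Welch
threshold of p < 10⁻¹⁰ (`rs_selected_regions: 0`), so the RS classifier
falls back to the full spectrum; at the full study scale the selection
typically yields 9–15 regions at the generator's shifted bands. The
`*_decision_threshold` values are the Youden thresholds of each modality's
record-level ROC (the fixed per-record decision rule), and accumulating all
of a sample's record decisions through Bayes' rule lifts the sample-level
AUC of the fused posterior (0.893) above either single modality
(0.866 / 0.875). The run directory contains per-record predictions,
per-sample posteriors, ROC curves, an operating-point report (`report.json`)
and figures.

The same pipeline is available as a library:

```python
from rsoct.pipeline import RunConfig, run_pipeline
out = run_pipeline(RunConfig(seed=7, oct_image_side=96), "runs/demo")
```

## Layout

| module | contents |
| --- | --- |
| `rsoct.synthetic` | hierarchical cohort generator (spectra, enface images, ground truth) |
| `rsoct.raman` | preprocessing chain + Welch band selection (sklearn-style transformers) |
| `rsoct.texture` | Gabor / LBP / LPQ / GLCM feature blocks, `TextureExtractor` |
| `rsoct.validation` | LOSO splitting, `TunedLDA`, `ModalityValidator`, ROC/operating points, confusion statistics |
| `rsoct.fusion` | sequential Bayes updates, combined validation, operating-point report |
| `rsoct.pipeline` / `rsoct.cli` | `RunConfig`, `run_pipeline`, metadata validation, `rsoct` CLI |

See `docs/methods.md` for the model, its assumptions, parameter defaults and
known limitations.
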