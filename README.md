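# bridgemil

Bridged multimodal fusion of whole-slide-image (WSI) patch bags and
omics profiles for censored survival prediction.

## The problem

Prognostic models for cancer patients can draw on two very different
views of a tumor: the histology slide (processed as a *bag* of patch
feature vectors, one 1024-dim embedding per 256×256 tile) and the
molecular profile (gene expression, copy-number, mutation). Multimodal
fusion usually beats either alone — but in the clinic the molecular half
is often missing. `bridgemil` trains a *bridge*: paired mappings between
the slide-embedding space and the omics-embedding space that (a)
regularize training so the two spaces align, and (b) synthesize a
pseudo-omics embedding from the slide at inference time, so the fused
predictor still runs when sequencing is unavailable.

The model couples a transformer multiple-instance-learning slide encoder
(class token + self-attention with a convolutional positional encoding on
the patch grid; Nystrom-approximated attention for long bags), a
self-normalizing (SELU) MLP omics encoder, and a discrete-time survival
head: per-bin hazards h_j = σ(logit_j), survival S(j) = ∏_{k≤j}(1−h_k),
scalar risk −Σ_j S(j). Training minimizes the censoring-aware
discrete-time negative log-likelihood plus λ times per-dimension bridge
residuals with stop-gradient targets:

    L = L_surv + λ·( ‖f_wo(h_w) − sg(h_o)‖²/d_o + ‖f_ow(h_o) − sg(h_w)‖²/d_w )

Evaluation follows the survival-analysis standard kit: Harrell's
concordance over five-fold cross-validation with a t-interval, median
risk stratification with Kaplan–Meier curves, the log-rank test and a
univariate Cox hazard ratio, kNN-graph Jaccard and Kraskov
mutual-information alignment metrics between the two embedding spaces,
integrated-gradient attributions for omics features, and per-patch
attention maps. A synthetic-cohort generator with a planted latent risk
signal provides ground truth for all of it; see `docs/methods.md`.

## Worked example

```python
import numpy as np
from bridgemil import (BridgedSurvivalModel, CohortSpec, LatentSpec,
                       RunConfig, generate_cohort)

cohort = generate_cohort(CohortSpec(n_patients=240, seed=1), LatentSpec())
model = BridgedSurvivalModel.from_synthetic(cohort, RunConfig())
results = model.fit(seed=1, n_folds=3)
print(results.summary())
```

prints

```
Bridged multimodal survival model — cross-validated fit
========================================================
modality:        multimodal
bridge mode:     bridge (lambda=0.5)
patients:        240   folds: 3   seed: 1
omics features:  300   time bins: 4
config hash:     113e679c816d
--------------------------------------------------------
fold C-indices:  0.665  0.606  0.606
mean C-index:    0.626   95% CI (0.540, 0.711)
log-rank chi2:   24.55   p = 7.25e-07
hazard ratio:    2.22 (1.61-3.07)  (high vs low, median split)
========================================================
```

The mean C-index is the cross-validated Harrell concordance of the fused
model (0.5 = random ranking); the log-rank test and hazard ratio compare
the high- vs low-risk halves at the median of pooled out-of-fold risks —
here the high-risk half has about 2.2× the event hazard. Missing-modality
inference for the same patients goes through
`results.predict_risks(missing_omics=True)`, and
`results.km_stratification()`, `results.embeddings()` and the
`bridgemil.interpret` / `bridgemil.alignment` modules expose the
stratification, alignment and attribution analyses.

The same pipeline is scriptable from the shell:

```
bridgemil simulate --n 240 --seed 1 --out data/
bridgemil train    --data data/ --out runs/bridge --seed 1
bridgemil evaluate --run runs/bridge --out report.json
bridgemil infer    --data data/ --run runs/bridge --missing-omics --out risks.csv
bridgemil attribute --data data/ --run runs/bridge --out attributions.csv
bridgemil heatmap  --data data/ --run runs/bridge --patient P0000 --out maps/
bridgemil alignment --data data/ --run runs/bridge --out alignment.json
```

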