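# milsurv

Weakly supervised, annotation-free survival prediction from whole-slide
images (WSIs) with gated-attention multiple-instance learning.

Gigapixel pathology slides carry prognostic information, but outcome
labels exist only per patient — never per pixel. `milsurv` treats each
case as a *bag* of 256×256 tissue patches at one or more magnifications
(5×, 10×, 20×), embeds every patch into 1024 dimensions through a
pluggable encoder, pools each bag with gated attention

    a_k = softmax_k( wᵀ( tanh(V f_k) ⊙ sigmoid(U f_k) ) ),   h = Σ_k a_k f_k,

fuses the per-magnification case embeddings (plus age and sex if
desired), and predicts discrete hazards `p_t = σ(W_c h)_t` over `n`
follow-up intervals. The survival curve is `S_t = Π_{τ≤t}(1−p_τ)` and
the scalar risk score — the digital pathology signature —

    DPS = −Σ_t S_t,

is higher for worse prognosis. Training maximises the censored
discrete-time survival likelihood under threefold rotated
cross-validation (every case gets exactly one out-of-fold score), and
the evaluation stack provides Harrell's C-index, Kaplan–Meier
dichotomization with log-rank test and hazard ratio, a cut-off
percentile sweep, IPCW time-dependent iAUC with bootstrap CIs, and the
continuous net reclassification improvement. Attention logits are
rank-normalised per slide into [0, 1] percentile scores for whole-slide
heatmaps and top-patch extraction. A synthetic-fixture module generates
mock slides and feature bags with planted, parameterised prognostic
signal so the entire pipeline is testable without clinical data.

Intended users: computational-pathology researchers prototyping
weakly supervised survival models, and anyone needing a transparent,
dependency-light reference implementation of attention-MIL survival
scoring with honest evaluation statistics.

## Worked example

Simulate a 300-case cohort in which 0–80% of each case's 50 patches
carry a prognostic texture signal (log hazard ratio 2 per SD of signal
burden, 20% censoring), then run the full cross-validated experiment:

```python
from milsurv import (FixtureConfig, gen_feature_bags, ExperimentConfig,
                     MILConfig, run_experiment)

data = gen_feature_bags(FixtureConfig(
    n_cases=300, bag_size=50, signal_fraction=0.4, signal_shift=3.0,
    effect_beta=2.0, censor_rate=0.2, seed=8))
res = run_experiment(
    data.records, data.bags,
    ExperimentConfig(model=MILConfig(scales=("20x",), n_bins=4,
                                     use_clinical=False), n_boot=0, seed=1))
rep = res.report
print(f"pooled out-of-fold C-index: {rep.c_index:.3f}")
print(f"iAUC: {rep.iauc:.3f}")
print(f"median-cutoff HR (high vs low DPS): {rep.hr:.2f}, "
      f"log-rank p = {rep.logrank_p:.2e}")
```

Output from this exact run:

```
pooled out-of-fold C-index: 0.818
iAUC: 0.919
median-cutoff HR (high vs low DPS): 7.57, log-rank p = 4.35e-45
```

The C-index of 0.818 approaches the generative optimum of this cohort
(scoring cases by their true simulated risk gives ≈ 0.84), the iAUC
tells the same concordance story on the time-dependent ROC scale, and
splitting patients at the median DPS separates survival decisively
(hazard ratio ≈ 7.6 between high- and low-risk halves). Rerunning with
`effect_beta=0` (survival independent of the images) returns a C-index
of ≈ 0.52 — chance level, as it must.

A command-line interface mirrors the pipeline stages for shell use:
`milsurv prep` (tissue segmentation + tiling), `extract` (patch
encoding into an HDF5 feature store), `simulate`, `train`, `infer` and
`heatmap`; see `milsurv --help`.

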