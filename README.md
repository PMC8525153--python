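# cytoilc

Mass-cytometry (CyTOF) immunophenotyping of tumor-infiltrating **innate
lymphoid cells (ILCs)**: automatic logicle transformation, threshold-based
hierarchical gating into ILC1 / ILC2 / ILC3(NKp44±) subsets, subset-frequency
statistics with tumor-stage association, t-SNE embedding with BIC-selected
Gaussian-mixture ("model-based") clustering, and Duncan's multiple range test
for per-marker group contrasts.

The package is aimed at cytometry analysts who want the whole analysis path —
from raw FCS/CSV event tables to cluster composition tables — as tested,
scriptable Python rather than a chain of GUI tools and ad-hoc R snippets.
Because clinical CyTOF datasets are rarely redistributable, a seeded
synthetic-cohort generator reproduces the statistical structure such studies
report (rare ILC subsets on an abundant CD45+ background, a tumor-stage
covariate, a planted multi-cluster phenotype mosaic), so every stage is
exercisable end to end with no data download.

## The analysis in brief

**Scale.** Raw dual counts `x` are mapped to display decades by the inverse
of the Parks–Moore biexponential

```
B(y) = T · 10^{-(M-W)} · (10^{z} - p₀² · 10^{-z/p₀} + p₀² - 1),   z = y - W - A
```

(odd-symmetric about `y = W + A`), with per-channel automatic parameters:
`T` = channel maximum, `M` = 4.5 decades, `A` = 0, and linearization width
`W` from the 5th percentile of the channel's negative events (fallback
`W = 0.25` when, as is typical for CyTOF, no negatives exist). Parameters are
estimated on the *merged* cohort so one raw intensity means one decade
everywhere.

**Gate.** On this scale a marker is positive iff its value is ≥ 1 decade.
Events are pre-gated for CD45 positivity, subsampled to 5000 events per
sample, pooled, and classified:

```
Lin(CD3/CD19/CD14/ILT3)+ or CD56+ or CD127−  →  nonILC
else CRTH2+                                  →  ILC2
else c-Kit+                                  →  ILC3  (NKp44+ / NKp44−)
else                                         →  ILC1
```

**Statistics.** Subset percentages (of CD45+ events) are compared between T2
and ≥T3 tumors by unpaired t-test. Per-marker group contrasts use Duncan's
multiple range test: ordered means, critical ranges
`R_p = q(α_p, p, df_e)·√(MSE/n_h)` at protection levels
`α_p = 1 − (1−α)^{p−1}`, step-down with the Kramer harmonic-mean adjustment
for unequal group sizes.

**Clustering.** ILC events are embedded by t-SNE on ten
identification/regulatory markers; the 2-D coordinates are fitted with
Gaussian mixtures under six covariance parameterizations (EII…VVV) and the
component count G ∈ 1..9 and family are chosen by maximizing
`BIC = 2·loglik − k·log n`.

## Worked example

```python
from cytoilc import (SyntheticSpec, generate_cohort, transform_cohort,
                     classify_events, Cohort)
from cytoilc.pregating import PregateConfig, pregate_and_subsample, pool
from cytoilc.ilc_gating import frequencies_from_pooled

spec = SyntheticSpec(seed=1)                 # 21 samples, 6000 CD45+ events each
cohort, truth = generate_cohort(spec)
gated, _ = pregate_and_subsample(cohort, PregateConfig(seed=1))
pooled = pool(Cohort([classify_events(s) for s in transform_cohort(gated).samples],
                     cohort.panel))
freqs = frequencies_from_pooled(pooled)
print(freqs[freqs.sample_id == "__pooled__"]
      [["pct_ILC1", "pct_ILC2", "pct_ILC3_NKp44pos", "pct_ILC3_NKp44neg", "n_cd45"]])
```

prints

```
    pct_ILC1  pct_ILC2  pct_ILC3_NKp44pos  pct_ILC3_NKp44neg  n_cd45
21   0.74381  0.573333           0.093333           0.092381  105000
```

i.e. from 21 × 5000 = 105,000 pooled CD45+ events the gate re-identifies the
planted subset frequencies (0.78 / 0.54 / 0.10 / 0.09 % of CD45+ cells) to
within binomial sampling error. Continuing with
`tsne_embed` + `bic_select` on the ~1580 ILC events selects a nine-component
mixture, matching the nine planted phenotype templates.

The same run is available from the shell:

```bash
cytoilc all --config run.yaml --out results/     # or: cytoilc simulate / gate / cluster / stats / report
```

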