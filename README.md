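# abcscreen

Analysis pipeline for dynamic signal-disruption screening of
developmental toxicants with live-cell luciferase reporter assays.

Chemicals that disturb embryonic signaling pathways — FGF signaling in
particular, which drives limb morphogenesis — are candidate
developmental toxicants. A reporter cell line carrying a luciferase
gene under an SRF response element turns FGF/SRF pathway activity into
a luminescence time course: cells are exposed to a chemical at −1 h,
stimulated with bFGF at 0 h, and read continuously over 0–24 h. This
package implements the full analysis of such plate time courses, for
screening scientists who want per-chemical disruption scores and binary
toxicant calls from raw plate-reader CSVs.

## Method

For each experiment (one chemical plus vehicle and background
controls):

1. **RLU** — each read is divided by the mean background (vehicle, no
   bFGF) signal at the same time point.
2. **Scaling** — RLU are min-max scaled over the whole experiment:
   x_scaled = (x − x_min)/(x_max − x_min).
3. **Fold change** — each series is divided by the mean scaled
   vehicle+bFGF series at the same time point (with a small floor ε)
   and log-transformed.
4. **Splines** — smoothing splines with six effective degrees of
   freedom (smoother-matrix trace) are fitted to the control, a(t), and
   chemical, b(t), log fold-change courses.
5. **ABC** — the area between the curves accumulates the node distances
   h_i = |a(t_i) − b(t_i)| by the trapezoid rule,
   ABC ≈ Σ_i [(h_i + h_{i+1})/2] Δt_i, and per-chemical scores sum the
   ABC over the concentration series.
6. **Statistics** — the Jonckheere–Terpstra test checks for a monotone
   concentration trend (one-sided, exact for pooled n ≤ 8); an
   empirical ROC over scores vs. reference labels yields the
   pair-concordance AUC and a closest-to-corner operating threshold;
   calls are P iff score ≥ threshold, with a Hedges' g effect size of
   the replicate score distribution against the threshold.

Exposure concentrations are planned from a four-parameter log-logistic
viability fit, f(x) = c + (d − c)/(1 + exp(b(log x − log e))): the IC50
(absolute 50%-viability crossing) when estimable, otherwise the highest
soluble concentration subject to vehicle caps (1% PBS, 0.1% DMSO).

A synthetic plate generator (`abcscreen.simulate`) produces data with
the structure the analysis assumes — a bFGF response peaking near 5 h,
multiplicative log-scale disruption with Hill concentration dependence,
sustained or early-transient time profiles, lognormal reader noise —
with exact, analytically known ABC values for validation. The
18-chemical ECVAM reference panel (scores, animal P/N labels, limb
flags) ships as a packaged table.

## Worked example

```python
from abcscreen import table2_benchmark

b = table2_benchmark()
print(round(b["roc_all"].auc, 2), round(b["roc_limb"].auc, 2), b["threshold"])
```

Running `python examples/04_validation_table_roc.py` prints:

```
AUC, all 18 chemicals (P vs N)     : 0.78
AUC, limb toxicants vs negatives   : 0.93
AUC, limb set replotted (+6-AN,BrdU): 0.87
optimal threshold (sum of ABC)     : 37.89
sensitivity / specificity / accuracy: 0.75 / 0.83 / 0.78
```

The dynamic assay separates developmental toxicants from
non-toxicants well (AUC 0.78 over all 18 chemicals) and detects
limb-malformation toxicants excellently (AUC 0.93): at the threshold of
37.89, every limb toxicant is called positive. The other examples show
the synthetic generator and scoring (`01`), viability fitting and dose
planning (`02`), and a full synthetic screen with trend tests and
effect sizes (`03`).

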