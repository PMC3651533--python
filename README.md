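# triroc

Three-class evaluation of serum marker panels: volume under the ROC
surface (VUS), Bayesian model averaging of a binary-decomposed
multinomial logit, CAR-score panels, and bootstrap
non-inferiority/superiority testing against a conventional reference
marker.

## The problem

Differentiating pancreatic carcinoma from pancreatitis *and* from
health is a genuinely three-class diagnostic question, but biomarker
studies are usually evaluated with two-class tools (AUROC, pairwise
tests). `triroc` implements the three-class analogue end to end for
metabolite concentration panels (e.g. serum amino-acid profiles
combined with a CA 19-9-like tumour marker):

* **Selectivity** of a scalar marker over three *ordered* classes
  H < P < C is measured by the volume under the ROC surface,

  VUS = P(X < Y < Z),

  the probability that a random triple of subjects — one per class —
  is correctly ordered by the marker. A perfect marker scores 1, an
  uninformative one 1/6. The estimator is the exact empirical
  U-statistic over all n₁n₂n₃ triples (with partial credit 1/2 and 1/6
  for ordering-consistent ties), computed in O(n log n); confidence
  intervals come from a class-stratified percentile bootstrap
  (B = 2000 by default).

* **Panel construction** combines the reference marker with metabolite
  concentrations or their principal components. The three-class
  multinomial logit is approximated by two binary logistic regressions
  against the baseline (healthy) class — the Begg–Gray decomposition —
  so each candidate feature subset gets a cheap BIC. Subsets within an
  Occam window are averaged with weights ∝ exp(−BIC/2), giving
  posterior inclusion probabilities and a weight-averaged coefficient
  vector. A CAR-score model (correlation-adjusted marginal
  correlations, R_XX^(−1/2) r_Xy, against pseudo-metric class responses
  1.0/0.3/0.1 for carcinoma/control/pancreatitis) serves as a
  non-Bayesian validation route.

* **Clinical surplus value** of a panel over the reference marker is
  tested on Δ_VUS = VUS_panel − VUS_reference with a paired,
  class-stratified bootstrap: the (100 − 2δ)% percentile CI (90% at
  the conventional δ = 5% margin) declares non-inferiority when its
  lower bound exceeds −δ and, in a second step, superiority when it
  exceeds 0.

Because real patient-level data of this kind are rarely published, the
package ships a first-class synthetic cohort generator (Gaussian-copula
latents with a monotone positive link, class-dependent latent shifts, a
heavy-tailed log-normal reference marker, MCAR marker missingness) that
reproduces the statistical structure such a study rests on — cohort
sizes 40/23/40, ~26 collinear metabolites with Kendall τ spanning
roughly −0.5 to 0.7 — so every stage is testable without any download.

## Worked example

```bash
$ triroc simulate --seed 7 --out cohort.csv
wrote 103 samples to cohort.csv

$ triroc vus --in cohort.csv --marker Gln --b 2000 --seed 17
{"compound": "Gln", "VUS": 0.8020652173913043, "ci_low": 0.7011548913043478,
 "ci_high": 0.8913186141304347, "B": 2000, "ci_level": 0.95, "seed": 17}
```

The glutamine-like marker orders healthy < pancreatitis < carcinoma
correctly for 80% of all cross-class subject triples — far above the
1/6 of an uninformative marker — with a 95% bootstrap CI of
0.70–0.89.

The same from Python, running the whole study pipeline:

```python
import triroc as tr
from triroc.pipeline import PipelineConfig, run_pipeline

art = run_pipeline(PipelineConfig(simulate=tr.CohortConfig(), seed=7))
print(art["vus_predictors"])
print(art["forest"])
```

```text
predictor   VUS  ci_low  ci_high
reference 0.502   0.379    0.622
      PCA 0.441   0.304    0.580
       AA 0.857   0.767    0.929
      CAR 0.853   0.770    0.928

    label  delta_hat  ci_low  ci_high  non_inferior  superior
reference      0.000  -0.050    0.050          True     False
      PCA     -0.061  -0.218    0.089         False     False
       AA      0.355   0.239    0.468          True      True
      CAR      0.351   0.214    0.474          True      True
```

The reference marker alone is a mediocre three-class classifier
(VUS 0.50). The concentration-based averaged panel (AA) and the
CAR-score panel both reach VUS ≈ 0.86; their Δ_VUS 90% CIs lie
entirely above 0, so both are non-inferior *and* superior to the
reference marker at the 5% margin, while the PC-based panel is
neither. `run_pipeline` also emits the descriptive statistics battery
(Anderson–Darling normality, Fligner–Killeen variance homogeneity,
Games–Howell pairwise comparisons), the Kendall-τ/Hochberg correlation
matrices, the Yeo–Johnson + correlation-PCA decomposition, a
per-metabolite VUS table with a closing “Random 1/6” row, and a
manifest that reproduces the run bit-identically.

The CLI mirrors the pipeline stages: `simulate`, `stats`, `vus`,
`model`, `test`, `report`, and `all`.

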