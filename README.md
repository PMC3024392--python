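# lipidshape

Integrative analysis linking the **serum lipidome** with **cardiac shape and
function** in subjects at risk of dilated cardiomyopathy (DCM). Carriers of
lamin A/C (*LMNA*) mutations develop DCM with high penetrance but are hard to
identify pre-symptomatically; their serum lipid profiles — in particular
diminished odd-chain triglycerides such as TG(49:3) — carry an early
signature that this package connects, statistically and geometrically, to
cine-MRI-derived measures of the heart.

The package is written for computational lipidomics / cardiac imaging
researchers. It implements, as a tested pipeline with a synthetic-data
module replacing the (undeposited) patient data:

1. **Lipidomics preparation** — a subjects × species concentration table is
   augmented with enzyme-activity ratio variables (desaturation:
   same class, Δ double bonds = 1, e.g. TG(49:2)/TG(49:1); elongation:
   same class, Δ carbons = 2), log-transformed, and compared between groups
   with two-sided t-tests on log values. Fold changes are reported on the
   raw scale as `fold = median(case) / median(control)`, with per-group
   quartiles. A Wilcoxon rank-sum screen handles the MRI-derived parameters.
2. **DCM-risk marker model** — logistic regression of case status on
   candidate lipids, subset selection by stepwise AIC
   (`AIC = 2k − 2·loglik`, bidirectional from the full model),
   a classification threshold tuned to minimise training
   misclassifications, and frozen-coefficient transfer to an independent
   study evaluated by a 1-df chi-square test and an ROC curve.
3. **Dependency network** — Pearson correlation heatmap plus an undirected
   Gaussian graphical model built from limited-order (q-order) partial
   correlations. For each variable pair the **non-rejection rate** (NRR) is
   the fraction of random size-q conditioning subsets on which
   H₀: ρ(i,j|Q) = 0 is *not* rejected (Fisher z, df = n − q − 3); edges with
   NRR above a threshold (0.53 by default) are omitted and edge width is
   1/NRR.
4. **Elasticnet relevance** — each image parameter is regressed on the full
   lipid profile by minimising the naive elasticnet objective
   `‖y − Xβ‖² + u₁‖β‖₁ + u₂‖β‖²` (coordinate descent), tuned by repeated
   5-fold cross-validation; the parameter is *explained by the lipid
   profiles* iff `e_min + e_sd,min < e_cons`, the one-SD rule against the
   constant model.
5. **Shape association** — corresponded two-phase (end-diastole /
   end-systole) heart surfaces are rigidly aligned (Kabsch), averaged over
   the control group into a mean model with vertex normals; each subject is
   coded as signed normal deviations `d_ji = (x_ji − x̄_i)·n̄_i`; per-vertex
   OLS `d = a_i + b_i·l` on a lipid value yields a regression field from
   which hearts are reconstructed at the control mean lipid and at a ±2 SD
   perturbation; differences in **wall thickening** (ray-cast thickness
   ES − ED) and **wall motion** (normal-projected ED→ES displacement) are
   exported as per-vertex maps.

The synthetic generator emulates the study design: two case-control studies
(11 vs 11 and 8 vs 8), 286 log-normal lipid species whose default panel
yields exactly 267 ratio variables (553 total), seven planted median folds
of 0.4–0.9, and two-phase heart cohorts of 906 + 1516 + 906 = 3328
corresponded vertices whose septal deviations are linearly coupled to a
designated lipid with stored ground truth.

## Worked example

```python
import numpy as np
import lipidshape as ls

panel = ls.default_lipid_panel()
table = ls.generate_lipid_study(panel, n_case=11, n_control=11, seed=1)
aug = ls.enumerate_ratio_variables(table)

comps = {c.variable: c for c in ls.compare_groups(aug, 1, 2)}
c = comps["TG(49:3)"]
print(f"TG(49:3): p = {c.p_value:.4f}, fold = {c.fold:.2f}")

logt = ls.log_transform(aug)
cands = ["PC(38:5e)", "PS(38:2)", "TG(49:2)/TG(49:1)", "TG(49:3)",
         "TG(50:10)", "TG(50:2)/TG(50:1)", "TG(54:3)/TG(54:2)"]
y = (logt.meta["group"] == 1).astype(int).values
model = ls.tune_threshold(ls.stepwise_aic(logt.data[cands], y),
                          logt.data[cands], y)
print("selected:", model.variables)
```

prints

```
TG(49:3): p = 0.0000, fold = 0.50
selected: ['TG(49:3)']
```

i.e. the odd-chain triglyceride planted at half the control median is
recovered at its generating fold and is the variable the stepwise search
keeps. Transferring the frozen model to a replication-style 8 vs 8 study
and running the shape pipeline at the full mesh resolution:

```
transfer: confusion [[8, 0], [1, 7]], chi2 = 12.44 (p = 0.000), AUC = 0.98
septal thickening difference: -0.91 mm; motion difference: -0.87 mm
```

— the marker generalises across studies, and decreasing TG(49:3) by two
control-group standard deviations reduces systolic wall thickening and
motion in the septal patch where the generator planted the coupling
(negative map values = reduced function), with off-patch values at the
noise floor. See `lipidshape --help` for the equivalent shell commands
(`simulate`, `prep`, `compare`, `markers`, `network`, `elasticnet`,
`shape`).

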