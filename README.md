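# immunosig

Multidimensional analysis of tissue-resolved human immunophenotypes in
humanized-mouse immunization studies.

Humanized mice — immunodeficient animals engrafted with human cord-blood
CD34+ stem cells — develop human immune lineages whose response to an
immunization (here, antigen-presenting induced dendritic cells) is read out
post-mortem by flow cytometry across tissues: peripheral blood (PB), bone
marrow (BM), spleen (SPL), thymus (THY) and lymph nodes (combined
peripheral + mesenteric, PLN_MLN, or mesenteric alone, MLN).  `immunosig`
asks the quantitative question behind such studies: *to what extent do the
tissue-resolved marker profiles of individual mice predict their
immunization status, and which markers carry that signal?*

The package provides four analysis stages over one long-format cohort
table, plus a seeded synthetic-cohort generator so every stage is testable
without animal data:

1. **Ensemble classification** (`immunosig.ann`).  Per tissue, the marker
   panel (15 lineage/memory frequencies; 8 thymus markers) feeds a small
   pattern network — one hidden layer of σ units (12; 8 for thymus), two σ
   output units, mean-squared error against one-hot targets — trained by
   Levenberg–Marquardt, Δw = −(JᵀJ + λI)⁻¹Jᵀr, with validation early
   stopping.  Accuracy, sensitivity TP/(TP+FN) and specificity TN/(TN+FP)
   (immunized = positive) are averaged over R = 2000 random 70/15/15
   train/validation/test splits, for all mice and per sex.
2. **PCA marker signatures** (`immunosig.pca`).  Per group, PCA of the
   standardized variable set (30 variables for BM/SPL: percentages and
   counts; 15 for PB/PLN_MLN/MLN; 14 for THY); markers with |r| > 0.8
   against a component score form its cluster; the control group's first
   ("governing") component defines the signature markers whose pairwise
   correlations are then compared between groups and classified as
   retained / inverted / lost / gained / neutral.
3. **Group regressions** (`immunosig.regression`).  Beta regression with a
   logit link for relative frequencies (exp of the group coefficient = odds
   ratio) and NB2 negative-binomial regression for counts (rate ratio),
   pooled and sex-stratified, with two-sided Wald z-tests at 0.05/0.01 and
   a variance F-test.
4. **Synthetic cohorts** (`immunosig.synthetic`).  Hierarchical
   compositional simulation — Dirichlet lineage and memory-subset
   compositions closing to 100%, beta CD4/CD8 splits, negative-binomial
   total counts with rounding-consistent gated counts — with plantable
   group/sex/tissue effects on the concentration log-odds.  Defaults mirror
   the reference design: 11 control vs 17 immunized mice, per-tissue
   availability, CD8 effector/terminal-memory effects in spleen and lymph
   nodes that are stronger in females.

## Worked example

```python
import immunosig as im
from immunosig import ann, panels, synthetic

cohort = synthetic.generate_cohort(synthetic.default_config(seed=1))
matrix = panels.standardize(panels.build_feature_matrix(cohort, "SPL", "ann_markers"))
report = ann.run_ensemble(matrix, R=200, seed=42)
print(f"SPL accuracy {report.accuracy_mean:.3f} "
      f"sensitivity {report.sensitivity_mean:.3f} "
      f"specificity {report.specificity_mean:.3f}")
```

prints

```
SPL accuracy 0.979 sensitivity 0.972 specificity 0.990
```

— the default synthetic cohort plants a CD8 effector-memory shift in the
spleen of immunized mice, and the ensemble recovers it well above the ~0.5
chance level it reports on an effect-free cohort.  The same pipeline from
the shell:

```bash
immunosig all --seed 1 --out run1 -R 2000
```

writes `cohort.csv`, per-tissue/per-sex `classification.csv` and a
`tissue_ranking.csv` ordered by accuracy, `marker_selection.csv` and
`signatures.csv` from the PCA stage, and the tidy `regression.csv` of odds
and rate ratios.

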