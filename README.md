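# tcafinger

Plasma untargeted LC-MS metabolomics pipeline for TCA-cycle metabolic
fingerprinting, built around the case/control analysis of mitochondrial
aconitase (ACO2) deficiency.

ACO2 catalyzes citrate → isocitrate via cis-aconitate inside the citric
acid cycle.  Its deficiency lacks conventional biomarkers; an LC-MS
plasma fingerprint — strongly decreased cis-aconitate, isocitrate and
alpha-ketoglutarate, decreased phosphoenolpyruvate and hydroxybutyrate,
mildly increased glutamate — can support diagnosis.  This package
implements the full analysis a metabolomics core would run to produce
such a fingerprint from feature tables, together with a synthetic cohort
generator (8 patients in 4 families vs 30 controls) that provides ground
truth for every stage.

**Stages**

1. **Pretreatment** — remove features missing in ≥ 75% of samples,
   half-minimum imputation, total-sum normalization.
2. **Univariate statistics** — signed fold changes
   (FC = mean꜀ₐₛₑ/meanᶜᵗʳˡ, reported as −1/r for decreases); moderated
   t-statistics on log2 intensities with an empirical-Bayes variance
   prior (s̃² = (d₀s₀² + d s²)/(d₀ + d), t referred to d₀ + d df);
   Benjamini–Hochberg q-values; the p < 0.05 & |FC| > 1.5 selection rule;
   Fisher combination of per-family contrasts.
3. **Multivariate models** — NIPALS PCA and OPLS-DA (one predictive +
   K orthogonal components) on the unit-variance-scaled selected-feature
   matrix, with R2X/R2Y and 7-fold cross-validated Q2 = 1 − PRESS/SS.
4. **Annotation** — exact-mass matching of features to a bundled
   metabolite library through a data-driven adduct/fragment grammar
   (18 ion forms: [M−H]⁻, [M+Cl]⁻/[M+³⁷Cl]⁻, [M+CH3COO]⁻, in-source
   losses of H2O/CO/CO2/HCOOH, ...), observed-minus-calculated delta m/z
   at 4 decimals, co-elution grouping, and per-metabolite averaged fold
   changes.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
from tcafinger import (
    CohortDesign, generate_cohort, pretreat, differential_analysis,
    match_features, fingerprint_report, load_metabolite_library,
    load_adduct_rules,
)

table, truth = generate_cohort(CohortDesign(seed=1))   # 38 samples, 1032 features
pre = pretreat(table)                                  # 983 features survive the 75% filter
res = differential_analysis(pre)                       # FC, moderated t, p, q, selected
print(int(res["selected"].sum()))                      # 36

anns = match_features(
    pre.features, load_metabolite_library(), load_adduct_rules(),
    tolerance=0.003, rt_window=5.0, fold_changes=res["fold_change"],
)
for a in anns:
    if a.forms:
        print(f"{a.name:22s} {len(a.forms)} forms  avg FC {a.avg_fold_change:6.1f}")
```

Output:

```
cis-aconitate          4 forms  avg FC  -35.2
isocitrate             4 forms  avg FC  -18.4
alpha-ketoglutarate    3 forms  avg FC   -4.2
succinate              2 forms  avg FC    1.2
fumarate               1 forms  avg FC   -1.3
malate                 2 forms  avg FC   -0.0
phosphoenolpyruvate    3 forms  avg FC   -6.3
glutamate              9 forms  avg FC    1.8
hydroxybutyrate        4 forms  avg FC  -22.3
```

The planted effects (−36.9, −17.7, −4.3, +1.1, −1.4, −1.1, −6.9, +1.8,
−21.8) are recovered within a few percent for the strong effects; malate
sits at the signed-FC boundary (|FC| = 1.1), where form-level estimates
straddle ±1 and average toward zero — the report flags this with a
sign-consistency warning.  `fingerprint_report(anns)` renders the same
information as a delimited table (metabolite, KEGG id, match form, m/z,
delta m/z, averaged fold change, feature ids).

The same pipeline is scriptable from the shell:

```sh
tcafinger simulate --out-dir sim --seed 1
tcafinger run --out-dir results --seed 1
```

`run` writes the pretreated table, the differential-statistics table, PCA
and OPLS-DA scores/loadings with metrics (`metrics.json`), the feature
ranking, the annotation report and a run manifest with stage counts and
parameters.

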