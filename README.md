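# senokit

Quantitative analyses for senolytic intervention studies in aging animals:
did a drug that kills senescent cells actually *rejuvenate* the
transcriptome, extend survival, and reduce the senescent-cell burden in
tissues?

The package is written for computational biologists analyzing three-arm
bulk RNA-seq designs (young, old vehicle-treated, old senolytic-treated
across several tissues), lifespan cohorts, and imaging-flow-cytometry
feature tables. Because real studies of this kind rarely ship reusable
ground truth, senokit pairs every analysis with a synthetic-data generator
whose parameters *are* the quantities the analyses estimate, so the whole
stack is testable end-to-end.

## The statistics

For each tissue, let `lfc_age = log2(old_vehicle / young)` and
`lfc_treat_vs_young = log2(old_treated / young)` be per-gene fold changes of
normalized expression (median-of-ratios size factors, `log2(x + 1)`).

* **Tilt regression.** Over age-affected genes, OLS fit
  `lfc_treat_vs_young = a + tilt * lfc_age`. Under no treatment effect
  tilt = 1; a tilt below 1 means treatment moved age-affected genes back
  toward young levels. The test statistic is `t = (tilt - 1) / SE(tilt)` on
  n − 2 df.
* **Anti-correlation.** Spearman ρ between `lfc_age` and
  `lfc_treat = log2(old_treated / old_vehicle)`; ρ < 0 means treatment
  opposes the aging signature gene-by-gene. Exact permutation p for n ≤ 8.
* **Affected-gene overlap.** Upper-tail hypergeometric probability
  `P(X ≥ k)` for the overlap k of the treatment-affected and age-affected
  sets in the universe of detected genes, with the overlap reported as a
  fraction of the treatment-affected set.
* **SASP score.** Mean log2 ratio (old over young) across detected genes of
  a senescence-associated secretory phenotype (SASP) set, computed for both
  old arms and compared by a paired Wilcoxon signed-rank test.
* **Survival.** Kaplan–Meier product-limit curves with the median taken as
  the smallest event time with S(t) ≤ 0.5, and the Gehan–Breslow–Wilcoxon
  test: the weighted log-rank statistic with weight w_j = number at risk,
  `U_g = Σ_j w_j (d_gj − n_gj d_j / n_j)`, chi-square `U' V⁻¹ U` on k − 1 df.
* **Senescence gating.** Sequential gates on per-cell features — singles
  (brightfield area, aspect ratio), focus (contrast, gradient RMS),
  CD45⁻, then SA-β-Gal⁺ with HMGB1 spot count 0 — with the senescent
  fraction reported relative to CD45⁻ focused singles.

## Worked example

```bash
python examples/rejuvenation_demo.py
```

simulates a four-tissue study in which treatment reverses 60% of every
aging effect (true tilt 0.4) and prints:

```
true tilt = 1 - kappa = 0.4
 kidney: tilt=0.399 [0.376, 0.422] p(tilt=1)=2.7e-84  rho=-0.95  overlap=93%  SASP vehicle=0.86 treated=0.29
  liver: tilt=0.404 [0.381, 0.427] p(tilt=1)=1.3e-88  rho=-0.96  overlap=100%  SASP vehicle=0.64 treated=0.21
   lung: tilt=0.396 [0.370, 0.422] p(tilt=1)=7.7e-90  rho=-0.94  overlap=92%  SASP vehicle=0.75 treated=0.33
   skin: tilt=0.414 [0.387, 0.442] p(tilt=1)=1.4e-70  rho=-0.94  overlap=88%  SASP vehicle=0.92 treated=0.35
```

Each tissue's estimated tilt sits at the true 0.4 with the null tilt = 1
overwhelmingly rejected; the negative ρ confirms treatment opposes the
aging fold changes; most treatment-affected genes are also age-affected;
and the treated arm's SASP score falls well below the vehicle arm's —
the signature of transcriptomic rejuvenation. `examples/survival_demo.py`,
`examples/gating_demo.py` and `examples/pipeline_demo.py` walk the survival,
gating and end-to-end pipeline capabilities the same way.

A thin CLI mirrors the library for shell use:

```bash
senokit run --out results/demo            # packaged demo config
senokit survival --table survival.csv --test gbw --out surv.json
senokit gate --features cells.csv --out gates.json
```

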