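# pdnet — phenotypic disease networks for matched case/control cohorts

`pdnet` quantifies multimorbidity from routinely collected diagnosis data.
Given long-format ICD-10 diagnosis records for a case cohort and a matched
control cohort (e.g. migraine patients and age/gender-matched controls from
occupational-healthcare EMR), it builds a **phenotypic disease network
(PDN)** per cohort: nodes are three-character ICD-10 codes, edges are
statistically significant pairwise co-occurrences, and cluster structure
reveals groups of conditions that travel together in patients.

## The model

For binary indicators $X_a, X_b \in \{0,1\}$ ("patient carries code
$a$/$b$"), co-occurrence is measured by the **phi coefficient** — the
Pearson correlation of two binary variables, computable from the 2×2 table
with joint count $n_{11}$, margins $n_a, n_b$ and cohort size $n$:

$$\phi = \frac{n\,n_{11} - n_a n_b}{\sqrt{n_a n_b (n-n_a)(n-n_b)}}, \qquad
t = \frac{\phi\sqrt{n-2}}{\sqrt{1-\phi^2}} \sim t_{n-2}.$$

The pipeline then:

1. keeps codes with cohort prevalence in **[2.5%, 20%]** (the very common
   codes would dominate clustering; they are reported separately),
2. keeps significant edges (two-sided $t$ test, $\alpha = 0.05$) and
   iteratively prunes nodes with **fewer than two** significant
   correlations until a fixed point,
3. clusters each PDN with a from-scratch, deterministic **Walktrap**
   (Pons–Latapy) implementation — 4-step random-walk profiles, Ward-style
   agglomeration, dendrogram cut at maximum weighted Newman modularity $Q$,
4. profiles node **degree, strength, betweenness and closeness**
   (path length $1/\phi$) with within-network z-scores,
5. compares cohorts: per-code fold changes with chi-squared tests, degree
   regression of case on control counts with **mean-shift outlier**
   detection (externally studentized residuals, Bonferroni), ICD-10
   **block enrichment** (> 2% case prevalence, ≥ 1.5-fold, $p<0.05$), and
   per-patient diagnosis-count summaries.

Because real EMR cohorts are access-restricted, `pdnet.simulate` generates
matched synthetic cohorts with planted comorbidity modules, a long rare-code
tail and a tunable case prevalence inflation — with closed-form expected
prevalences and fold changes, so every pipeline stage can be validated
against ground truth.

## Worked example

```python
from pdnet import PDNModel, SyntheticConfig, generate
from pdnet.simulate import matrices

cfg = SyntheticConfig(n_per_cohort=5000, n_codes=80, n_clusters=3,
                      codes_per_cluster=10, n_noise_codes=20, seed=42)
case_records, control_records, truth = generate(cfg)
mat_case, mat_control = matrices(case_records, control_records, cfg)
results = PDNModel(mat_case, mat_control).fit()
print(results.summary())
```

prints

```
Phenotypic disease network fit
==============================================
cohort size (case / control)           5000 / 5000
distinct 3-char codes                  80
candidate codes (prevalence window)    42 / 50
PDN nodes (>=2 significant edges)      34 / 44
significant phi correlations           92 / 159
Walktrap clusters                      5 / 6
modularity Q                           0.589 / 0.607
median diagnoses per patient           8 / 6
monodiagnosis fraction                 0.4% / 2.5%
mean diagnosis-count fold change       1.37
degree regression slope                0.39
degree regression intercept            2.35
degree regression R-squared            37.9%
mean-shift outliers                    none
```

Reading this: 80 synthetic codes were observed; 42 case-cohort codes fell
in the 2.5–20% prevalence window, of which 34 survived the ≥2-significant-
edges filter. The 1.5× generator inflation shows up as more diagnoses per
case patient (median 8 vs 6) and a much lower monodiagnosis fraction. The
three planted modules are recovered inside the 5 case clusters (noise codes
form their own small clusters). `results.save("outdir/")` writes edge,
centrality and cluster TSVs, GraphML exports (with a 0.04-phi visualization
flag on edges) and a summary JSON + run manifest.

The same analysis is scriptable from the shell:

```bash
pdnet simulate --config sim.yaml --out data/
pdnet run --cases data/cases.csv --controls data/controls.csv --out results/
```

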