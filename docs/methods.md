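# Methods

## Problem and data model

The package estimates multimorbidity structure from presence/absence
diagnosis data in a matched case/control design. The unit of analysis is
the binary patient × code incidence matrix per cohort, built at the ICD-10
three-character level (`G43.1` and `G431` both collapse to `G43`), pooling
diagnoses irrespective of their date. Patients with no surviving records
remain as all-zero rows, so prevalence denominators equal the enrolled
cohort size. Codes are additionally mapped to ICD-10 blocks (contiguous
within-chapter code ranges such as `H53-H54`); the packaged block table is
a finest-granularity, non-overlapping WHO-style list, and a user-supplied
table can override it. If an overlapping custom table is supplied, the
narrowest containing range wins; codes outside every range map to the
sentinel `UNMAPPED`.

## Co-occurrence statistics

Pairwise association is the phi coefficient — Pearson correlation of two
binary indicators — computed from the 2×2 table margins. Pairs where a
margin is 0 or n have an undefined denominator and are excluded (such codes
cannot pass the prevalence window anyway). Significance uses the standard
correlation t-transform, `t = phi·sqrt(n−2)/sqrt(1−phi²)`, two-sided
against Student-t with n−2 df; `|phi| = 1` is treated as the degenerate
limit (p = 0). No multiple-testing correction is applied to the pairwise
tests — a flat level (default α = 0.05) is used throughout, with
Bonferroni reserved for the mean-shift outlier test. Phi is known to be
attenuated when the two prevalences differ; no bias adjustment is applied.
Both signs count as significant; the sign is preserved on the edge.

## Network construction

Candidate nodes are codes with cohort prevalence in `[min_prev, max_prev]`
(defaults 2.5% and 20%, both bounds inclusive; codes strictly above the
ceiling are reported separately with fold changes and chi-squared tests,
since they would otherwise dominate cluster formation). Each cohort is
filtered on its own prevalences by default (`control_selection="own"`);
restricting controls to the case-selected codes is available
(`"case"`) because either reading of a two-cohort design is defensible.
Nodes with fewer than `min_significant_edges` (default 2) significant
correlations are removed **iteratively to a fixed point** — one-pass
removal could leave nodes violating the floor after their neighbours
vanish. Retained edges are exactly the significant ones; the 0.04 phi
cutoff is pure visualization metadata (an `above_viz_threshold` flag in
the GraphML export, strict inequality), never a filter.

## Walktrap clustering

Community detection is an original implementation of the exact Pons–Latapy
Walktrap. Negative-phi edges are clipped to weight 0: transition
probabilities require non-negative weights, and significant negative phi
between window-prevalence codes is rare in this regime. The walk matrix is
`P_ij = w_ij/strength(i)`; node profiles are rows of `P^t` (default
`t = 4` steps) computed by matrix power — deterministic, rather than
Monte-Carlo sampled walks, so identical inputs give identical dendrograms.
Distances are `r_ij² = Σ_k (P^t_ik − P^t_jk)²/strength(k)`; agglomeration
merges the adjacent community pair minimizing the Ward-style cost
`Δσ = (1/n)·|C1||C2|/(|C1|+|C2|)·r²`, with community profiles updated as
size-weighted means and ties broken by the lexicographically smallest pair
of community representatives. Connected components are agglomerated
independently (cross-component walk distances are undefined) and cluster
ids are globally unique; since weighted Newman modularity
`Q = Σ_c [W_c/W − (S_c/2W)²]` is additive over components given the global
total weight `W`, cutting each component's merge sequence at its own
maximum contribution maximizes global `Q`. The earliest level attaining
the maximum (tolerance 1e-12) is kept.

## Centralities

Degree counts significant edges; strength sums clipped phi. Betweenness
and closeness use edge length `1/phi` (stronger correlation = shorter
path): Brandes betweenness, unnormalized, with fractional counting of tied
shortest paths; closeness per connected component as
`(size−1)/Σ distances` (singleton components get 0, logged). Both are
invariant to uniform weight rescaling. Path-based measures run on the full
significant-edge graph, not the 0.04-thresholded view. Each measure is
also z-scored within its network (sample sd; constant measures yield zeros
with a log flag) so case and control profiles share an axis.

## Cohort comparison

Fold change is case prevalence over control prevalence, unrounded
internally and rounded to 2 decimals only for display. Prevalence
differences use the Pearson chi-squared test on the 2×2 table, Yates
continuity correction on by default (matching the convention of standard
statistical environments for 2×2 tables) and toggleable, which also
exposes the closed-form uncorrected statistic for verification. The degree
regression fits case significant-correlation counts on control counts by
OLS over the intersection of the two PDN node sets by default
(union-with-prefilter-degrees selectable); outliers are flagged by the
mean-shift test — externally studentized residuals referred to t with
m−k−1 df, equivalent to a per-point indicator regressor, Bonferroni
multiplier = number of regression points, capped at 1. Block enrichment
counts a patient once per block; a block is enriched when case prevalence
is strictly above 2%, fold change at least 1.5, and p < 0.05. Per-patient
summaries (median distinct codes, monodiagnosis fraction, cross-cohort
mean ratio) are computed over all codes, not the filtered subset.

## Synthetic cohorts

The generator is an independent-activation latent-module model: patient
activates module c with probability π (default 0.30); a code in module c
is present with probability `clip(base_prev·ρ_cohort + β·z_c)` (β default
0.15); noise codes are independent Bernoulli; rare-tail codes are drawn at
0.05–1.2% so that, even under case inflation, they stay below the 2.5%
analysis floor. Case marginals are inflated multiplicatively (ρ, default
1.5; controls ρ = 1). Defaults mirror the motivating study's shape:
17,623 patients per cohort, 1337 distinct codes, nine latent modules.
This model was chosen over a full correlation copula because all marginals
and fold changes have closed forms — `E[prev] = (1−π)·clip(pρ) +
π·clip(pρ+β)` — making parameter-recovery tests exact. What it does *not*
emulate: realistic ICD-10 frequency calibration, negative associations,
between-module correlation, age/gender structure (matching is by
construction) and visit timing. Passing recovery tests therefore
demonstrates correctness of the estimators under the assumed independence
structure, not robustness to real EMR confounding.

## Problem sizes and numerical choices

Tests and the acceptance script run the generator at n = 2,000–20,000
patients and 30–200 codes, sizes at which binomial standard errors make
the closed-form expectations sharp (e.g. a mean fold-change SE well below
0.01 at n = 20,000 over 160 codes) while the whole suite completes in
well under a minute of compute per module. The full study-scale shape
(17,623 × 1337) is exercised once as a construction smoke test.
Shortest-path tie tolerance is 1e-9 on lengths (inherited from fractional
tie counting); phi is validated against raw-column Pearson correlation to
1e-12; modularity bounds are [−0.5, 1].

## Known limitations

- Phi's prevalence-dependence is not corrected; comparisons across pairs
  with very different marginals should be interpreted with care.
- No follow-up-time or person-year adjustment: diagnoses are pooled over
  the observation window, so differential follow-up inflates the
  better-observed cohort.
- The Walktrap cut considers only partitions on the merge path, as in the
  reference algorithm; globally optimal modularity partitions off that
  path are not searched (the exhaustive-search cross-checks in the tests
  cover small graphs only).
- Directed/temporal disease networks are out of scope.
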