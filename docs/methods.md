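# Methods

## The problem this package models

In the FTD/ALS/PSP disease spectrum the underlying molecular pathology —
FTLD-tau versus FTLD-TDP-43 — can currently be established only at autopsy
or by a pathogenic mutation, yet it is exactly what trial stratification
needs. Two plasma extracellular-vesicle (EV) markers have been proposed to
fill this gap: the ratio of 3-repeat to 4-repeat tau isoforms (3R/4R tau,
unitless; low in the 4R tauopathy PSP, high in FTLD-tau bvFTD) and the EV
TDP-43 concentration (pg/ml; high in ALS and in the FTLD-TDP half of
bvFTD). This package implements the statistical framework of such a
two-marker study end to end: cohort simulation, nonparametric group
comparison, ROC/precision-recall analysis, Gaussian-mixture-derived decision
cut-offs, a two-marker classification grid, diagnostic performance with
exact binomial intervals, and cross-cohort cut-off transfer.

Patient-level data are not publicly available, so every stage runs on
synthetic cohorts calibrated to the published per-group summary statistics.
That choice frames what the tests can and cannot show (see *Limitations*).

## Synthetic cohorts

**Marginals.** Each diagnostic group's marker values are drawn from a
log-normal calibrated to the published median and IQR. For a printed
summary (m, q1, q3) the plain calibration is `mu = ln m`,
`sigma = ln(q3/q1) / (2 z_0.75)` with `z_0.75 = 0.6744898`. Several
published IQRs are asymmetric on the log scale (most strongly the ALS
TDP-43 summary 45.45 [28.88–83.21] pg/ml), for which a single sigma cannot
reproduce both quartiles (it misses each by ~7.5%). The generator therefore
defaults to a two-sided calibration: one sigma below the median
(`ln(m/q1)/z_0.75`) and one above (`ln(q3/m)/z_0.75`), applied to the
negative and positive half of the latent standard normal. This reproduces
all three printed quartiles exactly, is still a monotone transform of a
single latent normal (so rank-based couplings are untouched), and reduces to
the plain log-normal when the IQR is log-symmetric. The symmetric form
remains available (`quartile_matching="symmetric"`).

**bvFTD bimodality.** bvFTD is generated as a two-component mixture: a
putative FTLD-TDP-like component (control-range tau ratio 0.95 [0.92–0.97],
elevated TDP-43) and an FTLD-tau-like component (high tau ratio, control
TDP-43), with default weights 0.5/0.5 and the published subgroup
proportions available as a parameter (38.55/61.45 discovery, 58/42
validation). Joint dependence between the two markers inside bvFTD is
induced purely by component membership — the tau-like half gets low TDP-43
and vice versa — which reproduces the published negative Spearman
correlation (about −0.5) without an explicit bivariate copula.

The published bvFTD tau-ratio text admits two readings: 1.10 [0.99–1.76]
for the whole group and 2.28 [1.13–2.4] in the same paragraph. The package
reads the second as the tau-subgroup summary (default
`tau_calibration="subgroup"`), because a 50/50 mixture of the TDP-like
component at 0.95 and that subgroup component reproduces the whole-group
geometry; the whole-group reading is exposed as
`tau_calibration="whole_group"`. Note the subgroup IQR is strongly
left-asymmetric, so the tau-like component has a long left tail; this makes
*whole-group* bvFTD-versus-control rank statistics weaker on synthetic data
than published (the per-subgroup structure, which drives the cut-off
machinery, is unaffected).

**NfL coupling.** Plasma NfL is tied to the markers by a Gaussian copula:
the NfL latent is a weighted sum of the marker latents plus independent
noise, with loadings `2 sin(pi rho_S / 6)` so the sample Spearman
correlation targets the published values (tau–NfL −0.33 in PSP, +0.28 in
bvFTD; TDP-43–NfL +0.67 in ALS, +0.42 in bvFTD). Per-group NfL medians are
not published; medians are set to typical plasma-NfL magnitudes and
dispersions chosen so the NfL benchmark AUCs land near the published ones
(ALS-vs-HC ≈ 0.83, ALS-vs-PSP ≈ 0.62, bvFTD-vs-HC ≈ 0.73), which makes the
"EV TDP-43 outperforms NfL" comparison meaningful on synthetic data. NfL is
generated missing for ALS/ALS-FTD in the validation cohort, as in the study.

**Confirmed pathology.** Published counts of genetically or
neuropathologically confirmed cases are injected exactly (discovery: 50
TDP-43, 4 PSP/GGT-type tau, 3 MAPT, 6 non-tau/non-TDP; validation: 27
TDP-43, 7 non-tau/non-TDP), allocated across clinical diagnoses following
the per-gene counts. Labelled subjects' markers are re-drawn from the
published pathology-group summaries (e.g. MAPT carriers from 3.96
[3.81–4.12]), so they carry the marker signature of their pathology. The
printed q1 of the bvFTD TDP-pathology TDP-43 summary (4.52) is contaminated
by VCP/TBK1 outlier carriers; the TDP-like component uses a log-symmetric
completion of the printed median/q3 instead (36.15 [24.82–52.65]).

**Clinical scores** are monotone noisy transforms of a source marker
(`intercept + slope·ln(marker) + noise`, clipped to the scale range), so
correlation stages have signal; coefficients are configuration, not claims.

## Statistical stages

* **Group comparison** — Kruskal–Wallis on midranks with tie correction,
  followed by Dunn's pairwise z tests on pooled mean ranks with the tied
  variance term; p-values Bonferroni-adjusted over all k(k−1)/2 pairs and
  capped at 1 (the GraphPad convention; Holm available). Both are verified
  against independent brute-force rank oracles.
* **Descriptives** — median/IQR under the linear-interpolation (type-7)
  quartile convention, fixed and documented because printed IQRs do not
  disclose theirs.
* **Correlation** — two-tailed Spearman with pairwise-complete deletion and
  the t approximation for p; entries with fewer than 3 complete pairs are
  flagged missing, never fabricated.
* **Monotone trends** — least-squares isotonic regression
  (pool-adjacent-violators), direction fixed or chosen by residual sum of
  squares. The study used monotone regression splines purely for
  illustration; isotonic regression preserves the monotone contract with a
  testable, assumption-free fit. A smooth variant would be a cosmetic
  extension only.
* **ROC** — AUC as the tie-half-credited Mann–Whitney statistic; standard
  error by the Hanley–McNeil closed form; 95% CI by normal approximation
  clipped to [0, 1] (printed intervals like "0.90 [0.90–1.00]" show the
  same clipping). AUC differences: unpaired z from the two standard errors;
  paired comparisons estimate the covariance from per-subject placement
  values (DeLong-style), since the study compares markers measured on the
  same subjects without stating its correlation estimate.
* **Precision–recall** — at any population prevalence rho,
  `PPV = rho·TPR / (rho·TPR + (1−rho)·FPR)` at every ROC operating point;
  AUPRC by trapezoid over recall; CIs by seeded stratified bootstrap. At
  rho equal to the sample prevalence this reproduces the empirical
  precision–recall curve exactly. No epidemiological prevalences are
  hard-coded; they are user configuration.
* **Exact intervals** — sensitivity/specificity carry exact
  (Clopper–Pearson) two-sided binomial CIs from beta quantiles. The exact
  method is fixed deliberately: the published boundary cases (29.24% for
  3/3, 39.76% for 4/4, 91.40% for 41/41) are reproduced only by it. Two
  published bounds (for 44/50 and 56/58) match no standard interval and are
  reproduced exactly by the exact interval for counts shifted by one
  (45/51); the package reports the exact values for the printed counts
  (75.69, 88.09) rather than echoing the printed numbers.

## Mixture cut-offs

Cut-offs are derived per marker on the pooled cohort, excluding
confirmed-pathology cases (as the study did before testing the cut-offs on
them):

1. **EM fit** — univariate K-component Gaussian mixture on the raw marker
   scale (a log-scale option is recorded in provenance), best of several
   seeded starts (deterministic quantile split + random restarts),
   log-likelihood asserted nondecreasing at every iteration, component sds
   floored at 10⁻³ of the data range to prevent likelihood collapse,
   components sorted by mean so label switching cannot affect results.
2. **Component number** — sequential parametric-bootstrap likelihood-ratio
   tests (the mixtools `boot.comp` scheme): test k vs k+1 by simulating B
   datasets from the k-component fit and refitting both models on each
   (warm-started at the fitted parameters, as boot.comp does), p = fraction
   of bootstrap statistics ≥ observed; stop at the first non-rejection.
   Defaults B = 100, alpha = 0.05. Three components are required by the
   crossing construction, so a divergent bootstrap answer is recorded as a
   warning in the metadata and k = 3 is fitted regardless, mirroring how
   the study settled on three distributions after bootstrapping.
3. **Crossings** — the lower cut-off is the crossing of the low and middle
   component densities inside (mu1, mu2), the upper the crossing of middle
   and high inside (mu2, mu3). Crossings solve a quadratic in x (closed
   form; each root verified by a sign change of the log-density
   difference). Weighted densities pi·phi are the default — the crossing is
   then an equal-posterior (Bayes) boundary, and it is how mixture
   components are conventionally drawn — with the unweighted variant behind
   a flag, since a crossing of fitted distribution curves can be read
   either way. The choice is recorded in the output metadata.

## Classification grid and transfer

The four cut-offs partition the (tau ratio, TDP-43) plane: ratio below the
lower tau cut-off → PSP/GGT-type tauopathy-like; above the upper →
FTLD-tau (MAPT-like); in between with TDP-43 above the lower TDP cut-off →
TDP-43-positive (sub-flagged "high" above the upper TDP cut-off, which is
informational only — every published performance claim uses the lower one);
otherwise control-like. Conflicting cells (a tau label with elevated
TDP-43) return the tau label with a conflict flag rather than silently
resolving; the published grids show essentially empty conflict regions, so
no precedence claim is warranted. The discovery rule stores the upper tau
cut-off as 1.27 (the running-text value; the grid figure legend prints
1.28 — recorded in the rule's provenance).

Cross-cohort transfer classifies cohort B with cohort A's rule and scores
it against B's truth next to B's native rule. Published transfer claims are
one-marker threshold statements ("TDP-43 above the lower cut-off"), so the
scorer supports that mode besides grid-cell labels; the truth denominator
(confirmed cases only, or specific clinical groups) is explicit
configuration, because the published specificity denominators vary by claim.

## Numerical and design notes

* Quartile convention: type-7 everywhere (numpy default).
* EM: tol 1e-8 on the log-likelihood, max 500 iterations, 5 starts for
  final fits; bootstrap refits warm-start at the template parameters with
  tol 1e-6 / 300 iterations. Degenerate inputs (constant data with k > 1,
  n < 5k) are errors; a failed bootstrap replicate is redrawn a bounded
  number of times.
* All randomness flows from a root seed; per-stage seeds are derived by
  hashing the stage name into the root (SHA-256, reduced below 2^31), so a
  stage re-run in isolation reproduces its in-pipeline output.
* Units: TDP-43 and NfL in pg/ml throughout; tau ratio unitless; never
  converted silently.
* Problem sizes in the shipped analyses and tests: cohorts at the published
  group sizes (563 and 264 subjects), B = 100 bootstrap replicates, 20
  seeded replicates for the cut-off recovery study, 10^5-sample calibration
  checks.

## Limitations — what the synthetic results do and do not show

* Passing tests demonstrate that the machinery is correct (oracle
  equivalence, closed forms, parameter recovery) and that the published
  summaries are internally consistent enough to regenerate the study's
  qualitative structure. They do not validate the biology, and
  cohort-dependent published numbers (group p-values, real-data AUCs,
  percentages of bvFTD above cut-offs) are not reproducible from summaries
  alone.
* The log-normal tail extrapolated from the published ALS TDP-43 IQR is
  heavier than the real data evidently were: the third fitted TDP-43
  component drifts to high means across seeds, so the upper TDP-43
  crossing recovers at ~49–100 pg/ml (median ≈ 70) against the published
  56.18, while the other three cut-offs recover well (tau ratio within
  ±0.15 of 0.77/1.27, TDP-43 lower within ±6 of 13.87 in ~90% of seeds).
  The 20-replicate recovery test records this honestly rather than
  adjusting the generator to the published number.
* Injected confirmed cases draw from the published pathology-group
  summaries, which are sharper than individual patients; synthetic
  detection sensitivities therefore run a few points above the published
  ones.
* Assay features are not modelled: no plate effects, no left-censoring at
  the quantification limit by default (available as optional truncation),
  no EV particle-count normalisation.
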