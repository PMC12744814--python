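# Methods

## Strain model and conventions

Longitudinal strain is stored **signed** (negative = systolic shortening)
in percent; `GLS(%) = 100·(MLs − MLd)/MLd` from end-systolic/diastolic
myocardial lengths, both required positive. Clinical tables often print
strain magnitudes, so input may declare a `magnitude` convention and is
normalized to signed on read (`v → −v`); mixed-sign magnitude input is
refused as ambiguous rather than guessed at. `normalize_sign` is
idempotent.

Missing segments are a hard error by default. An explicit
`allow_missing` (intended ceiling: 2) treats missing segments as
*non-impaired* for pattern classification and averages strain over the
valid segments. This is deliberately conservative toward pattern
positivity: an unmeasurable segment never creates an ischemic cluster.

## The ischemic bull's-eye pattern

The 18-segment polar map has three rings (basal 1–6, mid 7–12, apical
13–18). Territories: LAD {1,2,7,8,13,14}, LCx {5,6,11,12,17,18},
RCA {3,4,9,10,15,16} — a partition into three sets of six.

A segment is **impaired** when its signed strain is strictly greater than
the cutoff (default −15 %): the magnitude of shortening is below 15 %.
The boundary −15.0 exactly is *not* impaired ("less than"). The literal
signed reading (GLS < −15 ⇒ abnormal) would label supernormal contraction
ischemic and healthy myocardium abnormal, so the magnitude reading is
implemented; the cutoff is configurable for sensitivity analysis.

"More than two consecutive segments" is read as a **connected cluster of
≥ 3 impaired segments lying entirely within one territory**. Two adjacency
readings ship, because "consecutive" on a polar display is ambiguous:

* `polar_graph` (default): circumferential neighbours within a ring
  (positions differing by 1 mod 6) plus radial neighbours across rings
  (ids differing by exactly 6). Each territory's subgraph is a 2×3 grid.
* `index_run`: ≥ 3 consecutive ids in the territory's sorted segment
  list. Strictly stronger than `polar_graph` within these territories
  (every index run is polar-connected; radial columns like {1,7,13} are
  polar-connected but not runs).

A cluster straddling two territories does not count unless ≥ 3 of its
members fall in a single territory — the rule is evaluated per territory.
The overall test is the OR of the three territory flags.

Implementation detail: the vectorized classifier flags a territory iff
some *minimal* connected subset of exactly `min_cluster` segments is fully
impaired. This is equivalent to the component-size rule because any
connected set of size ≥ k contains a connected subset of every size ≤ k
(prune leaves of a spanning tree); the per-map path uses literal
connected-component search and the two are tested against each other and
against an independent subset-enumeration oracle.

The exact angular layout of segments on the plot is cosmetic and does not
affect classification; the 17-segment model (apical cap) is out of scope.

## Physiology labeling and 2×2 statistics

Positive ⇔ (FFR measured and ≤ 0.80) or (NHPR measured and ≤ 0.89); both
boundaries are positive (the thresholds are "≤"). At least one index must
be measured; with both present they are OR-ed with no hierarchy.

* Proportion CIs: **Wilson score** (no method is canonical in the source
  literature; Wilson behaves well at the margins).
* DOR/OR CI: **Wald on log odds**, `exp(ln OR ± z·√(Σ 1/cell))`. The
  Haldane–Anscombe 0.5 correction is applied to all four cells only when a
  cell is zero, and only for odds ratios — never for
  sensitivity/specificity.
* A metric whose margin is empty (e.g. sensitivity with no diseased
  patients) is reported as *absent*, not NaN.
* ROC AUC is the rank-based Mann–Whitney estimate with average ranks
  (ties count ½), so it is invariant under strictly monotone transforms.
* Cohen's kappa uses marginal-product expected agreement; degenerate
  marginals (p_exp = 1) raise. Bland–Altman limits are
  bias ± 1.96·sd(difference) with the n−1 standard deviation.

### Reconstruction of an unpublished 2×2 table

`reconstruct_confusion(n_pos, n_neg, constraints)` enumerates every
integer table with the given margins and keeps those whose statistics
round to every constraint. Rounding is decimal **half-up** at the printed
number of decimals (how clinical tables round); proportions are matched on
the percent scale. With margins 99/108 and printed specificity 38 % and
NPV 87 %, the table (tp=93, fp=67, fn=6, tn=41) is the unique solution;
it reproduces the crude OR 9.49 with Wald CI (3.81, 23.62). Its
sensitivity is 93.9 % (rounds to 94) and DOR 9.4851 (rounds to 9.49) —
two published companion figures (93 %, 9.48) are internally inconsistent
with any table satisfying the other constraints and are treated as
truncation artefacts, not as checks.

## Screening and the multivariate model

Univariate screening fits one single-predictor logistic model per
candidate and keeps those with p < 0.2 (Wald by default; the
likelihood-ratio p of the single-predictor model is available via
`p_source="lr"`). Constant covariates are excluded as information-free.
Perfect separation is detected (unbounded coefficients / singular Hessian)
and the covariate is *retained with a flag and a warning* rather than
silently dropped — a perfectly discriminating predictor is a finding, not
a nuisance. No Firth-style penalization is applied by default, matching
plain maximum-likelihood practice.

All screened variables enter the multivariate logistic model together (no
stepwise elimination). CAPP is modeled per mmHg, untransformed. Adjusted
OR = exp(coefficient) exactly; CIs are exp(coefficient ± z·SE). Model
comparison uses **in-sample** AUC of the linear predictor (no
cross-validation, matching the analysis this emulates); an externally
supplied clinical-likelihood score is compared as a single opaque column.
Fits are Newton–Raphson with a BFGS fallback when separation makes the
Hessian singular; a separated fit returns with `converged=False` and a
warning, any other non-convergence raises.

## Synthetic cohort generator

The generator emulates the *statistical structure* of a single-center
physiology cohort, not its physiology. Defaults (all config-exposed):

| parameter | default | basis |
|---|---|---|
| n_patients | 207 | study size |
| prevalence | 0.47 | 99/207 positive physiology |
| culprit vessel (positives) | LAD .74 / LCx .12 / RCA .14 | target-vessel distribution |
| healthy segment strain | Normal(−18, 2.5) % | normal GLS ≈ −18 |
| ischemic signature | +7 % shift on a connected cluster of 3–6 culprit-territory segments | localized hypokinesis |
| background cluster in negatives | probability 0.62, same shift | reproduces the low specificity |
| CAPP | Normal(70,16) / Normal(65,15) mmHg | group medians ≈ 69/64 |
| FFR | trunc-Normal(0.76,0.05) on (0,0.80] / (0.88,0.04) on (0.80,1] | group medians 0.76/0.88 |
| NHPR | trunc-Normal(0.86,0.04) on (0,0.89] / (0.95,0.03) on (0.89,1] | group medians 0.86/0.95 |

Each index is measured with probability 0.75 (FFR) / 0.60 (NHPR), forced
to at least one per patient. Truncation makes every generated positive
satisfy the physiology rule and every negative fail it — truth labels are
consistent by construction. Auxiliary covariates (HbA1c, E/e′, prior
stroke/CAD, an opaque clinical risk score) get small group-conditional
effects so the screening stage has realistic material. Distribution
*families* are modeling choices (the emulated tables print only medians
and IQRs) and are config-exposed; CAPP is drawn independently of pattern
status given the truth label, as no joint information exists to calibrate
against.

The ischemic signature is a contiguous *cluster*, not a whole-territory
shift, so the average GLS moves little while the pattern classifier
responds strongly — the central contrast the analysis demonstrates. At
the defaults the pattern's empirical operating point is ≈ 94–95 %
sensitivity and ≈ 38–41 % specificity (n = 100,000), and group CAPP
medians land within ~1 mmHg of 70/65.

All randomness flows from one `numpy.random.Generator` seeded explicitly
(package default seed 20180824); cohorts are byte-identical given a seed,
and every stochastic test states its seed.

### What the generator does *not* emulate

Per-patient global strain variability (a random patient-level intercept):
segments are i.i.d. around −18 within a patient, so between-patient
average-GLS spread is far narrower than in real cohorts. Consequently the
average-GLS AUC on synthetic data (~0.65–0.69) exceeds the weak
discrimination seen in real patients (~0.56), and real-data AUCs are not
reproduction targets here — only the *ordering* (combined model strictly
above average-GLS-alone) is asserted, and it holds in every seeded
replicate tested. Strain-curve dynamics, FFR pullback physics, vessel
anatomy and the content of the clinical risk score are likewise out of
scope.

## Problem sizes and numerical choices

The test suite verifies classifier/oracle agreement on 10,000 random maps
per adjacency mode, generator calibration at n = 100,000, Wald-CI coverage
over 500 replicates of n = 5,000 (coverage required within 95 ± 3 %), and
the AUC ordering over 100 replicates of n = 5,000 — sizes chosen so that
binomial noise is far smaller than the asserted tolerances while the whole
suite runs in well under a minute of compute for these checks.
Proportions are compared after decimal half-up rounding when checking
against printed percentages. The reconstruction search space
(n_pos+1)×(n_neg+1) is enumerated exhaustively; no pruning heuristics.

## Known limitations

* In-sample AUC flatters all models equally; no cross-validation or
  external validation is implemented.
* The 17-segment (apical-cap) model and DICOM ingestion are out of scope;
  the package consumes segmental strain values, not images.
* The clinical-likelihood covariate is opaque: it is compared as a score,
  never recomputed.
* Separated logistic fits report unbounded CIs with a warning; a
  penalized-likelihood alternative is not provided.
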