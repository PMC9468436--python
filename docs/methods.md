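# Methods

## Measurement model and conventions

A qPCR run has 38 cycles. A reaction with no detectable curve by the
final cycle carries no point estimate, only the bound Ct ≥ 38; the
package records it as `CtValue(38, censored=True)` and uses 38 in all
arithmetic, carrying a censor flag alongside every derived quantity.
This keeps every QC-passing sample classifiable (no silent drop-outs)
at the cost of shrinking imbalances toward zero for near-silent genes —
which is conservative for screening, since a censored 5′ end makes the
computed imbalance a *lower* bound.

Sample quality is gated on the reference gene *SDHA*: evaluable means
an uncensored *SDHA* Ct strictly below 36 cycles. The gate is strict by
design (a signal *at* cycle 36 fails).

All expression statistics are Ct differences, i.e. log2 ratios
(one cycle ≈ 2-fold):

- relative expression of assay *a*: `Ct(SDHA) − Ct(a)`; larger = more
  transcript;
- imbalance of a gene: `ΔCt = Ct(5′ assay) − Ct(3′ assay)`; positive =
  3′ (kinase-domain) excess.

Because both ends are measured on the same cDNA, a per-sample shift of
all Cts (RNA quantity/degradation) cancels in ΔCt. That invariance is
asserted as a unit property and is the reason an imbalance screen works
on FFPE material at all. No amplification-efficiency correction is
applied; the statistics are raw Ct differences.

## The screening classifier

For *ALK*, two binomial logistic models are fitted per cohort, one per
5′ amplicon paired with the kinase-domain amplicon (exons 22–23):

- `alk_wide` — 5′: exons 9–10. Sees every breakpoint, but is exposed to
  rearrangement-independent imbalance (e.g. alternative splicing).
- `alk_narrow` — 5′: exons 19–20. Less artifact-prone, but blind to
  breakpoints upstream of exon 19.

Both use the same predictors: `x1` = 3′-end expression relative to
*SDHA* and `x2` = ΔCt. High kinase-domain expression with balanced ends
can still indicate a fusion, and moderate imbalance at very low 3′
expression usually does not; the two-predictor form encodes both facts.

**Fitting.** Maximum likelihood via IRLS (statsmodels GLM/binomial,
tolerance 1e-10). Under perfect separation (common in small or very
clean cohorts, where the unpenalised optimum diverges) the fit falls
back to a Newton/IRLS solver with a ridge penalty λ = 1e-6 on the two
slopes only (intercept free), gradient tolerance 1e-8, step-halving,
and emits a `SeparationWarning`. Rank-deficient designs (e.g. constant
predictors) use the same penalised solver, whose minimum-norm solution
zeroes uninformative coefficients. The fitted log-likelihood is always
at least the intercept-only likelihood; both are stored on the model.

**Cutoff calibration.** Given predicted probabilities of the *n*
training positives and a target sensitivity *s\** (default 0.95), the
cutoff is the *k*-th smallest positive probability with
*k = n − ⌈s\*·n⌉ + 1*: the largest observed value τ such that
`p ≥ τ` holds for at least a fraction *s\** of positives. Flagging uses
`p ≥ τ` (ties flag), so the calibrated sensitivity is attained exactly
and any strictly larger observed cutoff would violate the floor —
i.e. specificity is maximal subject to the sensitivity constraint.
⌈s\*·n⌉ is computed with a 1e-9 snap-to-integer guard so that binary
representations of targets like 0.95 do not shift *k*.

**Decision rule.** A sample is screen-positive when at least one model
flags it (union). The union can only gain sensitivity as models are
added, never lose it. QC-failed samples get an *indeterminate*
decision, never a boolean. Calibrating each model separately at 95%
makes the union's training sensitivity ≥ 95% by construction; enforcing
95% on the union directly would permit laxer per-model cutoffs and was
rejected as under-determined (one constraint, two free cutoffs).

**ROS1.** Fusions of *ROS1* typically raise **both** transcript ends
(the gene is already expressed in normal bronchial epithelium, and
kinase-driven tumours of any kind show elevated *ROS1*), so a
discriminative imbalance model is not attainable and none is exposed.
The package provides only the fixed triage rule ΔCt > 2 (strict) plus
exploratory plots; variant-specific PCR remains the primary *ROS1*
detector.

## Pipeline semantics

Stage order is fixed: QC → variant-specific calls → expression
classifier on the call-negative remainder → ROS1 rule (evaluated
independently for every evaluable sample). A sample with a
variant-specific call never enters the classifier. Primary statuses are
mutually exclusive with precedence
`qc_fail > fusion_detected > expression_flagged_reflex_recommended >
ros1_flagged > negative`; the independent ROS1 boolean is reported
per-sample regardless of primary status. QC failures are excluded from
the screening denominator by default (`include_qc_failed_in_denominator`
restores them).

Reported percentages use half-away-from-zero rounding at the printed
precision, computed in exact decimal arithmetic (so 21/40 → 53%, not
the 52% binary floats would give). Association tests are χ² for
sex × group, Fisher's exact for smoking × group (exact for 2×2; for
larger tables a seeded Monte-Carlo over margin-conditioned tables,
default 10⁵ resamples, using the conditional table probability as the
ordering statistic with the +1 correction), and Kruskal–Wallis for age.
No multiple-testing adjustment is applied — the screen is exploratory.
The RAS co-occurrence summary is a plain proportion with a
Clopper–Pearson 95% interval.

## Synthetic cohorts

The generator draws, per sample: an *SDHA* Ct ~ Normal(μ=26, σ=1.8)
(RNA quantity/quality); a per-gene biological term ~ Normal(0, 1.0)
shared by both ends of a gene; and per-reaction technical noise
~ Normal(0, 0.45). Each assay Ct is the *SDHA* Ct plus a class/assay
mean offset plus those terms, then censored at 38. Splitting biological
from technical variation matters: between-sample expression variability
inflates single-assay spread but cancels in ΔCt, which is what makes
the imbalance statistic tight (negatives' ΔCt SD ≈ 0.64 cycles) while
single-end expression varies by whole cycles.

Class geometry (offsets in cycles above *SDHA*; all magnitudes are
tuning constants chosen for realistic group separation, not measured
values):

| class | ALK 5′/3′ | ROS1 5′/3′ | notes |
|---|---|---|---|
| negative, RAS plain | 9 / 9 | 5 / 5 | ALK near the detection limit |
| ALK fusion | 9 / 4.5 − boost spread | 3.5 / 3.5 | boost ~ N(4.5, 1.2), floor 0.3 |
| RAS imbalanced | 9 / 6.5 | 5 / 5 | imbalance without fusion |
| EGFR / MET ex14 | 9 / 9 | 3.5 / 3.5 | kinase-driven ROS1 elevation |
| ROS1 fusion | 9 / 9 | 3 / 3 (EZR/SLC34A2: 3′ → 1.5) | both ends raised |

The per-sample fusion "boost" emulates tumour-cell content and
expression heterogeneity; it is applied to every amplicon fully
downstream of the implanted breakpoint and never upstream, so a fusion
cannot move the 5′-assay distribution (asserted as a test). Class
counts are allocated exactly (not multinomially); the default cohort
mirrors a large *EGFR*-negative NSCLC referral series (107 ALK / 44
ROS1 / 31 MET ex14 / 140 EGFR / 401 RAS / 1426 negative), variant mixes
follow the published relative frequencies of common junctions, and 7%
of ALK-fusion samples carry a rare variant with no variant-specific
call — the fraction the classifier must recover. Demographic covariates
(age, sex, smoking, with ~55% smoking status missing) are generated
with the directions seen in fusion-driven NSCLC (younger, more often
female never-smokers) so the association tests have realistic input.

Under these defaults the trained screen operates at ~95–97% union
training sensitivity (≥ 95% by construction) and ~99.5% training
specificity, with held-out sensitivity within about ±3 points of the
target on average across seeds.

**What passing tests do not show.** The generator is Gaussian and
single-breakpoint per sample; it has no amplification-efficiency
differences, no multi-isoform mixtures, no batch effects, and its
false-positive mechanisms (censoring geometry, the RAS class) are
stylised. Passing the synthetic operating-point tests demonstrates the
statistical machinery is correct under the assumed structure, not that
the same sensitivity/specificity will be observed on any clinical
cohort.

## Numerical choices and degenerate inputs

- Censored-at-38 values are used at their bound in predictors; flags
  propagate to reports.
- Empty/NA Ct cells are censored, not errors; Ct ≤ 0 or > 38 is an
  error.
- Unicode dashes in fusion names are normalised; a breakpoint letter
  that does not match the flanking gene's initial warns but parses
  (published tables occasionally carry such slips).
- Model JSON persistence round-trips floats bit-exactly.
- Grand means of per-assay medians are computed in decimal arithmetic
  before rounding, so printed one-decimal medians average to the
  printed one-decimal mean.
- Problem sizes in the test suite (cohorts of a few hundred to 2250
  samples, 20-replicate properties) were chosen as the smallest sizes
  at which the binomial noise of the measured rates is well inside the
  asserted margins.

## Known limitations

- One Ct per assay per sample; technical replicates must be combined
  upstream.
- No melting-curve, efficiency, or raw-fluorescence modelling; CSV is
  the only table dialect.
- The ROS1 rule is triage only; its yield is low by nature and most
  flagged samples will not harbour fusions.
- The classifier is per-cohort: coefficients and cutoffs should be
  re-fitted when the assay panel, chemistry, or tissue handling change.
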