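# Methods

## The classification model

Each candidate instrument is a logistic classifier on one pair (i, j) of
0–3 ordinal items:

    z = w1·x_i + w2·x_j + b,    p = sigmoid(z).

The reference standard is the full-scale screen: label = (nine-item total
≥ 10).  Because the joint input space has only 4² = 16 response patterns,
the fitted model is equivalently a 16-entry pattern → probability table;
the table is always rederived from (w1, w2, b), never stored, so a
serialized model cannot desynchronize from its parameters.

**Fitting.**  The fitted parameters minimise

    mean negative log-likelihood + (w1² + w2²) / (2·reg_strength),

with the bias unpenalized so the intercept can absorb class prevalence.
`reg_strength` follows the inverse-penalty convention: larger values mean a
weaker penalty.  The likelihood depends on the data only through the 32
pattern counts (positives and negatives per pattern), so fitting is done by
damped Newton iteration on those sufficient statistics: backtracking line
search far from the optimum, undamped Newton steps once the gradient norm
falls below 1e-5 (where objective differences are at float precision and
Armijo tests are uninformative).  Convergence is declared only at gradient
norm < 1e-8; the objective is strictly convex in the weights, so the
optimum is unique and independent of the optimization path.  Unit tests
hold the fitted objective to within 1e-4 of a brute-force
coarse-to-fine grid search over (w1, w2, b) ∈ [−5, 5]³.

## Thresholds on the pattern lattice

A decision rule is "predict positive iff p ≥ t".  The meaningful values of
t are the distinct pattern probabilities — at most 16, merging when
probabilities coincide.  Each threshold induces a partition of the 4×4
lattice into predicted-positive and predicted-negative cells (the decision
boundary).  Two structural facts are verified by tests: a model with equal
positive weights induces exactly the 7 partitions of the unweighted
two-item sum-cutoff family (the classical rule is the equal-weights special
case), and a general-position model offers 16.

**AUC** is defined in tie-corrected rank (Mann–Whitney) form: the
probability that a random positive outscores a random negative, ties
counted ½.  With at most 16 distinct scores ties are pervasive and this
form is the unambiguous standard; it equals the trapezoidal area under the
ROC polygon over distinct score thresholds (tested to 1e-12) and is checked
exactly against an all-pairs double loop.

**Operating points** carry exact integer confusion counts; sensitivity,
specificity, J = sens + spec − 1, PPV and NPV are derived from counts, with
zero-denominator predictive values flagged `None` rather than silently 0.
`predictive_values` also maps (sens, spec) to PPV/NPV at an arbitrary
external prevalence via Bayes' rule.

## Preprocessing rules

Rows with more than two missing items are excluded; remaining gaps are
imputed with the item's modal observed response, ties broken toward the
lower (less symptomatic) value — a conservative, deterministic choice.
Labels are computed after imputation.  Out-of-range values are hard
validation errors naming the offending row, never coerced.  Modes are
computed per data set, never borrowed across samples.

## The selection pipeline

1. **Split.**  One stratified train/test split (default fraction 0.6999,
   giving 2817/1208 on a 4025-row table).  The total training size is
   round(fraction·n), allocated across the two label strata by largest
   fractional remainder, so sizes are a deterministic function of (n,
   fraction); membership is randomised by seed.
2. **Folds.**  Stratified k-fold (default k = 5).  Within each stratum the
   shuffled members are dealt as evenly as possible; the fold receiving a
   stratum's remainder rotates across strata, so overall fold sizes also
   differ by at most one (563/564 on 2817 rows).  A naive per-stratum
   "first folds get the remainder" rule would concentrate both remainders
   in fold 0 and violate that bound, which is why the assignment is
   hand-rolled rather than delegated.
3. **Tuning.**  For each pairing, the penalty scale is searched on a
   deterministic log ladder over six orders of magnitude (default 1e-3 to
   1e3), refined once around the incumbent, with a fixed evaluation budget
   (default 10); each candidate is scored by mean validation-fold AUC and
   the argmax over evaluated candidates is returned.  Because rank AUC is
   invariant to proportional shrinkage of the weights, widely different
   penalties often tie exactly; ties go to the weaker penalty, which keeps
   the 16 pattern probabilities spread out instead of compressed toward the
   prevalence and hence preserves a usable threshold menu.
4. **Ranking.**  All 36 pairings are tuned and sorted by mean CV AUC,
   descending; ties break lexicographically by pair for determinism.
5. **Finalization.**  The chosen pairing's model is refitted on the full
   training split at its tuned penalty.  Its candidate rules (pattern
   partitions) are scored on each CV validation fold — rules are
   pattern-level objects, so out-of-fold scoring needs no fold-model
   probabilities and no mixing of probability scales across fold models —
   and the rule with maximal mean CV Youden index is frozen, ties toward
   higher mean sensitivity (the rule-out convention for prescreening), then
   toward the lower threshold.

Frozen instruments are evaluated elsewhere exactly as frozen: no
retraining, no threshold adjustment, purity verified by content hash before
and after scoring.  Prevalence is never reweighted across evaluation data
sets.  An append-only audit log tags every data access with its pipeline
stage, so absence of test-set leakage is checkable after a run.

## The synthetic-data generator

Real screening surveys are emulated by a Gaussian copula: a latent
multivariate-normal severity draw with a one-factor correlation structure,
discretised per item through fixed cut points that reproduce configured
marginals.

Defaults (chosen once as a realistic community-screening scenario):

| parameter | default | rationale |
|---|---|---|
| marginals (all items) | (0.58, 0.22, 0.12, 0.08) | mass concentrated on "not at all" with a tail into symptomatic categories, as in community samples |
| factor loadings | 0.6 per item | pairwise latent correlation 0.36, the moderate positive inter-item dependence typical of depression questionnaires; also leaves headroom for loading boosts up to 1.66× before hitting the unit bound |
| missing rate | 0 (opt-in) | missingness is injected explicitly to exercise the exclusion/imputation rules |
| n_respondents | 4025 | a realistic single-study screening sample |

**Prevalence calibration** applies one scalar severity offset to all cut
points and bisects it until the Monte-Carlo estimate of P(total ≥ 10) at
n = 100,000 (fixed internal seed, common random numbers, hence exactly
monotone) hits the target; targets from roughly 8% to 30% are reachable
under the defaults.  **Planted pairs** multiply two items' loadings by a
boost factor (error if any loading would reach 1), making those items
carry the most information about the factor that drives the sum score — a
known ground truth for recovery experiments.  All randomness flows from
explicit integer seeds through per-operation seed-sequence streams;
identical configs give bit-identical tables.

What the generator does *not* emulate: item-specific marginals or loadings
(real anhedonia/suicidality items differ markedly), multi-factor symptom
structure, longitudinal drift, differential item functioning, interviewer
or administration-mode effects, and informative (non-random) missingness.
Passing recovery tests therefore show that the pipeline finds a pair that
genuinely dominates the latent signal; they do not show which pair is best
in any real population, nor that a single best pair exists when items are
exchangeable — under the exchangeable defaults the 36 mean CV AUCs differ
only by sampling noise and the top rank is arbitrary.

## Problem sizes and numerical choices

- Fit convergence: gradient norm < 1e-8, Newton iteration cap 200,
  failures raise — never a silent partial fit.
- Monte-Carlo checks of marginal/joint fidelity and calibration use
  n = 100,000; joint-cell and Spearman oracles integrate the bivariate
  normal over cut-point rectangles.
- Pairing-recovery experiments use 50 seeds at n = 4000 with boost 1.5 and
  a tuning budget of 4; the full-study demonstrations use n = 4025 with a
  budget of 6.  These sizes make a complete 36-pairing ranking take about a
  second and the whole recovery suite about a minute on one CPU.
- Degenerate inputs: single-class data refuse to fit or score (explanatory
  errors); constant scores yield AUC 0.5 by the rank definition; undefined
  PPV/NPV are `None`.
- Reported tables print metrics at 3 decimals; JSON artifacts store full
  precision.

## Known limitations

- The exhaustive-pair design is hard-wired to length-2 subsets of 9 items;
  triples or other questionnaire lengths would need a generalised lattice.
- CV-based threshold selection evaluates the *final* model's pattern rules
  out-of-fold; an alternative (fold-model thresholds averaged on the
  probability scale) was rejected because fold models' probability scales
  are not commensurable, but the choice is a design decision, not a
  mathematical necessity.
- Plain CV plus one held-out split estimates generalization optimistically
  relative to nested CV; confidence intervals for AUC/sensitivity/
  specificity are out of scope.
- The tuning ladder is deterministic; a Bayesian search over the same
  objective is a conforming alternative but is not implemented.
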