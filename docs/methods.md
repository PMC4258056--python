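# Methods

## Problem and model

`funrep` decides, for every ortholog-group function in a reference
database (e.g. a KEGG Ortholog accession), whether an organism possesses
that function, using nothing but homology hits of unassembled RNA-seq
short reads against the database's protein sequences. Short reads are
individually uninformative — conserved domains make single-read
assignments ambiguous, and liberal search cutoffs let almost every
function in the database collect *some* hits — so the decision is made
on aggregated per-function evidence, separated into genuine and spurious
homology by an unsupervised mixture model.

The stages are:

1. **Best-hit resolution.** Each read with several hits keeps only the
   hit with the highest alignment score. Score ties are broken by the
   lexicographically smallest function id; the tie rule is arbitrary in
   substance but pinned for bit-reproducibility across platforms.
2. **Evidence measures.** For each function *f* with hit scores
   *H_f* (n_f = |H_f|): `count` = n_f, `sum_of_scores` = Σ H_f,
   `mean_score` = mean of H_f, and the scaled mean-score
   `SMS_f = mean_f · ln(1 + n_f) / ln(1 + max_g n_g)`.
   Count-type measures track transcript abundance and inherit expression
   bias; the mean-type measures do not. SMS damps means supported by
   very few hits. The log base cancels in the ratio; the +1 shift keeps
   the ratio in (0, 1] for n_f ≥ 1 and keeps SMS positive whenever the
   mean is positive, which the Gamma model's support requires. Functions
   with zero hits carry no evidence entry, never enter a fit, and are
   predicted absent.
3. **Mixture calibration.** Per sample, the observed evidence values are
   modelled as a two-component mixture — low component = spurious weak
   homology, high component = genuine homology. Mean-score values use a
   Gaussian mixture fitted by EM; SMS values use a Gamma mixture fitted
   by stochastic EM (SEM). The decision threshold is the equal-cost 0/1
   Bayes boundary: the point between the component means where the
   weighted component densities cross. An optional cost ratio reweights
   the crossing when false positives should cost more than false
   negatives (default 1).
4. **Prediction and consensus.** A function is called present in a
   sample when its evidence is strictly greater than the threshold
   ("above" is read strictly, so a value equal to the threshold is
   excluded). Across R technical replicates — each fitted and
   thresholded independently — a consensus level c calls a function
   present when it is predicted in at least c replicates. c = 1 is the
   union, c = R the intersection; the consensus set is monotone
   non-increasing in c, which is the mechanism behind falling
   false-positive rates at higher consensus levels.
5. **Evaluation.** Against a reference annotation (positives P inside a
   function universe), predictions are scored by set algebra: TP/FP/FN/TN
   with TPR, FPR, specificity = 100 − FPR, PPV and
   F1 = 2·TPR·PPV/(TPR+PPV), all in percent. Evidence rankings are scored
   threshold-free by ROC/AUC and by the maximum achievable F1 over all
   thresholds. A naive E-value-cutoff predictor (function present iff it
   has ≥ 1 hit with E ≤ cutoff) is provided for comparison sweeps.

## Numerical choices

**Gaussian EM.** Initialisation splits the sorted values at the median
and seeds each component with its half's mean and standard deviation at
weight 0.5 — deterministic, so Gaussian calibration needs no seed.
Convergence: relative log-likelihood change < 1e-8, cap 500 iterations.
Component variances are floored at 1e-6 × the overall data variance to
prevent collapse onto a single point. The log-likelihood trace is kept on
the fit object; it is non-decreasing by the EM guarantee and tests assert
this at every iteration. A mixture needs at least 10 non-identical
values; anything less raises an "insufficient data" error.

**Gamma SEM.** Each iteration draws a hard component label for every
value from its posterior responsibilities, then re-estimates each
component by Gamma maximum likelihood: the shape solves
ln k − ψ(k) = ln(mean x) − mean(ln x) by Newton iteration (initialised at
the standard closed-form approximation, tolerance 1e-10, cap 50
iterations, shape capped at 1e6 for near-constant data), and the scale is
mean/shape in closed form. The schedule is 300 iterations with the first
100 discarded as burn-in; reported parameters are the post-burn-in means,
which smooths the label-sampling noise of the chain. Components are
labelled low/high by their mean (shape × scale) after averaging. A
component left with fewer than two values by a label draw is redrawn (cap
10) before the fit fails. The RNG is seeded and mandatory (default 1);
identical seeds give bit-identical fits. Values ≤ 0 violate the Gamma
support: the per-sample calibration step excludes them from the fit with
a logged count (they can arise under exotic scoring schemes), while the
Gaussian path uses all values.

**Threshold search.** The weighted-log-density difference is evaluated on
a 10,000-point grid between the component means; the first sign change is
refined by bisection to a width below 1e-9 × the inter-mean distance.
When the means coincide to tolerance, or no crossing exists in the
interval (one component dominates everywhere between the means, as
happens when the two components converge onto a unimodal sample), the
midpoint of the means is returned with `fallback_used` set. An
independent oracle (`bayes_threshold_oracle`: dense grid + Brent root on
exact spec densities, no code shared with the search) cross-checks the
derivation in tests to 1e-6 of the inter-mean range.

**ROC/AUC.** The AUC is computed by the Mann-Whitney rank-statistic
formulation with midranks for ties, over the *whole* universe: functions
without an evidence entry are ranked strictly below all observed values
(evidence −∞), since no evidence at all was found for them. This equals
the probability that a random positive outranks a random negative plus
half the tie probability, and tests verify exact agreement with the
brute-force pairwise statistic on tied rankings. Per-sample AUCs may be
averaged (`mean_auc`); curves are never averaged. `max_f1` scans every
distinct score as a candidate threshold under the same strict `> t` rule
used for prediction, so it is a true upper bound for any calibrated
threshold on the same ranking.

**Empty predictions.** PPV and F1 of an empty prediction are undefined;
both are reported as 0 and flagged (`ppv_defined`).

## Synthetic data

The generator emulates the study design the method targets: technical
replicates of one RNA pool searched against a large ortholog database
under liberal cutoffs.

* `simulate_evidence(MixtureSpec)` draws evidence values directly from a
  specified Gaussian or Gamma mixture with per-draw ground-truth labels —
  the oracle for parameter-recovery tests.
* `simulate_hit_tables(ExperimentSpec)` builds read-level hit tables.
  Exactly `round(fraction_present · n_functions)` functions are planted
  present. Per replicate, each present function draws a hit count from a
  negative binomial (default mean 50, dispersion 5 — mimicking
  expression-level variation in read counts), with scores from a
  truncated-at-zero Normal(60, 8); every function, present or absent,
  additionally draws Poisson(2) spurious hits with scores from a
  truncated Normal(20, 6). Replicates are independent redraws from the
  same spec (a technical-replicate model). Each hit also carries a
  pseudo E-value `10^(−score/10)`, monotone in the score, sufficient for
  E-value-sweep logic.

What the generator does *not* emulate: sequence-level effects (no reads,
no alignment), structured cross-hits between specific function pairs
sharing conserved domains, biological replicate variation, and the heavy
overlap of genuine and spurious evidence seen for some real tool/measure
combinations. Passing recovery tests therefore show that the pipeline's
statistics and plumbing are correct under a genuinely bimodal evidence
distribution — they do not certify performance on real data, where the
component overlap and the fit quality of the chosen families are the
binding constraints.

Default problem sizes (1,000 functions, 30% present, 5 replicates,
5,000-draw recovery checks) keep the full suite and the acceptance script
in the tens of seconds on one CPU while leaving the mixtures enough data
for stable fits.

## Design choices where the design was open

* **"Risk of false predictions".** Formalised as equal-cost 0/1 Bayes
  risk, i.e. the weighted-density crossing; a cost-ratio parameter
  exposes unequal costs without changing the default.
* **SMS formula.** Chosen as mean × ln(1+n_f)/ln(1+max n_g); natural log
  with a +1 shift (see above). Other log bases give identical values.
* **Strict threshold comparison** (`>` not `≥`), so a function sitting
  exactly on the threshold is not called present.
* **Per-sample fitting.** Each replicate gets its own fit and threshold;
  consensus combines calls, never evidence values, and only within one
  tool/measure combination.
* **No automatic refit.** Mixture fits can converge to a maximum that
  still describes the data poorly (e.g. a unimodal sample); the package
  flags the midpoint fallback and offers a diagnostic plot
  (`calibrate --plot`) rather than guessing a remediation.
* **m8 subjects are protein accessions**, not functions, so m8 input
  requires a two-column subject-to-function mapping; unmapped subjects
  are dropped with a logged count. No E-value filter is applied at parse
  time by default (liberal cutoffs are the upstream search's business);
  `--max-evalue` exists for convenience.
* **Scheduling randomness.** The pipeline derives every stage seed from
  one master seed via `SeedSequence`, so a run is reproducible
  byte-for-byte from a single integer.

## Known limitations

* Only two-component mixtures; no model selection between the Gaussian
  and Gamma families and no heavier-tailed families for measures they
  would suit better.
* Orthologs and paralogs cannot be distinguished from short-read homology
  alone; calls are about function presence, not gene identity.
* Native output dialects of tools beyond BLAST tabular must be converted
  to the generic three-column form by the caller.
* The E-value sweep evaluates one hit table at a time; aggregation across
  samples is left to the caller.
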