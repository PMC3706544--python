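# Methods

This note records the models implemented in `melagl`, the parameters that
matter, and the design choices made where the design was genuinely open.

## The grammar and its fixture

The stimulus language is a (possibly nondeterministic) finite-state machine
whose alphabet is a set of tone pairs; a k-terminal sequence realizes a
2k-tone melody. The package ships a documented fixture machine
(`data/fixture_grammar.yaml`) rather than any previously published grammar:
8 terminals (a–h), 8 states, a start state branching into an *upper* and a
*lower* pathway (each with a bounded self-loop and a back-loop) that rejoin
only at the accept state. Properties the fixture is built to satisfy:

- enumeration to 15 terminal pairs yields ≥ 33 distinct sequences, all of
  8–30 tones (minimum accepting path: 4 pairs);
- each pathway contributes ≥ 8 sequences, so cross-pathway hybrid
  (type-4) errors are always constructible;
- the 8 tone pairs cover 8 distinct pitches spanning exactly one octave.

The tone pairs favor steps, thirds and fourths. This is deliberate: the
source surface is meant to be *consistent* with common melodic expectancy,
and with these pairs the identity mapping ranks in the top percentile of
the consistency ranking over random re-voicings (a purely stepwise pair set
fails this, because seconds score poorly on consonance even though they
maximize proximity).

The 33 grammatical melodies are drawn length-stratified (cycling through
available lengths, seeded) and split 17/16 old/new by sorting on length and
alternating, with seeded tie order — so length carries no information about
old vs. new, and none about grammaticality after length matching.

## Narmour factor coding

The six implication–realization factors are coded from the implicative
interval I and realised interval R of each three-tone window. The verbal
principles do not fix numeric codings; the tables below are the package
defaults, are configuration-switchable (`ScoringConfig`), and only their
*relative* scale matters downstream because mapping candidates are compared
by z-scores.

| factor | coding (defaults: small ≤ 5 st, large ≥ 6 st) |
|---|---|
| rd | 1 if small I continued in the same direction, or large I reversed; lateral R counts as "not same direction" (scores after large I only) |
| rr | 1 if direction reverses (R ≠ 0) and the third tone lands within 2 st of the first (|I + R| ≤ 2) |
| id | small I: ‖R|−|I‖ ≤ 3 same direction / ≤ 2 reversed; large I: |R| ≤ |I|−3 |
| pr | max(0, 6 − |R|), graded 0–6 |
| cl | +1 for direction change; +1 for large I shrinking by ≥ 3 st (same direction) or ≥ 2 st (reversed) |
| co | weight vector over |R| = 0–12, intervals beyond an octave folded down |

For closure, the "smaller than 3 semitones" phrase admits two readings
(absolute size of R vs. amount of shrink); the *shrink-amount* reading is
implemented because it parallels the intervallic-difference rule for large
intervals. The consonance weights are modeled on empirically derived
consonance ratings of the chromatic intervals rescaled to [0, 1]; they are
explicitly configuration, not ground truth — any monotone-equivalent vector
yields the same rankings up to ties.

Invariants asserted in tests: transposition invariance, mirror (inversion)
invariance, proximity monotone non-increasing in |R|, and the factor
codomains ({0,1}, {0,1,2}, [0,6]).

## Mapping optimization

Candidates are injective maps from the 8 source pitches into a chromatic
pool spanning 15 semitones centred on the source tessitura (an octave
widened to about a tenth, giving room to break proximity and registral
return without unbounded range). If the injection count exceeds the limit
(default 200,000), a seeded uniform sample without replacement is scored
instead; scoring is vectorized over candidates and verified in tests
against per-mapping brute-force recomputation. Each factor is z-scored
across the candidate population (population SD; zero-variance factors
contribute z = 0), and candidates rank by the unweighted sum. Higher factor
scores mean more expectancy-consistent, so the *most inconsistent* mapping
is the arg-min of the total; ties break to the earliest candidate, and a
full ranked report is emitted so a final pick can be made by hand. No
heuristic search is used — exhaustive-or-sample only.

## Ungrammatical stimulus classes

All five generators rejection-sample under a seeded RNG and certify every
output against the membership oracle (bound: 1,000 retries, then a hard
error — never silent acceptance). Type 2 draws a random walk over the
bigram graph of the 33 grammatical sequences and additionally requires at
least one trigram absent from the grammatical trigram set. Type 3 anchors
are 2 terminal pairs at each end (configurable). Type 4 takes the first
⌈L/2⌉ pairs from a donor on one pathway and the last ⌊L/2⌋ from the other
pathway. Type 5 flips a seeded coin between an adjacent swap and a
deletion; a deletion shortens by one pair, so its donor is chosen one pair
longer than the target. Target lengths for the 33 ungrammatical slots are a
seeded permutation of the 33 grammatical lengths, making the length
multisets exactly equal.

## Rendering

Melodies render to Standard MIDI File format 0, one track: a set-tempo
event of IOI·1000 µs per quarter at 480 ticks/quarter makes one quarter
note exactly one inter-onset interval (default 330 ms); every note is held
one IOI at velocity 100. A minimal reader exists purely so tests can verify
onsets, pitches and velocities from the produced bytes.

## Behavioral analysis

- Accuracy: grammatical items correct iff endorsed familiar; chance is .5
  by the 33/33 construction. Outliers: |overall − mean| > 2 SD, computed
  once on the full group, no iteration.
- Planned one-sample t tests (sample SD, df = n−1, two-tailed) against .5,
  Holm step-down across the 7 planned cells (old, new, error types 1–5).
- Mixed ANOVA (2 between × 1 within): between effects are tested on subject
  means with Type III SS (Sum coding, statsmodels OLS/anova_lm) against the
  subjects-within-cells error; within effects use the univariate
  orthonormal-contrast decomposition, pooling per-contrast Type III SS
  against the subject × within residual. This equals the classical
  split-plot decomposition on balanced data (asserted against an
  independent sums-of-squares oracle) and handles unbalanced groups the way
  standard statistical packages do. No sphericity correction is applied
  (noted in the report output); contrasts are F = t² on participant-level
  difference scores, uncorrected.
- Chunk strength: overlapping n-gram counts (n = 1–8; pitch view and
  interval view) of each stimulus against the training corpus — the 17
  old-grammatical melodies counted once; the learning blocks repeat items,
  which would scale all counts by a constant, so the multiplier is
  configurable but defaults to 1.
- Per-participant logistic regressions (intercept + ACS 1–8 +
  grammaticality, raw unstandardized predictors, familiar = 1) are ML fits
  by Newton/IRLS with a tiny ridge (1e−6) so complete separation cannot
  produce infinite coefficients; constant predictors are dropped with a
  warning. Group inference is a one-sample t of each coefficient across
  participants.
- Type-2 d′ = Φ⁻¹(P(confident | correct)) − Φ⁻¹(P(confident | incorrect)),
  with empty-cell rates replaced by 1/(2N) and 1 − 1/(2N).

## The synthetic cohort

Each participant j draws a weight vector w_j ~ Normal(weight_means,
weight_sd²); endorsement is Bernoulli(logistic(w_j·x)) where x is the
stimulus's ACS 1–8 (pitch view) plus grammaticality, and confidence is
Bernoulli(logistic(γ·|w_j·x|)). Confidence is driven by *evidence
magnitude*, not by accuracy, so above-zero Type-2 d′ emerges
mechanistically. Defaults (chosen once; intercept −2.0, ACS₂ weight 0.06,
grammaticality weight 1.2, γ = 0.45, n = 31 with 15 musicians) put the
default cohort's mean overall accuracy in the mid-.60s with
between-participant SD ≈ .07–.09 and mean d′ ≈ 0.2. The baseline
comparison cohort (n = 22, 11 musicians) has stronger structural weights
with a correspondingly lower intercept (−3.8) so that higher sensitivity is
not confounded with yes-bias; it lands near .75 overall. An error-type
difficulty gradient (type 1 easiest) emerges from the feature structure
alone, because fully random sequences have the lowest chunk strength.

What the simulator does *not* emulate: learning dynamics (weights are
static), sequential/order effects across test trials, response times,
lapses or attention drift, and any perceptual effect of the re-voicing —
chunk-strength features are invariant under injective re-voicing, so
expectancy-driven group differences are *injected* via the weight scale,
not derived from the melodic surface. Passing tests therefore validate the
pipeline's statistical machinery and its sensitivity/specificity, not any
claim about human listeners.

## Numerical choices and problem sizes

- Population (not sample) SD in mapping z-scores; sample SD (n−1)
  everywhere in the behavioral statistics; two-tailed p throughout.
- Mapping runs in tests and the acceptance script score seeded samples of
  a few hundred to a few thousand candidates — the selection property
  (span ≤ 15, proximity suppressed, leaps amplified) is stable across
  sample sizes, and the z-ranking is verified against brute force on
  enumerable pools.
- Logistic recovery is asserted at 8 passes over the 66-item set (528
  trials/participant), where per-participant ML bias with 10 predictors is
  negligible relative to the group SE; at the study-scale 66 trials the
  fits carry visible small-sample bias (a known property of ML logistic
  regression), which is why group-level t tests, not individual
  coefficients, are the unit of interpretation.
- Type-I control of the planned-test family is checked over 150 seeded
  null-cohort replicates against the one-sided 99.5% binomial bound for
  the nominal 5% FWER.
- Degenerate inputs: zero-variance t tests and correlations raise; a
  within factor that is constant per participant reports F = 0; zero-SD
  factors in the z-ranking contribute 0 and are flagged.

## Known limitations

- The fixture grammar and tone pairs are synthetic stand-ins; absolute
  accuracy levels and factor means depend on them.
- Consonance weights are one defensible choice among several published
  rating sets.
- The ANOVA assumes complete within-factor data per participant and
  two-level between factors.
- Holm decisions are reported per planned family; no across-family
  correction is attempted.
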