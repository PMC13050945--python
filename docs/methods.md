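# Methods

This note documents the statistical procedures implemented in `ldd`, the
assumptions behind them, the defaults and why they were chosen, and the
limitations a user should keep in mind.

## Annotation model

The unit of analysis is the *sentence*: one complete enunciation by a speaker
in a two-party dialogue (enunciations are never split into clauses).  Three
raters independently assign each sentence up to 4 discourse labels from
{Master, University, Analyst, Hysteric, Capitalist} — each with an ordinal
confidence and a strength-of-presence weight in [0, 1] — and up to 3 emotion
labels from a closed 30-label vocabulary (27 GoEmotions categories plus
`neutral`, `anguish`, `anxiety`), each with a confidence.  "Comfort",
sometimes listed as a pre-emotion in developmental taxonomies, is not a
GoEmotions label and is not in the vocabulary.

Two ordinal confidence scales are supported (`four_level`: Definitely Not …
Definitely Yes; `three_level`: Low/Mid/High) because annotation platforms use
both.  Estimators need numbers, so levels are mapped through configurable,
strictly increasing tables; defaults are four_level = (0, 1/3, 2/3, 1),
three_level = (1/3, 2/3, 1) and consensus H/M = (1, 1/2), with the top of
every scale at 1.  Any order-preserving mapping is admissible; corpora built
directly from numeric confidence tables bypass the mapping via per-label
numeric overrides.  Downstream statistics depend only on the chosen mapping,
which is recorded in provenance.

## The common-user consensus

The three raters' vote sets are merged per sentence by a general law rather
than a lookup table:

* **support**: a label is kept iff ≥ 2 of 3 raters voted for it;
* **confidence**: H if unanimous (3/3), else M;
* **weight**: `max(weight_floor, 1 − 0.2 · n_dc)`, where `n_dc` counts
  discarded-companion incidences — for each rater vote set containing the
  kept label, each co-listed label that was discarded counts once;
* **none-outcome**: if no label survives, the sentence is marked `(none, L, 0)`,
  excluded, and never enters any estimator.

The law reproduces all 29 published merge rules exactly, for arbitrary
concrete label assignments and rater orderings, and — unlike a 29-branch
table — resolves every possible vote pattern deterministically.  The merge is
a function of the multiset of label sets only: individual raters' confidences
and weights are provably ignored (asserted by a metamorphic test).  Emotions
are merged under the same support/confidence law without weights; the
original study describes its emotion merge only in supplementary material not
available here, so this surrogate is a design decision of this package and is
flagged as such.  A missing rater record is an empty vote set, not an error,
because several published rules depend on "(none)" slots.

Weight floor 0 clamps patterns more penalized than any published rule (e.g.
four discarded companions) instead of going negative.  Under the default
penalty 0.2, weights are multiples of 0.2 in [0, 1].

## Association statistics

For a pair (D, E) of a discourse combination and an emotion set, matching is
**exact**: a sentence contributes iff its consensus sets equal D and E as
sets.  This partition semantics is what makes per-emotion-set probabilities
sum to 1 and the estimator unbiased; subset semantics would break both.  The
column-sum-to-1 property sometimes claimed for such tables does not follow
from the estimator under any matching semantics we could construct, and is
not asserted.

* `Prob(D|E)` — ratio of confidence-product sums (see README for the
  formula).  An emotion set that never occurs raises
  `UndefinedConditionalError` rather than returning 0, so absence of evidence
  stays distinguishable from evidence of no association.
* `W(D|E)` — per-sentence product of the pair's discourse weights, aggregated
  across matching sentences.  The definitional wording (sum) and the worked
  numeric convention (product across sentences) disagree in the source
  material; **product is the default** because it matches the only worked
  number, and sum mode is selectable (`mode="sum"`); tables record which mode
  produced them.  Note product-mode W decreases with support, so it rewards
  few strongly-weighted matches.
* `R = Prob × W`; `RI = R / max R` within the stratum of pairs with the same
  (n, l) = (|D|, |E|).  A stratum whose maximal R is 0 yields RI = 0.  Only
  observed pairs are enumerated; unobserved cells are implicitly zero.

`top_k_filter` keeps, per emotion set, the k records with largest RI; ties at
the cutoff break by larger support, then lexicographically smaller
discourse-combination code — deterministic and documented rather than
arbitrary.

## Inter-rater agreement

Krippendorff's alpha with the nominal metric, computed from the coincidence
matrix with the small-sample (n − 1) correction and missing-data support.
Because raters assign label *sets*, agreement is computed one discourse at a
time on binary presence codings (5 discourses × {all raters, each pair} = 20
alphas).  A rater who cast no discourse votes on a sentence is a missing
cell, not a 0.  When only one category is ever used, expected disagreement is
0 and alpha is reported as 1 (no disagreement is possible).  Alpha is *not*
invariant under replication of the data — the (n − 1) correction makes it
size-dependent, converging to the asymptotic value as units accumulate; the
tests assert this behaviour rather than a false invariance.  Bootstrap
confidence intervals are out of scope (point estimates only).

## Sample-size and stability analysis

Closed form: `n ≥ Z²·p(1−p)/E²` for estimating a proportion to margin E at a
given confidence; the worst case sets p = 1/2.  With Z = 1.645 (90 %) and
E = 0.05 this gives n = 270.60; conversely n = 264 gives E = 0.0506.  The
conventional rounded Z values can be supplied explicitly; otherwise the exact
normal quantile is used.

Simulation: for sizes s₁ … s₂₆ = 10, 20, …, 260, draw `n_reps` uniform
subsets of sᵢ included sentences **without replacement**, evaluate the
estimator on each, and average the defined estimates into pᵢ.  Draws on which
the conditioning emotion set is absent are dropped and counted (`dropped_reps`
in the output) — small subsets of rare sets can otherwise silently bias the
mean.  Dispersion is summarized two ways: cumulative std c_k = std(p₁…p_k)
(c₁ ≡ 0) and rolling std over windows of w = 10 (17 values on the 26-point
grid), both with the n − 1 denominator.  The relative standard error is

    RSE = 100 · std / (√n · μ)   [percent]

with n the point's sample size sᵢ and μ the grand mean of the pᵢ.  The
literal `std/(n·μ)` variant is available via `rse_denominator="n"` for
comparability with sources that print it that way, but √n is the standard
definition of an RSE and is the default.  Regimes: RSE < 1 % high, < 5 %
good, < 10 % adequate stability, else unstable; boundaries are exact.

## Synthetic data

The generator emulates the study's data shape: dialogues of speaker turns,
each sentence carrying a latent discourse combination drawn from a combo
distribution, an emotion set drawn from that combo's conditional, and three
raters who see the truth through label noise (per-label drop probability,
per-set spurious-add and swap probabilities), with ordinal confidences and
weights sampled independently.  Defaults: 40 dialogues × Uniform{6, 7}
sentences (≈264 in total, the study regime); 13 discourse combinations
(5 singletons, 6 pairs, 2 triples) with mass skewed toward
Hysteric-containing combinations; emotion conditionals over sets of size 1–3
shared across combos so that the implied Pr(combo | emotion set) are
non-degenerate; rater noise drop/add/swap = 0.15/0.10/0.05, a moderate
disagreement level.  Noise acts on label sets only, because the consensus
merge ignores confidences and weights; the confidence and weight models exist
to exercise I/O and the estimator's numerics.

Because emotion sets are drawn as exact sets, the planted conditional
Pr(D | E) is closed-form Bayes arithmetic on the config
(`planted_conditional`), enabling recovery tests: with zero rater noise the
consensus reproduces the truth exactly (every label H, weight 1), and the
estimator's mean over many corpora matches the planted conditional within
Monte-Carlo error.  `generate_annotated_corpus` skips the rater layer and
emits consensus-level corpora with uniform random numeric confidences — the
input shape for estimator-recovery and subsampling studies.

What the generator does **not** model: linguistic content (sentence text is a
placeholder), correlated rater errors, sentence-order effects within
dialogues, and per-sentence difficulty.  Passing tests therefore validate the
*statistical machinery*, not claims about any particular human-annotated
corpus; reproducing published dataset-dependent tables requires the deposited
annotations via the `convert_deposited_votes` hook.

## Numerical and engineering choices

* Weights are rounded to 10 decimals after the penalty arithmetic to keep
  them exactly on the 0.2 grid.
* Undefined quantities raise typed errors (`UndefinedConditionalError`,
  `UndefinedAgreementError`) instead of returning sentinel values.
* All randomness flows through `numpy.random.default_rng(seed)`; generation,
  harmonization and tabulation are byte-reproducible under a fixed seed
  (asserted end to end, including the CLI).
* Problem sizes in the test suite (≈264-sentence corpora, 200 subsampling
  reps, 500 recovery corpora of 200 sentences) are chosen to match the study
  regime at the scale where Monte-Carlo error bars are already far tighter
  than the effects being checked.
* Heat-map PNGs suppress date metadata so renders are byte-stable for a
  fixed matplotlib version.

## Known limitations

* The emotion-merge law is a surrogate (see above); users comparing against
  the original study's emotion consensus should treat H/M emotion levels as
  this package's convention.
* Only the 3-rater merge semantics are tested; `min_support` is configurable
  but other rater counts are unsupported.
* Product-mode W, and hence R and RI, are not comparable across rows with
  different support counts — read tables row-wise.
* Alpha is computed per discourse on binary codings; set-distance metrics
  (e.g. MASI) are not implemented.
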