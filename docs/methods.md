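# Methods

## The concordance model

The framework scores a search strategy's agreement with an expert panel
over a scenario family. Every (scenario i, item j, rater k) triple
contributes the product h_ij · r_ijk, where h_ij ∈ {+1, −1} is the
strategy's include/exclude decision and r_ijk ∈ {+1, +½, −½, −1} is the
rater's mapped four-step relevance rating. S_total is the sum of these
products over all rated triples, normalized so it spans [−1, +1]. The score
is kappa-like in spirit — it rewards strategy/expert agreement — but it
carries no chance-expected-agreement correction term: 0 means "no
correspondence", not "chance-level agreement", and we deliberately
implement the normalized-sum form rather than Cohen's kappa.

Two restricted scores reuse the formula on consensus pools. An item's
consensus is Σ_k r_ijk: S_included uses only items with positive consensus
(how well relevant material is included — sensitivity), S_excluded only
items with negative consensus (how well irrelevant material is excluded).
The inequalities are strict, so a zero-consensus item is *neutral*: it
contributes to S_total but to neither pool. An empty pool makes its
restricted score undefined, and it is reported as an explicit `undefined`
marker rather than 0, because 0 is a meaningful score.

### Normalization

Two denominators are supported and reported in the metrics file:

- `abs` (default): Σ|r_ijk|. The bounds ±1 are attained at perfect
  (dis)agreement *regardless of rating magnitudes* — a panel of "Probably
  relevant" hits still scores +1 if every decision agrees in sign.
- `count`: the number of rated triples (a plain mean of h·r). This reaches
  ±1 only when every rating is extreme (±1).

The two coincide on all-extreme panels, which is where the boundary
behavior (+1 / 0 / −1) is defined. Properties that hold for both: bounds,
sign antisymmetry under negating all hits or mirroring all labels, and
strict monotonicity — flipping one item's hit flag toward the sign of its
consensus raises the numerator by 2·|Σ_k r_ijk| while leaving the
denominator unchanged.

### Missing ratings

Panels in the field have dropout, so the default policy is *skip-pair*: an
unrated (item, rater) pair contributes to neither numerator nor
denominator. A *strict* mode fails on any missing rating for audits of
supposedly complete panels. Sums run over actually-present pairs, so ragged
scenarios (different item counts) and partially rated items need no fixed
N_items or N_raters.

### Numerics

All rating values are halves, so sums and scores are exact `Fraction`s;
pool assignment at the Σr = 0 boundary is never a floating-point question.
Scores are serialized with six fractional digits (round-half-even at the
last digit). Mismatch drill-down lists items with h_ij · Σ_k r_ijk < 0
sorted ascending by that contribution (worst first), ties broken
lexicographically by (scenario_id, item_id) for determinism.

## Interchange formats

The four data documents — clinical scenario, scenario family, family
ratings, strategy result set — plus the metrics report are XML with RELAX
NG schemas shipped in the package. The element names follow the field's
convention for this workflow (`<clinical_scenario>`, `<medical_record_item>`,
`<scenario_family>`, `<scenario_reference>`, `<scenario_family_ratings>`,
`<rater_data>`, `<item_rating>`, `<item_result>`); the concrete attribute
layout is this package's own dialect. Writers emit canonical UTF-8 (fixed
attribute order, two-space indentation that never touches text content), so
serialization is byte-deterministic and read∘write is the identity; tests
enforce both properties on randomized objects. Carriage returns in content
are not preserved verbatim (XML line-ending normalization); identifiers are
opaque non-empty strings, with the generator emitting version-4 UUIDs so
shared datasets cannot collide.

`days_offset` is signed — record date minus index-exam date, negative for
records predating the exam — because day-window conditions need the
before/after distinction. `record_type` is an open vocabulary (non-empty
token), not a closed list. Demographics expose age and sex plus an open
name/value attribute bag.

Strategy definitions are deliberately *not* XML: they are the artifact a
designer edits by hand in a tuning loop, so they are YAML (a commented
example lives in the README). A definition without an explicit
`strategy_id` gets one derived deterministically from its content.

## Strategy semantics

An item is a hit iff (1) its record type is in `allowed_record_types` when
that set is given, (2) its day offset lies in the closed `day_window` when
given (either bound may be null = unbounded), (3) the require-clauses are
satisfied under the clause logic — `all-required` (conjunctive, the
conservative IR default) or `any-required` — vacuously satisfied when there
are none, and (4) no forbid-clause matches. Forbid clauses exist because
clinical text is full of negated key terms ("no mass"); they always veto.
Patterns are Python/Perl-compatible regexes, case-insensitive unless a
clause opts out (clinical text is rife with casing variants, abbreviations
and synonyms; authors handle those with alternation). Clauses search the
title and text concatenated with a newline. Consequences tested as
invariants: narrowing the allowed record types and adding forbid clauses
are both monotone (they can only lose hits), and a run covers every item
exactly once, as a pure function of (strategy, family).

## Synthetic study conditions

Real rated EMR data cannot be shipped, so the generator fabricates families
with known ground truth. Defaults — the conditions used throughout the
tests and the worked example — are 5 scenarios × 4 items, planting
probability 0.5, day offsets in [−365, +30], a seven-type record
vocabulary, and a liver-MR-flavoured keyword lexicon disjoint (checked at
config time) from the distractor vocabulary. Planted items embed ≥1
lexicon keyword into template prose at a random position and draw latent
relevance uniformly from [0.75, 1]; others get distractor prose only and
latent from [0, 0.25]. The band gap leaves a margin around the default
rating thresholds (0.25, 0.5, 0.75), making the noise-free limit
analytically forced: every planted item is rated "Certainly relevant",
every other item "Irrelevant", and the planted keyword-alternation strategy
scores exactly +1 end to end.

The simulated panel (default 3 raters) rates item j as latent_j + bias_k +
noise_jk, with bias_k ~ U(rater_bias_range) (default ±0.05) modelling
optimist/sceptic raters and noise_jk ~ N(0, rater_noise_sd²) (default 0.1)
modelling per-judgment variability, cut at the three thresholds into the
four labels; (rater, item) ratings drop out with probability
`dropout_rate` (default 0). One global seed feeds separate substreams for
family, panel, and strategy material, and the JSON manifest records every
latent value, planted flag, and keyword, so it serves as the oracle for
end-to-end tests. Stochastic properties checked under these conditions
(fixed seeds): the planted strategy outscores 20 random-alternation
strategies under noise 0.1; mean S_total does not improve as rater noise
grows; and the variance of S_total across re-simulated panels does not grow
with panel size (adding raters damps individual idiosyncrasy).

What the generator does not emulate: realistic clinical language, items
whose relevance is not keyword-detectable, correlated rater errors, or
systematically missing record types. Passing tests therefore demonstrate
the correctness of the formats, engine, and metric — not that any
particular strategy generalizes to real EMR data.

## Design notes and limitations

- The tuning loop is batch-scriptable (edits supplied as a YAML list,
  re-scored after each, best-so-far kept) rather than interactive; a script
  is reproducible and testable where a GUI is not.
- Per-scenario scores apply the S_total formula within one scenario; with a
  single scenario the per-scenario score equals S_total.
- `n_raters_effective` counts distinct rater ids across the whole family;
  raters need not rate every scenario.
- Problem sizes throughout (families of ≤5 scenarios, ≤6 items, panels ≤9
  raters, ≤50 replicate panels) are desk-scale by design: every property
  the metric definition forces is already decidable there, and the exact
  rational arithmetic makes the checks sharp rather than approximate.
- No confidence intervals are computed for the scores; bootstrap over
  raters would be a natural extension. Qualitative free-text rater feedback
  is out of scope.
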