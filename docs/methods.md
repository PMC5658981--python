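# Methods

## The model

The package implements additive multi-attribute value measurement. A
decision problem is a value tree (one root, one layer of value clusters,
leaf attributes), a performance table of options × attributes, per-attribute
value functions, and a normalised weight vector. The overall value of an
option is V(a) = Σᵢ wᵢ·vᵢ(a). The additive form presumes preferential
independence between attributes — trade-offs between two criteria must not
depend on the level of a third; checking that property is part of model
structuring and outside the software's reach.

All partial value scales are *interval* scales anchored at two reference
levels per attribute: x_l ("satisfactory" performance, e.g. a
best-supportive-care benchmark) scores 0 and x_h ("best plausible")
scores 100. Anchoring at interior benchmarks rather than the scale extremes
is deliberate: options worse than the satisfactory level score negative,
which carries real information (in the packaged case study, a 21% Grade 4
adverse-event rate scores −117.9 against a 10% reference). Because the
scales are interval, only affine transformations are admissible; the
anchoring transform v′ = 100·(v − v(x_l))/(v(x_h) − v(x_l)) is the canonical
one, and anchored results are invariant to positive affine rescaling of the
unanchored scale (tested).

## MACBETH scale derivation

Qualitative difference-of-attractiveness judgments on the seven-category
ladder (no, very weak, weak, moderate, strong, very strong, extreme) are
converted to cardinal scores by linear programming. With stimuli ordered
best to worst, v(bottom) = 0 and δ = 1:

* pair judged category k ≥ 1: v(a) − v(b) ≥ k·δ;
* pairs in categories k₁ > k₂: d₁ ≥ d₂ + (k₁ − k₂)·δ;
* category-0 pairs equal;
* objective: minimise the top stimulus' score.

The published literature admits several LP variants; this one was chosen
because it is simple, reproducible, and — by affine invariance — yields the
same *anchored* scale as any other choice of δ. Intermediate unanchored
scores may differ from other MACBETH implementations. Consistency checking
is two-stage: an ordinal check (a wider span may never receive a smaller
category than a span it contains, each violating cell pair reported) and a
cardinal check (LP feasibility). Infeasibility raises an error carrying the
constraint labels. Equality constraints are implemented exactly (HiGHS
handles them natively); derived scores are rounded at 1e-9 to suppress
solver noise. `feasible_bounds` pins all other stimuli at their derived
scores and solves two further LPs for the admissible score interval of one
stimulus; an unbounded maximum is reported at a configurable ceiling
(default 1e6) rather than infinity.

Swing weighting reuses the same machinery: a judgment matrix over the
reference swings plus a mandatory fictitious null swing (bottom stimulus,
score 0) yields scores that, normalised, are the weights. The null swing is
required because ratio-scale weights need a true zero; elicitation without
it is rejected.

## Scoring

Continuous attributes use piecewise-linear interpolation between anchor
points; the anchors must include both reference levels (at 0 and 100) and
be monotone in the attribute's preference direction (weak monotonicity is
accepted, since real elicitations contain flat segments). Evaluating
outside the anchor coverage raises an error rather than extrapolating:
elicited value beyond the anchors is typically non-linear (the case study's
−117.9 at 21% is far from the −110 a linear extension would give), so
silent extrapolation would fabricate preferences. Ordinal and binary
attributes use a direct level → score lookup with no interpolation.
Decreasing-preference attributes (adverse events, costs) are stored in
natural units with direction metadata; nothing is pre-negated, so the
packaged tables read exactly as published.

## Sensitivity analysis

One-way weight thresholds use proportional renormalization — the probed
attribute takes weight w, all others are scaled by (1−w)/(1−w₀) — which is
the behaviour of the established decision-conferencing software and the
only renormalization that reproduces the published thresholds. V_A(w) −
V_B(w) is affine in w, giving the closed form documented in
`mavt/sensitivity.py`; thresholds outside [0, 1) are reported as "no
reversal", and the closed form is verified against a bisection oracle in
the tests (agreement to 1e-6). The robustness margin is the minimum of
|w* − w₀|/w₀ over adjacent-rank pairs.

The score-perturbation ("robustness") check is this package's own defined
semantics, since published descriptions of the analogous software feature
are not specific: for each attribute independently, each option's score on
that attribute is shifted by ±δ value points adversarially (all sign
combinations enumerated) and adjacent ranks are re-examined. A simultaneous
adversarial shift across all attributes at once was considered and
rejected: for any realistic δ it reverses almost any ranking (including the
packaged case study's, where the top two options sit 3.4 value points
apart against a total weight of 1), so it cannot be the semantics under
which that ranking was reported stable.

## Efficiency analysis

Costs (drug acquisition plus administration) stay outside the value model:
only attributes of benefit act as criteria, with the medical-costs
attribute capturing non-drug resource impact. Cost per value point is
total cost / V (undefined for V ≤ 0); pairwise comparison returns an ICVR
only for genuine trade-offs and a dominance verdict otherwise; the frontier
is the set of non-dominated options under (max V, min cost), checked
against an O(n²) filter in the tests. Costs are plain GBP floats: the only
arithmetic performed on them is division and subtraction of table figures,
which is exact at these magnitudes.

## The packaged mCRC case study

The fixture encodes the published appraisal of three second-line mCRC
treatments: nine attributes in four clusters (therapeutic impact: OS,
HRQoL, PFS; safety: Grade 4 AEs; innovation: ATC L4, Phase 3 indications,
marketing authorisations, posology; socioeconomic: medical costs impact),
the 3×9 performance table, baseline weights, and rounded treatment costs.

Two reconstruction choices matter:

* **Value functions.** The originally elicited functions are not in the
  public record; each packaged function carries the reference levels plus
  every option's observed (performance, partial score) pair as anchors.
  Scoring the packaged performances therefore reproduces the published
  partial scores *exactly* — this is reconstruction, not elicitation, and
  interpolating at unobserved performances uses these reconstructed
  segments. Attribute ranges are set to the anchor coverage for the same
  reason. Two published OS scores (44.4 and 48.9 at 10 and 10.4 months)
  sit slightly off the line through the neighbouring anchors (linear
  interpolation from the other anchors would give 43.7/48.3, consistent
  with performance rounding at one decimal in the source tables); the
  published scores are stored as anchors verbatim rather than guessing
  corrected performances.
* **Weights.** The precise one-decimal baseline weights are taken from the
  published sensitivity analysis, which lists eight of the nine; HRQoL is
  the residual closing the sum to exactly 100 (12.8). The coarser printed
  integer weights are available via `load_case_study(weights="printed")`
  and are what make the therapeutic-cluster total come out at exactly 47.

With these inputs the pipeline reproduces the published overall values to
within 0.11 value points (45.68/42.31/14.29 vs 45.7/42.3/14.4) and every
published sensitivity threshold to within 0.6 weight points — the residual
discrepancies are the arithmetic consequence of one-decimal rounding in
the published inputs. The published cost-per-value figures derive from the
published (rounded) overall values, so the verification harness computes
those ratios from the published values and separately checks that ratios
from the recomputed values preserve the efficiency ordering. The
18-attribute pre-workshop model ships as a documentation-only fixture (no
value functions, weights or expected outputs exist for it).

## Synthetic problems

The generator emulates the structure of a facilitated appraisal: random
attribute ranges and preference directions; latent monotone
piecewise-linear value functions with 3–6 knots; reference levels at the
range ends or strictly interior (default probability 0.5, mimicking
satisfactory-performance benchmarks); positive weights normalised to 1;
option performances uniform inside the reference interval, so true scores
stay within anchor coverage. Judgment matrices are produced by equal-width
binning of latent value differences over (0, max difference] into
categories 1–6 (ties map to category 0); any strictly monotone binning
would do, equal-width is the simplest. A corruption rate perturbs
categories by ±1 for error-path testing. All randomness flows through one
`numpy.random.Generator` seed.

What the generator does *not* emulate: group disagreement and its
facilitation, correlated attribute performances, evidence synthesis
uncertainty, and ordinal attributes (synthetic problems are all
continuous). Passing tests on synthetic problems therefore demonstrate
numerical correctness of the pipeline, not behavioural realism of
elicitation.

Problem sizes in the test suite (3–6 options, 4–12 attributes, hundreds of
seeded replicates) mirror the scale of real decision conferences, where
models of this size are built and appraised in a day.

## Known limitations

* Binned judgments constrain each latent difference only to a bin, so
  derived-scale *values* (unlike orderings, which are recovered exactly)
  are only accurate to about one bin width after anchoring; for
  pathologically clustered latent scales (many stimuli within a sliver of
  the range) the minimal-LP solution can deviate further. The recovery
  tests run on the generator's output distribution at realistic sizes.
* No interval ("weak-to-moderate") judgments; one category per cell.
* Single cluster layer; no deeper weight hierarchies.
* No probabilistic sensitivity (SMAA-style) — thresholds here are
  deterministic point analyses.
* Additive aggregation only; multiplicative/multilinear forms for
  preference-dependent attributes are out of scope.
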