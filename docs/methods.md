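# Methods

## Scope and shape

`ichtriage` re-creates, as a desk-scale and fully inspectable artifact, a
clinical pipeline of the kind used for emergency ICH triage: named-entity
extraction over narrative emergency-record text feeding a weighted rule-based
expert module. The extraction stage is deliberately a dictionary + regex
tagger rather than a neural model: the verifiable substance at this scale is
the matching, normalisation and rule logic, and the tagger contract
(`record in, mentions out`) is pluggable so a trained sequence tagger can be
substituted without changing anything downstream. The reference dialect is
English; tokenisation is whitespace/punctuation based and table-driven, so a
different-language lexicon and segmenter can be swapped in.

## Case model

Every clinical variable supports an explicit unknown state (`None`), never a
sentinel value — emergency records are lossy, and the expert module must be
able to act conservatively on missing data. GCS total/component consistency
is enforced only when both are known, because narratives often state only the
total. Age outside 10–80 years (the usual inclusion band for this
population) is a validation *warning*, not an error, since real corpora
deviate.

## Text extraction

Preprocessing lowercases, replaces non-text characters (anything outside
letters, digits and basic clinical punctuation) by spaces, collapses
whitespace, then applies token-level misspelling correction and abbreviation
expansion from the lexicon's tables. A character offset map from the cleaned
text back to the raw section is maintained throughout, including through
token substitutions (each replacement character points into the original
token's span), so mentions can always be reported against the source.

Matching is longest-match-first, left to right, with no overlapping mentions
of the same label — the standard deterministic policy for dictionary NER.
Numeric attributes are captured by named groups and normalised table-side:
volumes to mL (`ml` and `cc` are the same scale), lengths to mm (`cm` × 10),
pressures to mmHg. Negation uses a minimal clause-scope rule: a cue
(`no`, `not`, `without`, `denies`, `denied`, `absent`) anywhere in the same
clause (clauses split on `.,;`) flips negatable findings to `absent` and
removes symptom mentions. This is enough to distinguish "no midline shift"
(a known zero) from an unmentioned shift (unknown); full negation parsing is
out of scope. Assembly resolves conflicting field values by section
precedence CT report > physical exam > history > chief complaint, then by
later offset, recording every conflict as data.

## Expert module

Rules are conjunctions of field comparators (`eq ne lt le gt ge in contains
is_unknown`); unknown field values satisfy no comparator except
`is_unknown`. The score is the fired-weight sum divided by the table's total
weight, so it is always in [0, 1], reaching 0 when nothing fires and 1 only
if every rule fires. Ties at a cut-point classify into the more aggressive
plan — a deliberate clinical-safety bias. Mandate rules carry weight 0 and
short-circuit to Plan I.

The shipped default table encodes widely published surgical indications:
mandates for cerebellar hematoma ≥ 10 mL, cerebellar bleed with ventricular
cast or depressed consciousness (brainstem-compression proxy), supratentorial
hematoma ≥ 30 mL with GCS ≤ 8, bilateral fixed dilated pupils, and
anisocoria with coma (herniation proxy); weighted rules for supratentorial
volume ≥ 30 mL (3), GCS ≤ 8 (3), midline shift ≥ 5 mm (2), ventricular cast
(2), deteriorating course (2), anisocoria (2), supratentorial volume
10–30 mL (1), GCS 9–12 (1), pathological reflex (1); cut_high 0.5, cut_low
0.15. Both volume rules are restricted to supratentorial locations so the
score is monotone in volume at *every* location (an unqualified 10–30 mL
band would make the score drop when an infratentorial volume crosses
30 mL). All of this is configuration, not code; brainstem hemorrhage is
deliberately routed to weighted scoring rather than a mandate, its surgical
indication being controversial. When both GCS and hematoma volume are
unknown the decision carries an explicit "insufficient data" warning.

## Synthetic cohorts

The generator emulates the *structure* of an emergency-record corpus, not
any particular hospital's distributions. Location priors (basal ganglia 0.50,
thalamus 0.15, lobar 0.20, cerebellum 0.08, brainstem 0.05, primary IVH
0.02), location-conditional log-normal volumes (medians ≈ 18/12/25/9/4/8 mL),
and a GCS-total prior with mean ≈ 11.6 are literature-typical defaults and
configurable. Coherence constraints: consciousness grade follows the GCS
band (alert 13–15, drowsy 9–12, stupor 6–8, coma 3–5); midline shift is
positively coupled to volume for supratentorial bleeds; pupil abnormalities
become more likely as consciousness falls. Vitals come from truncated
normals; age is truncated to 10–80.

The gold standard is produced by a reference logic table evaluated on the
*true* facts — a stand-in for senior human raters. Keeping the gold table
distinct from the deployed table is a first-class experimental knob: it
produces non-trivial confusion matrices (an ~80–90% accuracy regime) without
human raters. Plan mix, when requested, is achieved by rejection sampling
against the gold table, bounded at 1000 × n draws; the largest-remainder
rule converts ratios into exact split sizes (both the 700/300 two-way and
the 6:2:2 three-way presets ship, since both designs are common).

Rendering is one sentence per fact group from a template file; with all
noise rates zero it is canonical and exactly invertible by the default
lexicon. The noise model applies, in order: abbreviation substitution,
misspellings, and symbol-run insertion, with unit variants and field dropout
decided at sentence build time. Misspellings draw from the lexicon's
correction table (undone by preprocessing) except for a configurable
fraction (default 0.35) of random character-level corruptions — real typos
are not all enumerable, and without them misspelling noise would be
informationless. Every corruption site consumes its random draws whether or
not it triggers, so under a shared seed the corrupted-site set at a lower
rate is a subset of the set at a higher rate; since corruption can only
remove recoverable information, and the rule table only loses fired rules as
information disappears, pipeline accuracy is non-increasing in each noise
rate under paired seeds by construction, not merely in expectation.

What the generator does **not** emulate: free narrative style and word-order
variation beyond the templates, co-morbidity text, contradictory findings,
anaphora, and any real-world correlation structure beyond the couplings
above. Passing tests therefore demonstrate correctness of the pipeline
mechanics and calibrated degradation under controlled corruption — not
performance on real clinical text.

One rendering subtlety: midline laterality (brainstem, primary IVH) is
implicit in the location phrase and never worded as "midline", because that
token would collide with the midline-shift patterns; the round-trip oracle
compares the fields a rendering actually encodes
(`synthetic.recoverable_fields`).

## Evaluation

Plan I (emergency surgery) is the positive class of the coarse dichotomy;
Plan IIA/IIB collapse to Plan II. Proportion CIs are Wald by default
(Wilson selectable); zero-denominator metrics are reported as undefined,
never as 0. AUC is the Mann–Whitney statistic computed from midranks (ties
½), with the threshold-sweep trapezoidal curve kept as an independent route
(the two agree to 1e-12 on random instances in the tests, alongside a
pair-enumeration brute force and scikit-learn as external oracle). Its CI is
Hanley–McNeil. κ uses the large-sample standard error
√(p_o(1−p_o)/(n(1−p_e)²)) and returns 1 outright on perfect observed
agreement, covering the degenerate single-category case. The ROC score for
a decision is the weighted score, with mandate-fired cases pinned to 1.0 so
they rank above every score-based decision; this adapter is isolated in
`evaluation.triage_score` because a deployed system might instead expose a
separate confidence output. Per-plan accuracy is the recall of each plan in
the 3×3 table.

## Reproducibility and problem sizes

A run is fully determined by its config: the single seed fans out to
per-case, per-stage child streams (SeedSequence keyed by case draw index),
so the same seed yields byte-identical outputs and the underlying facts are
identical across noise settings (paired cohorts). The test suite and the
acceptance script use cohorts of 500–2000 cases and 1000-draw property
sweeps, sizes at which every distributional check (plan-mix targets, GCS
prior mean within 3σ at 10,000 draws, noise dose-response) is already
stable; the whole suite runs in well under a minute.

## Known limitations

- The default rule table is a guideline-derived surrogate, not a validated
  clinical instrument; weights and cut-points were chosen for face validity
  and score granularity, not fitted to outcomes.
- The dictionary tagger has no robustness to unlisted surface variation
  beyond its misspelling table; that is by design (the learned tagger slot
  exists for exactly that reason).
- Negation handling is clause-local; "denies headache, nausea" negates only
  the first clause.
- CIs are classical large-sample approximations; no bootstrap or exact
  intervals.
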