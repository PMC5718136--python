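# Methods

This note documents the models and procedures implemented in `sarakit`,
the defaults and their rationale, and what the synthetic-data generator
does and does not emulate.

## The interpretation model

SARA data enter as 12 raw integer scores (4 axial items; 4 bilateral
items × 2 sides) validated against a declarative scale definition (the
shipped `sara_scale.yaml` encodes the canonical ranges: gait 0–8,
stance 0–6, sitting 0–4, speech 0–6, limb items 0–4; bilateral counted
once via the side mean, maximum total 40).  Interpretation is a staged,
deterministic rule pipeline:

1. **Calculation** — five rules: one side-mean per bilateral item,
   `mᵢ = (sᵢᴿ + sᵢᴸ)/2`, and the total
   `T = s₁+s₂+s₃+s₄+m₅+m₆+m₇+m₈`.  Rules fire as their operands become
   available, so rule order within the stage is immaterial.
2. **Severity cut-offs** — one finding per item (per side for bilateral
   items).  Published anchors are fixed: sitting 4 → severe sitting
   instability; gait 8 → abasia; stance 6 → astasia; speech 6 →
   anarthria.  The remaining bins are an even grading chosen here
   (e.g. gait 0 absent, 1–2 mild, 3–5 moderate, 6–7 severe) and are
   deliberately *data*: any replacement table can be passed as
   `cutoff_overrides`, and the builder verifies by exhaustive
   enumeration that every reachable score is covered by exactly one
   rule.  Bilateral severity rules fire on the per-side integer scores,
   not the means — side means only feed `T` — so lateralized findings
   exist for the synopsis and asymmetric syndromes are visible.
3. **Syndrome assessment** — banding of `T`: absent (T ≤ 1), mild
   (1, 10], moderate (10, 20], severe (20, 30], very severe (> 30).
   The absent threshold is aligned with healthy-control totals around
   0.4 ± 1.1; the rest is a pragmatic, non-standardized grading and is
   config-overridable.  Bands must partition [0, 40].

## The phenotype ontology and inference

Reasoning uses a scaled-down phenotype ontology: a rooted DAG of named
classes under `phenotypic_abnormality` with `is_a` edges only.  The
skeleton follows the clinical subsumptions relevant to the SARA:
truncal (midline) ataxia subsumes gait ataxia and ataxic postural
instability (itself subsuming standing and sitting instability);
appendicular ataxia subsumes limb dysmetria, intention tremor and
dysdiadochokinesis; abasia/astasia/anarthria hang under their graded
parents as terminal classes.  Severity subclasses (`moderate_dysarthria`
etc., five levels per graded class) and left/right limb variants (with
their own severity subclasses, multi-parented under both the side
variant and the plain severity class) pad the slim to 109 subclasses of
the root.  The composition beyond the named clinical classes is this
package's own reconstruction; only the subsumption skeleton and the
severity-subclass idiom are clinically fixed.

Inference is named-class subsumption only: an individual's inferred
type set is the union of asserted classes and their ancestors
(transitive `is_a` closure).  That is exactly what a DL reasoner does
on an ontology with no property restrictions, so no OWL machinery is
needed at run time; the OWL/XML import is correspondingly restricted to
asserted named-class `subClassOf` axioms (anything else is skipped and
counted).  Findings assert the most specific matching class —
`<severity>_<side>_<class>`, then `<severity>_<class>`, then
`<side>_<class>`, then the bound class — and absent findings assert
nothing.  Seed-based module extraction returns the upward closure of
the seeds, which is idempotent and yields a valid rooted sub-ontology.

## Synopsis and reporting

The synopsis aggregates findings per clinical dimension with **max**
(worst member wins): midline over gait/stance/sitting, speech over the
dysarthria finding, appendicular separately per side over the four limb
findings.  Terminal classes rank above severe in the ordinal order used
for monotonicity (absent < borderline < mild < moderate < severe <
profound/terminal) but are *reported* as "severe" in the synopsis; the
label "profound" is reserved for findings explicitly graded so.
Asymmetry is flagged when the left/right appendicular ranks differ by
≥ 2 ordinal steps (configurable; one step apart is within ordinary
rating noise).  Report rendering is a pure function of the evaluation
record: text, JSON, XML (lossless; parses back to an equal record) and
a node-link/DOT graph of the inferred closure.

## Weighted kappa

Agreement between ordinal raters uses weighted Cohen's κ with weights
`w_ij = |i−j|/(k−1)` (linear, default) or its square (quadratic), and
`κ_w = 1 − Σw_ij o_ij / Σw_ij e_ij` with `e_ij = row_i col_j / n`.
Linear is the default because it is the common choice for ordinal
severity bands; both schemes are exposed.  A table with all mass in one
cell has zero expected disagreement; it is reported as degenerate with
κ = 1 (agreement is necessarily perfect there).  Landis–Koch bands are
closed on the upper boundary (0.80 → Substantial, 0.81 → Almost
Perfect); values below 0 read Poor and 0.00 reads Slight.

## Synthetic data

The generator exists because real SARA cohorts and expert ratings are
not distributable.  It emulates:

* the three archetypal worked-example patients (exact score vectors,
  total 20 each);
* archetypal random patients: per-slot score caps express the clinical
  loading (`midline_dominant` uses only the four axial items, max
  T = 24; `appendicular_*` only limb items, max T = 16, the asymmetric
  variant keeping one side's limb-score sum strictly above the other's;
  `mixed` caps trunk items at 2 like the speech/limb-dominant worked
  examples).  A target total is drawn uniformly from the requested
  syndrome band's reachable 0.5-grid, split between axial points and
  lateral units, and partitioned exactly over the slots
  (bounded-composition sampling), so every draw validates and lands in
  band; unreachable bands raise an explicit infeasibility error;
* noisy ordinal raters: each rater reports the truth with probability
  `p`, otherwise a uniform draw from the other categories within
  `drift` ordinal steps.  With `p = 1/k` and unrestricted drift the
  output is independent of the truth, giving the κ ≈ 0 calibration
  point; `p = 1` gives κ = 1.

It does **not** emulate disease-specific score distributions,
progression, or correlated rater bias: passing tests show the machinery
is correct and calibrated, not that any clinical population looks like
the simulator.

## Numerical and design choices

* All scores are integers and means half-integers; totals are compared
  exactly (no floating tolerance is needed on the 0.5 grid).
* Randomness flows through `numpy.random.default_rng(seed)` per call;
  no global state.  Problem sizes in tests and the acceptance script
  (500-rater and 5000-rater simulations, 100–200-node random DAGs,
  100–200 generated profiles) were chosen as the smallest sizes at
  which the Monte-Carlo checks are stable.
* Ontology validation rejects cycles (naming the classes involved),
  dangling parents, and classes that do not reach the root.
* The OBO flat-file subset (id/name/is_a/property_value) is the native,
  lossless serialization; severity/laterality ride in `property_value`
  lines.  OWL export/import carries the `is_a` skeleton only.
* CSV ingestion collects *all* row-level problems with line and column
  before failing, rather than stopping at the first.

## Known limitations

* Cut-off bins between the published anchors and the syndrome banding
  are this package's defaults, not a validated standard; studies should
  supply their own tables via config where one exists.
* The ontology slim's padding classes (lateral severity variants,
  syndrome severity subclasses) are a reconstruction; identifiers are
  package-local, not standard ontology IRIs.
* Weighted-κ confidence intervals and >2-rater designs (Fleiss) are out
  of scope.
* The evaluation XML schema is package-local, aimed at lossless
  round-tripping rather than any EHR standard.
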