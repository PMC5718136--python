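# sarakit

Ontology-aware interpretation of the **Scale for the Assessment and
Rating of Ataxia (SARA)**.

The SARA rates cerebellar ataxia through 8 motor items — gait (0–8),
stance (0–6), sitting (0–4), speech disturbance (0–6), and four
limb-coordination tests scored 0–4 once per side (finger chase,
nose–finger, fast alternating hand movements, heel–shin).  Side scores
of the bilateral items are averaged, and the four means added to the
four axial scores give a total *T* ∈ [0, 40]:

    T = s₁ + s₂ + s₃ + s₄ + m₅ + m₆ + m₇ + m₈,   mᵢ = (sᵢᴿ + sᵢᴸ)/2

A single total hides clinically decisive structure: patients with the
same *T* can have midline (truncal) ataxia, severe dysarthria, or a
strongly lateralized limb syndrome.  `sarakit` recovers that structure
automatically.  It is aimed at neurologists and clinical-research
engineers who collect SARA scores and want standardized, machine- and
human-readable interpretations rather than a bare number.

## What it does

1. **Derived scores** — a declarative calculation stage computes the
   four bilateral means and *T* (five rules).
2. **Per-item severity grading** — cut-off rules translate every raw
   score into a graded finding (an ontology class plus a level from
   *absent, mild, moderate, severe*), per side for the bilateral items.
   Maximal scores map to terminal classes: gait 8 → *abasia*, stance 6
   → *astasia*, speech 6 → *anarthria*.  Cut-off tables are data and
   can be replaced from config.
3. **Cerebellar-syndrome assessment** — banding of *T* into
   *absent / mild / moderate / severe / very severe* (absent at T ≤ 1,
   consistent with healthy-control totals around 0.4 ± 1.1).
4. **Phenotype synopsis** — findings are asserted as individuals of a
   scaled-down phenotype ontology (109 subclasses of *phenotypic
   abnormality*, shipped as OBO) and closed under `is_a` subsumption:
   severe standing + sitting instability entails *ataxic postural
   instability* and hence *truncal ataxia*; any lateral limb finding
   entails *appendicular ataxia*.  A per-dimension synopsis (midline,
   speech, appendicular left/right, asymmetry flag) and a textual
   report with JSON/XML/DOT exports are rendered deterministically.
5. **Validation harness** — weighted Cohen's κ (linear or quadratic
   weights) with Landis–Koch interpretation, plus a seeded simulator of
   noisy ordinal raters and archetypal synthetic patients.

## Worked example

```python
from sarakit import (default_scale, load_sara_ontology,
                     build_sara_rulebase, run_pipeline, table1_patients)

scale = default_scale()
ont = load_sara_ontology()
rb = build_sara_rulebase(scale)

p1, p2, p3 = table1_patients()   # three patients, all with T = 20
record = run_pipeline(scale, rb, ont, p3)
print(record.derived.total)              # 20.0
print(record.assessment.category)        # moderate
for f in record.synopsis.features:
    print(f.name, f.laterality, f.severity)
print(record.synopsis.asymmetry)
```

prints

```
20.0
moderate
midline_ataxia None mild
speech_impairment None severe
appendicular_ataxia right mild
appendicular_ataxia left severe
True
```

— patient 3 totals the same 20 points as the others, but the pipeline
exposes anarthric speech and a marked right/left asymmetry of limb
coordination (mild vs. severe), which the total alone cannot show.
The same run from the shell:

```bash
sara interpret observations.csv --out reports/ --formats text,json,xml
sara kappa ratings.csv --scheme linear
sara simulate --what observations --archetype appendicular_asymmetric \
     --band moderate --n 20 --seed 1 --out observations.csv
sara extract-module src/sarakit/data/sara_phenotype.obo abasia --out module.obo
```

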