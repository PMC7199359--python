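# Methods

## The index

GlucoTRIG scores a meal challenge as the difference of two
insulin × triglyceride products:

GlucoTRIG = TG₁₈₀·INS₁₈₀ − TG₀·INS₀,  insulin in pmol/L, TG in mmol/L.

The multiplication combines two interdependent analytes that share a
per-litre base into a single factorial value; the difference removes the
fasting level, so only the joint postprandial excursion is scored. The
method is deliberately a **two-fixed-draw difference, not an AUC**: samples
must sit exactly at the configured times (default 0 and 180 min) and are
never interpolated. 180 min is chosen because insulin has normally returned
to the fasting range by then while triglycerides are near their peak, so
joint elevation at that point marks a persistently unhealthy response.
Negative values are retained (the postprandial product can fall below the
fasting product); glucose is carried through the data model as a side
outcome but never enters the index. Test meals are normalised as
`test / reference`; normalisation is rejected for a zero reference value.

Unit conventions: all computation happens after canonicalisation. The
insulin mU/L→pmol/L factor defaults to the standard clinical-chemistry
constant 6.945 and is overridable, because published cohort tables are not
always consistent — one can find the same fasting insulin printed as
6.1 mU/L and 44.1 pmol/L, implying ≈7.23. We do not guess which assay
convention produced such numbers; the constant is configuration. The
triglyceride (÷88.5) and glucose (÷18.0) mg/dL divisors are the usual
molar-mass constants. Because the index is bilinear, a cohort supplied in
mU/L yields index values exactly `factor ×` those of the same cohort in
pmol/L — this is a tested invariant, and it also means the *numerical*
index scale depends on the insulin unit; we fix pmol/L as canonical.

## Meal energy accounting

Total energy = Σ grams × factor over carbohydrate, fat, protein and
dietary fibre, with FSANZ-style metabolisable-energy factors
17/37/17/8 kJ/g by default. Fibre is included in the total (it is a
genuine, if small, energy contributor and is needed for a non-zero fibre
% energy entry). Percent energy is reported unrounded and with
nearest-integer rounding (ties away from zero, the label convention).
For the bundled reference meal (50 g CHO, 22 g fat, 19 g protein, 6 g
fibre) this gives 2035 kJ with fat 40.0 %, protein 15.87 %, fibre 2.36 %
and carbohydrate 41.77 %. Note the carbohydrate entry rounds to 42 while
nutrition panels for this meal conventionally print 41; available-
carbohydrate factors or a different rounding path would explain a 41, but
since the factors behind such labels are unstated we report the computed
value and do not force agreement. Sub-class gram fields (sugar/starch,
fat fractions) are validated against their parents with a 0.5 g tolerance
for label rounding but never enter the energy computation.

## Cohort statistics

- **Summaries**: mean ± SEM with the sample (n−1) standard deviation;
  SEM = sd/√n. CV = 100·sd/|mean|, undefined at mean 0.
- **Outlier rule**: single-pass mean ± 2 SD. Bounds are computed once from
  *all* input values and never recomputed after exclusion; the rule is
  applied to per-subject mean index values (one value per subject), the
  reading under which excluding a small number of aberrant subjects from a
  cohort makes sense. A manual exclusion list (e.g. abnormal pathology)
  is supported alongside the rule.
- **Between-visit CV** is defined over the k visit-level means:
  100·sd(visit means)/mean(visit means). This is a repeatability measure
  of the cohort-level index and is the only definition under which a CV of
  order 1 % can coexist with a between-subject SEM of order 20 % of the
  mean; a CV over raw per-visit values would conflate subject variance
  with visit variance. The denominator population of a "between-visit CV"
  is otherwise ambiguous, so the choice is documented here.
- **Repeated-measures ANOVA**: standard within-subject decomposition
  SS_total = SS_subjects + SS_conditions + SS_error, F = MS_cond/MS_error
  with df (k−1), (k−1)(n−1). No sphericity correction is applied — a known
  limitation; with k = 3 visits the Greenhouse–Geisser adjustment would be
  mild but non-zero. Post hoc: all k(k−1)/2 paired t-tests with Bonferroni
  correction min(1, p·n_pairs). Missing cells are rejected rather than
  imputed. Degenerate inputs are flagged, not silently passed: MS_error = 0
  yields F = +∞, p = 0 (non-zero condition effect) or F = 0, p = 1 (fully
  constant matrix), with `degenerate=True` and CLI exit code 3.
  The implementation is cross-checked in the tests against both an
  explicit-loop sums-of-squares oracle (1e-10 agreement) and statsmodels'
  AnovaRM, and against the F = t² identity at k = 2.

## Activity scoring

IPAQ-style MET-min/week = days × min/day × MET with multipliers 3.3
(walking), 4.0 (moderate), 8.0 (vigorous) from the official long-form
scoring protocol. Categories, evaluated high-first: **high** = ≥3 vigorous
days with total ≥1500 MET-min, or ≥7 activity days (summed across
intensities) with total ≥3000; **moderate** = ≥3 vigorous days of ≥20
min/day, or ≥5 days of moderate activity and/or walking of ≥30 min/day,
or ≥5 activity days with total ≥600 MET-min; **low** otherwise. Study
descriptions often abbreviate the moderate criterion to its last two
clauses; we implement the full three-clause rule. Official day-capping and
truncation rules (e.g. 180 min/day) are out of scope. The classifier is
monotone: more minutes or days never lowers the category (property-tested).

## The synthetic cohort generator

The generator emulates a small healthy-adult crossover study: each subject
receives the same meal on `n_visits` days, with subject-level fasting
physiology held fixed across visits.

Model, per subject s and visit v (all concentrations floored at 0):

- fasting levels: INS₀ˢ, TG₀ˢ, GLU₀ˢ ~ zero-truncated normals with
  between-subject moments (44.1, 13.91) pmol/L, (0.8, 0.316) mmol/L,
  (4.4, 0.443) mmol/L — healthy-adult fasting means, with sds
  reconstructed from cohort SEMs as sd = SEM·√10 for a 10-subject study
  (SEMs 4.4, 0.1, 0.14);
- visit re-measurement: subject value + N(0, σ_visit), σ_visit = 3 pmol/L
  insulin, 0.05 mmol/L TG, 0.1 mmol/L glucose (assay + day-to-day noise,
  small relative to between-subject spread);
- meal response at 180 min: INS₁₈₀ = INS₀·f·ε with fold f = 1.3 and
  unit-mean lognormal ε (σ = 0.2; multiplicative noise keeps insulin
  positive); TG₁₈₀ = TG₀ + r + N(0, 0.1) with rise r = 0.15 mmol/L
  (additive, floored at 0); glucose returns to baseline in expectation
  (change 0, sd 0.3 mmol/L).

**The response parameters are calibration constants, not estimates**: no
per-subject 180-min data are published for the reference meal, so f and r
were fixed once such that the analytic expected index,

E[GlucoTRIG] = μ_T·μ_I·(f−1) + f·r·μ_I ≈ 19.3,

is positive and of order 10¹, matching the scale reported for a reference
mixed meal (19 ± 3.5). μ_I, μ_T are the truncation-corrected subject-level
means; the closed form neglects the flooring of noisy visit values at 0,
which sits ≥2.5 sd below every default mean. This expectation is the
oracle for the parameter-recovery tests (5000 subjects, agreement within
3 Monte-Carlo standard errors, <1 min on one CPU).

What the generator does **not** emulate: correlation between insulin and
triglyceride levels across subjects (drawn independently), insulin
resistance spectra, sex differences, and — importantly — the remarkably
low between-visit variation of a real supervised crossover study. The
generator's visit means at n = 10 fluctuate with full sampling noise, so
its between-visit CV is tens of percent, far above the ~1 % a tightly
controlled cohort can show; passing tests therefore demonstrate pipeline
correctness and calibration consistency, not that the simulator reproduces
real-data repeatability. A `dense_trajectory` mode exists for plotting
only: a gamma-shaped insulin excursion peaking at 30–60 min and a
saturating TG rise still increasing at 180 min (peak ~210 min). The curve
family is our invention; the index never uses it.

Determinism: one `numpy` Generator seeded from the config; identical
configs give bitwise-identical cohorts.

## Pipeline and I/O choices

Long CSV (subject_id, visit, time_min, analyte, value, unit) is canonical;
a wide variant is accepted with units taken from the run configuration.
Reads use exact (`round_trip`) float parsing so write→read→write is
bit-identical for canonical-unit files. Rows at non-configured times are
retained but flagged unused. Duplicate keys, unknown units and missing
required time points are rejected with the offending rows named. The
pipeline reports per-visit summaries, the grand value (mean of per-subject
means — identical to the overall mean in a balanced design), between-visit
CV, the rmANOVA, exclusions with reasons, the relative value against the
configured reference index (default 19), and a config hash for logging.
Exit codes: 0 success, 2 validation failure, 3 statistical degeneracy.

## Problem sizes

Defaults keep everything fast and deterministic: the study-scale
simulation is 10 subjects × 3 visits; law-of-large-numbers checks use
2000 subjects and parameter-recovery checks 5000 × 1–2 visits, sizes at
which Monte-Carlo error is a few percent of the index scale while the
whole suite runs in seconds.
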