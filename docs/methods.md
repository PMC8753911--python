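# Methods

## The model

`cmatree` implements a cost-minimisation analysis (CMA) on a decision tree.
A CMA is valid only when the compared strategies are clinically equivalent;
it then reduces the choice to expected cost. The built-in case study
compares two strategies for managing vaginal bleeding in early pregnancy in
Danish general practice:

- **usual practice** — the GP refers every patient, 23% to a private
  gynaecologist and 77% directly to a hospital gynaecology department; a
  gynaecologist completes 92% of referred patients and passes 8% on to the
  hospital;
- **intervention** — the GP performs point-of-care ultrasound and completes
  73% of patients; the referred 27% split 16%/84% between gynaecologist and
  hospital, with the same 92%/8% onward split.

The tree is rooted at a decision node; chance-node branches reference named
probability parameters; terminal nodes record the completion location.
Costs accrue **on branches**, not only at terminals, so a referral path
accumulates the GP visit's costs plus each downstream visit's costs. The
expected cost of a strategy is computed by roll-back (value of a node =
cost accrued entering it + Σ branch-probability × child value) and is
required to agree with an exhaustive path-enumeration oracle to 1e-9. All
arithmetic is full floating precision; rounding to whole euros happens only
in reporting, because the headline figures (€235, €125, €110, €78, €32)
are rounded presentation of full-precision values (234.683, 125.286,
−109.397, −77.781, 31.978). The headline incremental saving is reported as
the difference of the two *rounded* averages (235 − 125 = 110); the
full-precision incremental (−109.40) is always reported alongside it.

The engine supports n-ary chance nodes; validation enforces that branch
probabilities sum to 1 within 1e-9, that the graph is a rooted tree with
terminal leaves, and that every probability and cost reference resolves.
Alternatives keep declaration order; the incremental cost is the
last-declared alternative minus the first (the comparator).

## Costing

Every cost component is `quantity × unit_price` (2019 €), tagged with a
location (GP, private gynaecologist, hospital) and a bearer (healthcare
sector or patient). The **societal** perspective counts everything; the
**healthcare-sector** perspective keeps only healthcare-borne components,
dropping patient time (€0.408/min of lost earnings) and transport
(€0.473/km mileage, €0.408/min travel time). Societal cost decomposes
exactly as healthcare + patient-borne cost.

Capital items are annuitised to an equivalent annual cost: per-use cost =
`capital × use_fraction / AF(r, L) / annual_uses` with annuity factor
`AF(r, L) = (1 − (1+r)^−L)/r` (continuity limit `L` at r = 0). Defaults in
the case study: 7-year lifespan, 4% interest, 2.4 scans per GP per year.
The €2,008 training course is apportioned to 1/24 (six course categories ×
four subcategories) before annuitisation, giving €5.81 per scan; the
€15,508.70 scanner's indication share is not published, so the fixture
stores the published €7.54 per-scan cost directly and exposes
`use_fraction` for generic use (back-solving gives ≈0.70%). Transport
times are stored as the published rounded minutes (11/47/47) rather than
re-derived from the 50 km/h rule (which gives 11.4/47.04), because the
published per-visit products use the rounded values.

The GP's per-scan remuneration is the sum of the six intervention add-on
components (10 min scanning time €18.07, scanner €7.54, training €5.81,
wet wipes €0.108, transducer cover €0.24, gel €0.21 → €31.98 ≈ €32); by
construction it equals the GP-visit healthcare add-on in the intervention
arm, and a test asserts that equality.

## Sensitivity analysis

**One-way DSA.** Each parameter is set to the ends of its plausible range
with everything else at base, and the societal incremental cost recorded.
For a probability, its complement-group partner is co-varied
(`partner = 1 − value`, clamped at 0) so the chance node keeps summing
to 1; whether to co-vary or renormalise siblings was an open choice and
co-variation was adopted as the natural reading for binary nodes. Ranges
stated in resource-use units (minutes, km) are stored as per-visit € ranges
at the fixed unit price. The three consumables are varied jointly as one
"utensils" bundle (base €0.558, range €0.34–0.56), scaling members
proportionally, since their uncertainty was elicited as a single bundle
range. The tornado ranks entries by swing |ΔC(high) − ΔC(low)|,
descending, emitting one bar per complement group (both members are the
same axis; the first-declared member — completion-at-GP for the
intervention group — keys the bar). Because the incremental cost is affine
in every per-visit cost, the midpoint response equals the mean of the
endpoint responses, which the tests verify.

**Scenario.** Re-evaluation under the healthcare-sector perspective
(patient-borne components excluded): saving €78 per patient.

**PSA.** Second-order Monte Carlo, default 10,000 draws. The published
analysis names the distribution families (beta for probabilities, gamma
for costs) but not their parameterisation, so method of moments anchored
at the base value with sd = (range width)/4 is used — the stated range
read as roughly a ±2 sd interval — which uses only published numbers and
preserves the base-case mean, keeping the PSA mean consistent with the
deterministic result (the model is multilinear in independent parameters).
Beta: α = m(m(1−m)/v − 1), β = α(1−m)/m, with an error prescribing a
narrower range when v ≥ m(1−m). Gamma: shape = m²/v, scale = v/m.
Zero-width ranges become point masses. Exactly one member per complement
group is sampled, the partner set to its complement; other parameters are
independent (no correlation structure was published). The three unit costs
held fixed in the reference analysis (mileage, GP scanning time, patient
time) are excluded structurally: the sampled quantities are per-visit
component costs whose ranges derive from resource-use variation at fixed
unit prices, and the GP scanning-time cost, which has no published range,
stays at base. `PsaConfig.excluded_ids` can pin any further axis. Sampling
uses `numpy.random.default_rng(seed)` with a fixed parameter order, so
identical configurations are bitwise-reproducible.

## Synthetic data

`simulate_gp_responses` emulates the questionnaire that produced the
referral probabilities: n independent beta-distributed per-GP probability
estimates with a requested mean and standard deviation (beta keeps the
moments controllable; any distribution on [0,1] would serve). The default
panel size used in tests is 21, the number of ultrasound-using responders
in the original survey, with sd 0.15 — a realistic spread given the
published min–max range 0.40–0.98 for the completion probability.
`aggregate_questionnaire` reproduces the published aggregation: arithmetic
mean per question, range = [min, max] response. What the synthetic panel
does **not** emulate: correlation between a GP's answers to related
questions, non-response, anchoring to round numbers, and the clustering of
experience levels — so passing recovery tests shows the aggregation is
correct, not that a 21-GP convenience sample estimates referral behaviour
accurately.

`random_model` generates arbitrary valid trees (Dirichlet-normalised
chance nodes, random non-negative component costs with random
location/bearer tags) for property tests: roll-back vs enumeration
equivalence, probability conservation, and price linearity hold on 200
seeded models per run.

## Numerical and design choices

- Probability sum tolerance 1e-9 at chance nodes and for complement groups.
- Complement groups are binary by definition; n-ary chance nodes use free
  parameters that must sum to 1.
- A one-way endpoint of 1.0 annihilates the sibling branch (complement
  clamped to 0); this is allowed for the published [0, 1] ranges.
- The utensil bundle's base (0.558) sits inside its elicited range
  (0.34–0.56) only because of rounding in the range's upper end; the base,
  not the range midpoint, anchors the PSA mean.
- Monetary output precision: full precision in JSON, two decimals in CSV,
  whole euros in the human summary. CSV fields are formatted explicitly so
  identical runs are byte-identical.
- YAML was chosen as the single configuration dialect; the reader rejects
  unknown keys with their path and runs full structural validation before
  returning a model.

## Problem sizes

The default test suite evaluates the case-study tree (7 paths), 200 random
models for the property suite, and PSAs of 10,000 draws (the analysis'
published simulation count); a full 10,000-draw PSA takes well under a
second. The acceptance script's figures are deterministic roll-back
results and involve no simulation.

## Limitations

- The case study is early-stage modelling on expert elicitation; the
  package reproduces its arithmetic, not its evidential weight.
- No discounting (the episode spans days), no QALYs or cost-effectiveness
  ratios — a CMA compares costs only; Markov/state-transition models are
  out of scope.
- DSA/PSA treat per-visit costs as the uncertain quantities; joint
  variation of transport time with distance is available in principle by
  editing ranges but is off by default (the published analysis lists them
  as separate parameters).
- Beta/gamma parameterisation is this package's choice; other spreads
  (e.g. range as a 95% interval of the fitted distribution) would widen or
  narrow the PSA without moving its mean.
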