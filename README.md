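# cmatree

Decision-tree **cost-minimisation analysis** (CMA) for health-economic
comparisons, built around a fully worked case study: point-of-care
ultrasonography (POCUS) performed by general practitioners (GPs) on women
with vaginal bleeding in early pregnancy, versus usual practice where every
patient is referred to a private gynaecologist or a hospital gynaecology
department.

A CMA assumes the compared strategies are clinically equivalent and ranks
them by expected cost alone. The model here is a rooted decision tree: a
decision node with one branch per strategy, chance nodes for the pattern of
referral, and terminal nodes labelled with the location where management
completes. Costs accrue on branches along each path (a referral path pays
the GP visit *and* the specialist visit), and the expected per-patient cost
of strategy *a* is the probability-weighted sum over its paths,

```
E[C_a] = Σ_paths ( Π_branches p_b ) × ( Σ_branches c_b )
```

computed by bottom-up roll-back and cross-checked against an independent
path-enumeration oracle. The incremental cost ΔC = E[C_intervention] −
E[C_usual]; negative values are savings. The package provides:

- **model core** — tree types, structural validation, roll-back,
  path enumeration, incremental cost;
- **costing** — components tagged by location and bearer (healthcare sector
  vs patient), societal/healthcare perspective filtering, equivalent annual
  cost for capital items (annuity factor `(1 − (1+r)^−L)/r`), and the GP's
  per-scan remuneration composition;
- **sensitivity** — one-way deterministic analyses with tornado ranking
  (complement probabilities co-varied so chance nodes keep summing to 1),
  a healthcare-perspective scenario, and a seeded probabilistic sensitivity
  analysis with method-of-moments beta (probabilities) and gamma (costs)
  distributions;
- **fixture** — the built-in case-study model plus synthetic generators
  (random valid trees; simulated GP questionnaire panels);
- **io / CLI** — a YAML model-configuration format with round-trip
  emission, CSV/JSON reports, and a `cmatree` command-line tool.

## Worked example

All headline numbers come from the built-in model; no input files needed.

```
$ cmatree evaluate --paper --out out/ --quiet
Perspective: societal
  usual_practice: EUR 235 per patient (234.68)
  intervention: EUR 125 per patient (125.29)
  incremental (full precision): EUR -109.40
  cost-saving of the intervention: EUR 110 per patient (difference of rounded averages)
```

Referring every patient out costs €235 per patient on average; letting the
GP scan costs €125, a societal saving of €110 per patient. The same from
Python:

```python
import cmatree as ct

model = ct.build_paper_model()
result = ct.evaluate(model, "societal")   # EvaluationResult
print(result.expected_cost_by_alternative, result.incremental)
# {'usual_practice': 234.68276784, 'intervention': 125.2856017856} -109.3972
```

The proposed per-scan fee covering the GP's add-on costs (scanning time,
scanner and training depreciation, consumables):

```
$ cmatree remunerate --paper --out out/ --quiet
  gp_scan_time: EUR 18.07
  scanner: EUR 7.54
  ceclus_training: EUR 5.81
  wet_wipes: EUR 0.11
  transducer_cover: EUR 0.24
  gel: EUR 0.21
  total: EUR 31.98
```

Robustness:

```
$ cmatree tornado --paper --out out/ --quiet
most influential parameter: p_pocus_complete_gp (swing EUR 118.38)

$ cmatree psa --paper --n-draws 10000 --seed 1 --out out/ --quiet
mean incremental EUR -109.56 (95% CI -170.41 to -36.20); cost-saving in 99.8% of draws

$ cmatree scenario --paper --out out/ --quiet   # healthcare-sector perspective
  ...
  cost-saving of the intervention: EUR 78 per patient (difference of rounded averages)
```

The probability that the GP completes management (base 0.73, range
0.40–0.98) dominates the uncertainty, but the intervention stays
cost-saving at every one-way endpoint, in 99.8% of Monte Carlo draws, and
after dropping all patient-borne time and transport costs (€78 saving).

User-defined models are YAML files with the same structure the fixture
emits (`cmatree emit-config --paper --out out/` writes the reference
configuration).

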