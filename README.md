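# fittree

Cost-sensitive, gain-ratio decision trees for physical-fitness test data,
bundled with the national BMI band scoring standard, a seeded synthetic
student-cohort generator, and cost-stratified error-rate reports.

## What it does

- **`fittree.criterion`** — entropy, conditional entropy, information gain,
  split information and gain ratio (all in bits), plus misclassification-cost
  class weights `w(i) = C(i)·n / Σ C(k)·n_k` (where `C(i)` is the row sum of
  the cost matrix) and the weight-adjusted class probabilities that make the
  criterion cost-sensitive. Uniform off-diagonal costs reduce exactly to the
  standard criterion.
- **`fittree.induction`** — recursive C4.5-style tree growth: boundary-point
  midpoint thresholds for continuous attributes, one branch per observed
  value for categorical ones, gain-ratio split selection with deterministic
  tie-breaking, optional cost weighting, JSON serialization with a versioned
  schema, and routing-based prediction (`value <= threshold` goes left).
- **`fittree.scoring`** — (grade, gender)-keyed BMI band tables at
  one-decimal resolution with a shipped default standard (freshman/
  sophomore/junior males, senior females; bands low weight / normal /
  overweight / obesity scoring 80/100/80/60). Other indices (e.g. vital
  capacity) are supported via user-supplied band configs.
- **`fittree.cohort`** — reproducible synthetic cohorts: grade × gender ×
  tested strata via a multinomial, truncated-normal BMI per stratum, labels
  from a chosen band standard with optional noise. Same seed + config gives
  a byte-identical CSV.
- **`fittree.evaluation`** — confusion matrices, total and high/general/
  low-cost error rates (records stratified by their true class's row-sum
  cost), model-to-model "error value" deltas, and a two-arm comparison
  (standard vs cost-weighted tree) over a seeded stratified split.

## CLI

```sh
fittree generate --n 1000 --seed 7 --noise-rate 0.1 --out cohort.csv
fittree score    --input cohort.csv --out scored.csv
fittree train    --input cohort.csv --attribute bmi:continuous \
                 --attribute gender:categorical --out tree.json
fittree evaluate --tree tree.json --input cohort.csv --out report.json
fittree compare  --input cohort.csv --cost-config costs.yaml \
                 --attribute bmi:continuous --seed 7 --out comparison.csv
```

Cost configs are YAML/JSON mappings `{true_class: {predicted_class: cost}}`;
omitted cells default to 1 off the diagonal and 0 on it (which reproduces
the standard, cost-blind criterion). Scoring standards are YAML/JSON band
tables; see `fittree.scoring.load_scoring_standard` for the layout.

## Python API sketch

```python
import fittree as ft

config = ft.CohortConfig(n=2000, seed=11, noise_rate=0.0)
frame = ft.generate_cohort(config)
ds = ft.as_dataset(frame, attributes={"bmi": "continuous"})

costs = ft.CostMatrix.from_mapping(
    {"obesity": {"normal": 8, "overweight": 8, "low weight": 8}},
    labels=ds.classes,
)
comparison = ft.compare_models(ds, costs, seed=7)
print(comparison.to_text())
```
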