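# gaitsep

Discriminating runner sub-populations (gender, and gender within age bands)
from bilateral lower-extremity stance kinematics.

Running injury risk differs markedly between female and male runners, and
kinematic differences between the groups are spread across many joints and
planes rather than concentrated in a single discrete angle. `gaitsep`
implements the full analysis chain for studying this as a classification
problem:

1. **Gait events** — initial contact from the calcaneal marker's vertical
   velocity (positive-to-negative crossing), toe-off at peak knee extension;
   each stance phase resampled to 101 points.
2. **Discrete features** — per channel (2 sides × 3 joints × 3 planes), the
   angle at touchdown, maximum peak, minimum peak and angle at toe-off:
   a 72-variable table per cohort.
3. **PCA** — standardize columns (X → Z), eigendecompose the correlation
   matrix (Z gives V, L), scores Z·V; with n subjects, min(72, n−1)
   components.
4. **PC ranking** — classically by variance explained; alternatively by the
   between-group effect size of each score column, Hedges's
   g = (x̄_f − x̄_m)/s_pooled with small-sample correction
   J = 1 − 3/(4N − 9), ranked by |g|.
5. **Classification** — linear soft-margin SVM (c = 1), ten-fold
   cross-validation, accuracy evaluated at every prefix of each ranking.
6. **Statistics** — per-variable pooled t-tests with Holm step-down
   adjustment (family-wise α = 0.05) and PC–variable Pearson correlations
   with moderate (|r| ≥ 0.36) / strong (|r| > 0.67) categories.

No subject-level dataset accompanies the published group statistics, so the
package ships a calibrated synthetic-cohort generator: packaged fixtures
transcribe the published per-gender means/SDs and demographics (220 male /
263 female overall; 16/40 aged 18–26; 34/17 aged 55–72), and a stride-level
simulator plants gait events that are exactly recoverable by the detection
definitions. Everything downstream is testable end to end without any
download.

## Worked example

```python
from gaitsep import (
    CovariancePCA, accuracy_curve, generate_feature_cohort,
    load_cohort_fixture, rank_by_effect_size, rank_by_variance,
)

spec = load_cohort_fixture("general")          # 483 subjects, 72 variables
table = generate_feature_cohort(spec, seed=1)
y = table["gender"].to_numpy()

pca = CovariancePCA().fit(table[list(spec.variables)])
for ranking in (rank_by_variance(pca), rank_by_effect_size(pca, y)):
    curve = accuracy_curve(pca, ranking, y, seed=2)
    print(f"{ranking.mode:>12}: {curve.max_accuracy:.2%} at k={curve.argmax_k}")
```

```
    variance: 84.27% at k=50
 effect_size: 86.96% at k=26
```

Sorting PCs by effect size reaches a higher cross-validated accuracy with
roughly half the components: variance-ordered PCs describe how runners vary,
not how the groups differ, so the discriminative components enter the
feature vector late under the classical ordering. On this synthetic cohort
the top-|g| PC is low-order (the generator concentrates the printed group
contrast); on real data the discriminative PCs sit deeper in the spectrum,
which is exactly when the effect-size sort pays off most.

The same analysis over all three groups, with serialized reports, rankings,
curves and statistics tables:

```bash
gaitsep run --source general --outdir results/ --cohort-seed 1 --fold-seed 2
```

Each stage is also exposed individually (`gaitsep simulate cohort`,
`gaitsep events detect`, `gaitsep features extract`, `gaitsep pca fit`,
`gaitsep rank`, `gaitsep classify`, `gaitsep stats compare` …); see
`gaitsep --help`.

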