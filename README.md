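# ctpipe

A five-stage analysis pipeline for RT-qPCR Ct/Cq expression data:

1. **Parse** per-sample tab-separated Ct reports (SDS, EDS, OpenArray,
   LightCycler, CFX, BioMark or Plain dialects) plus a two-column
   `SampleName`/`Treatment` file with exactly two groups. The group of the
   first listed sample is the *calibrator*, the other the *target*.
2. **Categorize** every Ct value as `OK`, `Unreliable` (outside a user Ct
   range) or `Undetermined` (missing sentinel or failed quality flag), then
   mask non-OK values as missing.
3. **Normalize** with one of six methods: global mean, modified global mean
   (common-detected set / geometric mean), deltaCt (explicit housekeepers or
   geNorm / NormFinder selection), quantile, norm rank invariant, scale rank
   invariant. The rank-invariant methods spline-fill missing values
   internally and restore them afterwards.
4. **Filter and impute**: drop features above a missing-percentage threshold
   or on an explicit removal list; impute the rest by KNN, Mestdagh
   (feature max + 1 cycle) or cubic spline.
5. **Differential expression** between the two groups by t-test (Welch,
   pooled or paired), Wilcoxon, or the rank product permutation test, with
   multiple-testing adjustment, ddCt (`mean_target − mean_calibrator`), fold
   change `FC = 2^−ddCt`, group means and per-group reliability categories.

A run produces exactly seven outputs: the raw Ct table, pre-normalization
boxplots, the normalized table, the CV-ECDF comparison with a
Kolmogorov–Smirnov p-value, post-normalization boxplots, the imputed table
and the differential-expression table — plus a run log and a JSON manifest.

## CLI

```bash
# list supported input dialects
ctpipe formats

# generate a synthetic dataset (Plain files + treatment TSV + truth JSON)
ctpipe simulate --out demo --seed 1 --features 384 --per-group 8 8 --spiked 20

# run the pipeline
ctpipe run --input-dir demo --treatment demo/treatment.tsv --out demo_results \
    --normalization globalmean --max-missing 40 --imputation knn --knn-k 10 \
    --de ttest --adjust BH --seed 1

# or drive everything from YAML (CLI flags override the file)
ctpipe run --config analysis.yaml
```

Exit codes: `0` success, `2` configuration error, `3` stage failure (partial
outputs up to the failed stage are kept and listed).

Example YAML:

```yaml
input_dir: demo
treatment: demo/treatment.tsv
out: demo_results
dialect: Plain
category: {ct_min: 10, ct_max: 35, use_flags: true}
normalization: {method: deltact, hk_selector: genorm, genorm_cutoff: 1.5}
filter: {max_missing: 30}
imputation: {method: knn, k: 10}
de: {method: ttest, adjust: BH, stringent: true}
seed: 1
```

## Library use

```python
from ctpipe import (parse_ct_file, parse_treatment_file, assemble_dataset,
                    CategorySettings, assign_categories, mask_unreliable,
                    NormalizationSpec, apply_normalization,
                    FilterSpec, ImputeSpec, filter_features, apply_imputation,
                    DESpec, run_diffexp)
```

Each stage takes and returns an immutable-by-convention `CtDataset`
(features × samples Ct matrix with NaN missing values, flags and categories).

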