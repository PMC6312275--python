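# clonecast

Multifactorial prediction of post-immunotherapy T-cell clonal expansion
from pre-treatment patient data.

## The problem

Checkpoint-inhibitor response biomarkers are usually assessed one at a time
(mutation load, PD-L1 staining), and each is an imperfect predictor. An
alternative is to model a fine-grained *molecular* response — the number of
tumor-infiltrating lymphocyte (TIL) clones that expand in peripheral blood
shortly after anti-PD-L1 therapy — from clinical, tumor, and circulating
(blood TCR repertoire) attributes all measured *before* treatment, and to
use the predicted expansion to stratify patients by expected durable
clinical benefit (DCB, progression-free survival ≥ 6 months).

`clonecast` is a small-cohort analysis toolkit for exactly this design:
n ≈ 21 patients, 19 attributes encoded into p = 36 features, so honest
held-out evaluation is the entire game. It is aimed at computational
biologists and biostatisticians building or stress-testing
immunotherapy-response models on small clinical cohorts.

## The model

The response is y = log(1 + expanded-clone count). Each continuous
attribute x enters as the pair (x, log(1+x)); binary attributes enter as
0/1 columns. The model is the elastic net,

    min over (β₀, β) of (1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀβ)²
                        + λ [ ρ‖β‖₁ + ((1−ρ)/2)‖β‖₂² ],

with ρ selected from {0.1, 0.5, 0.7, 0.9, 0.95, 0.99} and λ from a
100-point geometric path by leave-one-out cross-validation *inside the
training set*. Evaluation is outer leave-one-out over patients with
imputation, standardization, and hyperparameter selection all refit per
fold; performance is held-out variance explained,
1 − MSE_LOOCV / Var(y). Significance comes from permutation tests on the
held-out error (globally, by permuting responses; per feature category, by
jointly permuting that category's attributes), and clinical relevance from
a triage statistic: the minimal fraction of non-DCB patients that must be
treated so that every DCB patient is treated when patients are ranked by a
biomarker. A synthetic-cohort generator with planted ground truth makes
every stage testable without patient data. See `docs/methods.md` for the
full account.

## Worked example

`examples/02_loocv_evaluation.py` simulates a default 21-patient cohort
(four planted effects, oracle variance explained 0.8) and evaluates the
full pipeline:

```text
                y  held_out_prediction  squared_error
patient_id
P000        2.565                2.882          0.100
P001        2.197                2.708          0.260
P002        2.639                2.740          0.010
...

baseline MSE (response variance): 0.695
LOOCV MSE:                        0.329
variance explained (held-out):    53%
oracle ceiling:                   80%
```

Each row is one patient predicted by a model that never saw them. The
baseline MSE is the error of always predicting the mean log expansion;
the pipeline halves it, explaining 53% of response variance out of the 80%
that is explainable at all given the noise floor. The other examples cover
simulation (`01`), permutation tests (`03`: on a tumor-planted cohort the
tumor-category test rejects at p = 0.005 while the clinical one does not,
p = 0.92), category ablation (`04`: excluding the signal-bearing tumor
category collapses variance explained to 0%), and DCB triage (`05`: ranking
by predicted expansion treats 60% of non-DCB patients to capture all DCB
patients, versus 70–90% for single biomarkers).

The same analyses are available from the shell:

```bash
clonecast simulate --seed 7 --out out/
clonecast report --cohort out/cohort.csv --out out/ --B 200
```

## Cohort file format

CSV/TSV, one row per patient: `patient_id`, the 19 canonical attribute
columns (see `clonecast.default_schema()`), `expanded_clone_count`,
optional `dcb`, and optional comparator columns (`pd_l1_staining_pct`,
`bajorin_score`). Missing cells are `NA` or empty. `clonecast.load_cohort`
validates types, ranges, and schema membership on read.
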