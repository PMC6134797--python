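# priolasso

Hierarchical block-wise Lasso ("priority Lasso") for building sparse,
transportable risk-prediction models from multi-omics data, with a full
external-validation metric suite and a synthetic multi-omics data generator.

## The problem

Clinical datasets increasingly combine covariates of very different character
— an established clinical risk score, routine clinical variables, binary
mutation indicators, genome-wide expression values. These *blocks* often
carry heavily overlapping predictive information, and a flat Lasso over the
pooled matrix freely trades a cheap clinical variable for an expensive omics
one. Practitioners usually want the opposite: predictive information that is
available in an easy-to-collect block should be credited to that block, and
later blocks should only contribute what the earlier ones cannot explain.

## The method

The user partitions the p covariates into M blocks and fixes a priority
permutation π. Writing x<sub>ij</sub><sup>(m)</sup> for feature j of block m
and taking a continuous outcome for concreteness, step 1 fits an ordinary
Lasso to the top-priority block:

minimize Σ<sub>i</sub> (y<sub>i</sub> − Σ<sub>j</sub> x<sub>ij</sub><sup>(π₁)</sup> β<sub>j</sub><sup>(π₁)</sup>)² + λ<sup>(π₁)</sup> Σ<sub>j</sub> |β<sub>j</sub><sup>(π₁)</sup>|

Step m fits block π<sub>m</sub> the same way, with the accumulated linear
score η̂<sub>m−1,i</sub> of the previous steps entering the linear predictor
as an **offset** — forced in with coefficient 1, not re-estimated. For a
metric outcome this is exactly a Lasso on the running residuals; for binary
and survival outcomes the offset enters the logistic or Cox partial
likelihood. Each λ<sup>(π_m)</sup> is chosen by K-fold cross-validation
(`lambda.min` or the sparser `lambda.1se` rule), optionally with a per-block
cap on nonzero coefficients. The final predictor is the sum of the per-block
full-data contributions:

η̂<sub>M,i</sub>(π) = Σ<sub>m</sub> Σ<sub>j</sub> β̂<sub>j</sub><sup>(π_m)</sup> x<sub>ij</sub><sup>(π_m)</sup>

Because the in-sample score of a step is over-optimistic about what its block
explains, the offset carried forward can instead be **cross-validated**: each
sample's offset is computed from fits that excluded that sample's fold, which
restores influence to lower-priority blocks. The top-priority block may also
be left unpenalized (requires p < n for that block), and several candidate
priority orders can be compared by cross-validated prediction error.

For survival models the package also implements the external-validation
bundle used to judge such scores on an independent cohort: Uno's IPCW
C-index, IPCW prediction-error (Brier) curves and integrated Brier scores
over two horizons, calibration slopes on training and validation data and
their difference ("optimism"), risk stratification into three groups by the
cutpoint pair maximizing the three-group logrank statistic on the training
scores, per-group hazard ratios against the intermediate group with Wald CIs
and a likelihood-ratio test, observed vs predicted Kaplan–Meier curves per
group, and TPR/TNR/AUC of the median-dichotomised score at a clinical
horizon.

## Worked example

```python
import priolasso as pl

# a study-shaped synthetic cohort: score (2), clinical (8), mutation (40),
# expression (79) blocks, survival outcome, ~50% censoring
cfg = pl.aml_like_preset(scale=0.005, n=447, seed=42)
train, truth = pl.generate(cfg)
val, _ = pl.generate(
    __import__("dataclasses").replace(cfg, n=250), seed=4242
)

opts = pl.FitOptions(
    penalize_first_block=False,        # keep the risk score as-is
    cv_offsets=True,                   # fold-external offsets
    max_nonzero={"expression": 10},    # at most 10 expression variables
    seed=5,
)
model = pl.fit(train, opts)
print(model.n_nonzero())
# {'score': 2, 'clinical': 5, 'mutation': 11, 'expression': 4}

report, extras = pl.external_validation(model, train, val, horizon=2.0)
print(f"C_Uno={report.c_uno:.3f}  AUC={report.auc:.3f}  "
      f"IBS_2={report.ibs_horizon:.3f}  optimism={report.optimism:.3f}")
# C_Uno=0.740  AUC=0.787  IBS_2=0.141  optimism=0.114
```

`C_Uno` is the censoring-adjusted probability that of two comparable
patients, the one with the higher score dies earlier; `IBS_2` is the
time-averaged squared error of the predicted survival curves up to two
years (lower is better; ~0.25 is uninformative); a positive `optimism` means
the effect scale of the score shrinks on independent data, i.e. the training
fit was somewhat over-confident.

The same workflow is available from the shell:

```bash
priolasso simulate --preset-scale 0.005 --n 447 --seed 42 --out sim/
priolasso fit --matrix sim/matrix.csv --outcome sim/outcome.csv \
    --blocks sim/blocks.yaml --unpenalized-first-block --cv-offsets \
    --max-nonzero expression=10 --out fitdir/
priolasso predict --model fitdir/model.tsv --matrix new_patients.csv \
    --baseline fitdir/baseline.tsv --out preds/
```

`fit` exports the model as a plain TSV of nonzero coefficients — everything
a third party needs to apply the score to their own patients.

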