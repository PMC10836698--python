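# betaforest

Forest-plot variations for visualizing large ensembles of single-predictor
linear regression models, with the full supporting computation:

- **regression grids** — standardized (z-scored) single-predictor models:
  plain OLS, weighted least squares, and cluster random-intercept (REML)
  fits with Wald confidence intervals;
- **Rubin's-rules pooling** — combine the per-plausible-value fits within
  each domain × predictor cell into a pooled estimate, variance, and CI;
- **beta-range summaries** — extreme point estimates and outermost CI
  limits per cell;
- **bootstrap distributions** — case-bootstrap resampling of standardized
  coefficients, reproducible per cell from a seed;
- **synthetic data** — a truncated-multivariate-normal "decathlon" table
  (10 events + 7 hematological markers) and a hierarchical assessment
  table (students in schools in countries, 10 domains × 5 plausible
  values, country-level predictors, sampling weights);
- **three figures** — the beta-range forest plot, the bootstrap ridgeline
  plot, and the bootstrap violin plot, rendered deterministically
  (identical inputs → byte-identical SVG).

## CLI

The stages compose into two pipelines. Beta-range forest plot:

```sh
betaforest simulate timss --countries 38 --schools 18 --students 15 --seed 1 --out timss.csv
python -c "from betaforest.simulate import pv_column_names; print('\n'.join(pv_column_names()))" > pvs.txt
betaforest fit --data timss.csv --outcomes @pvs.txt --predictors GDP,GPI,Gini,GeS,GeT \
    --weights weight --cluster school_id --out fits.csv
betaforest pool --fits fits.csv --out pooled.csv
betaforest summarize --fits fits.csv --pooled pooled.csv --out ranges.csv
betaforest plot beta-range --table ranges.csv --out forest.png
```

Bootstrap ridgeline / violin plots:

```sh
betaforest simulate decathlon --n 10000 --seed 42 --out d.csv
betaforest bootstrap --data d.csv \
    --outcomes "100 m,Long jump,Shot put,High jump,400 m,110 m hurdles,Discus throw,Pole vault,Javelin throw,1500 m" \
    --predictors "Ferritin,Haptoglobin,Hematocrit,Hemoglobin,Iron,Red blood cell count,Transferrin" \
    --reps 500 --seed 7 --out b.csv
betaforest plot ridgeline --table b.csv --out ridge.svg
betaforest plot violin --table b.csv --out violin.svg
```

All randomness is controlled by `--seed`; seeded runs are bit-reproducible.
Figures accept `--null-line`, `--benchmarks`, `--xlim`, `--width/--height/--dpi`;
output format follows the file extension (png/svg/pdf).

## Table schemas (CSV)

| stage | header |
| --- | --- |
| fit | `predictor,outcome,beta,se,t,p,ci_lower,ci_upper,n_obs,degenerate,error` |
| pooled | `domain,predictor,m,beta_pooled,se_pooled,df_rubin,ci_lower,ci_upper` |
| ranges | `domain,predictor,beta_pooled,est_min,est_max,ci_outer_lower,ci_outer_upper` |
| bootstrap | `beta,predictor,outcome,replicate` |

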