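# firgrowth

Individual-tree growth modelling for repeatedly surveyed forest-inventory
plots, built around the question of how much competition, site and climate
add to a purely age-driven growth curve.  The motivating system is Chinese
fir (*Cunninghamia lanceolata*) in subtropical plantations measured on
continuous-forest-inventory (CFI) plots at five-year intervals, with
diameter at breast height (DBH, cm) or total height (H, m) as the response.

## What it implements

**The re-parameterized (RP) Mitscherlich model.**  The bounded growth curve

```
y = ω0 · (1 − e^(−ω1·T))
```

(age `T` in years, asymptote `ω0`, rate `ω1`) is re-parameterized so both
parameters are linear in plot covariates:

```
ω0 = α0 + α1·N + α2·PW + α3·HB + α4·TRHD + α5·DM + α6·DD18 + α7·Eref
ω1 = β0 + β1·N + β2·PW + β3·HB + β4·TRHD + β5·DM + β6·DD18 + β7·Eref
```

where `N` is stand density (competition), `PW/HB/TRHD/DM` are coded or
continuous site factors (slope position, elevation, soil thickness,
landform) and `DD18/Eref` are climate variables (degree-days above 18 °C,
Hargreaves reference evaporation).  The α/β vectors are fitted by nonlinear
least squares; published coefficient sets for DBH and H ship as fixtures.

**Everything around it**:

- domain types and CSV I/O for the CFI plot/tree schema, Pauta-criterion
  (3σ) outlier filtering per plot, seeded 80/20 splitting;
- base-model selection among Gompertz, Logistic, Mitscherlich and Richards
  curves;
- covariate screening: random-forest impurity importance, Pearson |r| > 0.7
  redundancy screening, VIF < 5 iterative elimination, and both-direction
  stepwise search under AIC = n·ln(SSE/n) + 2k;
- BP neural-network (three layers, logistic hidden units, target-loss
  stopping) and random-forest baselines, evaluated on the nested covariate
  ladder f(T) ⊂ f(T,Comp) ⊂ f(T,Comp,Site) ⊂ f(T,Comp,Site,Clim);
- metrics (R², RMSE, MAE), residual diagnostics, relative-change
  arithmetic, cross-validated group importance and partial dependence;
- a synthetic CFI generator with a known RP-law ground truth, correlated
  climate fields and published covariate ranges, so the whole pipeline is
  testable although the original survey data are not public.

## Worked example

```python
import firgrowth as fg
from firgrowth.synthetic import GeneratorConfig, generate_dataset

cfg = GeneratorConfig(seed=1)                  # DBH study conditions
ds = generate_dataset(cfg)
kept, removed = fg.pauta_filter(ds)
print(f"simulated {len(ds)} observations on {len(ds.plots)} plots; "
      f"Pauta filter removed {len(removed)}")

report = fg.select_environment(kept, seed=1)
print("site variables:", report.site)
print("climate variables:", report.clim)

ladder = fg.run_ladder("RF", kept, seed=1)
print(ladder.to_frame()[["model", "variables", "test_r2", "test_mae",
                         "test_rmse"]].round(3).to_string(index=False))
```

prints

```
simulated 9600 observations on 800 plots; Pauta filter removed 0
site variables: ['PW', 'HB', 'TRHD', 'DM', 'PX']
climate variables: ['DD18', 'MAP', 'Eref']
      model              variables  test_r2  test_mae  test_rmse
Sub-model 1                      T    0.338     3.863      4.893
Sub-model 2               T + Comp    0.386     3.720      4.715
Sub-model 3        T + Comp + Site    0.819     2.044      2.562
Whole model T + Comp + Site + Clim    0.874     1.697      2.136
```

Reading the output: the screening keeps the five site factors and three
climate variables that actually drive the generator (the two temperature
means, MAT and MCMT, are discarded as redundant with the retained climate
set), and each covariate group added to the random forest raises test R²
and lowers the error metrics — age alone explains about a third of the
variance, the whole model about seven-eighths.

The same pipeline is scriptable from a shell:

```sh
firgrowth simulate --seed 1 -o inventory.csv
firgrowth filter inventory.csv -o clean.csv
firgrowth select clean.csv -o selection.json
firgrowth ladder clean.csv --method rf -o ladder.csv
firgrowth compare clean.csv -o comparison.json
```

## Layout

```
src/firgrowth/
  datamodel.py          types, CSV I/O, Pauta filter, splitting
  synthetic.py          CFI-like generator with known ground truth
  base_growth.py        age-only growth curves and selection
  rp_model.py           RP model, VIF, stepwise AIC  (+ fixtures/)
  feature_selection.py  importance ranking and correlation screen
  ml_baselines.py       BP network, random forest, covariate ladder
  evaluation.py         metrics, residuals, comparison, importance
  cli.py                `firgrowth` command-line entry point
docs/methods.md         modelling assumptions and design choices
```
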