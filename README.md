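# pigpex

Phosphorus-excretion modelling for market pigs.

Excess phosphorus (P) in pig manure is a leading agricultural water
pollutant, and nutrient-management policy needs per-animal excretion
budgets. Older budgets (1990s, Europe/US) predate the near-universal
supplementation of swine diets with exogenous phytase, which sharply
improves P digestibility, so they overstate what a modern pig excretes.
`pigpex` implements a current-generation budget: regression equations
that predict daily fecal and urinary P excretion of growing pigs fed
phytase-supplemented corn–soybean-meal diets, driven over a growth
curve to lifetime and annual totals, plus the statistical pipeline to
re-develop equations of the same family from balance-trial data.

## The models

Daily excretion (g/d) is an affine function of body weight BW (kg),
feed intake FI (kg/d) and dietary total-P concentration dietP
(% as-fed). The six shipped equations (fitted to n = 95 pig×period
records from four total-collection experiments spanning 15–93 kg):

```text
Eq1  fecal   = −0.654 − 0.000618·BW² + 0.273·BW·dietP   (RMSE 0.656, R² 0.83)
Eq2  urinary =  0.045 + 0.00781·BW·dietP                (RMSE 0.194, R² 0.15)
Eq3  total   = −0.598 − 0.000613·BW² + 0.280·BW·dietP   (RMSE 0.624, R² 0.86)
Eq4  fecal   = −0.855 + 5.35·FI·dietP                   (RMSE 0.572, R² 0.87)
Eq5  urinary =  0.023 + 0.11·FI                         (RMSE 0.198, R² 0.11)
Eq6  total   = −0.842 + 5.60·FI·dietP                   (RMSE 0.550, R² 0.89)
```

The BW×dietP product is a proxy for P intake, the natural driver of
excretion; the BW² term captures the saturating fecal output of heavy
pigs on low-P finisher diets.

The lifetime projection evaluates BW from the Gompertz growth curve

```text
BW(t) = 217.4 · exp(−4.6919 · exp(−0.0116 t)),   t = age in days,
```

for each integer age from 27 d (7 kg) to 180 d (121.5 kg, marketing),
looks up dietP from a six-phase feeding schedule (0.64 % down to
0.40 % as-fed), applies Eq1 and Eq2 day by day, sums them into a total
stream, and averages: phase means, a lifetime mean (g/d) and an annual
total (mean × 365 / 1000, kg/yr). A herd-level adjustment folds in the
sow population (sows ≈ 2× the excretion of a market pig, ≈ 10 % of the
herd).

Because the raw trial records are not published, the package includes a
synthetic balance-trial generator that emulates the four experiments'
design (12 pigs × 2 periods each, three diets, feed allowance as a
fixed % of initial BW, Gaussian residuals at the published RMSEs,
occasional urinary gross errors), so the model-development pipeline —
per-experiment 3×IQR urinary outlier screen, Pearson correlation
screen, and forward-stepwise OLS at p < 0.05 — can be exercised and
validated end to end.

## Worked example

```sh
$ pigpex project --out-dir out/
$ pigpex report --summary out/summary.json
phase          fecal g/d   urinary g/d     total g/d
phase1              0.85          0.09          0.94
phase2              1.91          0.12          2.04
phase3              3.40          0.18          3.59
phase4              4.38          0.24          4.62
phase5              4.66          0.30          4.95
phase6              3.95          0.37          4.32
lifetime            3.39          0.24          3.63
kg/yr               1.24          0.09          1.33
```

Reading: a pig in phase 1 (27–39 d, 7–11 kg, 0.64 % dietary P)
excretes 0.85 g fecal P per day; by phase 5 (118–138 d) that peaks at
4.66 g/d, then declines in the finisher phase as dietary P drops to
0.40 %. Over the whole 27–180 d growing period the pig averages
3.39 g/d fecal and 0.24 g/d urinary P — an annual budget of 1.24 and
0.09 kg/yr (1.33 kg/yr total). Folding in sows:

```python
>>> from pigpex import herd_adjust
>>> herd_adjust(1.33, sow_multiplier=2.0, sow_fraction=0.10)
1.463
```

i.e. ≈ 1.46 kg P per head per year at herd level.

The same library surface drives simulation and refitting:

```sh
$ pigpex simulate --seed 7 --out trial.csv
wrote 96 records to trial.csv
$ pigpex fit --input trial.csv --response fecal_p_g_d --out model.json
selected ['FIxDIETP', 'FI_SQ', 'BWxDIETP'] (n=96, R2=0.844, RMSE=0.605); wrote model.json
```

(On a single noisy dataset the FI-family terms can win the fecal
response — FI and BW are nearly proportional under percentage-of-BW
feeding, and the FI-based published equation indeed has the higher R².
Restrict `candidates` to one covariate family for guided selection; see
`docs/methods.md`.)

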