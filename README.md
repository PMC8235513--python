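# breathct

Calibration transfer for multi-device electronic-nose (eNose) breath
classification.

## The problem

Breath-analysis studies with chemical sensor arrays rarely scale beyond a
single instrument: sensor-to-sensor variability means a classifier calibrated
on one device (the **master**, M) degrades badly on nominally identical
sibling devices (**slaves**, S). Recalibrating every slave with a full
measurement campaign is costly — and for human breath there is no synthetic
standard to recalibrate against. **Calibration transfer** (CT) instead links
instruments through a small set of *transfer samples*: breaths measured on
both instruments back to back (*standard* samples), labeled near-matches
(*nonstandard* samples), or unlabeled measurements.

`breathct` implements, as scikit-learn-style estimators, the five transfer
methods relevant to this setting, the transfer-sample selection schemes, the
PCA+LDA evaluation classifier, and an end-to-end evaluation protocol, plus a
calibrated synthetic generator of linked multi-device breath studies
(15 subjects x 3 visits x pre/post-meal, 3 devices, 18 R0/R sensor features).

## The methods

With row-aligned transfer blocks `Xm_ct`, `Xs_ct` (same breaths on master and
slave):

- **DS** (direct standardization): `Xm_ct = Xs_ct B`, solved by a truncated
  pseudoinverse `B = pinv(Xs_ct) Xm_ct`; new slave data maps to the master
  space as `Xs B`.
- **PDS** (piecewise DS): one local PLS model per master variable *j* on a
  sliding window of `w` slave variables centred at *j*, giving a banded `B`.
- **PLSDA component removal**: a PLS model of instrument membership (+1/−1)
  on stacked transfer blocks; its predicted subspace is projected out of all
  data, `X' = X − X W (PᵀW)⁻¹ Pᵀ` (unlabeled, both instruments corrected).
- **PLSDA-CT** (score-space PLS transfer): project both transfer blocks
  through the master's PLSDA model, `T = X W (PᵀW)⁻¹`, and estimate the
  score-space map `M = (T'ₛᵀT'ₛ)⁻¹ T'ₛᵀ Tm` by least squares; classification
  happens on scores.
- **CORAL** (correlation alignment, unsupervised): regularized second
  moments `C = XᵀX + λI`; the master is re-colored with the slave's
  structure, `Xm' = Xm Cm^{-1/2} Cs^{1/2}`, so the classifier is trained on
  transformed master data and applied to raw slave data.

Transfer samples are picked by the **Kennard–Stone** max–min algorithm (per
class and interleaved in the two-class scheme); the **CEM** baseline simply
adds raw labeled slave transfer rows to the master training set. Performance
is AUC ± SE of a PCA+LDA classifier over 20 repeated balanced splits, with
the master's self-AUC as the *reference* to approach and the uncorrected
cross-device AUC as the *threshold* to beat.

## Worked example

```python
from breathct import (SimConfig, simulate_study, reference_table,
                      ExperimentConfig, Condition, evaluate_condition)

datasets = simulate_study(SimConfig(seed=1))          # 3 linked devices, 86 rows each
ref = reference_table(datasets, n_pcs=13, reps=20, seed=1)
print(ref[["pair", "auc", "se"]].round(3).to_string(index=False))

cfg = ExperimentConfig(seed=1)
rec = evaluate_condition(Condition("DS", 2, 40, "standard", "two_class"), datasets, cfg)
print(f"DS, 40 two-class standard samples, slave 2: AUC = {rec['auc']:.3f} +/- {rec['se']:.3f}")
```

prints

```
 pair   auc    se
M1-M1 0.887 0.009
S2-S2 0.872 0.012
S3-S3 0.763 0.015
M1-S2 0.759 0.004
M1-S3 0.655 0.008
DS, 40 two-class standard samples, slave 2: AUC = 0.882 +/- 0.007
```

Read: the master's own classifier reaches AUC 0.887; applied unchanged to
slave 2 it drops to 0.759 (the threshold). Direct standardization fitted on
40 standard transfer samples lifts slave 2 back to 0.882 — within half a
point of the master's own performance, a successful transfer.

The same pipeline is available from the shell:

```sh
breathct simulate --seed 1 --out data
breathct tune --features data/device1.csv --grid 2:18 --seed 1
breathct run --seed 1 --data-dir data --out run
breathct report --results-dir run
```

`run/results.csv` holds one row per condition (method x slave x transfer-set
size x sample type x class scheme x hyperparameter); `report` draws AUC
against the number of transfer samples with the reference and threshold as
horizontal lines.

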