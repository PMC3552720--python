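# cmrperf

Semi-quantitative analysis of first-pass myocardial perfusion CMR for
rest / vasodilator-stress / recovery protocols, with a synthetic perfusion
phantom for validation.

## The problem

Vasodilator stress CMR estimates myocardial perfusion reserve from the
first pass of a gadolinium bolus: one short-axis frame per heartbeat while
the contrast transits the left-ventricular cavity and then the myocardium.
The semi-quantitative index used clinically is the **normalized up-slope**
— the maximum rate of signal rise in each myocardial sector, divided by
the maximum up-slope of the LV blood pool, which cancels the injection
profile, contrast dose and receiver gain:

```
upslope_norm = 100 * max-slope(myocardial sector) / max-slope(LV cavity)
MPRi-rest    = upslope_norm(stress) / upslope_norm(rest)
MPRi-recov   = upslope_norm(stress) / upslope_norm(recovery)
```

With A2A-agonist stress (regadenoson), hyperemia persists into a 15-minute
recovery acquisition, so MPRi-recov underestimates MPRi-rest; some
subjects are even *more* hyperemic at recovery than at stress ("delayed
maximal hyperemia"), which forces MPRi-recov < 1. `cmrperf` implements the
whole measurement chain, a ground-truth phantom to validate it, and the
cohort statistics (Welch and paired t-tests, Fisher's exact test, two-group
sample-size computation) needed to compare recovery strategies such as
aminophylline reversal.

The phantom drives a gamma-variate arterial input through one-compartment
(Kety-type) tissue kinetics, `dc_m/dt = F·c_a(t) − (F/λ)·c_m(t)`, renders
cavity/myocardium/background pixels with per-state gain and offset, adds
Gaussian noise, and retains the true per-state flows — so the pipeline's
accuracy can be measured against known flow ratios.

## Worked example

```
$ cmrperf simulate --out sim --seed 7
$ cmrperf analyze --in sim --out subj.json
INFO cmrperf: MPRi-rest 1.922, MPRi-recov 1.175, delayed=False
```

The default phantom has true stress/rest flow ratio 2.0 and recovery/rest
1.68. The analysis recovers MPRi-rest = 1.922 (within the documented 10%
washout bias of the up-slope surrogate) and MPRi-recov = 1.175 — the
residual-hyperemia underestimation the recovery-baseline protocol suffers
by construction. The mean rest normalized up-slope of the default phantom
is 8.85, on the same scale as measured resting values in healthy adults.

Statistics are available directly:

```
$ cmrperf stats samplesize --mean 1.78 --sd 0.60 --rel-diff 0.25
normal_approximation: 29 per group, 58 total
$ cmrperf stats fisher 7 3 5 5
fisher exact p = 0.6499
```

## Layout

| module | contents |
| --- | --- |
| `cmrperf.phantom` | gamma-variate AIF, Kety tissue kinetics, rendering, cohort simulation |
| `cmrperf.segmentation` | masks, 4-sector partition, curve extraction, Simpson volumes |
| `cmrperf.upslope` | baseline/foot detection, sliding-window maximum up-slope, normalization |
| `cmrperf.reserve` | MPRi-rest / MPRi-recov, percent reduction, delayed-hyperemia flag |
| `cmrperf.cohort_stats` | Welch/paired t, Fisher exact, sample size, cohort tables |
| `cmrperf.io`, `cmrperf.cli` | NIfTI/CSV/YAML/JSON round-trips and the `cmrperf` command |

See `docs/methods.md` for the model, parameter defaults and limitations.
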