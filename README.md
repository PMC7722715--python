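# oculorate

Analysis pipeline for **pre-target oculomotor inhibition**: the drop in
(micro)saccade rate just before an anticipated visual target. When a cue
starts a foreperiod whose duration is drawn from a block-specific
distribution, the momentary expectancy of the target can be described by
the foreperiod's **hazard rate** — the probability that the target occurs
at time *t* given that it has not occurred yet,

    h(t) = P(FP = t) / P(FP >= t).

Two accounts make different predictions for the mean saccade rate (SR) in
the −100…0 ms window before target onset, across four trial conditions
(full-certainty, high-certainty-frequent, high-certainty-rare,
low-certainty) at the 1 s and 2 s foreperiods:

* **certainty**: inhibition tracks block-level temporal certainty, so at
  both foreperiods `full < {frequent = rare} < low`;
* **temporal orienting**: inhibition tracks the momentary conditional
  target probability, so at 1 s `full < frequent < {rare = low}` (marginal
  frequencies 100/80/20/20%) while at 2 s `{full = frequent = rare} < low`
  (hazard 1/1/1 vs 1/3 — e.g. with five equiprobable foreperiods the
  target has only a 33% chance of appearing at 2 s given it has not yet).

The package implements the whole chain for testing these predictions on
binocular 1000 Hz gaze recordings, with a synthetic-data generator (known
ground truth, configurable hazard-driven inhibition) standing in for real
eye-tracking sessions:

| module | what it does |
| --- | --- |
| `oculorate.synthdata` | counterbalanced trial schedules, binocular gaze simulation (drift, main-sequence microsaccades, blinks, noise), 1-up-3-down staircase |
| `oculorate.preprocess` | zero-phase 60 Hz low-pass, per-trial segmentation (−300 ms pre-cue to +300 ms post-target), blink detection (missing data + binocular 2.5 SD pupil criterion), 200 ms exclusion margins |
| `oculorate.saccades` | Engbert-style velocity-threshold detection (6 robust SD, ≥6 samples), binocular conjunction, 50 ms overshoot rule, main-sequence QC |
| `oculorate.rates` | saccade-rate time courses, mean pre-target SR per subject × condition × foreperiod |
| `oculorate.hypotheses` | hazard rates, ordinal prediction tables, verdicts against contrast results |
| `oculorate.stats` | two-way RM-ANOVA (Mauchly, GG/HF), planned contrasts with BH-FDR, Cohen's dz + CI, JZS Bayes factors, within-subject SEM, foreperiod linear trend |
| `oculorate.pipeline` / `oculorate.cli` | end-to-end orchestration with one seed, `oculorate` command |

## Worked example

```python
from oculorate.pipeline import RunConfig, run_experiment

cfg = RunConfig(n_subjects=20, trials_per_block=20, seed=42)
res = run_experiment(cfg)
print(res.sr_table.groupby(["condition", "foreperiod_ms"])["mean_sr"].mean())
for c in res.analysis.contrasts:
    print(f"{c.label:26s} t={c.t:6.2f} p_fdr={c.p_fdr:.4g} BF01={c.bf01:.3g}")
print({k: v.verdict for k, v in res.analysis.verdicts.items()})
```

prints (seed 42):

```
condition                foreperiod_ms
full_certainty           1000             0.471
                         2000             0.233
high_certainty_frequent  1000             0.779
                         2000             0.308
high_certainty_rare      1000             1.501
                         2000             0.343
low_certainty            1000             1.875
                         2000             1.833
...
full_vs_low@1s             t= -5.07 p_fdr=0.0002052 BF01=0.00256
rare_vs_frequent@1s        t=  3.84 p_fdr=0.00166   BF01=0.0299
rare_vs_low@1s             t= -1.34 p_fdr=0.1956    BF01=1.97
full_vs_low@2s             t= -5.36 p_fdr=7.091e-05 BF01=0.00142
full_vs_high_combined@2s   t= -0.70 p_fdr=0.4943    BF01=3.46
{'certainty': 'inconsistent', 'orienting': 'consistent'}
```

Reading: pre-target SR is lowest where the target is momentarily most
probable. At 1 s the rare and low cells do not differ (both 20% marginal
frequency; BF01 ≈ 2 favors the null), and at 2 s the full-certainty and
combined high-certainty cells do not differ (hazard is 1 in all three) —
exactly the temporal-orienting pattern, and the opposite of what the
certainty account predicts for those two contrasts.

The same run is available from the shell:

```bash
oculorate run --out results/run42 --seed 42 --n-subjects 20 --trials-per-block 20
```

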