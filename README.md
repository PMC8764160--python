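# mstates

Resting-state EEG **microstate** analysis: the scalp potential field is
modeled as a sequence of brief (~60–120 ms) quasi-stable topographies drawn
from a small repertoire of template maps (canonically four classes, A–D).
`mstates` estimates the templates from the topographies at global field
power (GFP) peaks with polarity-invariant atomize–agglomerate hierarchical
clustering (AAHC), assigns every sample a class by backfitting, derives the
standard temporal parameters — duration, occurrence, coverage and the 12
between-class transition ("syntax") fractions — and compares them between
two subject groups with nonparametric statistics.  It is written for
researchers studying altered brain dynamics in clinical cohorts (e.g.
epilepsy with comorbid depression), where the typical finding is a shorter
mean microstate duration with a higher switching rate in the affected
group.

Core quantities, for average-referenced potentials `v(t)` over `C`
channels:

    GFP(t) = sqrt( (1/C) Σ_i (v_i(t) − v̄(t))² )
    GEV    = Σ_t GFP(t)² corr(v(t), map_label(t))² / Σ_t GFP(t)²

Clustering, backfitting and labeling all use the Pearson correlation of
average-referenced maps with polarity disregarded (|corr|).

Because clinical EEG is rarely shareable, the package includes a
first-class synthetic-EEG generator: a hidden Markov-style state process
over K template maps, a state-locked 10 Hz carrier producing GFP peaks
inside every state, white sensor noise at a configurable snr, and a
two-group cohort builder with a dwell-time group effect — every recording
carries its ground-truth labels, so the whole pipeline is validated by
parameter recovery.

## Worked example

```python
from mstates import (SimulationConfig, generate_cohort, run_pipeline)

cfg = SimulationConfig(n_channels=16, sampling_rate_hz=125,
                       duration_s=20, snr=4.0, seed=11)
sims, table = generate_cohort(19, 0.8, cfg, seed=11)   # g2 dwell x0.8
result = run_pipeline(
    [(s.subject_id, s.recording) for s in sims],
    dict(zip(table.subject_id, table.group)),
    out_dir="out",
)
print(result.stats[result.stats.metric.isin(
    ["duration_mean", "occurrence_mean"])].to_string(index=False))
```

On this cohort the shipped analysis (`analysis/01…04`, same settings)
prints:

```
         metric      g1_median_q1_q3         g2_median_q1_q3     U            p      auc
  duration_mean 0.108 (0.101, 0.112)    0.092 (0.088, 0.093) 347.0 1.255996e-06 0.961219
occurrence_mean 9.200 (8.850, 9.900) 10.850 (10.675, 11.400)  12.5 9.995544e-07 0.965374
```

i.e. the group whose generating dwell times were scaled by 0.8 shows a
shorter median mean-duration (92 ms vs 108 ms) and a higher mean occurrence
(10.9/s vs 9.2/s), both rank-sum p < 1e-5 — the qualitative signature the
pipeline is built to detect — while the syntax doublets (whose generating
transition structure was *not* altered) show 0/12 significant at q < 0.01.
The four fitted group maps match the generating templates with
|spatial correlation| ≥ 0.998, and the model explains ~93% of the
GFP-weighted variance.

The numbered scripts under `analysis/` run the same study step by step
(simulate → fit → backfit → statistics), writing all tables under
`results/`.  A thin CLI mirrors the stages
(`mstates simulate|preprocess|fit|backfit|stats|run`).

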