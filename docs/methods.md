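# Methods

## The model

Resting-state EEG is treated as a sequence of microstates: brief
(~60–120 ms) periods during which the scalp potential topography stays
quasi-stable before switching abruptly to another of a small repertoire of
maps, canonically four classes labeled A–D.  The package estimates the
repertoire, assigns every sample to a class, derives the temporal
parameters of the resulting state sequence, and compares them between two
subject groups.

Notation: `v(t)` is the average-referenced potential vector over `C`
channels at sample `t`.  Global field power is the spatial standard
deviation

    GFP(t) = sqrt( (1/C) Σ_i (v_i(t) − v̄(t))² ),

and topographies are compared by the Pearson correlation across channels of
two average-referenced maps; polarity is disregarded everywhere (|corr|),
because an oscillatory field reverses sign within a state without the
spatial pattern changing.

### Template estimation (AAHC)

Topographies at GFP peaks — moments of maximal signal-to-noise — are
average-referenced and scaled to unit norm, so clustering sees shape only.
Atomize–agglomerate hierarchical clustering (AAHC) starts with every peak
map as its own cluster and repeats:

1. find the cluster with the lowest summed GEV contribution
   `Σ_p GFP(p)² · corr(x_p, c)²` over its members;
2. dissolve ("atomize") it and reassign each member individually to the
   remaining cluster with the highest |spatial correlation| to its centroid;
3. update affected centroids as the first principal component of their
   members (a plain mean would cancel sign-mixed members), sign-fixed so the
   largest-magnitude channel is positive;

until `K` clusters remain (`K = 4` by default).  Unlike k-means the
procedure has no random initialization: it is deterministic given the input
order, with all ties broken toward the lowest index.  AAHC is greedy; on
tiny instances it reaches within a few percent of the exhaustive-search
optimum (verified against brute-force bipartition in the test suite) but is
not guaranteed exact.

Group templates come from two-level clustering: AAHC per subject to `K`
maps, then AAHC over the pooled subject maps.  Each subject map enters the
pool weighted by its within-subject GEV contribution share, normalized per
subject so every subject carries equal total weight.  Group maps are
matched to canonical A–D topographies by the optimal one-to-one assignment
(Hungarian algorithm) maximizing total |correlation|, and sign-aligned to
their canonical counterpart.  The packaged canonical maps are synthetic
idealizations — dipolar patterns along the classically described axes
(right-frontal→left-occipital, left-frontal→right-occipital,
prefrontal→occipital, frontocentral→occipital) — intended as a stable
labeling anchor and overridable by any measured template set.

### Backfitting and temporal parameters

Each GFP peak takes the class of the template with maximal |correlation|;
every other sample inherits the label of its nearest peak in time (exact
midpoints go to the earlier peak, deterministically).  Interpolation never
crosses an epoch boundary, and epochs without any GFP peak stay unassigned.
No temporal smoothing or minimum-duration rejection is applied by default;
such post-processing would silently change the metrics.

From the maximal constant-label runs:

- duration_k: mean run length (s) of class k,
- occurrence_k: class-k run onsets per second of assigned time,
- coverage_k: fraction of assigned samples in class k,
- syntax: counts of ordered consecutive-run pairs within epochs, normalized
  to fractions of all between-class transitions (12 values for K=4).

Runs cut by an epoch boundary have unknown true length: by default they are
excluded from duration, and epoch-initial runs are not counted as onsets.
With `truncated_runs="include"` every run counts, in which case
`coverage_k = duration_k × occurrence_k` holds exactly on single-epoch
data.  The mean duration pools all counted runs; the mean occurrence is the
sum over classes.  A class never observed has missing (not zero) duration.

The explained variance of a segmentation is

    GEV = Σ_t GFP(t)² corr(v(t), map_label(t))² / Σ_t GFP(t)²

over assigned samples.

### Preprocessing

2 s non-overlapping epochs (trailing partial data dropped); a channel bad
in ≥ 20% of epochs (inclusive) is bad everywhere; an epoch with > 15%
(strict) bad channels after that step is rejected; surviving bad channels
are replaced per epoch by the inverse-distance-weighted mean of their 4
nearest good neighbors.  Which channels are bad is an *input* mask —
artifact detection and ICA-style cleaning happen upstream, and the pipeline
exposes that insertion point rather than re-implementing it (a simple
amplitude/flatline heuristic is provided as a clearly optional
convenience).  Filtering is a zero-phase (forward–backward) 4th-order
Butterworth band-pass, 0.2–20 Hz by default; zero-phase realization
preserves topography timing.  The common-average reference is applied after
any channel subsetting, so the reference is over the analyzed montage, and
epoch-wise interpolation follows the epoch-wise bad masks.

### Group statistics

Duration, occurrence and coverage are compared with the two-sided Wilcoxon
rank-sum test, summarized as median (Q1, Q3).  For groups of at most 10 the
null distribution is enumerated exactly over all splits of the pooled
mid-ranks (ties handled exactly); larger groups use the tie-corrected
normal approximation with continuity correction.  The 12 syntax doublets
are tested jointly under Benjamini–Hochberg FDR control at q < 0.01.
Demographics use Welch's two-tailed t-test (robust unequal-variance
default).  Discrimination is summarized by the empirical ROC; the AUC
equals the Mann–Whitney U scaled by 1/(n₁n₂) with ties counted ½, oriented
so AUC ≥ 0.5 with the positive group reported explicitly.  Ordinal clinical
scores are related to metrics by Spearman rank correlation (appropriate for
an ordinal scale).

## The synthetic-data generator

No patient EEG ships with the package, so validation rests on a generator
whose truth is recoverable.  A hidden state process switches between K
orthogonal, smooth (low-order polynomial over the montage) template maps;
run lengths are geometric by default (memoryless per-sample switching —
the simplest law consistent with quasi-stability; a rounded-gamma option
gives smoother runs) with 80 ms mean dwell, the middle of the canonical
60–120 ms range; switching among the other classes is uniform unless a
transition matrix is supplied.  The signal is

    v(t) = 15 µV · template[label(t)] · sin(2π f (t − t_onset)) + noise(t),

with `f = 10 Hz` (alpha-band, matching the empirical pairing of GFP peaks
with alpha half-cycles) and spatially white Gaussian noise scaled to the
configured overall signal-to-noise amplitude ratio.  The carrier's phase
resets at each state onset, so the GFP envelope (|sin|) rises from zero and
peaks *inside* every state, however short; with a free-running carrier
~40% of 80 ms geometric states would contain no GFP peak at all and the
dwell ground truth would be systematically unrecoverable.  A two-group
cohort scales one group's dwell means by a configurable factor (0.8 in the
shipped analysis), emulating a phenotype with shorter microstates and a
higher switching rate; per-subject seeds are master seed + subject index.

What the generator does *not* emulate: forward-modeled cortical sources,
spatially correlated sensor noise, 1/f background spectra, blinks and EMG,
and non-stationarity across a session.  Passing tests therefore demonstrate
the correctness and calibration of the algorithms under a controlled state
model, not robustness to every property of clinical EEG.

## Numerical and design choices

- GFP peaks: strict local maxima with ≥ 10 ms separation (ceil to samples);
  the separation suppresses noise-split duplicates of one peak.
- Template generation needs `C > K` channels: K mutually orthogonal
  average-referenced maps cannot exist in the (C−1)-dimensional centered
  subspace otherwise.
- The band-pass is an artifact-removal step for real recordings.  Its
  ~25 ms temporal resolution (20 Hz corner) merges the shortest geometric
  dwells and inflates estimated durations by ~25% at 80 ms mean dwell —
  a property of filtering any fast-switching process, not of the estimator.
  Validation of dwell recovery and template recovery therefore runs on
  unfiltered synthetic data (band-limited by construction); the explained-
  variance and end-to-end group analyses keep the filter.
- Degenerate inputs: zero-GFP samples contribute nothing to GEV;
  constant maps make spatial correlation an error, not a NaN; a
  segmentation with a single run has missing (NaN) syntax.
- Determinism: every stochastic component is a pure function of its seed;
  AAHC and all assignments break ties toward the lowest index; two runs of
  the pipeline on the same input produce bit-identical tables.

## Problem sizes in the shipped analysis and validation suite

The shipped cohort analysis uses 19 + 19 subjects, 16 channels, 125 Hz,
20 s per subject, snr 4, dwell effect 0.8.  The validation suite uses
recordings from 16–64 channels and 10–300 s; the group-effect power check
runs 50 cohort replicates backfitting each subject with the labeled
generating templates (template recovery is validated separately on
10-subject cohorts), and the type-I calibration check runs 1,000 replicate
cohorts at the hidden-process level, where the metric (mean run length) is
available without synthesizing and re-clustering EEG.  These sizes are the
package's own choices for a fast, reproducible desk-scale analysis; all of
them are parameters, not constants.

## Known limitations

- AAHC is greedy and order-dependent in principle; determinism is
  guaranteed, global optimality is not.
- Duration estimates after a 20 Hz low-pass are upward-biased for processes
  with many sub-25 ms states (see above).
- The syntax layer counts first-order transitions only; no Markov-order
  testing or long-range dependence analysis is provided.
- EDF/BDF files can be read (via MNE) but not written; all outputs are
  plain text.
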