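"""Backfitting and microstate temporal parameters.

Given fitted template maps, every sample is assigned a microstate class:
each GFP peak takes the class of the template with maximal absolute spatial
correlation, and the samples between peaks inherit the label of their
nearest peak in time (nearest-neighbor interpolation; an exact midpoint goes
to the earlier peak).  Interpolation never crosses an epoch boundary - kept
epochs are non-contiguous excerpts, so a run or transition spanning two
epochs would be fabricated.

From the resulting label track the standard temporal parameters follow:

- duration: mean length (s) of the stable runs of a class,
- occurrence: runs of a class beginning per second of assigned time,
- coverage: fraction of assigned samples spent in a class,
- syntax: the 12 (for K=4) normalized between-class transition fractions.

Runs cut short by an epoch boundary have unknown true length; by default
they are excluded from duration and their epoch-initial onsets are not
counted as occurrences (``truncated_runs="include"`` counts everything,
which is the convention under which coverage = duration x occurrence holds
exactly on single-epoch data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Recording
from .model import GFPSeries, MicrostateModel

__all__ = [
    "Segmentation",
    "SegmentRun",
    "MicrostateMetrics",
    "backfit",
    "extract_runs",
    "compute_metrics",
    "compute_syntax",
    "metrics_to_frame",
    "syntax_pairs",
]

UNASSIGNED = -1


@dataclass
class Segmentation:
    """Per-sample class indices (-1 = unassigned) with epoch boundaries."""

    labels: np.ndarray
    sampling_rate_hz: float
    class_labels: list[str]
    epoch_bounds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epoch_bounds is None:
            self.epoch_bounds = np.array([0, self.labels.size])
        self.epoch_bounds = np.asarray(self.epoch_bounds, dtype=int)
        if self.epoch_bounds[0] != 0 or self.epoch_bounds[-1] != self.labels.size:
            raise ValueError("epoch_bounds must span the whole label track")
        if np.any(np.diff(self.epoch_bounds) <= 0):
            raise ValueError("epoch_bounds must be strictly increasing")
        k = len(self.class_labels)
        valid = (self.labels == UNASSIGNED) | (
            (self.labels >= 0) & (self.labels < k)
        )
        if not valid.all():
            raise ValueError("labels contain invalid class indices")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_assigned(self) -> int:
        return int((self.labels >= 0).sum())


@dataclass
class SegmentRun:
    """One maximal constant-label run inside one epoch."""

    class_index: int
    start_sample: int
    length_samples: int
    epoch_index: int
    truncated_start: bool = False
    truncated_end: bool = False

    @property
    def truncated(self) -> bool:
        return self.truncated_start or self.truncated_end


@dataclass
class MicrostateMetrics:
    """Per-class and mean temporal parameters for one subject."""

    subject_id: str
    class_labels: list[str]
    duration_s: dict  # class -> mean run length in s (nan if class unseen)
    duration_mean_s: float
    occurrence_hz: dict  # class -> run onsets per second of assigned time
    occurrence_mean_hz: float
    coverage: dict  # class -> fraction of assigned samples
    syntax: dict  # "XY" -> fraction of between-class transitions


def backfit(
    rec: Recording,
    gfp: GFPSeries,
    model: MicrostateModel,
    epoch_bounds: Optional[np.ndarray] = None,
) -> Segmentation:
    """Assign every sample a microstate class from the fitted maps.

    GFP-peak samples take the template with maximal |spatial correlation|;
    other samples take their nearest peak's label within the same epoch
    (midpoint ties to the earlier peak).  Epochs containing no GFP peak are
    left unassigned with a warning.
    """
    n = rec.n_samples
    if epoch_bounds is None:
        epoch_bounds = np.array([0, n])
    epoch_bounds = np.asarray(epoch_bounds, dtype=int)

    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    peaks = gfp.peak_indices
    # model maps are centered and unit-norm, so |dot| ranks |corr|
    peak_labels = np.abs(centered[:, peaks].T @ model.maps.T).argmax(axis=1)

    labels = np.full(n, UNASSIGNED, dtype=int)
    for e in range(epoch_bounds.size - 1):
        start, end = epoch_bounds[e], epoch_bounds[e + 1]
        sel = (peaks >= start) & (peaks < end)
        if not sel.any():
            warnings.warn(f"epoch {e} has no GFP peak; left unassigned")
            continue
        p = peaks[sel]
        pl = peak_labels[sel]
        # nearest-peak fill; exact midpoint -> earlier peak
        cuts = (p[:-1] + p[1:]) // 2  # floor((p_i + p_{i+1}) / 2)
        seg_starts = np.concatenate([[start], cuts + 1])
        seg_ends = np.concatenate([cuts + 1, [end]])
        for s, t, lab in zip(seg_starts, seg_ends, pl):
            labels[s:t] = lab
    return Segmentation(
        labels=labels,
        sampling_rate_hz=rec.sampling_rate_hz,
        class_labels=list(model.class_labels),
        epoch_bounds=epoch_bounds,
    )


def extract_runs(seg: Segmentation) -> list[SegmentRun]:
    """Run-length encode the segmentation, epoch by epoch.

    Runs abutting an epoch boundary (or an unassigned stretch) are flagged
    truncated: their true extent is unknown.
    """
    runs: list[SegmentRun] = []
    for e in range(seg.epoch_bounds.size - 1):
        start, end = seg.epoch_bounds[e], seg.epoch_bounds[e + 1]
        lab = seg.labels[start:end]
        if lab.size == 0:
            continue
        change = np.flatnonzero(np.diff(lab) != 0) + 1
        bounds = np.concatenate([[0], change, [lab.size]])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            cls = int(lab[b0])
            if cls == UNASSIGNED:
                continue
            trunc_start = b0 == 0 or lab[b0 - 1] == UNASSIGNED
            trunc_end = b1 == lab.size or lab[b1] == UNASSIGNED
            runs.append(
                SegmentRun(
                    class_index=cls,
                    start_sample=int(start + b0),
                    length_samples=int(b1 - b0),
                    epoch_index=e,
                    truncated_start=bool(trunc_start),
                    truncated_end=bool(trunc_end),
                )
            )
    return runs


def compute_syntax(
    runs: Sequence[SegmentRun], class_labels: Sequence[str]
) -> dict:
    """Between-class transition fractions from consecutive runs.

    Ordered pairs of consecutive runs within one epoch are counted (adjacent
    runs always differ in class, so the diagonal is excluded by construction)
    and normalized by the total transition count: 12 values for K=4.
    """
    k = len(class_labels)
    counts = np.zeros((k, k), dtype=float)
    for a, b in zip(runs[:-1], runs[1:]):
        if a.epoch_index != b.epoch_index:
            continue
        if a.start_sample + a.length_samples != b.start_sample:
            continue  # unassigned gap between runs
        counts[a.class_index, b.class_index] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no between-class transitions in the segmentation")
    frac = counts / total
    return {
        f"{class_labels[i]}{class_labels[j]}": float(frac[i, j])
        for i in range(k)
        for j in range(k)
        if i != j
    }


def syntax_pairs(class_labels: Sequence[str]) -> list[str]:
    """Ordered doublet names: AB, AC, AD, BA, ... (K*(K-1) of them)."""
    return [
        f"{a}{b}" for a in class_labels for b in class_labels if a != b
    ]


def compute_metrics(
    runs: Sequence[SegmentRun],
    seg: Segmentation,
    subject_id: str = "subject",
    truncated_runs: str = "exclude",
) -> MicrostateMetrics:
    """Duration, occurrence, coverage and syntax from the run list.

    ``truncated_runs="exclude"`` (default) drops boundary-truncated runs
    from duration and counts occurrences only for runs starting inside their
    epoch; ``"include"`` counts every run in both.  Coverage always uses all
    assigned samples.  A class never observed gets duration nan (missing),
    occurrence 0 and coverage 0.
    """
    if truncated_runs not in ("exclude", "include"):
        raise ValueError("truncated_runs must be 'exclude' or 'include'")
    if not runs:
        raise ValueError("no runs to compute metrics from")
    fs = seg.sampling_rate_hz
    k = len(seg.class_labels)
    assigned = seg.n_assigned
    total_time_s = assigned / fs

    include_all = truncated_runs == "include"
    duration_s: dict = {}
    occurrence_hz: dict = {}
    coverage: dict = {}
    pooled_lengths: list[int] = []
    for ci, cname in enumerate(seg.class_labels):
        cls_runs = [r for r in runs if r.class_index == ci]
        dur_runs = [r for r in cls_runs if include_all or not r.truncated]
        onset_runs = [r for r in cls_runs
                      if include_all or not r.truncated_start]
        samples = sum(r.length_samples for r in cls_runs)
        coverage[cname] = samples / assigned if assigned else 0.0
        occurrence_hz[cname] = len(onset_runs) / total_time_s
        if dur_runs:
            duration_s[cname] = float(
                np.mean([r.length_samples for r in dur_runs]) / fs
            )
            pooled_lengths.extend(r.length_samples for r in dur_runs)
        else:
            duration_s[cname] = float("nan")
    duration_mean = (
        float(np.mean(pooled_lengths) / fs) if pooled_lengths else float("nan")
    )
    occurrence_mean = float(sum(occurrence_hz.values()))
    try:
        syntax = compute_syntax(runs, seg.class_labels)
    except ValueError:
        # single-run segmentations have no transitions; syntax is missing
        syntax = {p: float("nan") for p in syntax_pairs(seg.class_labels)}
    return MicrostateMetrics(
        subject_id=subject_id,
        class_labels=list(seg.class_labels),
        duration_s=duration_s,
        duration_mean_s=duration_mean,
        occurrence_hz=occurrence_hz,
        occurrence_mean_hz=occurrence_mean,
        coverage=coverage,
        syntax=syntax,
    )


def metrics_to_frame(all_metrics: Sequence[MicrostateMetrics]) -> pd.DataFrame:
    """One row per subject: durations, occurrences, coverages, syntax."""
    if not all_metrics:
        raise ValueError("no metrics to tabulate")
    classes = all_metrics[0].class_labels
    pairs = syntax_pairs(classes)
    rows = []
    for m in all_metrics:
        row = {"subject_id": m.subject_id}
        for c in classes:
            row[f"duration_{c}"] = m.duration_s[c]
        row["duration_mean"] = m.duration_mean_s
        for c in classes:
            row[f"occurrence_{c}"] = m.occurrence_hz[c]
        row["occurrence_mean"] = m.occurrence_mean_hz
        for c in classes:
            row[f"coverage_{c}"] = m.coverage[c]
        for p in pairs:
            row[f"syntax_{p}"] = m.syntax.get(p, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
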