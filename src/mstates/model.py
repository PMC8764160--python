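"""Microstate template estimation.

Resting EEG is modeled as a sequence of a few recurring, quasi-stable scalp
topographies ("microstates", canonically four classes A-D).  Template maps
are estimated from the topographies at global field power (GFP) peaks -
moments of maximal signal-to-noise - using the atomize-agglomerate
hierarchical clustering (AAHC) scheme: every peak map starts as its own
cluster, and the cluster contributing least to the global explained variance
(GEV) is repeatedly dissolved, its members reassigned one by one to the
remaining cluster with the highest absolute spatial correlation, until the
target number of clusters remains.  Polarity is disregarded throughout:
a topography and its negation are the same microstate.

Two-level estimation first fits each subject separately, then clusters the
pooled subject maps into group templates, which are finally matched to
canonical A-D topographies by optimal assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.optimize import linear_sum_assignment

from .core import Recording, scalp_positions, default_channel_names
from .synthetic import TemplateSet, CLASS_SYMBOLS

__all__ = [
    "GFPSeries",
    "PeakMaps",
    "MicrostateModel",
    "compute_gfp",
    "spatial_correlation",
    "extract_peak_maps",
    "aahc_cluster",
    "compute_gev",
    "two_level_clustering",
    "label_maps",
    "canonical_templates",
]

#: default minimum separation between detected GFP peaks, ms
PEAK_MIN_SEPARATION_MS = 10.0


@dataclass
class GFPSeries:
    """Global field power trace with detected peak locations."""

    values: np.ndarray
    sampling_rate_hz: float
    peak_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.values.min() < 0:
            raise ValueError("GFP values must be nonnegative")
        if self.peak_indices.size and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak_indices must be strictly increasing")


@dataclass
class PeakMaps:
    """Unit-norm, average-referenced topographies at GFP peaks.

    ``weights`` carries the squared GFP at each peak: clustering operates on
    map *shape* only, but the explained-variance bookkeeping keeps the GFP
    weighting.
    """

    maps: np.ndarray  # (n_peaks, C)
    weights: np.ndarray  # squared GFP at each peak
    peak_indices: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if not (len(self.maps) == len(self.weights) == len(self.peak_indices)):
            raise ValueError("maps, weights and peak_indices must align")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


@dataclass
class MicrostateModel:
    """K microstate template maps with their explained-variance share."""

    maps: np.ndarray  # (K, C), average-referenced, unit norm
    class_labels: list[str]
    gev: float
    level: str = "subject"  # or "group"
    channel_names: Optional[list[str]] = None
    gev_contributions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be K x C")
        if len(self.class_labels) != self.maps.shape[0]:
            raise ValueError("one class label per map required")
        if not (0.0 <= self.gev <= 1.0 + 1e-9):
            raise ValueError("gev must lie in [0, 1]")
        if self.level not in ("subject", "group"):
            raise ValueError("level must be 'subject' or 'group'")

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]


def compute_gfp(
    rec: Recording,
    min_peak_separation_ms: float = PEAK_MIN_SEPARATION_MS,
) -> GFPSeries:
    """Global field power: the spatial standard deviation at each sample.

    GFP(t) = sqrt( (1/C) * sum_i (v_i(t) - vbar(t))^2 ).  The average
    reference is (re-)applied internally, so GFP is reference-free.  Peaks
    are strict local maxima at least ``min_peak_separation_ms`` apart; the
    separation suppresses noise-split duplicates of one underlying peak.
    """
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    gfp = np.sqrt(np.mean(centered**2, axis=0))
    distance = max(1, int(np.ceil(min_peak_separation_ms
                                  * rec.sampling_rate_hz / 1000.0)))
    peaks, _ = sps.find_peaks(gfp, distance=distance)
    return GFPSeries(values=gfp, sampling_rate_hz=rec.sampling_rate_hz,
                     peak_indices=peaks)


def spatial_correlation(
    map1: np.ndarray, map2: np.ndarray, polarity_invariant: bool = False
) -> float:
    """Pearson correlation across channels of two scalp maps.

    Both maps are centered (average-referenced) first.  With
    ``polarity_invariant`` the absolute value is returned, reflecting that
    oscillatory fields reverse sign within a microstate.
    """
    a = np.asarray(map1, dtype=float)
    b = np.asarray(map2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have equal channel counts")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spatial correlation undefined for a constant map")
    r = float(a @ b / (na * nb))
    return abs(r) if polarity_invariant else r


def extract_peak_maps(rec: Recording, gfp: GFPSeries) -> PeakMaps:
    """Topographies at GFP peaks, average-referenced and unit-normalized."""
    if gfp.peak_indices.size == 0:
        raise ValueError(
            "no GFP peaks found - provide a longer or less degenerate recording"
        )
    maps = rec.data[:, gfp.peak_indices].T.copy()
    maps -= maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1)
    if np.any(norms == 0):
        raise ValueError("constant topography at a GFP peak")
    maps /= norms[:, None]
    return PeakMaps(
        maps=maps,
        weights=gfp.values[gfp.peak_indices] ** 2,
        peak_indices=gfp.peak_indices,
    )


def _principal_map(member_maps: np.ndarray) -> np.ndarray:
    """First principal component of member maps: the polarity-invariant
    centroid (sign-mixed members cancel under a plain mean).  Sign is fixed
    deterministically: largest-magnitude channel positive."""
    _, _, vt = np.linalg.svd(member_maps, full_matrices=False)
    v = vt[0]
    s = np.sign(v[np.abs(v).argmax()])
    return v * (s if s != 0 else 1.0)


def _aahc(
    x: np.ndarray, w: np.ndarray, k_target: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core AAHC loop on unit-norm centered maps ``x`` with weights ``w``.

    Returns (centroids (k, C), assignment (n,), contributions (k,)), clusters
    ordered by descending GEV contribution.  Deterministic: ties in worst-
    cluster selection and member reassignment go to the lowest index.
    """
    n, c = x.shape
    if not 1 <= k_target <= n:
        raise ValueError(f"k_target must be in [1, {n}], got {k_target}")

    members: list[Optional[list[int]]] = [[i] for i in range(n)]
    centroids = x.copy()
    contrib = w.copy().astype(float)
    active = np.ones(n, dtype=bool)
    n_active = n

    while n_active > k_target:
        active_idx = np.flatnonzero(active)
        worst = active_idx[np.argmin(contrib[active_idx])]
        orphans = members[worst]
        members[worst] = None
        active[worst] = False
        n_active -= 1

        remaining = np.flatnonzero(active)
        # polarity-invariant nearest centroid (dot = Pearson r here)
        corr = np.abs(x[orphans] @ centroids[remaining].T)
        targets = remaining[np.argmax(corr, axis=1)]

        for t in np.unique(targets):
            moved = [orphans[j] for j in np.flatnonzero(targets == t)]
            members[t].extend(moved)
            m = x[members[t]]
            v = _principal_map(m)
            centroids[t] = v
            proj = m @ v
            contrib[t] = float(w[members[t]] @ proj**2)

    active_idx = np.flatnonzero(active)
    order = active_idx[np.argsort(-contrib[active_idx], kind="stable")]
    out_centroids = centroids[order]
    out_contrib = contrib[order]
    assignment = np.empty(n, dtype=int)
    for rank, cl in enumerate(order):
        assignment[members[cl]] = rank
    return out_centroids, assignment, out_contrib


def aahc_cluster(
    peak_maps: PeakMaps,
    k_target: int = 4,
    level: str = "subject",
    channel_names: Optional[list[str]] = None,
) -> tuple[MicrostateModel, np.ndarray]:
    """Cluster GFP-peak topographies into ``k_target`` microstate maps.

    Returns the fitted model and the per-peak cluster assignment.  The
    model's ``gev`` is the peak-level explained-variance fraction (squared
    spatial correlation weighted by squared peak GFP); full-recording GEV
    after backfitting comes from :func:`compute_gev`.
    """
    if peak_maps.n_maps < k_target:
        raise ValueError(
            f"{peak_maps.n_maps} peak maps cannot support k_target={k_target}"
        )
    centroids, assignment, contrib = _aahc(
        peak_maps.maps, peak_maps.weights, k_target
    )
    total = float(peak_maps.weights.sum())
    model = MicrostateModel(
        maps=centroids,
        class_labels=[str(i + 1) for i in range(k_target)],
        gev=float(contrib.sum() / total) if total > 0 else 0.0,
        level=level,
        channel_names=channel_names,
        gev_contributions=contrib / total if total > 0 else contrib,
    )
    return model, assignment


def compute_gev(rec: Recording, model: MicrostateModel,
                segmentation) -> float:
    """Global explained variance of a labeled segmentation.

    GEV = sum_t GFP(t)^2 * corr(v(t), map_label(t))^2 / sum_t GFP(t)^2,
    over assigned samples (label >= 0).
    """
    labels = np.asarray(
        segmentation.labels if hasattr(segmentation, "labels") else segmentation,
        dtype=int,
    )
    if labels.shape != (rec.n_samples,):
        raise ValueError("segmentation must align with the recording")
    assigned = labels >= 0
    if not assigned.any():
        raise ValueError("segmentation assigns no samples")
    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    c = rec.n_channels
    gfp2 = np.mean(centered**2, axis=0)  # = GFP(t)^2
    norms2 = gfp2 * c  # squared norm of the centered sample map
    dots = np.einsum(
        "ct,tc->t", centered[:, assigned], model.maps[labels[assigned]]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr2 = np.where(norms2[assigned] > 0,
                         dots**2 / norms2[assigned], 0.0)
    denom = gfp2[assigned].sum()
    if denom == 0:
        raise ValueError("zero total GFP over assigned samples")
    return float((gfp2[assigned] * corr2).sum() / denom)


def two_level_clustering(
    subject_peak_maps: Sequence[PeakMaps],
    k_target: int = 4,
    channel_names: Optional[list[str]] = None,
) -> MicrostateModel:
    """Subject-level AAHC, then AAHC on the pooled subject maps.

    Each subject's K maps enter the pool weighted by their subject-level GEV
    contribution shares (normalized per subject, so every subject carries
    equal total weight).  Subjects with fewer than ``k_target`` peak maps are
    skipped with a warning.
    """
    if len(subject_peak_maps) < 1:
        raise ValueError("need at least one subject")
    pooled_maps, pooled_w = [], []
    n_used = 0
    for i, pm in enumerate(subject_peak_maps):
        if pm.n_maps < k_target:
            warnings.warn(
                f"subject {i} has {pm.n_maps} peak maps < K={k_target}; skipped"
            )
            continue
        model, _ = aahc_cluster(pm, k_target)
        share = model.gev_contributions
        share = share / share.sum() if share.sum() > 0 else np.full(k_target,
                                                                    1.0 / k_target)
        pooled_maps.append(model.maps)
        pooled_w.append(share)
        n_used += 1
    if n_used == 0:
        raise ValueError("every subject was skipped; no maps to pool")
    pool = np.concatenate(pooled_maps, axis=0)
    w = np.concatenate(pooled_w)
    centroids, _, contrib = _aahc(pool, w, k_target)
    total = float(w.sum())
    return MicrostateModel(
        maps=centroids,
        class_labels=[str(i + 1) for i in range(k_target)],
        gev=float(contrib.sum() / total),
        level="group" if n_used > 1 else "subject",
        channel_names=channel_names,
        gev_contributions=contrib / total,
    )


def label_maps(model: MicrostateModel, canonical: TemplateSet) -> MicrostateModel:
    """Match model maps to canonical class topographies (A-D).

    Solves the optimal one-to-one assignment maximizing total absolute
    spatial correlation over the K x K |corr| matrix, reorders the maps into
    canonical class order, and flips each map's sign to correlate positively
    with its canonical counterpart.
    """
    if model.n_classes != canonical.n_classes:
        raise ValueError(
            f"model has K={model.n_classes}, canonical set K={canonical.n_classes}"
        )
    k = model.n_classes
    corr = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = spatial_correlation(canonical.maps[i], model.maps[j])
    row, col = linear_sum_assignment(-np.abs(corr))
    maps = model.maps[col].copy()
    signs = np.sign(corr[row, col])
    signs[signs == 0] = 1.0
    maps *= signs[:, None]
    contrib = (
        model.gev_contributions[col]
        if model.gev_contributions is not None else None
    )
    return MicrostateModel(
        maps=maps,
        class_labels=list(canonical.class_labels),
        gev=model.gev,
        level=model.level,
        channel_names=model.channel_names,
        gev_contributions=contrib,
    )


def canonical_templates(
    positions: Optional[np.ndarray] = None,
    channel_names: Optional[list[str]] = None,
    n_channels: int = 64,
) -> TemplateSet:
    """Idealized canonical A-D topographies over a montage.

    Dipolar field patterns along the classically described axes
    (+x right, +y anterior, +z vertex):

    - A: right frontocentral to left occipito-parietal diagonal,
    - B: left frontocentral to right parieto-occipital diagonal,
    - C: prefrontal to occipital (anterior-posterior),
    - D: frontocentral to occipital, with a radial (vertex) component.

    These are synthetic idealizations intended as a stable labeling anchor;
    any measured template set can be passed in their place.
    """
    if positions is None:
        positions = scalp_positions(n_channels)
    if channel_names is None:
        channel_names = default_channel_names(positions.shape[0])
    axes = np.array(
        [
            [0.70, 0.70, 0.15],   # A
            [-0.70, 0.70, 0.15],  # B
            [0.0, 0.90, 0.30],    # C
            [0.0, 0.40, 0.95],    # D
        ]
    )
    maps = positions @ axes.T  # (C, 4)
    maps -= maps.mean(axis=0, keepdims=True)
    maps /= np.linalg.norm(maps, axis=0, keepdims=True)
    return TemplateSet(
        maps=maps.T,
        channel_names=list(channel_names),
        class_labels=list(CLASS_SYMBOLS[:4]),
        channel_positions=positions,
    )
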