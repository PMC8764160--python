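"""Epoching, artifact bookkeeping, filtering and referencing.

The cleaning pipeline mirrors standard resting-state practice: the recording
is cut into fixed-length non-overlapping epochs (2 s default); a channel bad
in 20% or more of epochs is declared bad throughout; an epoch with more than
15% bad channels is rejected outright; surviving bad channels are replaced by
inverse-distance-weighted interpolation from their nearest good neighbors.
Band-pass filtering (0.2-20 Hz default) is zero-phase 4th-order Butterworth,
and the common-average reference is applied over the analyzed montage.

Which channels are "bad" is an *input* (a per-epoch boolean mask): artifact
detection itself, like ICA cleaning, happens upstream of this pipeline.  A
simple amplitude/flatline heuristic is provided as an optional convenience
(:func:`flag_bad_channels`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core import Recording

__all__ = [
    "EpochSet",
    "segment_epochs",
    "apply_bad_channel_rules",
    "interpolate_channel",
    "bandpass_filter",
    "average_reference",
    "select_channels",
    "flag_bad_channels",
    "concatenate_epochs",
]

#: channel bad in >= this fraction of epochs -> bad in all epochs (inclusive)
CHANNEL_BAD_FRACTION = 0.20
#: epoch with > this fraction of bad channels -> rejected (strict)
EPOCH_BAD_FRACTION = 0.15


@dataclass
class EpochSet:
    """Fixed-length non-overlapping epochs cut from one Recording."""

    epochs: list[np.ndarray]
    epoch_length_s: float
    sampling_rate_hz: float
    channel_names: list[str]
    channel_positions: Optional[np.ndarray] = None
    bad_channel_mask: Optional[np.ndarray] = None  # (n_epochs, C) boolean
    rejected_epochs: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {e.shape for e in self.epochs}
        if len(shapes) > 1:
            raise ValueError("all epochs must share one shape")
        length = int(round(self.epoch_length_s * self.sampling_rate_hz))
        for e in self.epochs:
            if e.shape[1] != length:
                raise ValueError(
                    "epoch_length_s x sampling_rate_hz must equal the sample count"
                )
        if self.bad_channel_mask is None:
            self.bad_channel_mask = np.zeros(
                (len(self.epochs), len(self.channel_names)), dtype=bool
            )
        self.bad_channel_mask = np.asarray(self.bad_channel_mask, dtype=bool)
        if self.bad_channel_mask.shape != (len(self.epochs), len(self.channel_names)):
            raise ValueError("bad_channel_mask must be (n_epochs, n_channels)")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def kept_indices(self) -> list[int]:
        rejected = set(self.rejected_epochs)
        return [i for i in range(self.n_epochs) if i not in rejected]


def segment_epochs(rec: Recording, epoch_length_s: float = 2.0) -> EpochSet:
    """Cut a recording into floor(T/L) non-overlapping epochs.

    Trailing samples that do not fill a whole epoch are dropped.
    """
    length = int(round(epoch_length_s * rec.sampling_rate_hz))
    if length < 1:
        raise ValueError("epoch length must be at least one sample")
    if rec.n_samples < length:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than one epoch ({length})"
        )
    n_epochs = rec.n_samples // length
    epochs = [
        rec.data[:, i * length:(i + 1) * length].copy() for i in range(n_epochs)
    ]
    return EpochSet(
        epochs=epochs,
        epoch_length_s=epoch_length_s,
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_names=list(rec.channel_names),
        channel_positions=rec.channel_positions,
    )


def interpolate_channel(
    epoch: np.ndarray,
    bad_channel: int,
    positions: np.ndarray,
    good_channels: Optional[Sequence[int]] = None,
    k_neighbors: int = 4,
) -> np.ndarray:
    """Replace one channel by the inverse-distance-weighted mean of its
    ``k_neighbors`` nearest good channels.

    Returns a copy; other channels are untouched.  An exact-coincident good
    electrode (distance 0) simply copies that channel.
    """
    if positions is None:
        raise ValueError("channel positions are required for interpolation")
    epoch = np.asarray(epoch, dtype=float)
    c = epoch.shape[0]
    if good_channels is None:
        good_channels = [i for i in range(c) if i != bad_channel]
    good = np.asarray([g for g in good_channels if g != bad_channel], dtype=int)
    if good.size < 2:
        raise ValueError("need at least 2 good channels to interpolate")
    d = np.linalg.norm(positions[good] - positions[bad_channel], axis=1)
    order = np.argsort(d, kind="stable")[: min(k_neighbors, good.size)]
    nbrs, dist = good[order], d[order]
    out = epoch.copy()
    if np.any(dist < 1e-12):
        out[bad_channel] = epoch[nbrs[dist < 1e-12][0]]
        return out
    w = 1.0 / dist
    out[bad_channel] = (w[:, None] * epoch[nbrs]).sum(axis=0) / w.sum()
    return out


def apply_bad_channel_rules(
    eset: EpochSet,
    per_epoch_bad: Optional[np.ndarray] = None,
    interpolate: bool = True,
) -> EpochSet:
    """Apply the channel-then-epoch rejection rules and interpolate the rest.

    1. A channel bad in >= 20% of epochs is flagged bad in *all* epochs
       (inclusive threshold).
    2. After step 1, an epoch with > 15% bad channels is rejected (strict
       threshold).
    3. Remaining bad channels in kept epochs are interpolated per epoch.
    """
    if per_epoch_bad is None:
        per_epoch_bad = eset.bad_channel_mask
    mask = np.array(per_epoch_bad, dtype=bool)
    n_epochs, n_channels = len(eset.epochs), len(eset.channel_names)
    if mask.shape != (n_epochs, n_channels):
        raise ValueError(
            f"mask shape {mask.shape} does not match "
            f"(n_epochs={n_epochs}, n_channels={n_channels})"
        )

    globally_bad = mask.mean(axis=0) >= CHANNEL_BAD_FRACTION
    mask[:, globally_bad] = True

    epoch_bad_frac = mask.mean(axis=1)
    rejected = np.flatnonzero(epoch_bad_frac > EPOCH_BAD_FRACTION).tolist()
    if len(rejected) == n_epochs:
        raise ValueError("all epochs rejected by the bad-channel rules")

    epochs = [e.copy() for e in eset.epochs]
    if interpolate:
        if eset.channel_positions is None and mask.any():
            raise ValueError(
                "channel positions required to interpolate bad channels"
            )
        rejected_set = set(rejected)
        for i in range(n_epochs):
            if i in rejected_set:
                continue
            bad = np.flatnonzero(mask[i])
            good = np.flatnonzero(~mask[i])
            for ch in bad:
                epochs[i] = interpolate_channel(
                    epochs[i], ch, eset.channel_positions, good_channels=good
                )

    return EpochSet(
        epochs=epochs,
        epoch_length_s=eset.epoch_length_s,
        sampling_rate_hz=eset.sampling_rate_hz,
        channel_names=list(eset.channel_names),
        channel_positions=eset.channel_positions,
        bad_channel_mask=mask,
        rejected_epochs=rejected,
    )


def bandpass_filter(rec: Recording, low_hz: float = 0.2,
                    high_hz: float = 20.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass."""
    nyquist = rec.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz ({high_hz}) must be below the Nyquist rate ({nyquist})"
        )
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass",
                     fs=rec.sampling_rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=filtered)


def average_reference(rec: Recording) -> Recording:
    """Subtract each sample's channel mean (idempotent)."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data, reference="average")


def select_channels(rec: Recording, keep_list: Sequence[str]) -> Recording:
    """Row-subset the montage, in ``keep_list`` order."""
    keep_list = list(keep_list)
    if not keep_list:
        raise ValueError("keep_list must not be empty")
    index = {name: i for i, name in enumerate(rec.channel_names)}
    unknown = [name for name in keep_list if name not in index]
    if unknown:
        raise ValueError(f"unknown channel name(s): {', '.join(unknown)}")
    rows = [index[name] for name in keep_list]
    positions = (
        rec.channel_positions[rows] if rec.channel_positions is not None else None
    )
    return Recording(
        data=rec.data[rows].copy(),
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_names=keep_list,
        channel_positions=positions,
        reference="original",  # reference set is no longer the full montage
    )


def flag_bad_channels(
    eset: EpochSet,
    amplitude_uv: float = 150.0,
    flat_uv: float = 1e-3,
) -> np.ndarray:
    """Heuristic per-epoch bad-channel mask: peak amplitude above
    ``amplitude_uv`` or peak-to-peak range below ``flat_uv`` (flatline).

    Convenience only - the rejection rules take any mask as input.
    """
    mask = np.zeros((eset.n_epochs, len(eset.channel_names)), dtype=bool)
    for i, e in enumerate(eset.epochs):
        ptp = e.max(axis=1) - e.min(axis=1)
        mask[i] = (np.abs(e).max(axis=1) > amplitude_uv) | (ptp < flat_uv)
    return mask


def concatenate_epochs(eset: EpochSet) -> tuple[Recording, np.ndarray]:
    """Stitch the kept epochs back into one Recording.

    Returns the concatenated recording plus the epoch boundaries as sample
    indices (length n_kept + 1) - downstream backfitting must not let any
    microstate run or transition cross these boundaries, since consecutive
    kept epochs are generally not contiguous in time.
    """
    kept = eset.kept_indices
    if not kept:
        raise ValueError("no epochs left to concatenate")
    data = np.concatenate([eset.epochs[i] for i in kept], axis=1)
    length = eset.epochs[0].shape[1]
    bounds = np.arange(len(kept) + 1) * length
    rec = Recording(
        data=data,
        sampling_rate_hz=eset.sampling_rate_hz,
        channel_names=list(eset.channel_names),
        channel_positions=eset.channel_positions,
    )
    return rec, bounds
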