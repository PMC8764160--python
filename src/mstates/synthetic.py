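"""Synthetic resting-state EEG with ground-truth microstate structure.

The generator emulates the quasi-stable topography model of resting EEG:
a hidden state process switches between K template scalp maps, each map is
modulated by a rectified oscillatory amplitude envelope (producing global
field power peaks inside each state), and spatially white sensor noise is
added at a configurable signal-to-noise ratio.  Every recording carries its
per-sample truth labels, so downstream clustering, backfitting and group
statistics can be validated against a recoverable ground truth.

A two-group cohort generator scales one group's mean dwell times by a
multiplicative factor, mimicking a phenotype with shorter microstates and a
higher switching rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import Recording, default_channel_names, scalp_positions

__all__ = [
    "TemplateSet",
    "StateProcess",
    "SimulationConfig",
    "SimulatedRecording",
    "make_templates",
    "simulate_state_sequence",
    "synthesize_eeg",
    "generate_cohort",
]

#: default per-class mean dwell time, ms (middle of the canonical 60-120 ms range)
DEFAULT_DWELL_MS = 80.0
#: peak template amplitude, microvolts (typical resting alpha scalp amplitude)
TEMPLATE_AMPLITUDE_UV = 15.0

CLASS_SYMBOLS = "ABCDEFGHIJ"


@dataclass
class TemplateSet:
    """K unit-norm, average-referenced scalp topographies (K x C)."""

    maps: np.ndarray
    channel_names: list[str]
    class_labels: list[str]
    channel_positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be K x C")
        k, c = self.maps.shape
        if len(self.channel_names) != c:
            raise ValueError("channel_names length must match C")
        if len(self.class_labels) != k:
            raise ValueError("class_labels length must match K")
        self.validate()

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def validate(self, tol: float = 1e-10) -> None:
        """Check average reference, unit norm and map distinguishability."""
        if np.abs(self.maps.mean(axis=1)).max() > tol:
            raise ValueError("template maps must be average-referenced")
        norms = np.linalg.norm(self.maps, axis=1)
        if np.abs(norms - 1.0).max() > 1e-8:
            raise ValueError("template maps must have unit norm")
        k = self.n_classes
        if k > 1:
            corr = self.maps @ self.maps.T  # centered & unit -> Pearson corr
            off = corr[~np.eye(k, dtype=bool)]
            if np.abs(off).max() >= 0.95:
                raise ValueError(
                    "template maps too similar (|spatial correlation| >= 0.95)"
                )


@dataclass
class StateProcess:
    """Hidden state-switching process generating microstate label tracks.

    ``transition_matrix`` holds per-switch probabilities (zero diagonal,
    rows sum to 1); ``mean_dwell_ms`` the expected dwell per class.  Dwell
    law is geometric (memoryless per-sample switching) by default; a gamma
    law with shape ``gamma_shape`` gives smoother, more regular runs.
    """

    transition_matrix: np.ndarray
    mean_dwell_ms: np.ndarray
    dwell_distribution: str = "geometric"
    gamma_shape: float = 2.0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.mean_dwell_ms = np.atleast_1d(
            np.asarray(self.mean_dwell_ms, dtype=float)
        )
        k = self.transition_matrix.shape[0]
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition_matrix must be square")
        if self.mean_dwell_ms.size == 1:
            self.mean_dwell_ms = np.full(k, float(self.mean_dwell_ms[0]))
        if self.mean_dwell_ms.shape != (k,):
            raise ValueError("mean_dwell_ms must have one entry per class")
        if np.any(self.mean_dwell_ms <= 0):
            raise ValueError("mean_dwell_ms must be positive")
        if self.dwell_distribution not in ("geometric", "gamma"):
            raise ValueError("dwell_distribution must be 'geometric' or 'gamma'")
        if k > 1:
            if np.abs(self.transition_matrix.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError("transition_matrix rows must sum to 1")
            if np.abs(np.diag(self.transition_matrix)).max() > 1e-12:
                raise ValueError("transition_matrix diagonal must be zero")

    @property
    def n_classes(self) -> int:
        return self.transition_matrix.shape[0]

    @classmethod
    def uniform(
        cls,
        k_classes: int,
        mean_dwell_ms: float | np.ndarray = DEFAULT_DWELL_MS,
        dwell_distribution: str = "geometric",
        gamma_shape: float = 2.0,
    ) -> "StateProcess":
        """Equal-probability switching among the other K-1 classes."""
        if k_classes == 1:
            tm = np.ones((1, 1))
        else:
            tm = np.full((k_classes, k_classes), 1.0 / (k_classes - 1))
            np.fill_diagonal(tm, 0.0)
        return cls(tm, np.asarray(mean_dwell_ms, dtype=float),
                   dwell_distribution, gamma_shape)

    def scaled(self, dwell_factor: float) -> "StateProcess":
        """Same switching structure with all mean dwell times scaled."""
        if dwell_factor <= 0:
            raise ValueError("dwell_factor must be positive")
        return StateProcess(
            self.transition_matrix.copy(),
            self.mean_dwell_ms * dwell_factor,
            self.dwell_distribution,
            self.gamma_shape,
        )


@dataclass
class SimulationConfig:
    """Knobs of one synthetic recording."""

    n_channels: int = 64
    sampling_rate_hz: float = 250.0
    duration_s: float = 60.0
    snr: float = 4.0
    envelope_freq_hz: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz < 100:
            raise ValueError("sampling_rate_hz must be >= 100")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not self.snr > 0:
            raise ValueError("snr must be positive (math.inf for noiseless)")
        if self.envelope_freq_hz <= 0:
            raise ValueError("envelope_freq_hz must be positive")


@dataclass
class SimulatedRecording:
    """A Recording bundled with the truth that generated it."""

    recording: Recording
    truth_labels: np.ndarray
    truth_model: TemplateSet
    truth_process: StateProcess
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        self.truth_labels = np.asarray(self.truth_labels, dtype=int)
        if self.truth_labels.shape != (self.recording.n_samples,):
            raise ValueError("truth_labels must have one entry per sample")
        k = self.truth_model.n_classes
        if self.truth_labels.min() < 0 or self.truth_labels.max() >= k:
            raise ValueError("truth_labels contain invalid class indices")


def make_templates(
    n_channels: int,
    k_classes: int = 4,
    seed: int = 0,
    positions: Optional[np.ndarray] = None,
) -> TemplateSet:
    """Draw K smooth, mutually orthogonal scalp template maps.

    Maps are built as random low-order polynomial patterns over the electrode
    positions (smooth, dipolar-to-quadrupolar spatial structure), then
    average-referenced, orthonormalized and sign-fixed.  Because the centered
    subspace of C channels has dimension C-1, K orthogonal average-referenced
    maps require ``n_channels > k_classes``.
    """
    if k_classes < 2:
        raise ValueError("k_classes must be >= 2")
    if n_channels <= k_classes:
        raise ValueError(
            "n_channels must exceed k_classes: K orthogonal average-referenced "
            f"maps need at least K+1 channels (got C={n_channels}, K={k_classes})"
        )
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = scalp_positions(n_channels)
    x, y, z = positions.T
    basis = np.column_stack(
        [x, y, z, x * x, y * y, z * z, x * y, x * z, y * z]
    )
    coef = rng.standard_normal((basis.shape[1], k_classes))
    maps = basis @ coef
    # tiny full-rank jitter guards against degenerate montages
    maps = maps + 1e-6 * rng.standard_normal(maps.shape)
    maps = maps - maps.mean(axis=0, keepdims=True)  # average reference
    q, _ = np.linalg.qr(maps)  # columns stay centered (combinations of centered cols)
    q = q[:, :k_classes]
    # deterministic sign: largest-magnitude channel positive
    signs = np.sign(q[np.abs(q).argmax(axis=0), np.arange(k_classes)])
    signs[signs == 0] = 1.0
    q = q * signs
    return TemplateSet(
        maps=q.T,
        channel_names=default_channel_names(n_channels),
        class_labels=list(CLASS_SYMBOLS[:k_classes]),
        channel_positions=positions,
    )


def simulate_state_sequence(
    process: StateProcess,
    duration_s: float,
    sampling_rate_hz: float,
    seed: int = 0,
) -> np.ndarray:
    """Sample a per-sample class-label track from the hidden state process.

    Run lengths follow the configured dwell law (geometric or rounded gamma,
    both with the per-class mean ``mean_dwell_ms``); successive classes follow
    the per-switch transition matrix.  Deterministic given the seed.
    """
    n_samples = int(round(duration_s * sampling_rate_hz))
    if n_samples < 1:
        raise ValueError("requested state sequence has zero length")
    rng = np.random.default_rng(seed)
    k = process.n_classes
    mean_samples = process.mean_dwell_ms * sampling_rate_hz / 1000.0
    if np.any(mean_samples < 1.0):
        raise ValueError("mean dwell shorter than one sample at this rate")

    labels = np.empty(n_samples, dtype=int)
    if k == 1:
        labels[:] = 0
        return labels

    state = int(rng.integers(k))
    pos = 0
    while pos < n_samples:
        m = mean_samples[state]
        if process.dwell_distribution == "geometric":
            run = int(rng.geometric(1.0 / m))
        else:
            run = max(1, int(round(rng.gamma(process.gamma_shape,
                                             m / process.gamma_shape))))
        end = min(pos + run, n_samples)
        labels[pos:end] = state
        pos = end
        state = int(rng.choice(k, p=process.transition_matrix[state]))
    return labels


def _run_bounds(labels: np.ndarray) -> np.ndarray:
    """Start indices of each constant-label run, plus the terminal bound."""
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    return np.concatenate([[0], change, [labels.size]])


def state_locked_carrier(
    labels: np.ndarray, sampling_rate_hz: float, envelope_freq_hz: float
) -> np.ndarray:
    """Sinusoidal carrier, phase-locked to state onsets.

    Within every run the carrier is sin(2*pi*f*(t - t_onset)): each state -
    however short - rises from zero amplitude at onset, so its global field
    power (the *rectified* carrier, |sin|) carries at least one local maximum
    inside the state rather than at an arbitrary phase of a free-running
    oscillation.  Using the signed carrier (the field reverses polarity every
    half-cycle, which backfitting disregards) keeps the signal's spectral
    content at the carrier frequency itself, inside a typical analysis band,
    instead of at the doubled frequency of a rectified envelope.
    """
    n = labels.size
    t = np.arange(n, dtype=float)
    bounds = _run_bounds(labels)
    onsets = np.repeat(bounds[:-1], np.diff(bounds)).astype(float)
    phase = 2.0 * np.pi * envelope_freq_hz * (t - onsets) / sampling_rate_hz
    return np.sin(phase)


def synthesize_eeg(
    templates: TemplateSet,
    labels: np.ndarray,
    config: SimulationConfig,
) -> SimulatedRecording:
    """Render a label track into multichannel EEG.

    signal(t) = template[label(t)] * a(t) + noise(t), with ``a`` the
    state-locked sinusoidal carrier (so the amplitude envelope seen by global
    field power is the rectified sinusoid |a|, peaking mid-state) and noise
    spatially white Gaussian scaled so rms(signal)/rms(noise) equals
    ``config.snr``.  The output is average-referenced per sample.
    """
    labels = np.asarray(labels, dtype=int)
    if templates.n_channels != config.n_channels:
        raise ValueError(
            f"templates have {templates.n_channels} channels, "
            f"config expects {config.n_channels}"
        )
    if labels.min() < 0 or labels.max() >= templates.n_classes:
        raise ValueError("labels contain classes outside the template set")

    rng = np.random.default_rng(config.seed)
    env = state_locked_carrier(labels, config.sampling_rate_hz,
                               config.envelope_freq_hz)
    amp = TEMPLATE_AMPLITUDE_UV * env
    signal = templates.maps[labels].T * amp[np.newaxis, :]  # C x T

    if math.isinf(config.snr):
        data = signal
    else:
        noise = rng.standard_normal(signal.shape)
        signal_rms = float(np.sqrt(np.mean(signal**2)))
        noise_rms = float(np.sqrt(np.mean(noise**2)))
        data = signal + noise * (signal_rms / (config.snr * noise_rms))

    data = data - data.mean(axis=0, keepdims=True)  # average reference
    rec = Recording(
        data=data,
        sampling_rate_hz=config.sampling_rate_hz,
        channel_names=list(templates.channel_names),
        channel_positions=templates.channel_positions,
        reference="average",
    )
    return SimulatedRecording(rec, labels, templates,
                              StateProcess.uniform(templates.n_classes))


def simulate_recording(
    config: SimulationConfig,
    process: Optional[StateProcess] = None,
    templates: Optional[TemplateSet] = None,
    k_classes: int = 4,
    subject_id: str = "sim",
) -> SimulatedRecording:
    """Convenience wrapper: templates + state track + EEG in one call."""
    if templates is None:
        templates = make_templates(config.n_channels, k_classes, seed=config.seed)
    if process is None:
        process = StateProcess.uniform(templates.n_classes)
    labels = simulate_state_sequence(
        process, config.duration_s, config.sampling_rate_hz, seed=config.seed
    )
    sim = synthesize_eeg(templates, labels, config)
    sim.truth_process = process
    sim.subject_id = subject_id
    return sim


def generate_cohort(
    n_per_group: int,
    group_effect: float,
    base_config: SimulationConfig,
    seed: int = 0,
    process: Optional[StateProcess] = None,
    templates: Optional[TemplateSet] = None,
    k_classes: int = 4,
) -> tuple[list[SimulatedRecording], pd.DataFrame]:
    """Two-group synthetic cohort sharing one template set.

    Group ``g1`` uses the base dwell means; group ``g2`` uses means scaled by
    ``group_effect`` (e.g. 0.85 -> 15% shorter microstates, higher switching
    rate).  Per-subject seeds are ``seed + subject_index``, so any subject can
    be regenerated in isolation.  Returns the recordings and a subject table
    (subject_id, group, seed, dwell_scale).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if group_effect <= 0:
        raise ValueError("group_effect must be positive")
    if templates is None:
        templates = make_templates(base_config.n_channels, k_classes, seed=seed)
    if process is None:
        process = StateProcess.uniform(templates.n_classes)

    recordings: list[SimulatedRecording] = []
    rows = []
    idx = 0
    for group, proc in (("g1", process), ("g2", process.scaled(group_effect))):
        for j in range(n_per_group):
            subject_seed = seed + idx
            cfg = SimulationConfig(
                n_channels=base_config.n_channels,
                sampling_rate_hz=base_config.sampling_rate_hz,
                duration_s=base_config.duration_s,
                snr=base_config.snr,
                envelope_freq_hz=base_config.envelope_freq_hz,
                seed=subject_seed,
            )
            sid = f"{group}_s{j + 1:02d}"
            sim = simulate_recording(cfg, process=proc, templates=templates,
                                     subject_id=sid)
            recordings.append(sim)
            rows.append(
                {"subject_id": sid, "group": group, "seed": subject_seed,
                 "dwell_scale": 1.0 if group == "g1" else group_effect}
            )
            idx += 1
    return recordings, pd.DataFrame(rows)
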