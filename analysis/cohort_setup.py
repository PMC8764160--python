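"""Shared study conditions for the analysis scripts.

One synthetic two-group cohort stands in for a 19 + 19 patient study: both
groups share four generating template maps and a uniform switching process
with 80 ms mean dwell; the affected group's dwell means are scaled by 0.8
(shorter microstates, higher switching rate).  Recordings are 16 channels,
125 Hz, 20 s at snr 4 - sizes chosen to keep the whole analysis re-runnable
in seconds on a laptop while leaving the group effect comfortably
recoverable.
"""

from mstates import SimulationConfig, generate_cohort

MASTER_SEED = 11
N_PER_GROUP = 19
GROUP_EFFECT = 0.8

BASE_CONFIG = SimulationConfig(
    n_channels=16,
    sampling_rate_hz=125.0,
    duration_s=20.0,
    snr=4.0,
    seed=MASTER_SEED,
)


def get_cohort():
    """Deterministically regenerate the study cohort."""
    return generate_cohort(N_PER_GROUP, GROUP_EFFECT, BASE_CONFIG,
                           seed=MASTER_SEED)
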