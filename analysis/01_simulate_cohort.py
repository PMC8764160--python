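#!/usr/bin/env python
"""Simulate the two-group study cohort and archive it as plain text.

Writes the subject table to results/ and the full recordings (signal
matrices plus ground-truth label sidecars) to scratch/cohort/ - the later
scripts regenerate the cohort deterministically from the master seed, so the
archived copies are for inspection, not a dependency.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from cohort_setup import get_cohort, GROUP_EFFECT, MASTER_SEED

from mstates import io as msio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sims, table = get_cohort()
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    msio.write_subject_table(results / "subjects.tsv", table)

    scratch = ROOT / "scratch" / "cohort"
    scratch.mkdir(parents=True, exist_ok=True)
    for sim in sims:
        msio.write_recording(scratch / f"{sim.subject_id}.tsv", sim.recording)
        msio.write_labels(scratch / f"{sim.subject_id}.labels.txt",
                          sim.truth_labels, sim.truth_model.class_labels)
    first = sims[0].recording
    msio.write_montage(scratch / "montage.tsv", first.channel_names,
                       first.channel_positions)

    dwell = sims[0].truth_process.mean_dwell_ms[0]
    print(f"cohort: {len(sims)} subjects (seed {MASTER_SEED}), "
          f"group g1 dwell {dwell:.0f} ms, "
          f"group g2 dwell {dwell * GROUP_EFFECT:.0f} ms")
    print(f"subject table -> {results / 'subjects.tsv'}")
    print(f"recordings    -> {scratch}/")


if __name__ == "__main__":
    main()
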