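#!/usr/bin/env python
"""Simulate the study-scale synthetic cohort.

Ten comatose TBI patients and fifteen healthy controls, each with the
full stimulation protocol (4 tactile stimulus types × 10 trials × 10 s,
plus 40 rest fragments of 10 s) at 250 Hz on the 19-channel 10-20
montage, together with FreeSurfer-style morphometry tables and the
clinical table (GCS, GOSe).  EEG goes to scratch/ (bulky); the small
tables are part of the cohort directory.
"""

from pathlib import Path

from comareact.pipeline import run_simulate
from comareact.synthetic_cohort import CohortSpec

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
SEED = 2020


def main() -> None:
    spec = CohortSpec(seed=SEED)
    out = run_simulate(spec, COHORT_DIR, dialect="edf")
    print(f"cohort written to {out}")
    print(f"  patients: {spec.n_patients}, controls: {spec.n_controls}")
    print(f"  per subject: {len(spec.subjects())} x "
          f"(4 x {spec.trials_per_condition} stimulation trials + "
          f"{spec.n_rest_fragments} rest fragments) x "
          f"{spec.epoch_seconds:g} s at {spec.sample_rate:g} Hz")


if __name__ == "__main__":
    main()
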