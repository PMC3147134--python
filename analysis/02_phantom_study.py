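#!/usr/bin/env python
"""Simulated phantom volumetry study.

Re-runs the validation design on synthetic data: the 6716 mL cylinder with
four hot spheres at each of the four sphere/background activity levels, plus
the standalone 774 and 473 mL cylinders; every object measured with both
delineation strategies by two pseudo-operators (display gammas 1.0 and 0.4),
over 10 independent noise replicates (15 mm PSF, 1e7 counts, Poisson noise).

Findings (seeded run): anatomically guided volumetry stays within ~5%
absolute error on average (spheres >= 16 mL within ~3%), while hot-spot-only
delineation averages ~20-40% with the bright-window pseudo-operator
systematically overestimating — reproducing the ordering of the physical
study.  The one systematic anatomical failure is the big cylinder at the
hottest sphere level, where the integer threshold grid cannot drop below the
background fraction of the in-mask maximum.

Writes results/simulated_measurements.csv and results/simulated_summary.csv.
"""

import time
from pathlib import Path

from maaspect.pipeline import StudyConfig, run_phantom_study

OUT = Path(__file__).resolve().parents[1] / "results"
N_SEEDS = 10


def main():
    config = StudyConfig(seeds=tuple(range(N_SEEDS)))
    t0 = time.perf_counter()
    records, summary = run_phantom_study(config)
    OUT.mkdir(exist_ok=True)
    records.to_csv(OUT / "simulated_measurements.csv", index=False)
    summary.to_csv(OUT / "simulated_summary.csv", index=False)
    print(f"{len(records)} measurements in {time.perf_counter() - t0:.0f}s")
    print(summary.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
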