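#!/usr/bin/env python
"""Case-report dosimetry: planning and partition doses.

Reproduces the treatment-planning numbers of the three-artery case: the
vascularized volume seen by quantitative MAA SPECT was 1829 mL (vs 346 mL by
angiography + CT), the tumor held 69.1% of hepatic counts, and no lung shunt
was present.

Findings: planning 120 Gy to the 346 mL angiographic volume would call for
0.855 GBq; the 5 GBq actually injected into the 1829 mL SPECT-derived volume
delivers 132.7 Gy to the whole vascularized liver.  With a 610 mL tumor at
69.1% uptake the partition model gives ~275 Gy to the tumor and ~61 Gy to
the healthy injected liver.  An end-to-end run on the synthetic liver+tumor
phantom (ideal acquisition, anatomically fitted VOIs) recovers the same
numbers from images.

Writes results/case_dosimetry.json.
"""

import dataclasses
import json
from pathlib import Path

from maaspect.dosimetry import (
    CompartmentQuant,
    DosePlan,
    activity_for_dose,
    dose_from_activity,
    dose_report,
)
from maaspect.io import write_json
from maaspect.pipeline import run_clinical_case

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    plan_angio = activity_for_dose(120.0, 0.0, 346.0)
    d_treated = dose_from_activity(5.0, 0.0, 1829.0)
    # tumor volume 610 mL is a back-derived convenience value (the case does
    # not print the tumor mass); counts chosen to give the 69.1% uptake
    report = dose_report(DosePlan(5.0, 0.0),
                         CompartmentQuant("liver", 1829.0, 1000.0),
                         CompartmentQuant("tumor", 610.0, 691.0))
    phantom_report = run_clinical_case(1829.0, 610.0, 0.691, 5.0, 0.0, acq=None)

    payload = {
        "planned_activity_for_120Gy_346mL_GBq": round(plan_angio, 4),
        "whole_liver_dose_5GBq_1829mL_Gy": round(d_treated, 2),
        "partition_model": dataclasses.asdict(report),
        "synthetic_phantom_end_to_end": dataclasses.asdict(phantom_report),
    }
    OUT.mkdir(exist_ok=True)
    write_json(payload, OUT / "case_dosimetry.json")
    print(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
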