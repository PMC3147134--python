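#!/usr/bin/env python
"""Validation statistics of the packaged phantom measurement tables.

Recomputes the stratified mean +/- SD of absolute volume-measurement errors
for each operator and method (SPECT-alone hot-spot delineation vs SPECT/CT
anatomically guided delineation) and the interobserver agreement
(Bland-Altman bias/limits and Lin's concordance coefficient).

Findings: anatomically guided measurements average ~8.5% / ~9.4% absolute
error over all 23 objects per operator (~5.5% for objects >= 16 mL), against
~20% / ~211% for hot-spot-only delineation — the second observer's display
settings produced large overestimates of the small spheres.  SPECT/CT
interobserver concordance is in the "excellent" band (>= 0.8).

Writes results/table_error_summary.csv and results/interobserver_agreement.json.
"""

import dataclasses
import json
from pathlib import Path

from maaspect.accuracy import bland_altman, summarize
from maaspect.io import load_fixture_tables, write_json

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    tables = load_fixture_tables()
    summary = summarize(tables)
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "table_error_summary.csv", index=False)
    print(summary.round(2).to_string(index=False))

    agreement = {}
    for method in ("spect", "spect_ct"):
        sub = tables[tables["method"] == method]
        wide = sub.pivot_table(index=["config", "object"], columns="operator",
                               values="measured_mL")
        res = bland_altman(wide[1], wide[2])
        agreement[method] = dataclasses.asdict(res) | {"band": res.band}
    write_json(agreement, OUT / "interobserver_agreement.json")
    print(json.dumps(agreement, indent=2))


if __name__ == "__main__":
    main()
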