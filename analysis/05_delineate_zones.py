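#!/usr/bin/env python
"""Delineate seed/breeding zones from the genomic-composition grid.

Scans k = 2..16 with PAM on the top-3 PC scores, reports the
within-cluster variation curve and its reductions, applies the elbow rule
to choose the operational number of zones, and writes the zone raster.
"""

import json
from pathlib import Path

import pandas as pd

from gfzones.pipeline import RunConfig, run_stage

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = RunConfig.from_yaml(HERE / "config.yaml")
    artifacts = run_stage("zone", cfg)
    scan = pd.read_csv(artifacts["scan"])
    sel = json.loads(Path(artifacts["selection"]).read_text())
    in_range = scan[scan["k"].between(2, 16)]
    print("within-cluster variation W(k):")
    print(in_range.to_string(index=False))
    flag = " (no clear elbow)" if sel["no_elbow"] else ""
    print(f"chosen number of zones: {sel['chosen_k']}{flag} "
          f"at theta = {sel['theta']}")
    areas = pd.read_csv(artifacts["areas"])
    print("zone areas (km^2):")
    print(areas.to_string(index=False))


if __name__ == "__main__":
    main()
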