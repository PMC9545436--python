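#!/usr/bin/env python
"""Transform the climate rasters into genomic-composition space.

Pushes every grid cell through the aggregate turnover functions,
summarizes the 20 transformed bands by PCA over the valid cells, and
renders the top three components as an RGB map where similar colors mean
similar predicted allelic composition.
"""

from pathlib import Path

import pandas as pd

from gfzones.pipeline import RunConfig, run_stage

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = RunConfig.from_yaml(HERE / "config.yaml")
    artifacts = run_stage("transform", cfg)
    var = pd.read_csv(artifacts["variance"])
    pc123 = 100 * var["variance_fraction"].head(3).sum()
    print(f"PC1-3 of the transformed grid capture {pc123:.1f}% of variance")
    print(var.head(3).to_string(index=False))
    load = pd.read_csv(artifacts["loadings"], index_col=0)
    print("strongest loadings per component:")
    for pc in load.index:
        top = load.loc[pc].abs().sort_values(ascending=False).head(3)
        print(f"  {pc}: " + ", ".join(f"{v} ({load.loc[pc, v]:+.2f})"
                                      for v in top.index))
    artifacts.update(run_stage("map", cfg))
    print(f"wrote RGB map: {artifacts['rgb']}")


if __name__ == "__main__":
    main()
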