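#!/usr/bin/env python
"""Fit the gradient-forest model and check the positive-R2 screen.

Fits one 200-tree regression forest per SNP (dosage response, 20 climate
predictors), keeps SNPs with positive out-of-bag R2, and crosses the
retained set against the simulation truth table to show how the screen
treats planted clines versus neutral structure.
"""

from pathlib import Path

import pandas as pd

from gfzones.pipeline import RunConfig, run_stage

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = RunConfig.from_yaml(HERE / "config.yaml")
    artifacts = run_stage("fit", cfg)
    retained = pd.read_csv(artifacts["retained"])
    truth = pd.read_csv(Path(cfg.out_dir) / "truth.csv")
    cls = truth.set_index("snp_id")["class"]
    retained["class"] = retained["snp_id"].map(cls)
    counts = cls.value_counts()
    kept = retained["class"].value_counts().reindex(counts.index,
                                                    fill_value=0)
    print("positive-R2 retention by SNP class:")
    for c in counts.index:
        print(f"  {c:9s} {kept[c]:4d} / {counts[c]:4d} "
              f"({100 * kept[c] / counts[c]:5.1f}%)")
    print("NOTE: at Balding-Nichols F=0.1 with 10 seedlings per population "
          "neutral SNPs carry real climate-predictable signal (population "
          "frequencies are learnable through each population's unique "
          "climate), so neutral retention is high; see docs/methods.md.")
    print(f"mean retained R2: {retained['oob_r2'].mean():.3f}")
    imp = pd.read_csv(artifacts["importance"])
    print("top predictors by overall importance:")
    print(imp.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
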