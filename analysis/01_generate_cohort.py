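#!/usr/bin/env python
"""Generate the synthetic lesion cohort used by the downstream analyses.

Writes labelled outlines (one CSV per lesion plus a manifest) under
scratch/analysis/cohort/ — they are bulky, fully regenerable intermediates;
the summary tables of later stages go under results/. The cohort keeps the
class proportions of the clinical dataset the generator emulates
(benign : BCC : IEC : SCC roughly 588 : 239 : 78 : 88) at one fifth of its
size, which is ample for the group contrasts studied here.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from lesionshape import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "scratch" / "analysis" / "cohort"
SEED = 0


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    spec = syn.small_cohort_spec(seed=SEED)
    records = syn.generate_cohort(spec)
    manifest = []
    for i, r in enumerate(records):
        sid = f"{r.label}_{i:04d}"
        pd.DataFrame({"point_index": np.arange(len(r.outline)),
                      "x": r.outline[:, 0], "y": r.outline[:, 1]}
                     ).to_csv(OUT / f"{sid}.csv", index=False)
        manifest.append(dict(sample_id=sid, label=r.label, seed=r.seed,
                             outline=f"{sid}.csv"))
    df = pd.DataFrame(manifest)
    df.to_csv(OUT / "manifest.csv", index=False)
    counts = df["label"].value_counts().to_dict()
    print(f"wrote {len(df)} outlines to {OUT}")
    print(f"class counts: {counts}")


if __name__ == "__main__":
    sys.exit(main())
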