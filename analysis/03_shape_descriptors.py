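#!/usr/bin/env python
"""Elliptic Fourier descriptors, oscilloscope alpha and asymmetry indices.

Reads the cohort outlines written by 01_generate_cohort.py, computes the
normalized 19-harmonic EFA descriptor table (73 descriptors per lesion),
the per-class alpha of the mean shape, and the per-lesion asymmetry index.
The large per-lesion descriptor matrix goes to scratch/analysis/ (a
regenerable intermediate); the compact summary tables
(results/asymmetry.csv, results/alpha_by_class.csv) go to results/.
"""

import sys
from pathlib import Path

import pandas as pd

from lesionshape import pipeline

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "analysis" / "cohort"
SCRATCH = ROOT / "scratch" / "analysis"
OUT = ROOT / "results"
N_HARMONICS = 19


def main():
    manifest = pd.read_csv(COHORT / "manifest.csv")
    ids = manifest["sample_id"].tolist()
    labels = manifest["label"].tolist()
    outlines = [pd.read_csv(COHORT / f)[["x", "y"]].to_numpy()
                for f in manifest["outline"]]

    desc, coeffs, alphas = pipeline.descriptor_table(ids, outlines, N_HARMONICS)
    asym = pipeline.asymmetry_table(ids, outlines)
    alpha_cls = pipeline.class_alpha_table(labels, coeffs, alphas)

    desc.insert(0, "label", labels)
    desc.to_csv(SCRATCH / "descriptors.csv")
    asym.insert(0, "label", labels)
    asym.to_csv(OUT / "asymmetry.csv")
    alpha_cls.to_csv(OUT / "alpha_by_class.csv")

    print(f"{desc.shape[0]} lesions x {desc.shape[1] - 1} descriptors "
          f"({N_HARMONICS} harmonics)")
    print("alpha of the class mean shapes (benign should be lowest):")
    print(alpha_cls["alpha_mean_shape"].round(4).to_string())


if __name__ == "__main__":
    sys.exit(main())
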