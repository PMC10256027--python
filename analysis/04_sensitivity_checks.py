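"""Sanity checks of the validation protocol itself.

Two checks on one variety's data:
1. Leakage sentinel — spectrum-wise (ungrouped) leave-one-out keeps a
   sample's other temperature replicates in training and must therefore
   look optimistically better than the honest sample-grouped variant.
2. Noise path — multiplying the detector noise by 10 and 100 must
   degrade the grouped cross-validation RMSEP monotonically.

Writes results/sensitivity.csv.
"""
import argparse
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from mustspec.chemometrics import loo_cv
from mustspec.io import ANALYTES
from mustspec.spectra import preprocess
from mustspec.synthetic import TABLE1_RANGES, VarietyProfile, default_config, generate_dataset

ROOT = Path(__file__).resolve().parents[1]


def design(sim):
    ds = generate_dataset(sim)
    processed = [preprocess(s) for s in ds.spectra]
    X = np.vstack([s.values for s in processed])
    groups = np.array([s.sample_id for s in processed])
    ref = ds.primary_reference.set_index("sample_id")
    ys = {a: np.array([ref.loc[g, f"{a}_g_l"] for g in groups]) for a in ANALYTES}
    return X, ys, groups


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    base = replace(
        default_config(seed=args.seed),
        varieties=(VarietyProfile("Riesling", TABLE1_RANGES["Riesling"], 22),),
    )
    rows = []

    X, ys, groups = design(base)
    for analyte in ANALYTES:
        grouped = loo_cv(X, ys[analyte], groups, n_components=6)
        ungrouped = loo_cv(X, ys[analyte], np.arange(len(groups)), n_components=6)
        rows.append({"check": "leakage", "analyte": analyte,
                     "grouped_rmsep": grouped.rmsep,
                     "ungrouped_rmsep": ungrouped.rmsep,
                     "leaks": ungrouped.rmsep < grouped.rmsep})

    for mult in (1.0, 10.0, 100.0):
        sim = replace(base, noise_scale=base.noise_sd * mult)
        X, ys, groups = design(sim)
        for analyte in ANALYTES:
            cv = loo_cv(X, ys[analyte], groups, n_components=6)
            rows.append({"check": f"noise_x{mult:.0f}", "analyte": analyte,
                         "grouped_rmsep": cv.rmsep})

    df = pd.DataFrame(rows)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    df.to_csv(out / "sensitivity.csv", index=False)
    print(df.round(4).to_string(index=False))

    leak = df[df["check"] == "leakage"]
    print("\nungrouped LOO beats grouped on all analytes:",
          bool(leak["leaks"].all()))


if __name__ == "__main__":
    main()
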