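"""Generate the season-long four-variety must dataset.

Produces the synthetic stand-in for the 2021 field campaign: 26/22/23/18
samples for Chardonnay/Riesling/Dornfelder/Pinot Noir over six weekly
time points, three spectra per sample (10/14/18 degC) referenced against
water at 20 degC, plus primary ("HPLC role") and secondary ("FTIR role")
concentration tables.  Writes the delimited-text files under
results/data/ and prints the bookkeeping summary.
"""
import argparse
from pathlib import Path

import pandas as pd

from mustspec.io import ANALYTES, write_reference, write_spectra
from mustspec.synthetic import default_config, generate_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    ds = generate_dataset(default_config(seed=args.seed))
    out = ROOT / "results" / "data"
    out.mkdir(parents=True, exist_ok=True)
    write_spectra(ds.spectra, out / "spectra.csv")
    write_reference(ds.primary_reference, out / "reference_primary.csv")
    write_reference(ds.secondary_reference, out / "reference_secondary.csv")

    counts = pd.Series([s.variety for s in ds.spectra]).value_counts()
    print(f"dataset seed={args.seed}: {len(ds.primary_reference)} samples, "
          f"{len(ds.spectra)} spectra")
    for profile in ds.config.varieties:
        v = profile.variety
        print(f"  {v:12s} ({profile.n_samples}/{counts[v]})  " + "  ".join(
            f"{a}: {profile.ranges[a][0]:.2f}-{profile.ranges[a][1]:.2f} g/L"
            for a in ANALYTES))
    print(f"written to {out}")


if __name__ == "__main__":
    main()
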