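#!/usr/bin/env python
"""Stage 3: impact factors of tetracycline, compost and maize cultivation.

For each factor F the impact factor is IF_F = mean(treated)/mean(control) - 1,
computed per quantity, day and stratum of the other two factors.  Positive
values mean the factor raised the quantity; -0.5 means it halved it.

Usage: python analysis/03_effect_indices.py [--in DIR] [--out DIR]
"""

import argparse
from pathlib import Path

from tcsoil.design import read_design
from tcsoil.effects import FACTORS, if_frame, if_table
from tcsoil.tables import read_measurements


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="in_dir", type=Path, default=Path("results"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    design = read_design(args.in_dir / "design.tsv")
    meas = read_measurements(args.in_dir / "measurements.tsv")
    for factor in FACTORS:
        frame = if_frame(if_table(meas, design, factor))
        dest = args.out / f"if_{factor}.tsv"
        frame.to_csv(dest, sep="\t", index=False, na_rep="NA")
        print(f"wrote {len(frame)} IF_{factor} rows to {dest}")


if __name__ == "__main__":
    main()
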