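#!/usr/bin/env python
"""Stage 2: colony development (CD) and ecophysiological diversity (EP).

CD = 100 * sum_k (N_k / N) / k over the 10 observation days (range 10-100;
high values mean fast-growing r-strategists dominate).  EP is the evenness
of the emergence-day distribution, -sum p log10 p, equal to 1 when colonies
emerge uniformly over the 10 days.

Usage: python analysis/02_culture_indices.py [--in DIR] [--out DIR]
"""

import argparse
from pathlib import Path

from tcsoil.culture import culture_index_table
from tcsoil.tables import read_emergence


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="in_dir", type=Path, default=Path("results"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    series = read_emergence(args.in_dir / "emergence.tsv")
    idx = culture_index_table(series)
    dest = args.out / "culture_indices.tsv"
    idx.to_csv(dest, sep="\t", index=False, na_rep="NA")
    print(f"wrote {len(idx)} CD/EP rows to {dest}")


if __name__ == "__main__":
    main()
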