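#!/usr/bin/env python
"""Stage 5: homogeneous-group letters per measured quantity.

Replicated values per (variant, day) group are gated by a Shapiro-Wilk test
on the pooled residuals: normal residuals go through two-way ANOVA followed
by Duncan's multiple range test, non-normal ones through Dunn's rank test
with Bonferroni correction.  Either way the pairwise decisions are rendered
as a compact letter display (groups sharing a letter are not significantly
different).

Usage: python analysis/05_group_stats.py [--in DIR] [--out DIR] [--alpha A]
"""

import argparse
import json
from pathlib import Path

from tcsoil.design import design_frame, read_design
from tcsoil.groupstats import letter_table
from tcsoil.tables import read_measurements, write_letter_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="in_dir", type=Path, default=Path("results"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    design = read_design(args.in_dir / "design.tsv")
    meas = read_measurements(args.in_dir / "measurements.tsv")
    merged = meas.merge(design_frame(design), on="sample_id")

    decisions = {}
    for quantity, sub in merged.groupby("quantity"):
        groups = {
            f"{v}_d{day}": g["value"].tolist()
            for (v, day), g in sub.groupby(["variant_code", "day"])
        }
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            continue
        lt = letter_table(groups, alpha=args.alpha)
        decisions[quantity] = {
            "path": lt["path"].iloc[0],
            "letters": dict(zip(lt["group"], lt["letters"])),
        }
        write_letter_table(lt.drop(columns="path"),
                           args.out / f"letters_{quantity}.tsv")
    (args.out / "letters.json").write_text(
        json.dumps(decisions, indent=2, sort_keys=True))
    print(f"wrote letter tables for {len(decisions)} quantities to {args.out}")


if __name__ == "__main__":
    main()
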