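#!/usr/bin/env python
"""Stage 4: community composition, Shannon-Wiener diversity, core/unique sets.

From the genus-level taxon table this stage writes (a) the >=1 % phylum
abundance matrix with a pooled "other" row, (b) Shannon-Wiener H' per sample
at every rank from phylum to genus, and (c) the core genera shared by all
variants plus the genera unique to each variant, separately for the non-sown
and the maize-sown soils.

Usage: python analysis/04_community_diversity.py [--in DIR] [--out DIR]
       [--threshold PCT] [--strict-threshold]
"""

import argparse
import json
from pathlib import Path

from tcsoil.diversity import core_and_unique, filtered_matrix, genus_sets, rankwise_diversity
from tcsoil.tables import read_taxon_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="in_dir", type=Path, default=Path("results"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--threshold", type=float, default=1.0)
    ap.add_argument("--strict-threshold", action="store_true")
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    taxon = read_taxon_table(args.in_dir / "taxon_table.tsv")
    variant_of = {s: s.rsplit("_d", 1)[0] for s in taxon.sample_ids}

    hmat = filtered_matrix(taxon, variant_of, "phylum",
                           threshold=args.threshold, strict=args.strict_threshold)
    hmat.index.name = "phylum"
    hmat.to_csv(args.out / "phylum_matrix.tsv", sep="\t")

    hp = rankwise_diversity(taxon)
    hp.index.name = "sample_id"
    hp.to_csv(args.out / "shannon.tsv", sep="\t")

    sets = genus_sets(taxon, variant_of,
                      threshold=args.threshold, strict=args.strict_threshold)
    report = {}
    for scope, pred in (("non_sown", lambda v: not v.startswith("Zm")),
                        ("sown", lambda v: v.startswith("Zm"))):
        in_scope = {v: s for v, s in sets.items() if pred(v)}
        if len(in_scope) >= 2:
            report[scope] = core_and_unique(in_scope).to_json_dict()
    (args.out / "set_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    print(f"wrote phylum matrix, Shannon table and set report to {args.out}")


if __name__ == "__main__":
    main()
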