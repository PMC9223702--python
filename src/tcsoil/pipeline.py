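"""End-to-end analysis pipeline: simulate (or load) -> indices -> effects ->
diversity -> homogeneous groups -> report bundle.

Every output is a TSV/JSON under one directory; a run manifest echoes the
configuration, seed and a content hash so identical configurations can be
verified to yield byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .culture import culture_index_table
from .design import design_frame, read_design, write_design
from .diversity import core_and_unique, filtered_matrix, genus_sets, rankwise_diversity
from .effects import FACTORS, if_frame, if_table
from .groupstats import letter_table
from .simulate import SimulationConfig, generate_experiment
from .tables import (
    ORGANISM_GROUPS,
    read_emergence,
    read_measurements,
    read_taxon_table,
    write_emergence,
    write_letter_table,
    write_measurements,
    write_taxon_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "seed", "out_dir", "threshold", "strict_threshold", "alpha",
    "index_precision", "input_dir", "simulate",
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    threshold: float = 1.0
    strict_threshold: bool = False
    alpha: float = 0.05
    index_precision: int = 3
    input_dir: str | None = None  # read design/measurements/... instead of simulating
    simulate: bool = True

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown run-config key(s): {sorted(unknown)}")
        return cls(**data)

    def echo(self) -> str:
        """JSON of the analytic parameters only.

        Filesystem locations (out_dir/input_dir) are excluded so that file
        contents -- and hence the bundle hash -- depend only on the seed and
        analysis settings, not on where the bundle happens to be written.
        """
        data = dataclasses.asdict(self)
        data.pop("out_dir")
        data.pop("input_dir")
        return json.dumps(data, sort_keys=True)


def _load_inputs(cfg: RunConfig):
    base = Path(cfg.input_dir)
    design = read_design(base / "design.tsv")
    measurements = read_measurements(base / "measurements.tsv")
    emergence = read_emergence(base / "emergence.tsv")
    taxon = read_taxon_table(base / "taxon_table.tsv")
    return design, measurements, emergence, taxon, None


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comment = f"tcsoil {__version__} seed={cfg.seed} config={cfg.echo()}"

    if cfg.input_dir is not None:
        design, measurements, emergence, taxon, truth = _load_inputs(cfg)
    elif cfg.simulate:
        sim = generate_experiment(SimulationConfig(seed=cfg.seed))
        design, measurements = sim.design, sim.measurements
        emergence, taxon, truth = sim.emergence, sim.taxon_table, sim.truth
        write_design(design, out / "design.tsv", comment)
        write_measurements(measurements, out / "measurements.tsv", comment)
        write_emergence(emergence, out / "emergence.tsv", comment)
        write_taxon_table(taxon, out / "taxon_table.tsv", comment)
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    else:
        raise ValueError("run config needs either input_dir or simulate=True")

    # culture indices (replicate level)
    idx = culture_index_table(emergence)
    _write(idx, out / "culture_indices.tsv", comment)

    # impact-factor tables, one per factor
    for factor in FACTORS:
        frame = if_frame(if_table(measurements, design, factor))
        _write(frame, out / f"if_{factor}.tsv", comment)

    # diversity products
    ddf = design_frame(design)
    sample_variant = dict(zip(ddf.sample_id, ddf.variant_code))
    tx_variant = {s: s.rsplit("_d", 1)[0] for s in taxon.sample_ids}
    hmat = filtered_matrix(taxon, tx_variant, "phylum",
                           threshold=cfg.threshold, strict=cfg.strict_threshold)
    hmat.index.name = "phylum"
    hmat.to_csv(out / "phylum_matrix.tsv", sep="\t")
    hprime = rankwise_diversity(taxon)
    hprime.index.name = "sample_id"
    hprime.to_csv(out / "shannon.tsv", sep="\t")

    sets = genus_sets(taxon, tx_variant, threshold=cfg.threshold,
                      strict=cfg.strict_threshold)
    report = {}
    for scope, pred in (("non_sown", lambda v: not v.startswith("Zm")),
                        ("sown", lambda v: v.startswith("Zm"))):
        in_scope = {v: s for v, s in sets.items() if pred(v)}
        if len(in_scope) >= 2:
            report[scope] = core_and_unique(in_scope).to_json_dict()
    (out / "set_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    # homogeneous-group letter tables, one per quantity (groups = variant x day)
    merged = measurements.merge(ddf, on="sample_id")
    for quantity, sub in merged.groupby("quantity"):
        groups = {
            f"{v}_d{day}": g["value"].tolist()
            for (v, day), g in sub.groupby(["variant_code", "day"])
        }
        if len(groups) < 2 or min(len(v) for v in groups.values()) < 2:
            logger.warning("quantity %s lacks replication for letters; skipped", quantity)
            continue
        lt = letter_table(groups, alpha=cfg.alpha)
        write_letter_table(lt.drop(columns="path"), out / f"letters_{quantity}.tsv",
                           precision=cfg.index_precision, header_comment=comment)

    # CD/EP letter tables per organism group
    idx_design = idx.merge(ddf, on="sample_id")
    for group in ORGANISM_GROUPS:
        sub = idx_design[idx_design.organism_group == group]
        if sub.empty:
            continue
        for col in ("cd", "ep"):
            groups = {
                f"{v}_d{day}": g[col].dropna().tolist()
                for (v, day), g in sub.groupby(["variant_code", "day"])
            }
            groups = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            lt = letter_table(groups, alpha=cfg.alpha)
            write_letter_table(lt.drop(columns="path"),
                               out / f"letters_{col}_{group}.tsv",
                               precision=cfg.index_precision, header_comment=comment)

    manifest = {
        "tool": "tcsoil",
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.echo()),
        "bundle_sha256": _bundle_hash(out),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _write(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _bundle_hash(out: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(out.glob("*")):
        if p.name == "manifest.json" or p.is_dir():
            continue
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()
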