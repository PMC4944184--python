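"""End-to-end pipeline: annotate -> dedupe -> selection -> profile -> lineage.

Runs every analysis stage over one or more cohort FASTA files against a
germline reference and writes a reproducible output bundle per cohort:

    <outdir>/<cohort>/rearrangements.tsv   AIRR-style annotation table
    <outdir>/<cohort>/selection.tsv        per-sequence CDR/FWR selection tests
    <outdir>/<cohort>/profile.json         subclass/VH/CDR3/hotspot profile
    <outdir>/<cohort>/clones.tsv           clone table
    <outdir>/<cohort>/switch_events.tsv    strict + clonal class-switch events
    <outdir>/<cohort>/lineages.tsv         lineage edge lists
    <outdir>/<cohort>/lineages.nwk         Newick trees (expanded clones)
    <outdir>/manifest.json                 seed, thresholds, input checksums,
                                           per-stage record counts

The manifest records everything needed to re-execute the identical run;
reruns with the same config produce bitwise-identical result files.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_repertoire, dedupe_unique
from .germline import default_reference, load_germline_reference
from .io import read_fasta, selection_table, to_airr_table, write_tsv
from .lineage import build_lineage_tree, detect_class_switch, group_clones
from .profiling import build_cohort_profile
from .selection import sequence_selection

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("igprofile")


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries the stage and offending records."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    inputs: dict                       # cohort label -> FASTA path
    output_dir: str
    reference_path: Optional[str] = None   # packaged synthetic set if None
    binding_tables: dict = field(default_factory=dict)  # label -> TSV path
    subclass_identity: float = 0.90
    hotspot_threshold: float = 0.35
    binding_threshold: float = 0.25
    alpha: float = 0.05
    expectation_mode: str = "uniform"      # or "hotspot_weighted"
    seed: int = 0

    def __post_init__(self):
        for name in ("subclass_identity", "hotspot_threshold",
                     "binding_threshold", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.expectation_mode not in ("uniform", "hotspot_weighted"):
            raise ValueError("expectation_mode must be uniform|hotspot_weighted")
        if not self.inputs:
            raise ValueError("at least one input cohort is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate_paths(self) -> None:
        missing = [str(p) for p in list(self.inputs.values())
                   + list(self.binding_tables.values())
                   + ([self.reference_path] if self.reference_path else [])
                   if not Path(p).exists()]
        if missing:
            raise PipelineError(
                "config error: missing input paths: " + ", ".join(missing))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate_paths()
    if config.reference_path:
        reference = load_germline_reference(config.reference_path)
    else:
        reference = default_reference()

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "igprofile_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "subclass_identity": config.subclass_identity,
            "hotspot_threshold": config.hotspot_threshold,
            "binding_threshold": config.binding_threshold,
            "alpha": config.alpha,
        },
        "expectation_mode": config.expectation_mode,
        "reference": config.reference_path or "packaged synthetic_germline.fasta",
        "inputs": {}, "cohorts": {}, "complete": False,
    }

    for label, fasta_path in config.inputs.items():
        manifest["inputs"][label] = {"path": str(fasta_path),
                                     "sha256": _sha256(fasta_path)}
        stage = "read"
        try:
            pairs = read_fasta(fasta_path)
            stage = "annotate"
            annotated, rejected = annotate_repertoire(pairs, reference)
            stage = "dedupe"
            unique = dedupe_unique(annotated)
            stage = "selection"
            results_by_seq = {}
            for rec in unique:
                v_gene = reference.v_genes[rec.v_call]
                results_by_seq[rec.seq_id] = sequence_selection(
                    rec, v_gene, mode=config.expectation_mode)
            stage = "profile"
            binding_df = None
            if label in config.binding_tables:
                binding_df = pd.read_csv(config.binding_tables[label], sep="\t")
            profile = build_cohort_profile(
                label, unique, binding_table=binding_df,
                hotspot_threshold=config.hotspot_threshold,
                binding_threshold=config.binding_threshold)
            stage = "lineage"
            clones, ungrouped = group_clones(unique)
            switch_events = detect_class_switch(clones)
            trees = [build_lineage_tree(c) for c in clones if c.is_expanded]
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed for cohort "
                                f"{label!r}: {exc}") from exc

        cohort_dir = outdir / label
        cohort_dir.mkdir(parents=True, exist_ok=True)
        write_tsv(to_airr_table(unique), cohort_dir / "rearrangements.tsv")
        write_tsv(selection_table(results_by_seq), cohort_dir / "selection.tsv")
        with open(cohort_dir / "profile.json", "w") as fh:
            json.dump(profile.to_dict(), fh, indent=2, sort_keys=True)
        clone_rows = [{"clone_id": c.clone_id, "n_members": len(c.members),
                       "v_call": c.v_call, "j_call": c.j_call,
                       "junction": c.junction_nt,
                       "is_expanded": c.is_expanded,
                       "subclasses": ",".join(sorted(set(c.subclasses))),
                       "members": ",".join(c.seq_ids)} for c in clones]
        write_tsv(pd.DataFrame(clone_rows), cohort_dir / "clones.tsv")
        switch_rows = [{"kind": e.kind, "clone_id": e.clone_id or "",
                        "subclasses": ",".join(e.subclass_set),
                        "members": ",".join(e.seq_ids)} for e in switch_events]
        write_tsv(pd.DataFrame(switch_rows,
                               columns=["kind", "clone_id", "subclasses",
                                        "members"]),
                  cohort_dir / "switch_events.tsv")
        edge_rows = [row for t in trees for row in t.edge_table()]
        write_tsv(pd.DataFrame(edge_rows,
                               columns=["clone_id", "parent", "child",
                                        "n_mutations", "mutations",
                                        "subclasses"]),
                  cohort_dir / "lineages.tsv")
        with open(cohort_dir / "lineages.nwk", "w") as fh:
            for t in trees:
                fh.write(t.to_newick() + "\n")

        manifest["cohorts"][label] = {
            "read": len(pairs),
            "annotated": len(annotated),
            "rejected": len(rejected),
            "unique": len(unique),
            "clones": len(clones),
            "expanded_clones": sum(c.is_expanded for c in clones),
            "ungrouped": len(ungrouped),
            "switch_events_strict":
                sum(e.kind == "strict" for e in switch_events),
            "switch_events_clonal":
                sum(e.kind == "clonal" for e in switch_events),
        }
        logger.info("cohort %s: read=%d annotated=%d rejected=%d unique=%d",
                    label, len(pairs), len(annotated), len(rejected),
                    len(unique))

    manifest["complete"] = True
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
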