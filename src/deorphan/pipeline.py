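"""End-to-end pipeline: curate -> distances -> tree -> root -> annotate -> report.

All stage parameters live in :class:`PipelineConfig`; all randomness
(the bootstrap) flows from its single seed. The curation order is
length filter first, then duplicate collapse, then domain trimming, so
that an unmutated truncated fragment is attributed to the length rule
rather than collapsing into its full-length source.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import io as dio
from .annotate import (
    PropagationResult, propagate_labels, species_restriction, summarize,
)
from .curation import (
    DEFAULT_DUPLICATE_THRESHOLD, DEFAULT_MIN_LENGTH, OverrideTable,
    ProteinRecord, apply_overrides, collapse_duplicates, filter_by_length,
    trim_to_core,
)
from .pairwise import AlignmentMatrix, msa_distances
from .phylo import bootstrap_support, flag_long_branches, root_with_outgroup
from .tree import PhyloTree

logger = logging.getLogger(__name__)

#: Species groups used for restriction verdicts; vertebrates here are
#: the two vertebrate proteomes surveyed (human and zebrafish).
DEFAULT_SPECIES_GROUPS = {
    "vertebrate": ("HUMAN", "DANRE"),
    "animal": ("HUMAN", "DANRE", "DROME", "CAEEL"),
}


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its default.

    ``bootstrap_reps`` defaults to 100 (desk scale); larger replicate
    counts (e.g. 10000) are a parameter, not a code change. Support
    thresholds are strict: a clade qualifies for propagation only with
    support > ``s_prop`` and counts as high confidence only with
    support > ``s_conf``.
    """

    min_len: int = DEFAULT_MIN_LENGTH
    dup_threshold: float = DEFAULT_DUPLICATE_THRESHOLD
    correction: str = "poisson"
    bootstrap_reps: int = 100
    seed: int = 0
    s_prop: int = 90
    s_conf: int = 70
    outgroup: str = "MCU_HUMAN"
    long_branch_factor: float = 3.0
    species_groups: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SPECIES_GROUPS.items()}
    )
    class_colors: dict = field(default_factory=lambda: dict(dio.DEFAULT_CLASS_COLORS))

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not 0.0 <= self.dup_threshold <= 1.0:
            raise ValueError("dup_threshold must be in [0, 1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        for bound, name in ((self.s_prop, "s_prop"), (self.s_conf, "s_conf")):
            if not 0 <= bound <= 100:
                raise ValueError(f"{name} must be in [0, 100]")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **clean)


@dataclass
class CurationOutcome:
    records: list
    report_rows: list


def curate_records(
    records: Sequence[ProteinRecord],
    config: PipelineConfig,
    overrides: Optional[OverrideTable] = None,
) -> CurationOutcome:
    """Overrides -> length filter -> duplicate collapse -> domain trim."""
    rows = []
    current = list(records)
    if overrides is not None and len(overrides):
        before = {r.id for r in current}
        current = apply_overrides(current, overrides)
        for ov in overrides:
            if ov.target_id in before:
                rows.append({
                    "id": ov.target_id, "action": "overridden",
                    "detail": f"replaced by {ov.replacement.id}: {ov.reason}",
                })
    current, removed = filter_by_length(current, config.min_len)
    for rec in removed:
        rows.append({
            "id": rec.id, "action": "removed_short",
            "detail": f"length {len(rec)} < {config.min_len}",
        })
    current, collapsed = collapse_duplicates(current, config.dup_threshold)
    for kept_id, dropped_id, dist in collapsed:
        rows.append({
            "id": dropped_id, "action": "collapsed_duplicate",
            "detail": f"into {kept_id} (p-distance {dist:.5f})",
        })
    trimmed = []
    for rec in current:
        new = trim_to_core(rec)
        if new.sequence != rec.sequence:
            rows.append({
                "id": rec.id, "action": "trimmed",
                "detail": f"{len(rec)} -> {len(new)} aa (Solcar core)",
            })
        trimmed.append(new)
    return CurationOutcome(records=trimmed, report_rows=rows)


@dataclass
class PipelineResult:
    records: list
    msa: Optional[AlignmentMatrix]
    tree: PhyloTree
    rooted_tree: PhyloTree
    propagation: PropagationResult
    restrictions: list
    long_branches: list
    curation_report: list


def analyze(
    records: Sequence[ProteinRecord],
    config: PipelineConfig,
    labels: Optional[Mapping] = None,
    msa: Optional[AlignmentMatrix] = None,
    tree: Optional[PhyloTree] = None,
    overrides: Optional[OverrideTable] = None,
) -> PipelineResult:
    """Run the full analysis in memory.

    Either an external ``tree`` (Newick ingestion; skips distance and
    bootstrap stages) or an alignment is required; when ``msa`` is None
    the curated records must be equal length and gap free (the identity
    alignment, as for simulated families).
    """
    outcome = curate_records(records, config, overrides=overrides)
    curated = outcome.records
    kept_ids = {r.id for r in curated}
    if labels is None:
        labels = {
            r.id: r.label for r in curated if r.label is not None
        }
    labels = {t: l for t, l in labels.items() if t in kept_ids}

    if tree is None:
        if msa is None:
            lengths = {len(r) for r in curated}
            if len(lengths) != 1:
                raise ValueError(
                    "curated records are not equal length; supply a pre-built "
                    "alignment or an external tree"
                )
            msa = AlignmentMatrix.from_records(curated)
        else:
            msa = msa.subset([i for i in msa.ids if i in kept_ids])
        tree = bootstrap_support(
            msa, n_reps=config.bootstrap_reps, seed=config.seed,
            correction=config.correction,
        )
    rooted = root_with_outgroup(tree, config.outgroup)
    species_of = {r.id: r.species for r in curated}
    propagation = propagate_labels(
        rooted, labels, s_prop=config.s_prop, s_conf=config.s_conf,
        exclude=(config.outgroup,),
    )
    restrictions = species_restriction(
        rooted, species_of,
        species_groups=config.species_groups,
        s_conf=config.s_conf,
        exclude=(config.outgroup,),
    )
    long_branches = flag_long_branches(rooted, k=config.long_branch_factor)
    return PipelineResult(
        records=curated, msa=msa, tree=tree, rooted_tree=rooted,
        propagation=propagation, restrictions=restrictions,
        long_branches=long_branches, curation_report=outcome.report_rows,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(
    config: PipelineConfig,
    fasta_path,
    annotations_path=None,
    newick_path=None,
    out_dir="deorphan_out",
) -> Path:
    """File-based pipeline run; writes all artifacts into ``out_dir``.

    Outputs: curation report, distance matrix (PHYLIP), supported and
    rooted Newick trees, propagation report (+ per-tier counts), iTOL
    color strip, species-restriction report, and a machine-readable run
    manifest. Deterministic given the config seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read_inputs"
    try:
        records = dio.read_fasta(fasta_path)
        if annotations_path is not None:
            annotations = dio.read_annotations(annotations_path)
            records = dio.apply_annotations(records, annotations)
        external_tree = (
            PhyloTree.read(newick_path) if newick_path is not None else None
        )
        stage = "analyze"
        result = analyze(records, config, tree=external_tree)
        stage = "write_outputs"
        dio.write_curation_report(result.curation_report, out / "curation_report.tsv")
        dio.write_fasta(result.records, out / "curated.fasta")
        if result.msa is not None:
            D = msa_distances(result.msa, config.correction)
            dio.write_distances_phylip(D, out / "distances.phylip")
        result.tree.write(out / "tree_support.nwk")
        result.rooted_tree.write(out / "tree_rooted.nwk")
        species_of = {r.id: r.species for r in result.records}
        table, counts = summarize(result.propagation, species_of=species_of)
        dio.write_propagation_report(table, counts, out / "propagation.tsv")
        dio.write_itol_colorstrip(
            result.propagation.entries, out / "itol_colorstrip.txt",
            colors=config.class_colors,
        )
        dio.write_species_restriction_report(
            result.restrictions, out / "species_restriction.tsv"
        )
        manifest = {
            "parameters": asdict(config),
            "inputs": {
                "fasta": {"path": str(fasta_path), "sha256": _sha256(fasta_path)},
            },
            "n_input_records": len(dio.read_fasta(fasta_path)),
            "n_curated_records": len(result.records),
            "long_branch_tips": result.long_branches,
            "conflicts": result.propagation.conflicts,
            "evidence_counts": counts,
        }
        if annotations_path is not None:
            manifest["inputs"]["annotations"] = {
                "path": str(annotations_path), "sha256": _sha256(annotations_path),
            }
        if newick_path is not None:
            manifest["inputs"]["newick"] = {
                "path": str(newick_path), "sha256": _sha256(newick_path),
            }
        (out / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
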