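"""File formats: FASTA, annotation TSV, PHYLIP distances, reports, iTOL.

FASTA headers use the dialect ``>ACCESSION|SPECIES optional description``;
a bare ``>ACCESSION`` is tolerated, in which case the species mnemonic
is taken from the suffix after the last underscore of the accession
(``SF1_HUMAN`` -> ``HUMAN``) or left empty.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import ChemClass, Evidence, LigandLabel, ProteinRecord
from .pairwise import AlignmentMatrix, DistanceMatrix

#: Default hex colors per ligand chemical class (iTOL color strip).
DEFAULT_CLASS_COLORS = {
    "nucleotide": "#e41a1c",
    "amino_acid": "#377eb8",
    "carboxylate": "#4daf4a",
    "cofactor": "#984ea3",
    "inorganic_ion": "#ff7f00",
    "proton": "#a65628",
    "unknown": "#999999",
}


def _species_from_header(accession: str, rest: str) -> str:
    if "|" in accession:
        return accession.split("|", 1)[1]
    if "_" in accession:
        return accession.rsplit("_", 1)[1]
    return ""


def read_fasta(path, reviewed: bool = False) -> list:
    """Read protein records from FASTA (gaps stripped)."""
    records = []
    seen = set()
    for seq_record in SeqIO.parse(str(path), "fasta"):
        header = seq_record.id
        if "|" in header:
            accession, species = header.split("|", 1)
            species = species.split()[0] if species else ""
        else:
            accession = header
            species = accession.rsplit("_", 1)[1] if "_" in accession else ""
        if accession in seen:
            raise ValueError(f"duplicate FASTA id {accession!r} in {path}")
        seen.add(accession)
        sequence = str(seq_record.seq).upper().replace("-", "").replace(".", "")
        records.append(ProteinRecord(
            id=accession, species=species, sequence=sequence, reviewed=reviewed,
        ))
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}|{r.species}" if r.species else r.id,
                  description="")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_alignment(path) -> AlignmentMatrix:
    """Read an aligned FASTA into an AlignmentMatrix (ids without species suffix)."""
    ids, rows = [], []
    for seq_record in SeqIO.parse(str(path), "fasta"):
        accession = seq_record.id.split("|", 1)[0]
        ids.append(accession)
        rows.append(str(seq_record.seq).upper())
    return AlignmentMatrix(ids, rows)


def write_alignment(msa: AlignmentMatrix, path) -> None:
    seq_records = [
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(msa.ids, msa.rows)
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _parse_intervals(text: str) -> tuple:
    text = (text or "").strip()
    if not text:
        return ()
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        start, end = chunk.split("-")
        out.append((int(start), int(end)))
    return tuple(out)


def _format_intervals(intervals) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def read_annotations(path) -> dict:
    """Read the annotation TSV: id, species, intervals, ligand, chem_class, evidence.

    Returns ``{id: {"species": ..., "intervals": ..., "label": LigandLabel or None}}``.
    """
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id"}
    if not required <= set(table.columns):
        raise ValueError(f"annotation file {path} lacks columns {required}")
    out: dict = {}
    for _, row in table.iterrows():
        rid = row["id"]
        if rid in out:
            raise ValueError(f"duplicate annotation id {rid!r}")
        ligand = row.get("ligand", "")
        label = None
        if ligand:
            label = LigandLabel(
                ligand=ligand,
                chem_class=ChemClass(row.get("chem_class", "") or "unknown"),
                evidence=Evidence(row.get("evidence", "") or "experimental"),
            )
        out[rid] = {
            "species": row.get("species", ""),
            "intervals": _parse_intervals(row.get("intervals", "")),
            "label": label,
        }
    return out


def write_annotations(records: Sequence[ProteinRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "species": r.species,
            "intervals": _format_intervals(r.domain_intervals),
            "ligand": r.label.ligand if r.label else "",
            "chem_class": r.label.chem_class.value if r.label else "",
            "evidence": r.label.evidence.value if r.label else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def apply_annotations(records: Sequence[ProteinRecord], annotations: Mapping) -> list:
    """Attach species, intervals and labels from an annotation map to records."""
    from dataclasses import replace

    out = []
    for r in records:
        ann = annotations.get(r.id)
        if ann is None:
            out.append(r)
            continue
        out.append(replace(
            r,
            species=ann["species"] or r.species,
            domain_intervals=ann["intervals"] or r.domain_intervals,
            label=ann["label"] or r.label,
        ))
    return out


def write_distances_phylip(D: DistanceMatrix, path) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{D.n}\n")
        for i, rid in enumerate(D.ids):
            row = " ".join(f"{x:.6f}" for x in D.d[i])
            fh.write(f"{rid}  {row}\n")


def write_distances_tsv(D: DistanceMatrix, path) -> None:
    pd.DataFrame(D.d, index=D.ids, columns=D.ids).to_csv(path, sep="\t")


def write_curation_report(rows: Sequence[Mapping], path) -> None:
    """One row per removed/collapsed/overridden record with its reason."""
    columns = ["id", "action", "detail"]
    pd.DataFrame(list(rows), columns=columns).to_csv(path, sep="\t", index=False)


def write_propagation_report(table: pd.DataFrame, counts: Mapping, path) -> None:
    table.to_csv(path, sep="\t", index=False)
    summary_path = Path(path).with_suffix(".counts.json")
    summary_path.write_text(json.dumps(dict(counts), indent=2, sort_keys=True) + "\n")


def write_itol_colorstrip(
    entries: Mapping,
    path,
    colors: Optional[Mapping[str, str]] = None,
    dataset_label: str = "ligand_class",
) -> None:
    """iTOL color-strip dataset: one line per tip, colored by chemical class."""
    colors = dict(DEFAULT_CLASS_COLORS, **(colors or {}))
    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset_label}",
        "COLOR\t#000000",
        "DATA",
    ]
    for tip in sorted(entries):
        chem = entries[tip].label.chem_class.value
        lines.append(f"{tip}\t{colors.get(chem, colors['unknown'])}\t{chem}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_species_restriction_report(restrictions, path) -> None:
    rows = [
        {
            "verdict": sr.verdict,
            "support": sr.support,
            "n_tips": len(sr.clade),
            "species": ";".join(sorted(sr.species)),
            "tips": ";".join(sorted(sr.clade)),
        }
        for sr in restrictions
    ]
    pd.DataFrame(rows, columns=["verdict", "support", "n_tips", "species", "tips"]) \
        .to_csv(path, sep="\t", index=False)
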