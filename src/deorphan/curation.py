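"""Record-level curation of a transporter gene-family sequence set.

Mirrors the manual curation steps applied to UNIPROT-derived SLC25
(mitochondrial carrier) sequence sets before tree building: drop
truncated records below a length cutoff, collapse near-identical
duplicates, trim each protein to the region spanned by its Solcar
repeat domains, and patch individual records known to be mis-curated
upstream (e.g. a frameshift-truncated strain variant replaced by the
full-length protein from another strain).

All coordinates are 1-based inclusive, following the UNIPROT feature
convention.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from .pairwise import global_align, p_distance_pair

logger = logging.getLogger(__name__)

#: Amino-acid alphabet accepted in curated records. ``X`` marks an
#: unknown residue and is scored as a mismatch wherever identity or
#: p-distance is computed.
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Default length cutoff (residues) below which a record is considered
#: an obvious truncation. A functional carrier monomer is ~300 aa; 200
#: is a deliberately loose cutoff that tolerates shortened hydrophilic
#: loops.
DEFAULT_MIN_LENGTH = 200

#: Default p-distance below which two records are considered duplicate
#: entries of the same protein (>99.5% identical).
DEFAULT_DUPLICATE_THRESHOLD = 0.005


class ChemClass(str, Enum):
    """Chemical class of a transported ligand."""

    NUCLEOTIDE = "nucleotide"
    AMINO_ACID = "amino_acid"
    CARBOXYLATE = "carboxylate"
    COFACTOR = "cofactor"
    INORGANIC_ION = "inorganic_ion"
    PROTON = "proton"
    UNKNOWN = "unknown"


class Evidence(str, Enum):
    """Provenance tier of a ligand assignment."""

    EXPERIMENTAL = "experimental"
    PROPAGATED = "propagated"
    CLASS_LEVEL = "class_level"
    ORPHAN = "orphan"


@dataclass(frozen=True)
class LigandLabel:
    """A transported-ligand assignment with its chemical class and evidence tier."""

    ligand: str
    chem_class: ChemClass = ChemClass.UNKNOWN
    evidence: Evidence = Evidence.EXPERIMENTAL

    def __post_init__(self) -> None:
        if self.chem_class == ChemClass.UNKNOWN and self.ligand not in ("", "orphan"):
            raise ValueError(
                "a label of unknown chemical class must have ligand '' or 'orphan', "
                f"got {self.ligand!r}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """One curated protein sequence.

    Parameters
    ----------
    id : str
        Accession.
    species : str
        Species mnemonic (e.g. ``HUMAN``, ``YEAST``, ``DANRE``, ``DROME``,
        ``CAEEL``).
    sequence : str
        Amino-acid sequence over :data:`ALPHABET`.
    domain_intervals : tuple of (int, int)
        Ordered, non-overlapping 1-based inclusive intervals marking the
        Solcar repeats (at most three expected).
    label : LigandLabel, optional
        Experimentally established ligand, if any.
    reviewed : bool
        Whether the source database entry was manually reviewed.
    """

    id: str
    species: str
    sequence: str
    domain_intervals: tuple = ()
    label: Optional[LigandLabel] = None
    reviewed: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id}: invalid residues {sorted(bad)!r}"
            )
        ivs = tuple(tuple(iv) for iv in self.domain_intervals)
        object.__setattr__(self, "domain_intervals", ivs)
        last_end = 0
        for start, end in ivs:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"record {self.id}: interval ({start},{end}) outside [1,{len(self.sequence)}]"
                )
            if start <= last_end:
                raise ValueError(
                    f"record {self.id}: intervals overlap or are unsorted at ({start},{end})"
                )
            last_end = end
        if len(ivs) > 3:
            logger.warning(
                "record %s: %d Solcar intervals (at most 3 expected)",
                self.id, len(ivs),
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Override:
    """Replace one record by a hand-curated substitute (with a reason)."""

    target_id: str
    replacement: ProteinRecord
    reason: str = ""


@dataclass(frozen=True)
class OverrideTable:
    overrides: tuple = ()

    def __post_init__(self) -> None:
        ovs = tuple(self.overrides)
        object.__setattr__(self, "overrides", ovs)
        targets = [o.target_id for o in ovs]
        if len(targets) != len(set(targets)):
            raise ValueError("override target ids must be unique")

    def __iter__(self):
        return iter(self.overrides)

    def __len__(self) -> int:
        return len(self.overrides)


def filter_by_length(records: Sequence[ProteinRecord], min_len: int = DEFAULT_MIN_LENGTH):
    """Split ``records`` into (kept, removed) by full-sequence length.

    Records of length >= ``min_len`` are kept; input order is preserved
    on both sides.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in records if len(r) >= min_len]
    removed = [r for r in records if len(r) < min_len]
    return kept, removed


def record_p_distance(a: ProteinRecord, b: ProteinRecord, **align_kwargs) -> float:
    """p-distance between two records via global alignment.

    The records are globally aligned (affine-gap Needleman–Wunsch) and
    the p-distance taken over columns where both rows carry a residue.
    """
    aln = global_align(a.sequence, b.sequence, id_a=a.id, id_b=b.id, **align_kwargs)
    return p_distance_pair(aln.aligned_a, aln.aligned_b)


def collapse_duplicates(
    records: Sequence[ProteinRecord],
    threshold: float = DEFAULT_DUPLICATE_THRESHOLD,
    **align_kwargs,
):
    """Collapse near-identical records (p-distance < ``threshold``).

    Clustering is single-linkage over the "distance < threshold"
    relation. Each cluster keeps one representative chosen by priority:
    reviewed entries first, then the longest sequence, then the
    lexicographically smallest id. Returns ``(kept, collapsed_pairs)``
    where each collapsed pair is ``(kept_id, dropped_id, distance)``
    with the distance between the dropped record and its
    representative.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    recs = list(records)
    n = len(recs)
    dist: dict[tuple[int, int], float] = {}

    def d(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in dist:
            dist[key] = record_p_distance(recs[key[0]], recs[key[1]], **align_kwargs)
        return dist[key]

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if d(i, j) < threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    keep_index: set[int] = set()
    collapsed: list[tuple[str, str, float]] = []
    for members in clusters.values():
        rep = min(
            members,
            key=lambda i: (not recs[i].reviewed, -len(recs[i]), recs[i].id),
        )
        keep_index.add(rep)
        for i in sorted(members, key=lambda i: recs[i].id):
            if i != rep:
                collapsed.append((recs[rep].id, recs[i].id, d(rep, i)))
                logger.info(
                    "collapsed duplicate %s into %s (p-distance %.5f)",
                    recs[i].id, recs[rep].id, d(rep, i),
                )

    kept = [r for i, r in enumerate(recs) if i in keep_index]
    return kept, collapsed


def trim_to_core(record: ProteinRecord) -> ProteinRecord:
    """Trim a record to the span of its Solcar domain intervals.

    Keeps the substring from the first interval's start to the last
    interval's end (removing e.g. N-terminal EF-hand extensions) and
    re-offsets the intervals. A record with no annotated intervals is
    returned unchanged with a warning — missing annotation is not a
    failure.
    """
    if not record.domain_intervals:
        logger.warning("record %s: no domain intervals, not trimmed", record.id)
        return record
    start = record.domain_intervals[0][0]
    end = record.domain_intervals[-1][1]
    if start == 1 and end == len(record.sequence):
        return record
    seq = record.sequence[start - 1:end]
    intervals = tuple((s - start + 1, e - start + 1) for s, e in record.domain_intervals)
    return replace(record, sequence=seq, domain_intervals=intervals)


def apply_overrides(records: Sequence[ProteinRecord], overrides: OverrideTable):
    """Apply per-record replacements; unknown targets are skipped with a warning."""
    by_target = {o.target_id: o for o in overrides}
    out: list[ProteinRecord] = []
    applied: list[Override] = []
    for rec in records:
        ov = by_target.pop(rec.id, None)
        if ov is None:
            out.append(rec)
        else:
            out.append(ov.replacement)
            applied.append(ov)
            logger.info(
                "override: replaced %s with %s (%s)",
                rec.id, ov.replacement.id, ov.reason or "no reason given",
            )
    for missing in by_target.values():
        logger.warning(
            "override target %s not present in record set; skipped",
            missing.target_id,
        )
    return out
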