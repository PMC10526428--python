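"""Clade-support ligand-label propagation and species-restriction reports.

The central inference of the pipeline: a transporter whose ligand is
experimentally established anchors its clade, and the label is expanded
to the other members of the largest enclosing clade whose bootstrap
support exceeds a propagation threshold (strict ``> s_prop``, default
90) without meeting a conflicting experimental label. When expansion is
blocked by a different ligand of the same chemical class, the smallest
sufficiently supported clade containing both sources receives a
class-level annotation instead. Tips reached by no label are orphans.
A second, lower threshold (``> s_conf``, default 70) separates high-
from low-confidence assignments.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .curation import ChemClass, Evidence, LigandLabel
from .tree import Node, PhyloTree

logger = logging.getLogger(__name__)

DEFAULT_S_PROP = 90
DEFAULT_S_CONF = 70


@dataclass(frozen=True)
class PropEntry:
    """Final annotation of one tip."""

    tip: str
    label: LigandLabel
    sources: tuple = ()
    clade: Optional[frozenset] = None
    min_support: Optional[int] = None
    tier: Optional[str] = None  # "high" / "low" for inferred labels


@dataclass
class PropagationResult:
    entries: dict
    orphans: list
    conflicts: list
    s_prop: int = DEFAULT_S_PROP
    s_conf: int = DEFAULT_S_CONF

    def by_evidence(self, evidence: Evidence) -> list:
        return sorted(t for t, e in self.entries.items() if e.label.evidence == evidence)


@dataclass(frozen=True)
class SpeciesRestriction:
    """A well-supported clade whose members span only part of the species set."""

    clade: frozenset
    species: frozenset
    verdict: str
    support: int


def enumerate_clades(tree: PhyloTree, exclude: Iterable[str] = ()):
    """All internal-node clades of a rooted tree as (tipset, support, node).

    ``exclude`` removes tips (e.g. the outgroup) from every clade's tip
    set. One triple per internal node, root included (support None).
    """
    if not tree.rooted:
        raise ValueError("clade enumeration requires a rooted tree")
    drop = frozenset(exclude)
    lsm = tree.leafset_map()
    out = []
    for node in tree.preorder():
        if node.is_leaf:
            continue
        out.append((lsm[node] - drop, node.support, node))
    return out


def _tier(min_support: Optional[int], s_conf: int) -> Optional[str]:
    if min_support is None:
        return None
    return "high" if min_support > s_conf else "low"


def propagate_labels(
    tree: PhyloTree,
    labels: Mapping[str, LigandLabel],
    s_prop: int = DEFAULT_S_PROP,
    s_conf: int = DEFAULT_S_CONF,
    class_fallback: bool = True,
    exclude: Iterable[str] = (),
) -> PropagationResult:
    """Propagate experimental ligand labels across high-support clades.

    A clade is *accepted* for a labeled source tip when it contains the
    tip, its support is strictly above ``s_prop``, and its subtree
    contains no experimental label with a different ligand. The source's
    ligand expands to every unlabeled tip of the maximal accepted clade
    (evidence ``propagated``; ``min_support`` is the minimum support
    over the accepted clades, all above the threshold). Ancestors whose
    support does not clear the threshold are skipped — expansion is
    justified by the supported clade itself, not by its internal
    resolution — but the first threshold-clearing ancestor that does
    contain a conflicting label blocks the ascent for good (any higher
    clade inherits the conflict). When that blocking conflict is a
    different ligand of the same chemical class, the blocking clade —
    the smallest sufficiently supported clade containing both sources —
    gives its remaining unlabeled tips a class-level label. Tips reached
    by nothing are orphans. The root carries no support, so no
    justification can pass through it; ``exclude`` tips (the outgroup)
    take no part at all. Deterministic: sources are processed in
    lexicographic id order.
    """
    if not tree.rooted:
        raise ValueError("propagation requires a rooted tree")
    for bound, name in ((s_prop, "s_prop"), (s_conf, "s_conf")):
        if not 0 <= bound <= 100:
            raise ValueError(f"{name} must be in [0, 100]")
    leaf_names = set(tree.leaf_names())
    drop = frozenset(exclude)
    exp: dict[str, LigandLabel] = {}
    for tip, label in labels.items():
        if tip not in leaf_names:
            raise ValueError(f"label given for non-leaf id {tip!r}")
        if tip in drop:
            continue
        exp[tip] = LigandLabel(label.ligand, label.chem_class, Evidence.EXPERIMENTAL)

    lsm = tree.leafset_map()
    leaf_node = {leaf.name: leaf for leaf in tree.leaves()}

    # per-tip best ligand proposal: tip -> [ligand, chem_class, set(sources), clade, min_support]
    proposals: dict[str, list] = {}
    conflicts: list[dict] = []
    class_events: list[tuple[frozenset, int, ChemClass, str, str]] = []
    maximal_clade: dict[str, frozenset] = {}

    for source in sorted(exp):
        lig = exp[source].ligand
        accepted: list[Node] = []
        node = leaf_node[source].parent
        while node is not None:
            support = node.support
            if node is tree.root:
                break
            if support is None or not support > s_prop:
                node = node.parent  # unsupported ancestor: skip, keep climbing
                continue
            tips_here = lsm[node] - drop
            blockers = sorted(
                t for t in tips_here if t in exp and exp[t].ligand != lig
            )
            if blockers:
                for blocker in blockers:
                    conflicts.append({
                        "kind": "blocked_by_conflicting_ligand",
                        "source": source,
                        "blocker": blocker,
                        "source_ligand": lig,
                        "blocker_ligand": exp[blocker].ligand,
                        "clade_support": support,
                    })
                    same_class = (
                        exp[blocker].chem_class == exp[source].chem_class
                        and exp[source].chem_class != ChemClass.UNKNOWN
                    )
                    if class_fallback and same_class:
                        class_events.append(
                            (frozenset(tips_here), support,
                             exp[source].chem_class, source, blocker)
                        )
                break
            accepted.append(node)
            node = node.parent

        if not accepted:
            continue
        top = accepted[-1]
        clade = frozenset(lsm[top] - drop)
        maximal_clade[source] = clade
        min_support = min(n.support for n in accepted)
        for tip in sorted(clade):
            if tip in exp:
                continue
            prev = proposals.get(tip)
            if prev is None:
                proposals[tip] = [lig, exp[source].chem_class, {source}, clade, min_support]
            else:
                # two different ligands reaching one tip would require two
                # overlapping non-nested maximal clades, impossible in a tree
                assert prev[0] == lig, (
                    f"tip {tip} reachable from ligands {prev[0]!r} and {lig!r}"
                )
                prev[2].add(source)
                if min_support > prev[4]:
                    prev[3], prev[4] = clade, min_support

    # same-ligand sources that do not share an accepted clade: note, don't fail
    by_ligand: dict[str, list] = {}
    for source in sorted(exp):
        by_ligand.setdefault(exp[source].ligand, []).append(source)
    for lig, sources in sorted(by_ligand.items()):
        for i in range(len(sources)):
            for j in range(i + 1, len(sources)):
                a, b = sources[i], sources[j]
                ca, cb = maximal_clade.get(a), maximal_clade.get(b)
                if (ca is None or b not in ca) and (cb is None or a not in cb):
                    conflicts.append({
                        "kind": "non_monophyletic_sources",
                        "ligand": lig, "source": a, "blocker": b,
                    })

    entries: dict[str, PropEntry] = {}
    for tip in sorted(exp):
        entries[tip] = PropEntry(
            tip=tip, label=exp[tip], sources=(tip,), clade=None,
            min_support=None, tier=None,
        )
    for tip, (lig, chem, sources, clade, min_support) in sorted(proposals.items()):
        entries[tip] = PropEntry(
            tip=tip,
            label=LigandLabel(lig, chem, Evidence.PROPAGATED),
            sources=tuple(sorted(sources)),
            clade=clade,
            min_support=min_support,
            tier=_tier(min_support, s_conf),
        )

    # class-level fallback on still-unlabeled tips of conflict clades
    for clade, support, chem, source, blocker in sorted(
        class_events, key=lambda e: (len(e[0]), sorted(e[0]), e[3], e[4])
    ):
        for tip in sorted(clade):
            if tip in entries:
                continue
            entries[tip] = PropEntry(
                tip=tip,
                label=LigandLabel("", chem, Evidence.CLASS_LEVEL),
                sources=(source, blocker),
                clade=clade,
                min_support=support,
                tier=_tier(support, s_conf),
            )

    orphans = sorted(
        tip for tip in leaf_names - drop if tip not in entries
    )
    for tip in orphans:
        entries[tip] = PropEntry(
            tip=tip,
            label=LigandLabel("orphan", ChemClass.UNKNOWN, Evidence.ORPHAN),
            sources=(), clade=None, min_support=None, tier=None,
        )

    return PropagationResult(
        entries=entries, orphans=orphans, conflicts=conflicts,
        s_prop=s_prop, s_conf=s_conf,
    )


def species_restriction(
    tree: PhyloTree,
    species_of: Mapping[str, str],
    species_groups: Optional[Mapping[str, Iterable[str]]] = None,
    s_conf: int = DEFAULT_S_CONF,
    exclude: Iterable[str] = (),
    species_universe: Optional[Iterable[str]] = None,
) -> list:
    """Well-supported clades whose species content is restricted.

    For every maximal clade with support strictly above ``s_conf``
    whose species set is a strict subset of the species universe, emit
    a verdict: ``single-species`` for one species, ``<group>-restricted``
    when the set lies within a configured group (e.g.
    ``vertebrates={HUMAN, DANRE}``), else ``species-restricted``.
    Clades spanning all species emit nothing; nested clades with the
    same verdict report only the outermost.
    """
    drop = frozenset(exclude)
    tips = [t for t in tree.leaf_names() if t not in drop]
    missing = [t for t in tips if t not in species_of]
    if missing:
        raise ValueError(f"missing species mapping for {missing[:5]!r}")
    universe = frozenset(species_universe) if species_universe is not None else \
        frozenset(species_of[t] for t in tips)
    groups = {g: frozenset(s) for g, s in (species_groups or {}).items()}

    qualifying = []
    for tipset, support, _node in enumerate_clades(tree, exclude=drop):
        if support is None or not support > s_conf or len(tipset) < 2:
            continue
        species = frozenset(species_of[t] for t in tipset)
        if species >= universe:
            continue
        if len(species) == 1:
            verdict = "single-species"
        else:
            matching = sorted(
                (len(members), name) for name, members in groups.items()
                if species <= members
            )
            verdict = f"{matching[0][1]}-restricted" if matching else "species-restricted"
        qualifying.append(SpeciesRestriction(
            clade=tipset, species=species, verdict=verdict, support=support,
        ))

    maximal = [
        sr for sr in qualifying
        if not any(
            other is not sr and sr.clade < other.clade and other.verdict == sr.verdict
            for other in qualifying
        )
    ]
    return sorted(maximal, key=lambda sr: (-len(sr.clade), sorted(sr.clade)))


def summarize(
    result: PropagationResult,
    species_of: Optional[Mapping[str, str]] = None,
):
    """Per-tip report table plus counts by evidence tier.

    Returns ``(DataFrame, counts)``: one row per tip sorted by id with
    columns id, species, ligand, chem_class, evidence, min_support and
    a deterministic clade id, and a dict of evidence-tier counts that
    sum to the tip count.
    """
    clade_ids: dict[frozenset, str] = {}
    for entry in sorted(result.entries.values(), key=lambda e: e.tip):
        if entry.clade is not None and entry.clade not in clade_ids:
            clade_ids[entry.clade] = f"C{len(clade_ids) + 1}"
    rows = []
    for tip in sorted(result.entries):
        entry = result.entries[tip]
        rows.append({
            "id": tip,
            "species": (species_of or {}).get(tip, ""),
            "ligand": entry.label.ligand,
            "chem_class": entry.label.chem_class.value,
            "evidence": entry.label.evidence.value,
            "min_support": entry.min_support if entry.min_support is not None else "",
            "tier": entry.tier or "",
            "sources": ";".join(entry.sources),
            "clade": clade_ids.get(entry.clade, ""),
        })
    table = pd.DataFrame(rows)
    counts = {ev.value: 0 for ev in Evidence}
    for entry in result.entries.values():
        counts[entry.label.evidence.value] += 1
    return table, counts
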