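"""Synthetic transporter gene families with known ground truth.

The generator encodes the evolutionary structure the analysis assumes
of a metabolite-carrier family: ligand-defined subfamilies that
diverged before the species radiation, each carrying a disjoint set of
subfamily-specific signature residues (the sequence correlate of ligand
specificity), with one ortholog per species evolved along a fixed
species topology at a much lower rate than the subfamily divergence.
Curation decoys (near-duplicate and truncated records) and an
unrelated outgroup sequence are appended so the full pipeline —
curation, tree building, rooting, propagation — can be exercised
end to end against known labels.

The substitution process is deliberately minimal: per branch, a
Poisson(rate x sites) number of hits lands uniformly (with
replacement) on the non-signature positions, each replacing the
current residue with one of the 19 alternatives uniformly. No indels,
no rate heterogeneity, no duplication/loss — so the true alignment is
the identity alignment and every subfamily is monophyletic by
construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .curation import ChemClass, Evidence, LigandLabel, ProteinRecord
from .pairwise import AlignmentMatrix
from .tree import Node, PhyloTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: The five proteomes surveyed: human, zebrafish, fruit fly, roundworm,
#: budding yeast.
DEFAULT_SPECIES = ("HUMAN", "DANRE", "DROME", "CAEEL", "YEAST")

#: Fixed species topology used within every subfamily:
#: vertebrates (HUMAN, DANRE) vs protostomes (DROME, CAEEL), yeast outside.
DEFAULT_SPECIES_TOPOLOGY = ((("HUMAN", "DANRE"), ("DROME", "CAEEL")), "YEAST")

#: Ligand chemical classes cycled over subfamilies.
CHEM_CYCLE = (
    ChemClass.NUCLEOTIDE,
    ChemClass.AMINO_ACID,
    ChemClass.CARBOXYLATE,
    ChemClass.COFACTOR,
    ChemClass.INORGANIC_ION,
    ChemClass.PROTON,
)

#: Near-duplicate decoys mutate this fraction of sites — inside the
#: 0.005 duplicate-collapse radius.
DECOY_DUPLICATE_MUTATION = 0.003

#: Truncation decoys keep this many residues (below the 200-aa cutoff).
DECOY_TRUNCATION_LENGTH = 150


@dataclass(frozen=True)
class SyntheticFamilyConfig:
    """Parameters of one simulated gene family.

    Defaults follow the study conditions of the analysis this package
    supports: five model-organism proteomes, ~300-aa carrier cores, 10%
    of positions fixed per subfamily as ligand-signature residues, deep
    subfamily divergence (0.5 substitutions/site per subfamily branch)
    against shallow species divergence (0.05 per species-tree branch),
    and exactly one experimentally labeled representative per subfamily
    in a designated well-studied species.
    """

    n_subfamilies: int = 8
    species: tuple = DEFAULT_SPECIES
    seq_length: int = 300
    signature_fraction: float = 0.10
    sub_rate_subfamily: float = 0.5
    sub_rate_species: float = 0.05
    decoy_duplicates: int = 3
    decoy_truncations: int = 2
    representative_species: str = "HUMAN"
    outgroup_id: str = "MCU_HUMAN"
    species_topology: tuple = DEFAULT_SPECIES_TOPOLOGY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subfamilies < 1:
            raise ValueError("n_subfamilies must be >= 1")
        if len(self.species) < 2:
            raise ValueError("need at least two species")
        if not 0.0 <= self.signature_fraction <= 1.0:
            raise ValueError("signature_fraction must be in [0, 1]")
        if self.sub_rate_subfamily < 0 or self.sub_rate_species < 0:
            raise ValueError("substitution rates must be nonnegative")
        if self.representative_species not in self.species:
            raise ValueError("representative_species must be one of species")
        per = round(self.signature_fraction * self.seq_length)
        if per * self.n_subfamilies > self.seq_length:
            raise ValueError(
                f"{self.n_subfamilies} disjoint signature sets of {per} positions "
                f"exceed sequence length {self.seq_length}"
            )

    @property
    def signature_size(self) -> int:
        return round(self.signature_fraction * self.seq_length)


@dataclass
class TruthBundle:
    """Everything the simulator knows: records, alignment, tree, labels, decoys."""

    records: list
    msa: AlignmentMatrix
    true_tree: PhyloTree
    true_labels: dict
    decoy_manifest: list  # (record id, decoy kind)
    signature_map: dict  # subfamily index -> tuple of 0-based signature positions
    config: SyntheticFamilyConfig

    def experimental_labels(self) -> dict:
        """The labels handed to the pipeline: one representative per subfamily."""
        rep = self.config.representative_species
        return {
            tip: label for tip, label in self.true_labels.items()
            if tip.endswith(f"_{rep}")
        }

    def clean_tip_ids(self) -> list:
        decoys = {d for d, _ in self.decoy_manifest}
        return sorted(
            r.id for r in self.records
            if r.id not in decoys and r.id != self.config.outgroup_id
        )

    def subfamily_tips(self, k: int) -> list:
        return sorted(t for t in self.clean_tip_ids() if t.startswith(f"SF{k + 1}_"))


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """Apply one substitution per entry of ``positions`` (in order, in place)."""
    for pos in positions:
        current = seq[pos]
        repl = rng.integers(0, 19)
        if repl >= current:
            repl += 1
        seq[pos] = repl


def _evolve(
    seq: np.ndarray,
    rate: float,
    sites: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch: Poisson(rate x |sites|) uniform hits on ``sites``."""
    child = seq.copy()
    if rate > 0 and sites.size:
        n_hits = rng.poisson(rate * sites.size)
        if n_hits:
            hit_sites = sites[rng.integers(0, sites.size, size=n_hits)]
            _mutate(child, hit_sites, rng)
    return child


def _decode(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in seq)


def _species_node(topology, lengths: float) -> Node:
    if isinstance(topology, str):
        return Node(name=topology, length=lengths)
    node = Node(length=lengths)
    for part in topology:
        node.add_child(_species_node(part, lengths))
    return node


def _evolve_species_tree(
    topology,
    ancestor: np.ndarray,
    rate: float,
    sites: np.ndarray,
    rng: np.random.Generator,
) -> dict:
    """Recursively evolve one sequence per species along the topology."""
    seq = _evolve(ancestor, rate, sites, rng)
    if isinstance(topology, str):
        return {topology: seq}
    out: dict = {}
    for part in topology:
        out.update(_evolve_species_tree(part, seq, rate, sites, rng))
    return out


def simulate_family(config: SyntheticFamilyConfig) -> TruthBundle:
    """Simulate one gene family with known subfamily structure and decoys.

    Deterministic given ``config.seed``. See the module docstring for
    the generative model.
    """
    rng = np.random.default_rng(config.seed)
    length = config.seq_length
    per = config.signature_size

    ancestral = rng.integers(0, 20, size=length)
    shuffled = rng.permutation(length)
    signature_map = {
        k: tuple(int(p) for p in sorted(shuffled[k * per:(k + 1) * per]))
        for k in range(config.n_subfamilies)
    }

    records: list[ProteinRecord] = []
    true_labels: dict[str, LigandLabel] = {}
    msa_ids: list[str] = []
    msa_rows: list[str] = []
    subfamily_nodes: list[Node] = []
    intervals = _thirds(length)

    for k in range(config.n_subfamilies):
        sig = np.asarray(signature_map[k], dtype=int)
        nonsig = np.setdiff1d(np.arange(length), sig)
        sub_ancestor = ancestral.copy()
        # subfamily-specific residues at the signature positions, frozen after
        sub_ancestor[sig] = rng.integers(0, 20, size=sig.size)
        sub_ancestor = _evolve(sub_ancestor, config.sub_rate_subfamily, nonsig, rng)

        tips = _evolve_species_tree(
            config.species_topology, sub_ancestor,
            config.sub_rate_species, nonsig, rng,
        )
        ligand = f"LIG_{k + 1}"
        chem = CHEM_CYCLE[k % len(CHEM_CYCLE)]
        for species in config.species:
            tip_id = f"SF{k + 1}_{species}"
            seq = _decode(tips[species])
            label = LigandLabel(ligand, chem, Evidence.EXPERIMENTAL)
            true_labels[tip_id] = label
            is_rep = species == config.representative_species
            records.append(ProteinRecord(
                id=tip_id, species=species, sequence=seq,
                domain_intervals=intervals,
                label=label if is_rep else None,
                reviewed=True,
            ))
            msa_ids.append(tip_id)
            msa_rows.append(seq)

        sub_node = Node(length=config.sub_rate_subfamily)
        for child in _build_species_clade(config.species_topology, k, config):
            sub_node.add_child(child)
        subfamily_nodes.append(sub_node)

    # decoys: near-duplicates then truncations, cycling over clean records
    decoy_manifest: list[tuple[str, str]] = []
    clean = list(records)
    n_mut = max(1, round(DECOY_DUPLICATE_MUTATION * length))
    for i in range(config.decoy_duplicates):
        src = clean[i % len(clean)]
        src_subfamily = int(src.id[2:src.id.index("_")]) - 1
        sig = np.asarray(signature_map[src_subfamily], dtype=int)
        nonsig = np.setdiff1d(np.arange(length), sig)
        seq = np.array([AMINO_ACIDS.index(c) for c in src.sequence])
        positions = rng.choice(nonsig, size=n_mut, replace=False)
        _mutate(seq, positions, rng)
        dup_id = f"{src.id}_DUP"
        records.append(ProteinRecord(
            id=dup_id, species=src.species, sequence=_decode(seq),
            domain_intervals=intervals, reviewed=False,
        ))
        decoy_manifest.append((dup_id, "near_duplicate"))
    for i in range(config.decoy_truncations):
        src = clean[(config.decoy_duplicates + i) % len(clean)]
        cut = min(DECOY_TRUNCATION_LENGTH, length - 1)
        seq = src.sequence[:cut]
        trunc_id = f"{src.id}_TRUNC"
        kept_ivs = tuple((s, e) for s, e in intervals if e <= cut)
        records.append(ProteinRecord(
            id=trunc_id, species=src.species, sequence=seq,
            domain_intervals=kept_ivs, reviewed=False,
        ))
        decoy_manifest.append((trunc_id, "truncation"))

    # unrelated outgroup, mirroring rooting on a non-homologous channel
    out_seq = rng.integers(0, 20, size=length)
    records.append(ProteinRecord(
        id=config.outgroup_id, species="HUMAN",
        sequence=_decode(out_seq), domain_intervals=intervals, reviewed=True,
    ))
    msa_ids.append(config.outgroup_id)
    msa_rows.append(_decode(out_seq))

    # true rooted tree: caterpillar over subfamilies, outgroup at the root
    family = subfamily_nodes[0]
    for sub_node in subfamily_nodes[1:]:
        joint = Node(length=config.sub_rate_subfamily)
        joint.add_child(family)
        joint.add_child(sub_node)
        family = joint
    root = Node()
    family.length = config.sub_rate_subfamily
    root.add_child(family)
    root.add_child(Node(name=config.outgroup_id, length=1.0))
    true_tree = PhyloTree(root, rooted=True)

    return TruthBundle(
        records=records,
        msa=AlignmentMatrix(msa_ids, msa_rows),
        true_tree=true_tree,
        true_labels=true_labels,
        decoy_manifest=decoy_manifest,
        signature_map=signature_map,
        config=config,
    )


def _thirds(length: int) -> tuple:
    """Three equal Solcar-like repeat intervals spanning the whole core."""
    third = length // 3
    return (
        (1, third),
        (third + 1, 2 * third),
        (2 * third + 1, length),
    )


def _build_species_clade(topology, k: int, config: SyntheticFamilyConfig) -> list:
    def build(part) -> Node:
        if isinstance(part, str):
            return Node(name=f"SF{k + 1}_{part}", length=config.sub_rate_species)
        node = Node(length=config.sub_rate_species)
        for sub in part:
            node.add_child(build(sub))
        return node

    return [build(part) for part in topology]


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well propagation recovered the simulated ground truth."""

    accuracy: float  # correct / propagated (1.0 when nothing propagated)
    coverage: float  # propagated / unlabeled non-decoy tips
    orphan_rate: float
    n_propagated: int
    n_correct: int
    n_unlabeled: int


def score_recovery(truth: TruthBundle, result) -> RecoveryMetrics:
    """Score a PropagationResult against the simulator's true labels.

    Decoys and the outgroup are excluded. Accuracy is over propagated
    tips only; coverage and orphan rate are over the unlabeled
    (non-representative) clean tips.
    """
    clean = set(truth.clean_tip_ids())
    known = set(truth.experimental_labels())
    eligible = sorted(clean - known)
    unknown_ids = set(result.entries) - clean - {truth.config.outgroup_id}
    if unknown_ids - {d for d, _ in truth.decoy_manifest}:
        raise ValueError(
            f"result contains ids not in the truth bundle: {sorted(unknown_ids)[:5]}"
        )
    n_prop = n_correct = n_orphan = 0
    for tip in eligible:
        entry = result.entries.get(tip)
        if entry is None or entry.label.evidence == Evidence.ORPHAN:
            n_orphan += 1
            continue
        if entry.label.evidence == Evidence.PROPAGATED:
            n_prop += 1
            if entry.label.ligand == truth.true_labels[tip].ligand:
                n_correct += 1
    n_unlabeled = len(eligible)
    return RecoveryMetrics(
        accuracy=n_correct / n_prop if n_prop else 1.0,
        coverage=n_prop / n_unlabeled if n_unlabeled else 0.0,
        orphan_rate=n_orphan / n_unlabeled if n_unlabeled else 0.0,
        n_propagated=n_prop,
        n_correct=n_correct,
        n_unlabeled=n_unlabeled,
    )
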