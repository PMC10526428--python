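"""Clade-support label propagation, species restriction, and summaries."""
import numpy as np
import pytest

from deorphan import (
    ChemClass, Evidence, LigandLabel, enumerate_clades, propagate_labels,
    species_restriction, summarize,
)
from deorphan.tree import PhyloTree
from oracles import oracle_propagate, random_labeled_tree, summarize_result


def lab(ligand, chem=ChemClass.NUCLEOTIDE):
    return LigandLabel(ligand, chem, Evidence.EXPERIMENTAL)


def tree_two_cherries(support_left=95, support_right=60):
    return PhyloTree.from_newick(
        f"((t1:1,t2:1){support_left}:1,(t3:1,t4:1){support_right}:1);", rooted=True
    )


class TestPropagation:
    def test_high_support_cherry_propagates(self):
        """An experimental label expands to the sister tip of a >90 clade;
        tips in the unsupported clade stay orphans."""
        result = propagate_labels(tree_two_cherries(), {"t1": lab("ADP/ATP")})
        e = result.entries
        assert e["t1"].label.evidence == Evidence.EXPERIMENTAL
        assert e["t2"].label.ligand == "ADP/ATP"
        assert e["t2"].label.evidence == Evidence.PROPAGATED
        assert e["t2"].min_support == 95 and e["t2"].tier == "high"
        assert result.orphans == ["t3", "t4"]

    def test_support_exactly_at_threshold_blocks(self):
        """Threshold is strict: support 90 does not clear s_prop=90."""
        result = propagate_labels(tree_two_cherries(90), {"t1": lab("ADP/ATP")})
        assert result.entries["t2"].label.evidence == Evidence.ORPHAN
        assert "t2" in result.orphans

    def amino_acid_tree(self, third_cherry=False):
        inner = "(t1:1,t2:1)99:1,(t3:1,t4:1)99:1"
        if third_cherry:
            inner += ",(t5:1,t6:1)99:1"
        return PhyloTree.from_newick(f"(({inner})95:1,og:9);", rooted=True)

    def test_same_class_conflict_keeps_ligand_level_labels(self):
        tree = self.amino_acid_tree()
        labels = {
            "t1": lab("glutathione", ChemClass.AMINO_ACID),
            "t3": lab("glycine", ChemClass.AMINO_ACID),
        }
        result = propagate_labels(tree, labels, exclude=("og",))
        e = result.entries
        assert e["t2"].label.ligand == "glutathione"
        assert e["t4"].label.ligand == "glycine"
        assert all(x.label.evidence != Evidence.CLASS_LEVEL for x in e.values())
        assert any(c["kind"] == "blocked_by_conflicting_ligand" for c in result.conflicts)

    def test_same_class_conflict_gives_class_level_fallback(self):
        """A third unlabeled subclade inside the conflicted >90 clade gets a
        class-level (amino acid) label rather than either ligand."""
        tree = self.amino_acid_tree(third_cherry=True)
        labels = {
            "t1": lab("glutathione", ChemClass.AMINO_ACID),
            "t3": lab("glycine", ChemClass.AMINO_ACID),
        }
        result = propagate_labels(tree, labels, exclude=("og",))
        for tip in ("t5", "t6"):
            entry = result.entries[tip]
            assert entry.label.evidence == Evidence.CLASS_LEVEL
            assert entry.label.chem_class == ChemClass.AMINO_ACID
            assert entry.label.ligand == ""
            assert entry.min_support == 95
        # matches the clade-enumeration oracle as well
        assert summarize_result(result) == oracle_propagate(
            tree, labels, 90, exclude=("og",)
        )

    def test_class_fallback_can_be_disabled(self):
        tree = self.amino_acid_tree(third_cherry=True)
        labels = {
            "t1": lab("glutathione", ChemClass.AMINO_ACID),
            "t3": lab("glycine", ChemClass.AMINO_ACID),
        }
        result = propagate_labels(tree, labels, class_fallback=False, exclude=("og",))
        assert result.entries["t5"].label.evidence == Evidence.ORPHAN

    def test_unrooted_tree_rejected(self):
        tree = PhyloTree.from_newick("(t1:1,t2:1,(t3:1,t4:1)95:1);", rooted=False)
        with pytest.raises(ValueError):
            propagate_labels(tree, {"t1": lab("X", ChemClass.COFACTOR)})

    def test_label_for_unknown_tip_rejected(self):
        with pytest.raises(ValueError):
            propagate_labels(tree_two_cherries(), {"zz": lab("ADP/ATP")})

    def test_matches_oracle_on_random_trees(self):
        """Tree-walking propagation equals set-based clade enumeration on
        random rooted trees with random supports and labels."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            tree, labels = random_labeled_tree(rng)
            for s_prop in (50, 90):
                result = propagate_labels(tree, labels, s_prop=s_prop)
                assert summarize_result(result) == oracle_propagate(tree, labels, s_prop)

    def test_monotone_in_propagation_threshold(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            tree, labels = random_labeled_tree(rng)
            counts = [
                len(propagate_labels(tree, labels, s_prop=s).by_evidence(Evidence.PROPAGATED))
                for s in (50, 70, 90, 99)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_experimental_labels_immutable(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tree, labels = random_labeled_tree(rng)
            result = propagate_labels(tree, labels)
            for tip, label in labels.items():
                entry = result.entries[tip]
                assert entry.label.ligand == label.ligand
                assert entry.label.evidence == Evidence.EXPERIMENTAL


class TestEnumerateClades:
    def test_balanced_four_tip_count(self):
        clades = enumerate_clades(tree_two_cherries())
        assert len(clades) == 3  # root + two cherries
        root_entries = [c for c in clades if c[1] is None]
        assert len(root_entries) == 1

    def test_caterpillar_count(self):
        tree = PhyloTree.from_newick(
            "((((t1:1,t2:1)90:1,t3:1)80:1,t4:1)70:1,t5:1);", rooted=True
        )
        assert len(enumerate_clades(tree)) == 4

    def test_laminar_family(self):
        rng = np.random.default_rng(8)
        tree, _ = random_labeled_tree(rng)
        sets = [c[0] for c in enumerate_clades(tree)]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                assert a <= b or b <= a or not (a & b)


class TestSpeciesRestriction:
    GROUPS = {"vertebrate": ("HUMAN", "DANRE")}

    def species_tree(self):
        # one >70 clade of human+zebrafish tips, one clade spanning all species
        return PhyloTree.from_newick(
            "((a_HUMAN:1,b_DANRE:1)95:1,((c_HUMAN:1,d_YEAST:1)92:1,"
            "(e_DROME:1,f_CAEEL:1)91:1)85:1);",
            rooted=True,
        )

    def species_of(self, tree):
        return {t: t.rsplit("_", 1)[1] for t in tree.leaf_names()}

    def test_vertebrate_restricted_clade_reported(self):
        tree = self.species_tree()
        out = species_restriction(tree, self.species_of(tree), self.GROUPS)
        verdicts = {sr.verdict: sr for sr in out}
        assert "vertebrate-restricted" in verdicts
        assert verdicts["vertebrate-restricted"].clade == frozenset({"a_HUMAN", "b_DANRE"})

    def test_clade_spanning_all_species_not_reported(self):
        tree = self.species_tree()
        out = species_restriction(tree, self.species_of(tree), self.GROUPS)
        for sr in out:
            assert sr.species != frozenset({"HUMAN", "DANRE", "DROME", "CAEEL", "YEAST"})

    def test_single_species_verdict(self):
        tree = PhyloTree.from_newick(
            "((a_HUMAN:1,b_HUMAN:1)95:1,(c_YEAST:1,d_DANRE:1)40:1);", rooted=True
        )
        out = species_restriction(tree, self.species_of(tree), self.GROUPS)
        assert [sr.verdict for sr in out] == ["single-species"]

    def test_missing_species_mapping_rejected(self):
        tree = self.species_tree()
        with pytest.raises(ValueError):
            species_restriction(tree, {"a_HUMAN": "HUMAN"}, self.GROUPS)


class TestSummarize:
    def test_counts_sum_to_tip_count(self):
        result = propagate_labels(tree_two_cherries(), {"t1": lab("ADP/ATP")})
        table, counts = summarize(result)
        assert sum(counts.values()) == len(table) == 4
        assert counts["propagated"] == 1 and counts["orphan"] == 2

    def test_all_experimental(self):
        labels = {t: lab("ADP/ATP") for t in ("t1", "t2", "t3", "t4")}
        _, counts = summarize(propagate_labels(tree_two_cherries(), labels))
        assert counts == {"experimental": 4, "propagated": 0, "class_level": 0, "orphan": 0}

    def test_no_labels_all_orphans(self):
        _, counts = summarize(propagate_labels(tree_two_cherries(), {}))
        assert counts["orphan"] == 4

    def test_rows_sorted_by_id(self):
        result = propagate_labels(tree_two_cherries(), {"t1": lab("ADP/ATP")})
        table, _ = summarize(result)
        assert list(table["id"]) == sorted(table["id"])
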