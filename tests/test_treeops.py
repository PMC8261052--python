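"""Tree reading, monophyly, taxonomy-constrained collapsing, trait counts."""

import numpy as np
import pandas as pd
import pytest

from merscreen.inventory import GenomeInventory
from merscreen.treeops import (
    TreeError,
    annotate_traits,
    collapse_by_rank,
    export_annotation,
    is_monophyletic,
    read_tree,
    write_tree,
)


def meta_for(tips: dict[str, str]) -> pd.DataFrame:
    """Metadata frame mapping tip -> phylum; one genome per tip."""
    return pd.DataFrame(
        [
            {
                "protein_id": t, "genome_id": f"g_{t}", "domain": "Bacteria",
                "phylum": phylum, "class": "",
            }
            for t, phylum in tips.items()
        ]
    )


def random_labeled_tree(rng, n_tips, n_labels):
    tips = {f"t{i}": f"p{rng.integers(n_labels)}" for i in range(n_tips)}
    nodes = [f"t{i}:1" for i in range(n_tips)]
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        nodes.append(f"({a},{b}):1")
    return nodes[0] + ";", tips


class TestReadTree:
    def test_three_tip_tree(self):
        t = read_tree("(A:1,(B:1,C:1):1);", meta_for({"A": "p", "B": "p", "C": "p"}))
        assert sorted(t.tip_labels) == ["A", "B", "C"]

    def test_malformed_newick_raises(self):
        with pytest.raises(TreeError):
            read_tree("((A,B);", meta_for({"A": "p", "B": "p"}))

    def test_unresolvable_tips_listed(self):
        with pytest.raises(TreeError, match="ZZZ"):
            read_tree("(A:1,ZZZ:1);", meta_for({"A": "p"}))

    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        newick = "((A:0.5,B:1.25):0.1,(C:2,D:0.75):0.2);"
        tips = {x: "p" for x in "ABCD"}
        t = read_tree(newick, meta_for(tips))
        path = tmp_path / "t.nwk"
        write_tree(t, path)
        t2 = read_tree(path.read_text(), meta_for(tips))

        def splits(at):
            out = set()
            for node in at.tree.preorder_node_iter():
                leaves = frozenset(l.taxon.label for l in node.leaf_iter())
                out.add((leaves, node.edge.length))
            return out

        assert splits(t) == splits(t2)

    def test_outgroup_rooting_makes_outgroup_a_clade(self):
        # Unrooted shape with the outgroup hanging off the basal
        # trifurcation; rooting on the outgroup edge must separate the
        # ingroup and the outgroup into sister clades.
        newick = "(A:1,(B:1,C:1):1,(OG1:1,OG2:1):1);"
        t = read_tree(
            newick, meta_for({"A": "p", "B": "p", "C": "p"}),
            outgroup=("OG1", "OG2"),
        )
        assert is_monophyletic(t, {"OG1", "OG2"})
        assert is_monophyletic(t, {"A", "B", "C"})

    def test_missing_outgroup_tip_raises(self):
        with pytest.raises(TreeError):
            read_tree(
                "(A:1,B:1);", meta_for({"A": "p", "B": "p"}), outgroup=("OG",)
            )


class TestMonophyly:
    def test_simple_cases(self):
        t = read_tree("((A:1,B:1):1,C:1);", meta_for({"A": "p", "B": "p", "C": "p"}))
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})
        assert is_monophyletic(t, {"A", "B", "C"})

    def test_empty_subset_rejected(self):
        t = read_tree("(A:1,B:1);", meta_for({"A": "p", "B": "p"}))
        with pytest.raises(TreeError):
            is_monophyletic(t, set())

    def test_agrees_with_exhaustive_clade_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            newick, tips = random_labeled_tree(rng, int(rng.integers(4, 13)), 3)
            t = read_tree(newick, meta_for(tips))
            clades = {
                frozenset(l.taxon.label for l in node.leaf_iter())
                for node in t.tree.preorder_node_iter()
            }
            names = sorted(tips)
            for _ in range(10):
                size = int(rng.integers(1, len(names) + 1))
                subset = frozenset(rng.choice(names, size=size, replace=False))
                assert is_monophyletic(t, subset) == (subset in clades)


class TestCollapse:
    def test_star_tree_single_phylum_collapses_fully(self):
        tips = {f"t{i}": "p1" for i in range(5)}
        newick = "(" + ",".join(f"t{i}:1" for i in range(5)) + ");"
        t = read_tree(newick, meta_for(tips))
        clades, reduced = collapse_by_rank(t)
        assert len(clades) == 1
        assert clades[0].k_id == "K01"
        assert clades[0].n_homologs == 5
        assert len([l for l in reduced.leaf_node_iter()]) == 1

    def test_label_stranded_tip_stays_single(self):
        # D shares A/B's phylum but sits in a clade with C (another
        # phylum), so only {A,B} collapses; C and D remain singletons.
        t = read_tree(
            "((A:1,B:1):1,(C:1,D:1):1);",
            meta_for({"A": "p1", "B": "p1", "C": "p2", "D": "p1"}),
        )
        clades, _ = collapse_by_rank(t)
        collapsed = [c for c in clades if c.k_id]
        singles = [c for c in clades if c.k_id is None]
        assert len(collapsed) == 1
        assert set(collapsed[0].member_tips) == {"A", "B"}
        assert sorted(s.member_tips[0] for s in singles) == ["C", "D"]

    def test_proteobacteria_collapse_at_class_level(self):
        meta = pd.DataFrame(
            [
                {"protein_id": t, "genome_id": f"g_{t}", "domain": "Bacteria",
                 "phylum": "Proteobacteria", "class": cls}
                for t, cls in [
                    ("A", "Gammaproteobacteria"), ("B", "Gammaproteobacteria"),
                    ("C", "Alphaproteobacteria"), ("D", "Alphaproteobacteria"),
                ]
            ]
        )
        t = read_tree("((A:1,B:1):1,(C:1,D:1):1);", meta)
        clades, _ = collapse_by_rank(t)
        assert {c.label for c in clades} == {
            "Gammaproteobacteria", "Alphaproteobacteria",
        }

    def test_k_labels_assigned_in_preorder(self):
        t = read_tree(
            "((A:1,B:1):1,(C:1,D:1):1);",
            meta_for({"A": "p1", "B": "p1", "C": "p2", "D": "p2"}),
        )
        clades, _ = collapse_by_rank(t)
        by_k = {c.k_id: set(c.member_tips) for c in clades if c.k_id}
        assert by_k == {"K01": {"A", "B"}, "K02": {"C", "D"}}

    def test_tip_conservation_and_maximality_on_random_trees(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            newick, tips = random_labeled_tree(rng, int(rng.integers(4, 16)), 3)
            t = read_tree(newick, meta_for(tips))
            clades, _ = collapse_by_rank(t)
            # Tip conservation.
            all_members = [m for c in clades for m in c.member_tips]
            assert sorted(all_members) == sorted(tips)
            # Maximality: no two same-label collapsed clades may jointly
            # form a larger monophyletic pure clade.
            collapsed = [c for c in clades if c.k_id]
            for i, c1 in enumerate(collapsed):
                for c2 in collapsed[i + 1:]:
                    if c1.label == c2.label:
                        union = set(c1.member_tips) | set(c2.member_tips)
                        assert not is_monophyletic(t, union)

    def test_mixed_clades_collapse_only_when_designated(self):
        tips = {"A": "p1", "B": "p2", "C": "p3", "D": "p3"}
        t = read_tree("((A:1,B:1):1,(C:1,D:1):1);", meta_for(tips))
        clades, _ = collapse_by_rank(t)
        assert all(c.label != "mixed" for c in clades)
        clades2, _ = collapse_by_rank(t, mixed_clades=[frozenset({"A", "B"})])
        mixed = [c for c in clades2 if c.label == "mixed"]
        assert len(mixed) == 1 and set(mixed[0].member_tips) == {"A", "B"}
        with pytest.raises(TreeError):
            collapse_by_rank(t, mixed_clades=[frozenset({"A", "C"})])

    def test_outgroup_tips_never_collapsed(self):
        tips = {"A": "p1", "B": "p1"}
        newick = "((A:1,B:1):1,(OG1:1,OG2:1):1);"
        t = read_tree(newick, meta_for(tips), outgroup=("OG1", "OG2"))
        clades, reduced = collapse_by_rank(t)
        assert {c.label for c in clades if c.k_id} == {"p1"}
        leaf_names = {l.taxon.label for l in reduced.leaf_node_iter()}
        assert {"OG1", "OG2"} <= leaf_names


class TestTraits:
    def make_invs(self, flags):
        return [
            GenomeInventory(
                genome_id=g, domain="Bacteria", phylum="p1", merA_count=1,
                merB_count=1 if kind == "B" else 0,
                merB_like_counts={"117alt": 1} if kind == "like" else {},
            )
            for g, kind in flags.items()
        ]

    def test_counts_distinct_genomes(self):
        t = read_tree(
            "((A:1,B:1):1,C:1);", meta_for({"A": "p1", "B": "p1", "C": "p1"})
        )
        clades, _ = collapse_by_rank(t)
        invs = self.make_invs({"g_A": "B", "g_B": "none", "g_C": "like"})
        (clade,) = annotate_traits(clades, t, invs)
        assert clade.n_genomes_with_merB == 1
        assert clade.n_genomes_with_merB_like == 1

    def test_one_genome_many_tips_counts_once(self):
        meta = pd.DataFrame(
            [
                {"protein_id": t, "genome_id": "g_one", "domain": "Bacteria",
                 "phylum": "p1", "class": ""}
                for t in ("A", "B", "C")
            ]
        )
        t = read_tree("((A:1,B:1):1,C:1);", meta)
        clades, _ = collapse_by_rank(t)
        invs = [
            GenomeInventory("g_one", "Bacteria", "p1", merA_count=3, merB_count=2)
        ]
        (clade,) = annotate_traits(clades, t, invs)
        assert clade.n_genomes_with_merB == 1

    def test_missing_genome_rejected(self):
        t = read_tree("(A:1,B:1);", meta_for({"A": "p1", "B": "p1"}))
        clades, _ = collapse_by_rank(t)
        with pytest.raises(TreeError):
            annotate_traits(clades, t, [])


class TestExport:
    def test_round_trip_clade_table(self, tmp_path):
        t = read_tree(
            "((A:1,B:1):1,C:1);", meta_for({"A": "p1", "B": "p1", "C": "p2"})
        )
        clades, reduced = collapse_by_rank(t)
        tsv = tmp_path / "clades.tsv"
        nwk = tmp_path / "reduced.nwk"
        export_annotation(clades, reduced, tsv, nwk)
        frame = pd.read_csv(tsv, sep="\t").fillna("")
        assert len(frame) == len(clades)
        assert list(frame["n_homologs"]) == [f"[{c.n_homologs}]" for c in clades]
        assert "K01_p1" in nwk.read_text()

    def test_empty_clade_list_gives_header_only(self, tmp_path):
        tsv = tmp_path / "empty.tsv"
        export_annotation([], None, tsv)
        frame = pd.read_csv(tsv, sep="\t")
        assert len(frame) == 0
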