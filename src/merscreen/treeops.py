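"""Taxonomy-constrained collapsing and trait annotation of phylogenies.

A large MerA phylogeny is summarised for display by collapsing each
maximal monophyletic clade whose tips all belong to one taxon — the
phylum, or the class for Proteobacteria — into a single pseudo-tip.
Collapsed clades receive sequential "K" identifiers in preorder
(root-to-tip, left-to-right) order and carry the number of member
homologs in brackets; tips that fall in no taxonomically uniform clade
of size >= 2 remain as singletons without a K identifier. Clades mixing
taxa are never collapsed automatically; explicitly supplied monophyletic
tip sets may be collapsed as "mixed" lineages.

Each collapsed clade can then be annotated with trait counts: how many
of its distinct member genomes also encode MerB, and how many encode
MerB-like variants — the presence boxes of the summary figure.

Trees are consumed as Newick (with branch lengths and optional support
values as internal-node labels) and never inferred here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import dendropy
import pandas as pd

from .inventory import GenomeInventory

__all__ = [
    "AnnotatedTree",
    "CollapsedClade",
    "TreeError",
    "read_tree",
    "write_tree",
    "is_monophyletic",
    "collapse_by_rank",
    "annotate_traits",
    "export_annotation",
]


class TreeError(ValueError):
    """Invalid tree input or tree operation."""


@dataclass(frozen=True)
class TipInfo:
    genome_id: str
    domain: str
    phylum: str = "unclassified"
    class_: str | None = None

    @property
    def rank_label(self) -> str:
        """Collapsing label: phylum, or class for Proteobacteria."""
        if self.phylum == "Proteobacteria" and self.class_:
            return self.class_
        return self.phylum


@dataclass
class AnnotatedTree:
    """A rooted phylogeny whose tips resolve to genomes and taxonomy."""

    tree: dendropy.Tree
    tips: dict[str, TipInfo]
    outgroup: tuple[str, ...] = ()

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )


@dataclass(frozen=True)
class CollapsedClade:
    label: str
    k_id: str | None
    n_homologs: int
    member_tips: tuple[str, ...]
    n_genomes_with_merB: int | None = None
    n_genomes_with_merB_like: int | None = None


def read_tree(
    newick: str,
    meta: pd.DataFrame,
    outgroup: tuple[str, ...] = (),
    tip_to_protein=None,
) -> AnnotatedTree:
    """Parse a Newick tree and resolve its tips against genome metadata.

    ``meta`` holds one row per protein (columns protein_id, genome_id,
    domain, phylum, class); ``tip_to_protein`` optionally maps a tip
    label to its protein id (default: identity). Outgroup tips, if
    given, need not resolve to metadata; the tree is rerooted on the
    edge above their most recent common ancestor.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"unparseable Newick: {exc}") from None
    tree.is_rooted = True

    tip_to_protein = tip_to_protein or (lambda label: label)
    by_protein = {
        row["protein_id"]: TipInfo(
            genome_id=row["genome_id"],
            domain=row["domain"],
            phylum=row.get("phylum") or "unclassified",
            class_=row.get("class") or None,
        )
        for row in meta.to_dict("records")
    }
    tips: dict[str, TipInfo] = {}
    unresolved = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label in outgroup:
            continue
        info = by_protein.get(tip_to_protein(label))
        if info is None:
            unresolved.append(label)
        else:
            tips[label] = info
    if unresolved:
        raise TreeError(f"tips unresolvable to metadata: {sorted(unresolved)}")

    if outgroup:
        present = set(t.label for t in tree.taxon_namespace)
        missing = set(outgroup) - present
        if missing:
            raise TreeError(f"outgroup tips absent from tree: {sorted(missing)}")
        mrca = tree.mrca(taxa=[
            t for t in tree.taxon_namespace if t.label in set(outgroup)
        ])
        if mrca is not tree.seed_node:
            tree.reroot_at_edge(mrca.edge, update_bipartitions=True)
    return AnnotatedTree(tree=tree, tips=tips, outgroup=tuple(outgroup))


def write_tree(atree: AnnotatedTree | dendropy.Tree, path) -> None:
    tree = atree.tree if isinstance(atree, AnnotatedTree) else atree
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def is_monophyletic(atree: AnnotatedTree, tip_subset) -> bool:
    """True iff some node's complete descendant tip set equals ``tip_subset``.

    Rooted monophyly: the subset must form a clade of the rooted tree.
    """
    subset = frozenset(tip_subset)
    if not subset:
        raise TreeError("empty tip subset")
    all_tips = set(atree.tip_labels)
    stray = subset - all_tips
    if stray:
        raise TreeError(f"tips not in tree: {sorted(stray)}")
    return any(
        frozenset(l.taxon.label for l in node.leaf_iter()) == subset
        for node in atree.tree.preorder_node_iter()
    )


def _leaf_labels(node) -> list[str]:
    return [l.taxon.label for l in node.leaf_iter()]


def collapse_by_rank(
    atree: AnnotatedTree,
    mixed_clades: list[frozenset[str]] | None = None,
) -> tuple[list[CollapsedClade], dendropy.Tree]:
    """Collapse maximal taxonomically uniform clades into pseudo-tips.

    Returns the clade list (collapsed clades in preorder K order, then
    singleton tips with ``k_id=None``) and the reduced tree. Outgroup
    tips are never collapsed. ``mixed_clades`` are user-designated
    monophyletic tip sets collapsed with the label ``"mixed"``.
    """
    for label in {l for l in _leaf_labels(atree.tree.seed_node)}:
        if label not in atree.tips and label not in atree.outgroup:
            raise TreeError(f"tip {label!r} has no taxonomy label")

    mixed_sets = [frozenset(s) for s in (mixed_clades or [])]
    for s in mixed_sets:
        if not is_monophyletic(atree, s):
            raise TreeError(f"mixed clade {sorted(s)} is not monophyletic")

    tree = atree.tree.clone(depth=1)
    out = set(atree.outgroup)

    def tip_label_of(leaf) -> str | None:
        name = leaf.taxon.label
        if name in out:
            return None  # outgroup: blocks collapsing of any ancestor
        return atree.tips[name].rank_label

    # Postorder purity: node.pure_label is the shared rank label of all
    # descendant tips, or None when mixed / containing outgroup tips.
    pure: dict[int, str | None] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            pure[id(node)] = tip_label_of(node)
        else:
            child_labels = {pure[id(c)] for c in node.child_nodes()}
            pure[id(node)] = (
                child_labels.pop() if len(child_labels) == 1 else None
            )

    clades: list[CollapsedClade] = []
    singles: list[CollapsedClade] = []
    k = 0
    collapse_nodes: list[tuple[object, str]] = []
    consumed: set[str] = set()

    # Preorder: take each maximal pure node (>= 2 tips) or designated
    # mixed clade; skip anything beneath an already-collapsed node.
    for node in tree.preorder_node_iter():
        leaves = _leaf_labels(node)
        if consumed.intersection(leaves):
            continue
        label = pure[id(node)]
        if label is not None and len(leaves) >= 2:
            collapse_nodes.append((node, label))
            consumed.update(leaves)
        elif frozenset(leaves) in mixed_sets:
            collapse_nodes.append((node, "mixed"))
            consumed.update(leaves)

    for node, label in collapse_nodes:
        k += 1
        k_id = f"K{k:02d}"
        members = tuple(_leaf_labels(node))
        clades.append(CollapsedClade(label, k_id, len(members), members))
        # Reduce: turn the node into a leaf named after the clade.
        node.set_child_nodes([])
        taxon = tree.taxon_namespace.new_taxon(f"{k_id}_{label}")
        node.taxon = taxon

    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name in atree.tips:  # remaining singleton homolog tips
            singles.append(
                CollapsedClade(atree.tips[name].rank_label, None, 1, (name,))
            )
    return clades + singles, tree


def annotate_traits(
    clades: list[CollapsedClade],
    atree: AnnotatedTree,
    inventories: list[GenomeInventory] | dict[str, GenomeInventory],
) -> list[CollapsedClade]:
    """Count member genomes also encoding MerB or MerB-like homologs.

    Counts are over distinct genomes (a genome contributing several tips
    to a clade is counted once).
    """
    if not isinstance(inventories, dict):
        inventories = {inv.genome_id: inv for inv in inventories}
    annotated = []
    for clade in clades:
        genomes = {atree.tips[t].genome_id for t in clade.member_tips}
        missing = genomes - set(inventories)
        if missing:
            raise TreeError(f"genomes absent from inventory: {sorted(missing)}")
        with_b = sum(1 for g in genomes if inventories[g].merB_count > 0)
        with_b_like = sum(
            1
            for g in genomes
            if sum(inventories[g].merB_like_counts.values()) > 0
        )
        annotated.append(
            replace(
                clade,
                n_genomes_with_merB=with_b,
                n_genomes_with_merB_like=with_b_like,
            )
        )
    return annotated


def export_annotation(
    clades: list[CollapsedClade],
    reduced_tree: dendropy.Tree | None,
    tsv_path,
    newick_path=None,
) -> None:
    """Write the per-clade summary TSV and, optionally, the reduced Newick."""
    with open(tsv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "k_id",
                "label",
                "n_homologs",
                "n_genomes_with_merB",
                "n_genomes_with_merB_like",
                "member_tips",
            ]
        )
        for c in clades:
            writer.writerow(
                [
                    c.k_id or "",
                    c.label,
                    f"[{c.n_homologs}]",
                    "" if c.n_genomes_with_merB is None else c.n_genomes_with_merB,
                    ""
                    if c.n_genomes_with_merB_like is None
                    else c.n_genomes_with_merB_like,
                    ",".join(c.member_tips),
                ]
            )
    if newick_path is not None and reduced_tree is not None:
        write_tree(reduced_tree, newick_path)
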