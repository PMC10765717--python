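"""Gene-tree utilities for orthogroup post-processing.

Gene trees carry leaves labelled ``species|gene_id``.  The operations
mirror a standard comparative-genomics workflow around a focal clade
(here Brassicaceae): pick one representative protein per gene, split
each orthogroup's gene tree at maximal monophyletic in-clade subtrees,
filter those subtrees by topological compatibility with the species
tree, and count per-species gene copies.  Family membership calls from
two independent evidence tracks (domain scan and similarity search)
are combined by exact intersection.

Unrooted input trees are midpoint-rooted before splitting; the
compatibility filter checks that every species-informative bipartition
of the (duplicate-collapsed) subtree is present in the species tree
restricted to the same species set.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


def _parse_leaf(label: str) -> tuple[str, str]:
    if "|" not in label:
        raise ValidationError(f"leaf label {label!r} is not 'species|gene_id'")
    species, gene = label.split("|", 1)
    return species, gene


@dataclass
class GeneTree:
    """A rooted gene tree plus the set of in-clade (focal) species."""

    tree: dendropy.Tree
    in_clade: set[str] = field(default_factory=set)

    @classmethod
    def from_newick(cls, newick: str, in_clade: Iterable[str]) -> "GeneTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True, preserve_underscores=True,
            )
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"malformed newick: {exc}") from exc
        return cls(tree, set(in_clade))

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def species(self) -> set[str]:
        return {_parse_leaf(lbl)[0] for lbl in self.leaf_labels}

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def longest_isoform(
    proteins_per_gene: Mapping[str, Sequence[tuple[str, int]]]
) -> dict[str, str]:
    """One representative protein per gene: the longest, ties lexicographic.

    `proteins_per_gene` maps gene id -> [(protein_id, length), ...].
    Genes with no protein are skipped with a warning.
    """
    reps: dict[str, str] = {}
    for gene, prots in proteins_per_gene.items():
        valid = [(pid, ln) for pid, ln in prots if ln > 0]
        if not valid:
            logger.warning("gene %s has no protein with positive length; skipped", gene)
            continue
        # max length first, then lexicographically smallest id
        best = min(valid, key=lambda p: (-p[1], p[0]))
        reps[gene] = best[0]
    return reps


def _is_unrooted(tree: dendropy.Tree) -> bool:
    root = tree.seed_node
    return len(root.child_nodes()) > 2


def split_monophyletic(gt: GeneTree) -> list[GeneTree]:
    """Maximal subtrees whose leaves are all in-clade.

    Each returned subtree's parent edge subtends at least one out-clade
    leaf (maximality); together they partition the in-clade leaves.
    Unrooted trees (basal polytomy) are midpoint-rooted first.
    """
    tree = gt.tree.clone(depth=1)
    if _is_unrooted(tree):
        if any(e.length is None for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node):
            # no branch lengths: root arbitrarily at the first child edge
            tree.reroot_at_edge(tree.seed_node.child_edges()[0])
        else:
            tree.reroot_at_midpoint()

    subtrees: list[GeneTree] = []

    def all_in(node) -> bool:
        return all(
            _parse_leaf(lf.taxon.label)[0] in gt.in_clade
            for lf in node.leaf_iter()
        )

    def node_newick(node) -> str:
        if node.is_leaf():
            lbl = node.taxon.label
            return f"'{lbl}'" if any(c in lbl for c in "(),:;") else lbl
        inner = ",".join(node_newick(c) for c in node.child_nodes())
        return f"({inner})"

    def walk(node) -> None:
        if all_in(node):
            subtrees.append(GeneTree.from_newick(node_newick(node) + ";", gt.in_clade))
            return
        for child in node.child_nodes():
            walk(child)

    if any(True for _ in tree.leaf_node_iter()):
        walk(tree.seed_node)
    # drop subtrees with no in-clade leaf (possible only for an empty tree)
    return [s for s in subtrees if s.leaf_labels]


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Unrooted species bipartitions of a tree, collapsing duplicates.

    Edges whose two sides share a species are species-uninformative and
    skipped; trivial splits (a side with < 2 species) are skipped too.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    all_species = {_parse_leaf(l)[0] for l in leaves}
    out: set[frozenset[frozenset[str]]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = {_parse_leaf(lf.taxon.label)[0] for lf in node.leaf_iter()}
        other = all_species - side
        if side & other:
            continue  # species on both sides: uninformative after collapsing
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(frozenset({frozenset(side), frozenset(other)}))
    return out


def _restricted_species_bipartitions(
    species_tree: dendropy.Tree, keep: set[str]
) -> set[frozenset[frozenset[str]]]:
    out: set[frozenset[frozenset[str]]] = set()
    all_kept = keep
    for node in species_tree.preorder_node_iter():
        if node is species_tree.seed_node or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()} & keep
        other = all_kept - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(frozenset({frozenset(side), frozenset(other)}))
    return out


def topology_filter(
    subtree: GeneTree,
    species_tree: str | dendropy.Tree,
    min_species: int = 2,
) -> tuple[bool, dict]:
    """Check a split subtree against the species tree.

    Passes iff the subtree holds at least `min_species` distinct
    species and every species-informative bipartition of the subtree
    (after collapsing within-species duplicates) occurs in the species
    tree restricted to those species.  The report lists violated
    bipartitions.
    """
    if isinstance(species_tree, str):
        try:
            sp_tree = dendropy.Tree.get(
                data=species_tree, schema="newick",
                suppress_internal_node_taxa=True, preserve_underscores=True,
            )
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"malformed species-tree newick: {exc}") from exc
    else:
        sp_tree = species_tree
    sp_leaves = {lf.taxon.label for lf in sp_tree.leaf_node_iter()}
    present = subtree.species
    missing = present - sp_leaves
    if missing:
        raise ValidationError(
            f"species absent from species tree: {sorted(missing)}"
        )
    if len(present) < min_species:
        return False, {
            "reason": "too few species",
            "n_species": len(present),
            "violations": [],
        }
    gene_bips = _bipartitions(subtree.tree)
    ref_bips = _restricted_species_bipartitions(sp_tree, present)
    violations = [
        tuple(sorted(tuple(sorted(side)) for side in bip))
        for bip in gene_bips
        if bip not in ref_bips
    ]
    ok = not violations
    return ok, {
        "reason": "" if ok else "incompatible bipartitions",
        "n_species": len(present),
        "violations": sorted(violations),
    }


def count_copies(
    subtrees_per_orthogroup: Mapping[str, Sequence[GeneTree]],
    focal_species: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Orthogroup x species table of gene-copy numbers.

    Copy number is the leaf count per species summed over an
    orthogroup's retained subtrees; `focal_species` restricts (and
    orders) the columns, adding zero columns for absent species.
    """
    counts: dict[str, dict[str, int]] = {}
    species_seen: set[str] = set()
    for og, subtrees in subtrees_per_orthogroup.items():
        row: dict[str, int] = {}
        for st in subtrees:
            for lbl in st.leaf_labels:
                sp, _ = _parse_leaf(lbl)
                row[sp] = row.get(sp, 0) + 1
                species_seen.add(sp)
        counts[og] = row
    cols = list(focal_species) if focal_species is not None else sorted(species_seen)
    df = pd.DataFrame(
        [[counts[og].get(sp, 0) for sp in cols] for og in counts],
        index=list(counts), columns=cols, dtype=int,
    )
    df.index.name = "orthogroup"
    return df


@dataclass(frozen=True)
class FamilyEvidence:
    """Gene-family membership calls from two independent searches."""

    domain_hits: frozenset[str]
    similarity_hits: frozenset[str]


def intersect_family_evidence(ev: FamilyEvidence) -> list[str]:
    """Genes supported by both evidence tracks, sorted."""
    return sorted(set(ev.domain_hits) & set(ev.similarity_hits))
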