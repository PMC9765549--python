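"""Reference taxonomy of marine picocyanobacteria and lowest-common-ancestor queries.

The hierarchy has five named ranks, strictly descending along every
root-to-leaf path::

    genus > subcluster > clade > subclade > strain

e.g. Synechococcus > 5.1 > I > Ia > CC9311.  Strains flagged as outgroup
(non-picocyanobacterial reference genomes kept to absorb unspecific
alignments) hang from a distinguished sibling subtree directly under a
universal root, so that no outgroup strain ever shares an in-group ancestor
below that root.  A read whose candidate matches include an outgroup strain
therefore resolves above the genus and is discarded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import MissingTaxonError, ValidationError

#: Ranks ordered from shallowest to deepest. The two synthetic bookkeeping
#: ranks ("root" for the universal root, "outgroup" for the outgroup anchor)
#: sit above "genus" and never appear in read assignments.
RANKS: tuple[str, ...] = ("genus", "subcluster", "clade", "subclade", "strain")

ROOT_ID = "root"
OUTGROUP_ID = "outgroup"


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy: a label, a rank, and a parent pointer."""

    id: str
    rank: str
    parent: Optional["TaxonNode"] = None

    def path(self) -> tuple["TaxonNode", ...]:
        """Root-to-self path, root first."""
        nodes: list[TaxonNode] = []
        node: Optional[TaxonNode] = self
        while node is not None:
            nodes.append(node)
            node = node.parent
        return tuple(reversed(nodes))

    @property
    def depth(self) -> int:
        return len(self.path()) - 1

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxonNode({self.id!r}, rank={self.rank!r})"


@dataclass(frozen=True)
class StrainInfo:
    node: TaxonNode
    genome_length: int
    outgroup: bool


@dataclass
class TaxonomyTree:
    """Rooted rank hierarchy with per-strain genome lengths and outgroup flags.

    ``strains`` maps strain id to :class:`StrainInfo`; ``genome_to_strain``
    maps sequence-record identifiers to the owning strain (a strain may own
    several records; by default each strain owns one record named after
    itself).
    """

    root: TaxonNode
    nodes: dict[str, TaxonNode] = field(default_factory=dict)
    strains: dict[str, StrainInfo] = field(default_factory=dict)
    genome_to_strain: dict[str, str] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def node(self, taxon_id: str) -> TaxonNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise MissingTaxonError(f"unknown taxon id: {taxon_id!r}") from None

    def strain(self, strain_id: str) -> StrainInfo:
        try:
            return self.strains[strain_id]
        except KeyError:
            raise MissingTaxonError(f"unknown strain id: {strain_id!r}") from None

    def strain_for_genome(self, genome_id: str) -> str:
        """Resolve a sequence-record id to its strain id.

        Falls back to interpreting the genome id as a strain id directly,
        which covers the common one-record-per-strain layout.
        """
        if genome_id in self.genome_to_strain:
            return self.genome_to_strain[genome_id]
        if genome_id in self.strains:
            return genome_id
        raise MissingTaxonError(f"genome id {genome_id!r} is not in the taxonomy")

    def is_outgroup(self, strain_id: str) -> bool:
        return self.strain(strain_id).outgroup

    def ingroup_strains(self) -> list[str]:
        return [s for s, info in self.strains.items() if not info.outgroup]

    def strains_under(self, taxon_id: str) -> list[str]:
        """In-group strain ids whose root path passes through ``taxon_id``."""
        target = self.node(taxon_id)
        out = []
        for sid, info in self.strains.items():
            if info.outgroup:
                continue
            if target in info.node.path():
                out.append(sid)
        return out


def _attach(tree: TaxonomyTree, node_id: str, rank: str, parent: TaxonNode) -> TaxonNode:
    existing = tree.nodes.get(node_id)
    if existing is not None:
        if existing.rank != rank or existing.parent is not parent:
            raise ValidationError(
                f"taxon label {node_id!r} reused with conflicting rank or parent"
            )
        return existing
    node = TaxonNode(node_id, rank, parent)
    tree.nodes[node_id] = node
    return node


def build_taxonomy(
    records: Iterable[Sequence],
    genome_map: Optional[Mapping[str, str]] = None,
) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from strain records.

    Parameters
    ----------
    records:
        Iterable of ``(strain_id, subclade, clade, subcluster, genus,
        genome_length, outgroup_flag)``.  ``None``/``"NA"``/empty strings for
        an intermediate rank attach the strain to the nearest known ancestor
        (e.g. an SC 5.2 strain without a clade hangs directly from its
        subcluster).
    genome_map:
        Optional extra ``genome_id -> strain_id`` entries for strains whose
        genome is split over several sequence records.

    Raises
    ------
    ValidationError
        On empty input, duplicate strain ids, or non-positive genome lengths.
    """
    records = list(records)
    if not records:
        raise ValidationError("taxonomy requires at least one strain record")

    root = TaxonNode(ROOT_ID, "root", None)
    tree = TaxonomyTree(root=root, nodes={ROOT_ID: root})
    outgroup_anchor = _attach(tree, OUTGROUP_ID, "outgroup", root)

    for rec in records:
        strain_id, subclade, clade, subcluster, genus, genome_length, outgroup = rec
        strain_id = str(strain_id)
        if strain_id in tree.strains:
            raise ValidationError(f"duplicate strain id: {strain_id!r}")
        genome_length = int(genome_length)
        if genome_length <= 0:
            raise ValidationError(
                f"strain {strain_id!r} has non-positive genome length {genome_length}"
            )
        outgroup = bool(outgroup)
        if outgroup:
            # Outgroup internal ranks are irrelevant to assignment: strains
            # attach directly under the outgroup anchor.
            node = _attach(tree, strain_id, "strain", outgroup_anchor)
        else:
            parent = tree.root
            for label, rank in (
                (genus, "genus"),
                (subcluster, "subcluster"),
                (clade, "clade"),
                (subclade, "subclade"),
            ):
                if label is None:
                    continue
                label = str(label)
                if label in ("", "NA", "nan"):
                    continue
                parent = _attach(tree, label, rank, parent)
            node = _attach(tree, strain_id, "strain", parent)
        tree.strains[strain_id] = StrainInfo(node, genome_length, outgroup)
        tree.genome_to_strain[strain_id] = strain_id

    if genome_map:
        for genome_id, strain_id in genome_map.items():
            if strain_id not in tree.strains:
                raise ValidationError(
                    f"genome map references unknown strain {strain_id!r}"
                )
            tree.genome_to_strain[str(genome_id)] = strain_id
    return tree


def lowest_common_ancestor(tree: TaxonomyTree, strain_ids: Iterable[str]) -> TaxonNode:
    """Deepest node lying on the root path of every given strain.

    A singleton set returns the strain node itself.  Sets mixing in-group and
    outgroup strains resolve to the universal root, which downstream code
    treats as unassignable.
    """
    ids = list(strain_ids)
    if not ids:
        raise ValidationError("lowest_common_ancestor requires a non-empty strain set")
    paths = [tree.strain(s).node.path() for s in ids]
    lca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        candidate = paths[0][depth]
        if all(p[depth] is candidate for p in paths):
            lca = candidate
        else:
            break
    return lca
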