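"""Ranked taxonomy tree with lowest-common-ancestor queries.

The classification index, the report writer and the detection filters all
operate on a single rooted tree whose nodes carry one of eight fixed ranks
(root, domain, phylum, class, order, family, genus, species). Reads whose
k-mers match several species collapse onto the lowest common ancestor of
those species, so LCA lookup is the tree's central operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pandas as pd

RANKS: Tuple[str, ...] = (
    "root",
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_CODES: Dict[str, str] = {
    "root": "R",
    "domain": "D",
    "phylum": "P",
    "class": "C",
    "order": "O",
    "family": "F",
    "genus": "G",
    "species": "S",
}


class TaxonomyError(ValueError):
    """Raised when a node set violates the tree invariants."""


@dataclass(frozen=True)
class TaxonNode:
    """One taxon: opaque id, display name, rank and parent id (None for root)."""

    id: str
    name: str
    rank: str
    parent: Optional[str]


class TaxonomyTree:
    """Rooted tree of :class:`TaxonNode` records.

    Invariants enforced at construction: exactly one root; every parent's
    rank lies strictly above its child's in :data:`RANKS`; names are unique
    within a rank; every species has a genus ancestor.
    """

    def __init__(self, nodes: Iterable[TaxonNode]) -> None:
        self._nodes: Dict[str, TaxonNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise TaxonomyError(f"duplicate taxon id {node.id!r}")
            if node.rank not in RANKS:
                raise TaxonomyError(f"unknown rank {node.rank!r} for {node.id!r}")
            self._nodes[node.id] = node

        roots = [n for n in self._nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self._root = roots[0].id

        self._children: Dict[str, List[str]] = {nid: [] for nid in self._nodes}
        seen_names: Dict[Tuple[str, str], str] = {}
        for node in self._nodes.values():
            key = (node.rank, node.name)
            if key in seen_names:
                raise TaxonomyError(
                    f"name {node.name!r} duplicated within rank {node.rank!r}"
                )
            seen_names[key] = node.id
            if node.parent is None:
                continue
            parent = self._nodes.get(node.parent)
            if parent is None:
                raise TaxonomyError(f"{node.id!r} references missing parent")
            if RANKS.index(parent.rank) >= RANKS.index(node.rank):
                raise TaxonomyError(
                    f"parent rank {parent.rank!r} not above child rank "
                    f"{node.rank!r} ({node.id!r})"
                )
            self._children[node.parent].append(node.id)

        # stable child order: insertion order of the node iterable
        self._path_cache: Dict[str, Tuple[str, ...]] = {}
        for sid in self.ids_at_rank("species"):
            if not any(
                self._nodes[a].rank == "genus" for a in self.ancestors(sid)
            ):
                raise TaxonomyError(f"species {sid!r} lacks a genus ancestor")

        # species leaves reachable from each node, used when scoring reads
        self._subtree_species: Dict[str, Tuple[str, ...]] = {}
        self._fill_subtree_species(self._root)

    # -- basic accessors ---------------------------------------------------

    @property
    def root(self) -> str:
        return self._root

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxon_id: str) -> TaxonNode:
        return self._nodes[taxon_id]

    def name(self, taxon_id: str) -> str:
        return self._nodes[taxon_id].name

    def rank(self, taxon_id: str) -> str:
        return self._nodes[taxon_id].rank

    def children(self, taxon_id: str) -> Sequence[str]:
        return tuple(self._children[taxon_id])

    def ids_at_rank(self, rank: str) -> List[str]:
        return [nid for nid, n in self._nodes.items() if n.rank == rank]

    def find(self, name: str, rank: str) -> Optional[str]:
        for nid, n in self._nodes.items():
            if n.rank == rank and n.name == name:
                return nid
        return None

    # -- tree walks --------------------------------------------------------

    def ancestors(self, taxon_id: str) -> Tuple[str, ...]:
        """Path from the root down to ``taxon_id`` (inclusive at both ends)."""
        cached = self._path_cache.get(taxon_id)
        if cached is not None:
            return cached
        path: List[str] = []
        cur: Optional[str] = taxon_id
        while cur is not None:
            path.append(cur)
            cur = self._nodes[cur].parent
        result = tuple(reversed(path))
        self._path_cache[taxon_id] = result
        return result

    def depth(self, taxon_id: str) -> int:
        return len(self.ancestors(taxon_id)) - 1

    def is_ancestor_or_self(self, candidate: str, descendant: str) -> bool:
        return candidate in self.ancestors(descendant)

    def lca(self, taxon_ids: Iterable[str]) -> str:
        """Lowest common ancestor of one or more taxa."""
        ids = list(taxon_ids)
        if not ids:
            raise ValueError("lca of an empty taxon set is undefined")
        common = self.ancestors(ids[0])
        for tid in ids[1:]:
            other = self.ancestors(tid)
            n = 0
            for a, b in zip(common, other):
                if a != b:
                    break
                n += 1
            common = common[:n]
        return common[-1]

    def genus_of(self, taxon_id: str) -> Optional[str]:
        """The genus ancestor of a taxon (itself if a genus), else None."""
        for nid in reversed(self.ancestors(taxon_id)):
            if self._nodes[nid].rank == "genus":
                return nid
        return None

    def subtree_species(self, taxon_id: str) -> Tuple[str, ...]:
        """All species ids at or below a node."""
        return self._subtree_species[taxon_id]

    def _fill_subtree_species(self, taxon_id: str) -> Tuple[str, ...]:
        node = self._nodes[taxon_id]
        if node.rank == "species":
            out: Tuple[str, ...] = (taxon_id,)
        else:
            acc: List[str] = []
            for child in self._children[taxon_id]:
                acc.extend(self._fill_subtree_species(child))
            out = tuple(acc)
        self._subtree_species[taxon_id] = out
        return out

    def depth_first(self) -> Iterator[str]:
        """Pre-order traversal from the root, children in insertion order."""
        stack = [self._root]
        while stack:
            nid = stack.pop()
            yield nid
            stack.extend(reversed(self._children[nid]))

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "child_id": n.id,
                "parent_id": "" if n.parent is None else n.parent,
                "rank": n.rank,
                "name": n.name,
            }
            for n in (self._nodes[i] for i in self.depth_first())
        ]
        return pd.DataFrame(rows, columns=["child_id", "parent_id", "rank", "name"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TaxonomyTree":
        nodes = [
            TaxonNode(
                id=str(r.child_id),
                name=str(r.name),
                rank=str(r.rank),
                parent=None if (pd.isna(r.parent_id) or r.parent_id == "") else str(r.parent_id),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(nodes)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTree":
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))
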