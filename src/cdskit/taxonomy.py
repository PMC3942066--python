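"""NCBI taxonomy tree: taxdump loading, lineage traversal, rank queries.

The tree is loaded from ``nodes.dmp`` / ``names.dmp`` (fields separated
by ``\\t|\\t``, records terminated by ``\\t|``).  Each node carries its
rank, scientific name, optional common name, parent/child pointers and a
CDS counter that is incremented during GenBank ingest; the counter is
the proxy used to rank the relative scientific interest of a species
when choosing cluster representatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Optional


class TaxonomyError(ValueError):
    pass


@dataclass
class TaxonNode:
    tax_id: int
    parent_id: int
    rank: str
    scientific_name: str = ""
    common_name: Optional[str] = None
    cds_count: int = 0
    child_ids: list[int] = field(default_factory=list)


def _iter_dmp(stream: IO[str]) -> Iterable[list[str]]:
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.endswith("\t|"):
            line = line[: -len("\t|")]
        yield line.split("\t|\t")


class TaxonomyDB:
    """In-memory taxonomy tree indexed by tax_id."""

    def __init__(self) -> None:
        self.nodes: dict[int, TaxonNode] = {}
        self._by_name: dict[str, int] = {}

    # -- construction -------------------------------------------------

    def add_node(self, node: TaxonNode) -> None:
        if node.tax_id in self.nodes:
            raise TaxonomyError(f"duplicate tax_id {node.tax_id}")
        self.nodes[node.tax_id] = node

    def link(self) -> None:
        """Wire child pointers and validate parents after all nodes exist."""
        for node in self.nodes.values():
            node.child_ids = []
        for node in self.nodes.values():
            if node.tax_id == node.parent_id:
                continue  # root is its own parent
            parent = self.nodes.get(node.parent_id)
            if parent is None:
                raise TaxonomyError(
                    f"node {node.tax_id} references missing parent {node.parent_id}"
                )
            parent.child_ids.append(node.tax_id)
        self._by_name = {}
        for node in self.nodes.values():
            self._by_name.setdefault(node.scientific_name.casefold(), node.tax_id)
            if node.common_name:
                self._by_name.setdefault(node.common_name.casefold(), node.tax_id)

    # -- queries ------------------------------------------------------

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def get(self, tax_id: int) -> Optional[TaxonNode]:
        return self.nodes.get(tax_id)

    def node(self, tax_id: int) -> TaxonNode:
        try:
            return self.nodes[tax_id]
        except KeyError:
            raise TaxonomyError(f"unknown tax_id {tax_id}") from None

    def lineage(self, tax_id: int) -> list[TaxonNode]:
        """Root-first path from the root to ``tax_id``."""
        node = self.node(tax_id)
        path = [node]
        seen = {node.tax_id}
        while node.tax_id != node.parent_id:
            node = self.node(node.parent_id)
            if node.tax_id in seen:
                raise TaxonomyError(f"cycle in taxonomy at {node.tax_id}")
            seen.add(node.tax_id)
            path.append(node)
        path.reverse()
        return path

    def ancestor_at_rank(self, tax_id: int, rank: str) -> Optional[TaxonNode]:
        """The unique lineage node with the requested rank, or ``None``."""
        for node in self.lineage(tax_id):
            if node.rank == rank:
                return node
        return None

    def species_importance(self, tax_id: int) -> int:
        """CDS counter of the annotated taxon (leaf counts, not aggregated)."""
        return self.node(tax_id).cds_count

    def aggregate_count(self, tax_id: int) -> int:
        """Sum of CDS counters over the subtree rooted at ``tax_id``.

        Leaf counters drive representative selection; this derived query
        exists for rank-level reporting only.
        """
        node = self.node(tax_id)
        total = node.cds_count
        stack = list(node.child_ids)
        while stack:
            child = self.nodes[stack.pop()]
            total += child.cds_count
            stack.extend(child.child_ids)
        return total

    def find_by_name(self, name: str) -> Optional[TaxonNode]:
        """Exact, case-insensitive lookup on scientific or common name."""
        tax_id = self._by_name.get(name.strip().casefold())
        return self.nodes.get(tax_id) if tax_id is not None else None

    def count_cds(self, tax_id: Optional[int]) -> None:
        """Increment the CDS counter at the annotated taxon, if known."""
        if tax_id is not None and tax_id in self.nodes:
            self.nodes[tax_id].cds_count += 1


def load_taxdump(nodes_stream: IO[str], names_stream: IO[str]) -> TaxonomyDB:
    """Build a :class:`TaxonomyDB` from nodes.dmp / names.dmp streams.

    Scientific names come from name class ``scientific name``; common
    names from ``genbank common name`` with ``common name`` as fallback.
    Synonyms and other classes are ignored.
    """
    db = TaxonomyDB()
    for fields in _iter_dmp(nodes_stream):
        if len(fields) < 3:
            raise TaxonomyError(f"malformed nodes.dmp record: {fields!r}")
        db.add_node(
            TaxonNode(
                tax_id=int(fields[0]),
                parent_id=int(fields[1]),
                rank=fields[2].strip(),
            )
        )
    fallback_common: dict[int, str] = {}
    for fields in _iter_dmp(names_stream):
        if len(fields) < 4:
            raise TaxonomyError(f"malformed names.dmp record: {fields!r}")
        tax_id, name, _unique, name_class = (
            int(fields[0]),
            fields[1].strip(),
            fields[2],
            fields[3].strip(),
        )
        node = db.get(tax_id)
        if node is None:
            continue
        if name_class == "scientific name":
            node.scientific_name = name
        elif name_class == "genbank common name":
            node.common_name = name
        elif name_class == "common name":
            fallback_common.setdefault(tax_id, name)
    for tax_id, name in fallback_common.items():
        node = db.nodes[tax_id]
        if node.common_name is None:
            node.common_name = name
    db.link()
    return db
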