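"""Rank-annotated taxonomic tree with lineage, LCA and rank-rollup queries.

The taxonomy is the backbone of read classification: tied best hits are
resolved to their lowest common ancestor (LCA), and per-rank abundance
profiles are produced by rolling every assignment up to a canonical rank.

Two on-disk representations are supported:

* NCBI-style ``nodes.dmp`` / ``names.dmp`` dumps (pipe-delimited fields), and
* a 4-column flat TSV dialect (``taxon_id  parent_id  rank  name``, header
  line required) convenient for fixtures and simulated taxonomies.

Canonical ranks form a fixed ladder (root > domain > phylum > class > order >
family > genus > species > strain). NCBI's ``superkingdom`` maps onto
``domain``; every other rank name maps onto ``no_rank``.  ``no_rank`` nodes
are kept in lineages (so LCA stays exact) but are transparent to
:meth:`Taxonomy.rollup`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "CANONICAL_RANKS",
    "TaxonomyError",
    "TaxonomyNode",
    "Taxonomy",
    "load_taxonomy",
]

#: Canonical rank ladder, shallowest to deepest.
CANONICAL_RANKS = (
    "root",
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)

_RANK_DEPTH = {r: i for i, r in enumerate(CANONICAL_RANKS)}

# NCBI rank vocabulary -> canonical ladder.
_RANK_ALIASES = {
    "superkingdom": "domain",
    "domain": "domain",
    "kingdom": "no_rank",
}


def canonical_rank(rank: str) -> str:
    """Map an arbitrary rank name onto the canonical ladder (or ``no_rank``)."""
    rank = rank.strip().lower().replace(" ", "_")
    if rank in _RANK_DEPTH or rank == "no_rank":
        return rank
    return _RANK_ALIASES.get(rank, "no_rank")


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy source (cycle, orphan, duplicate...)."""


@dataclass(frozen=True)
class TaxonomyNode:
    taxon_id: str
    parent_id: str
    rank: str
    name: str


class Taxonomy:
    """Validated tree of :class:`TaxonomyNode` supporting lineage/LCA queries.

    The root is self-parental (NCBI convention: node 1 has parent 1).
    Construction validates that every parent exists, that there is exactly
    one root, that the parent graph is acyclic, and that canonical ranks
    never invert along a root-to-leaf path.
    """

    def __init__(self, nodes: dict[str, TaxonomyNode]):
        self.nodes = nodes
        roots = [n.taxon_id for n in nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root_id = roots[0]
        self._name_index: dict[str, str] = {}
        for n in nodes.values():
            self._name_index.setdefault(n.name, n.taxon_id)
        self._validate()
        self._lineage_cache: dict[str, tuple[str, ...]] = {}

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        state: dict[str, int] = {}  # 0 = visiting, 1 = done
        for start in self.nodes:
            path = []
            tid = start
            while tid not in state:
                node = self.nodes.get(tid)
                if node is None:
                    raise TaxonomyError(f"orphan parent_id {tid!r}")
                state[tid] = 0
                path.append(tid)
                if node.parent_id == tid:
                    break
                tid = node.parent_id
            else:
                if state[tid] == 0:
                    raise TaxonomyError(f"cycle detected through taxon {tid!r}")
            for p in path:
                state[p] = 1
        # rank monotonicity: a node's canonical rank must be deeper than any
        # canonical-ranked ancestor (no_rank nodes are transparent)
        for n in self.nodes.values():
            if n.parent_id == n.taxon_id:
                continue
            r = canonical_rank(n.rank)
            if r == "no_rank":
                continue
            tid = n.parent_id
            while True:
                anc = self.nodes[tid]
                ar = canonical_rank(anc.rank)
                if ar != "no_rank":
                    if _RANK_DEPTH[ar] >= _RANK_DEPTH[r]:
                        raise TaxonomyError(
                            f"rank inversion: {n.taxon_id} ({r}) below "
                            f"{anc.taxon_id} ({ar})"
                        )
                    break
                if anc.parent_id == tid:
                    break
                tid = anc.parent_id

    # -- basic accessors -------------------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxon_id: str) -> TaxonomyNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon_id {taxon_id!r}") from None

    def rank(self, taxon_id: str) -> str:
        if taxon_id == self.root_id:
            return "root"  # NCBI dumps label the root 'no rank'
        return canonical_rank(self.node(taxon_id).rank)

    def name(self, taxon_id: str) -> str:
        return self.node(taxon_id).name

    def taxon_by_name(self, name: str) -> Optional[str]:
        return self._name_index.get(name)

    # -- queries ---------------------------------------------------------

    def _lineage_ids(self, taxon_id: str) -> tuple[str, ...]:
        """Root-to-taxon path of taxon_ids (cached)."""
        cached = self._lineage_cache.get(taxon_id)
        if cached is not None:
            return cached
        node = self.node(taxon_id)
        if node.parent_id == node.taxon_id:
            path: tuple[str, ...] = (taxon_id,)
        else:
            path = self._lineage_ids(node.parent_id) + (taxon_id,)
        self._lineage_cache[taxon_id] = path
        return path

    def lineage(self, taxon_id: str) -> list[tuple[str, str]]:
        """Ordered ``(rank, taxon_id)`` pairs from the root to ``taxon_id``."""
        return [(self.rank(t), t) for t in self._lineage_ids(taxon_id)]

    def lca(self, taxon_ids: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty set of taxa.

        ``lca({x}) == x``; for an ancestor ``a`` of ``x``,
        ``lca({x, a}) == a``.
        """
        ids = list(taxon_ids)
        if not ids:
            raise ValueError("lca of an empty taxon set is undefined")
        paths = [self._lineage_ids(t) for t in ids]
        shortest = min(len(p) for p in paths)
        lca_id = self.root_id
        for depth in range(shortest):
            first = paths[0][depth]
            if all(p[depth] == first for p in paths):
                lca_id = first
            else:
                break
        return lca_id

    def rollup(self, taxon_id: str, rank: str) -> Optional[str]:
        """Ancestor-or-self of ``taxon_id`` at the requested canonical rank.

        Returns ``None`` when the lineage skips that rank or when the taxon
        sits above it. ``no_rank`` nodes are never returned.
        """
        rank = canonical_rank(rank)
        if rank == "no_rank":
            raise ValueError("cannot roll up to 'no_rank'")
        for tid in reversed(self._lineage_ids(taxon_id)):
            if self.rank(tid) == rank:
                return tid
        return None


# -- loaders -------------------------------------------------------------


def _add_node(nodes: dict[str, TaxonomyNode], node: TaxonomyNode) -> None:
    if node.taxon_id in nodes:
        raise TaxonomyError(f"duplicate taxon_id {node.taxon_id!r}")
    nodes[node.taxon_id] = node


def _load_flat_tsv(path) -> Taxonomy:
    nodes: dict[str, TaxonomyNode] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["taxon_id", "parent_id", "rank", "name"]:
            raise TaxonomyError(
                "flat taxonomy TSV must start with header "
                "'taxon_id\\tparent_id\\trank\\tname'"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TaxonomyError(f"line {lineno}: expected 4 columns")
            _add_node(nodes, TaxonomyNode(fields[0], fields[1], fields[2], fields[3]))
    return Taxonomy(nodes)


def _load_ncbi_dmp(nodes_path, names_path) -> Taxonomy:
    names: dict[str, str] = {}
    with open(names_path) as fh:
        for line in fh:
            fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
            if len(fields) < 4:
                continue
            taxid, name, _unique, name_class = fields[:4]
            if name_class == "scientific name" or taxid not in names:
                names[taxid] = name
    nodes: dict[str, TaxonomyNode] = {}
    with open(nodes_path) as fh:
        for line in fh:
            fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
            if len(fields) < 3:
                raise TaxonomyError("malformed nodes.dmp line")
            taxid, parent, rank = fields[:3]
            _add_node(
                nodes,
                TaxonomyNode(taxid, parent, rank, names.get(taxid, taxid)),
            )
    return Taxonomy(nodes)


def load_taxonomy(
    tsv=None,
    *,
    nodes=None,
    names=None,
) -> Taxonomy:
    """Load a taxonomy from a flat TSV or an NCBI nodes.dmp/names.dmp pair.

    Parameters
    ----------
    tsv : path, optional
        4-column tab-separated file (header required).
    nodes, names : path, optional
        NCBI-style dump pair; both must be given together.
    """
    if tsv is not None:
        if nodes is not None or names is not None:
            raise ValueError("give either tsv or nodes+names, not both")
        return _load_flat_tsv(tsv)
    if nodes is None or names is None:
        raise ValueError("need tsv or both nodes and names")
    return _load_ncbi_dmp(nodes, names)
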