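"""Rooted taxonomy trees.

A :class:`TaxTree` wraps a ``skbio.TreeNode`` whose leaves are genus-level
taxa and whose internal nodes may carry rank-prefixed labels (``p__Phylum``
for phyla).  Phylum membership of a leaf is recovered by walking to the
nearest rank-labelled ancestor.
"""

from __future__ import annotations

import io

from skbio import TreeNode

from .errors import InvalidArgumentError, MappingError

PHYLUM_PREFIX = "p__"
GENUS_PREFIX = "g__"


class TaxTree:
    """A rooted taxonomy tree with uniquely named leaves."""

    def __init__(self, root: TreeNode):
        if root.parent is not None:
            raise InvalidArgumentError("TaxTree root must have no parent")
        names = [t.name for t in root.tips()]
        if len(set(names)) != len(names) or None in names:
            raise InvalidArgumentError("leaf names must be unique and non-empty")
        self._root = root
        self._by_name: dict[str, TreeNode] | None = None

    # -- construction / IO ------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "TaxTree":
        return cls(TreeNode.read(io.StringIO(text), format="newick",
                                 convert_underscores=False))

    @classmethod
    def read(cls, path) -> "TaxTree":
        return cls(TreeNode.read(str(path), format="newick",
                                 convert_underscores=False))

    def to_newick(self) -> str:
        buf = io.StringIO()
        self._root.write(buf, format="newick")
        return buf.getvalue()

    def write(self, path) -> None:
        self._root.write(str(path), format="newick")

    # -- queries ----------------------------------------------------------
    @property
    def root(self) -> TreeNode:
        return self._root

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self._root.tips()]

    def _index(self) -> dict[str, TreeNode]:
        if self._by_name is None:
            self._by_name = {}
            for node in self._root.traverse(include_self=True):
                if node.name is not None:
                    self._by_name[node.name] = node
        return self._by_name

    def find(self, name: str) -> TreeNode:
        try:
            return self._index()[name]
        except KeyError:
            raise MappingError(f"node {name!r} not present in tree") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index()

    def phylum_of(self, leaf_name: str) -> str:
        """Phylum of ``leaf_name``: nearest ancestor labelled ``p__*``."""
        node = self.find(leaf_name)
        while node is not None:
            if node.name is not None and node.name.startswith(PHYLUM_PREFIX):
                return node.name[len(PHYLUM_PREFIX):]
            node = node.parent
        raise MappingError(f"no phylum ancestor for leaf {leaf_name!r}")

    def lineage(self, leaf_name: str) -> tuple[str, ...]:
        """Rank-prefixed lineage from phylum down to the genus leaf."""
        node = self.find(leaf_name)
        parts: list[str] = [GENUS_PREFIX + leaf_name]
        anc = node.parent
        while anc is not None:
            if anc.name is not None and "__" in anc.name:
                parts.append(anc.name)
                if anc.name.startswith(PHYLUM_PREFIX):
                    break
            anc = anc.parent
        return tuple(reversed(parts))

    def taxonomy(self) -> dict[str, tuple[str, ...]]:
        """Leaf name -> lineage tuple for every leaf."""
        return {name: self.lineage(name) for name in self.leaf_names}
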