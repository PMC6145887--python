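"""Two-stage phylogeny-guided aggregation of genus counts into taxonomic groups.

Stage 1 (rarity): moving upward along the tree, a node whose abundance is
below ``min_count`` in strictly more than ``prevalence`` of the samples is
merged into its nearest sibling group and the counts are summed; the rule is
re-checked after every merge (fixpoint), so the result does not depend on
which rare node is visited first.

Stage 2 (collinearity): on the stage-1 groups, sibling groups whose
abundances have Pearson correlation above ``r_threshold`` across samples are
merged and their abundances element-wise averaged, again to fixpoint.

Only tree-neighbouring units ever merge: a unit merges with a sibling group
under the same parent (ties broken by branch order, then name); when a unit
has no remaining sibling because its parent collapsed, the nearest remaining
sibling of an ancestor is used and the audit log records it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import AbundanceTable
from .errors import InvalidArgumentError, MappingError
from .trees import TaxTree


@dataclass
class AuditEntry:
    stage: int
    node_a: str      # unit that fired the rule (absorbed)
    node_b: str      # sibling group it merged into
    rule: str
    statistic: float


@dataclass
class MergeResult:
    """Mapping genera -> groups, the merged matrix and an audit log."""

    groups: dict[str, list[str]]       # ordered: group_id -> member genera
    matrix: pd.DataFrame               # samples x groups, real-valued
    audit: list[AuditEntry] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def member_of(self) -> dict[str, str]:
        return {m: g for g, members in self.groups.items() for m in members}

    def write(self, matrix_path, groups_path, audit_path) -> None:
        import json

        out = self.matrix.copy()
        out.index.name = "sample_id"
        out.to_csv(matrix_path, sep="\t")
        with open(groups_path, "w") as fh:
            json.dump(self.groups, fh, indent=1)
        pd.DataFrame(
            [
                {"stage": e.stage, "node_a": e.node_a, "node_b": e.node_b,
                 "rule": e.rule, "statistic": e.statistic}
                for e in self.audit
            ],
            columns=["stage", "node_a", "node_b", "rule", "statistic"],
        ).to_csv(audit_path, sep="\t", index=False)


class _Unit:
    """A mutable tree node holding (for leaves) a group of genera and values."""

    __slots__ = ("name", "children", "parent", "order", "members", "values")

    def __init__(self, name, order):
        self.name = name
        self.children: list["_Unit"] = []
        self.parent: "_Unit | None" = None
        self.order = order         # branch-order index for deterministic ties
        self.members: list[str] | None = None
        self.values: np.ndarray | None = None

    @property
    def is_group(self):
        return self.members is not None

    def depth_first_groups(self):
        if self.is_group:
            yield self
        for c in self.children:
            yield from c.depth_first_groups()


def _build_units(table: AbundanceTable, tree: TaxTree) -> _Unit:
    """Working tree whose group-leaves carry the table columns.

    A column that is itself a tree leaf is anchored there; a column that is a
    previously merged group (listed in ``table.meta['merge_groups']``) is
    anchored at its first member's leaf position with the full member list.
    """
    leaves = set(tree.leaf_names)
    known_groups: dict[str, list[str]] = table.meta.get("merge_groups", {})
    col_at_leaf: dict[str, tuple[str, list[str]]] = {}
    missing = []
    for col in table.taxon_ids:
        members = known_groups.get(col, [col])
        absent = [m for m in members if m not in leaves]
        if absent:
            missing.extend(absent)
            continue
        col_at_leaf[members[0]] = (col, list(members))
    if missing:
        raise MappingError(f"taxa absent from tree: {missing}")
    counter = [0]

    def convert(node):
        unit = _Unit(node.name, counter[0])
        counter[0] += 1
        if node.is_tip():
            if node.name in col_at_leaf:
                col, members = col_at_leaf[node.name]
                unit.members = members
                unit.values = table.counts[col].to_numpy(dtype=float)
            # tree leaves not anchoring a column are pruned below
        else:
            for child in node.children:
                cu = convert(child)
                if cu is not None:
                    cu.parent = unit
                    unit.children.append(cu)
        if not unit.is_group and not unit.children:
            return None
        return unit

    root = convert(tree.root)
    _collapse_unary(root)
    return root


def _collapse_unary(unit: _Unit) -> None:
    """Replace single-child internal nodes by their child, preserving order."""
    for child in list(unit.children):
        _collapse_unary(child)
    if not unit.is_group and len(unit.children) == 1 and unit.parent is not None:
        child = unit.children[0]
        child.parent = unit.parent
        idx = unit.parent.children.index(unit)
        unit.parent.children[idx] = child
    elif not unit.is_group and len(unit.children) == 1 and unit.parent is None:
        # root with one child: promote the child to root
        child = unit.children[0]
        unit.members = child.members
        unit.values = child.values
        unit.children = child.children
        for c in unit.children:
            c.parent = unit


def _remove(unit: _Unit) -> None:
    parent = unit.parent
    parent.children.remove(unit)
    unit.parent = None
    while parent is not None and not parent.is_group and len(parent.children) == 1:
        child = parent.children[0]
        if parent.parent is None:
            parent.members = child.members
            parent.values = child.values
            parent.children = child.children
            for c in parent.children:
                c.parent = parent
            break
        child.parent = parent.parent
        idx = parent.parent.children.index(parent)
        parent.parent.children[idx] = child
        parent = parent.parent


def _nearest_sibling_group(unit: _Unit) -> tuple["_Unit | None", bool]:
    """Closest group among sibling subtrees; walks up ancestors if needed.

    Returns (group, crossed) where ``crossed`` flags that no direct sibling
    existed and an ancestor's sibling was used.
    """
    node, crossed = unit, False
    while node.parent is not None:
        siblings = [c for c in node.parent.children if c is not node]
        candidates = []
        for sib in siblings:
            for depth, grp in _groups_with_depth(sib, 0):
                candidates.append((depth, grp.order, grp.name or "", grp))
        if candidates:
            candidates.sort(key=lambda c: (c[0], c[1], c[2]))
            return candidates[0][3], crossed
        node = node.parent
        crossed = True
    return None, crossed


def _groups_with_depth(unit: _Unit, depth: int):
    if unit.is_group:
        yield depth, unit
    for c in unit.children:
        yield from _groups_with_depth(c, depth + 1)


def _is_rare(values: np.ndarray, min_count: float, prevalence: float) -> tuple[bool, float]:
    n = values.size
    n_low = int(np.count_nonzero(values < min_count))
    return n_low > prevalence * n, float(n_low)


def _stage1(root: _Unit, min_count: float, prevalence: float,
            audit: list[AuditEntry]) -> None:
    changed = True
    while changed:
        changed = False
        for grp in list(root.depth_first_groups()):
            if grp.parent is None:
                continue  # single remaining group: nothing to merge into
            rare, stat = _is_rare(grp.values, min_count, prevalence)
            if not rare:
                continue
            target, crossed = _nearest_sibling_group(grp)
            if target is None:
                continue
            target.values = target.values + grp.values
            target.members = target.members + grp.members
            rule = "rare" + ("+ancestor-sibling" if crossed else "")
            audit.append(AuditEntry(1, _label(grp), _label(target), rule, stat))
            _remove(grp)
            changed = True
            break  # restart the scan on the modified tree


def _stage2(root: _Unit, r_threshold: float, audit: list[AuditEntry]) -> None:
    changed = True
    while changed:
        changed = False
        for parent in _postorder_internal(root):
            groups = [c for c in parent.children if c.is_group]
            done = False
            for i in range(len(groups)):
                for k in range(i + 1, len(groups)):
                    a, b = groups[i], groups[k]
                    if a.values.std() == 0.0 or b.values.std() == 0.0:
                        audit.append(AuditEntry(
                            2, _label(a), _label(b), "corr-undefined", np.nan))
                        continue
                    r = float(np.corrcoef(a.values, b.values)[0, 1])
                    if r > r_threshold:
                        a.values = (a.values + b.values) / 2.0
                        a.members = a.members + b.members
                        audit.append(AuditEntry(2, _label(b), _label(a), "corr", r))
                        _remove(b)
                        changed = done = True
                        break
                if done:
                    break
            if done:
                break


def _postorder_internal(unit: _Unit):
    for c in unit.children:
        yield from _postorder_internal(c)
    if not unit.is_group:
        yield unit


def _label(unit: _Unit) -> str:
    return "+".join(unit.members)


def _common_rank_name(members: list[str], taxonomy: dict) -> str:
    lineages = [taxonomy.get(m) for m in members]
    if any(l is None for l in lineages):
        return members[0]
    prefix = lineages[0]
    for l in lineages[1:]:
        k = 0
        while k < min(len(prefix), len(l)) and prefix[k] == l[k]:
            k += 1
        prefix = prefix[:k]
    if not prefix:
        return members[0]
    name = prefix[-1]
    return name.split("__", 1)[-1] if "__" in name else name


def _result(root: _Unit, table: AbundanceTable,
            audit: list[AuditEntry]) -> tuple[AbundanceTable, MergeResult]:
    groups: dict[str, list[str]] = {}
    cols: dict[str, np.ndarray] = {}
    for k, grp in enumerate(root.depth_first_groups()):
        if len(grp.members) == 1:
            gid = grp.members[0]
        else:
            gid = f"{_common_rank_name(grp.members, table.taxonomy)}_{k + 1}"
        groups[gid] = list(grp.members)
        cols[gid] = grp.values
    matrix = pd.DataFrame(cols, index=table.counts.index)
    result = MergeResult(groups=groups, matrix=matrix, audit=audit)
    taxonomy = {}
    for gid, members in groups.items():
        lin = table.taxonomy.get(members[0])
        if lin is not None:
            taxonomy[gid] = lin[:-1] + (f"g__{gid}",) if len(members) > 1 else lin
    int_ok = np.allclose(matrix.to_numpy(), np.rint(matrix.to_numpy()))
    out_table = None
    if int_ok:
        meta = dict(table.meta)
        meta["merge_groups"] = {g: list(m) for g, m in groups.items()}
        out_table = AbundanceTable(counts=matrix.round().astype(np.int64),
                                   taxonomy=taxonomy, tree=table.tree, meta=meta)
    return out_table, result


def merge_low_abundance(table: AbundanceTable, tree: TaxTree,
                        min_count: float = 5, prevalence: float = 0.90
                        ) -> tuple[AbundanceTable, MergeResult]:
    """Stage 1: absorb rare taxa into their nearest sibling group, summing counts."""
    audit: list[AuditEntry] = []
    root = _build_units(table, tree)
    _stage1(root, min_count, prevalence, audit)
    out_table, result = _result(root, table, audit)
    return out_table, result


def merge_correlated(table: AbundanceTable, tree: TaxTree,
                     r_threshold: float = 0.7) -> tuple[pd.DataFrame, MergeResult]:
    """Stage 2 alone: average sibling groups correlated above ``r_threshold``."""
    audit: list[AuditEntry] = []
    root = _build_units(table, tree)
    _stage2(root, r_threshold, audit)
    _, result = _result(root, table, audit)
    return result.matrix, result


def merge_taxa(table: AbundanceTable, tree: TaxTree, min_count: float = 5,
               prevalence: float = 0.90, r_threshold: float = 0.7) -> MergeResult:
    """Both stages in order on shared state; the audit log covers both."""
    if not 0.0 <= prevalence <= 1.0:
        raise InvalidArgumentError(f"prevalence must be in [0,1], got {prevalence}")
    audit: list[AuditEntry] = []
    root = _build_units(table, tree)
    _stage1(root, min_count, prevalence, audit)
    _stage2(root, r_threshold, audit)
    _, result = _result(root, table, audit)
    return result
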