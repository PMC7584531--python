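"""Haplogroup assignment by maximal marker concordance on a mini-tree.

Each tree node carries the variants (relative to the packaged
reference, an H-lineage baseline) that define its branch; a node's
*cumulative* marker set is the union along the root-to-node path. A
subject is assigned the node maximising

    score = matched − λ · missing

where ``matched`` counts cumulative defining variants present in the
profile, ``missing`` counts those expected but absent, and λ defaults
to 0.5. Ties go to the deeper node, then lexicographically. Hotspot
positions on the ignore list are excluded from both sides of the score.

This scorer is a deliberately simple local stand-in for web-service
haplogroup classifiers; it is validated by exact label recovery on
marker-complete cohorts, not by agreement with any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .cohort import SubjectProfile, parse_m_notation

DEFAULT_MISMATCH_PENALTY = 0.5


@dataclass
class HaploNode:
    name: str
    parent: str | None
    defining_variants: frozenset[tuple[int, str]]
    depth: int = 0
    cumulative: frozenset[tuple[int, str]] = field(default_factory=frozenset)


@dataclass(frozen=True)
class HaplogroupCall:
    haplogroup: str
    matched: int
    expected: int
    score: float

    def __post_init__(self):
        if not 0 <= self.matched <= self.expected:
            raise ValueError("matched count outside [0, expected]")


class HaploTree:
    """Validated rooted tree of :class:`HaploNode`."""

    def __init__(self, nodes: list[HaploNode]):
        if not nodes:
            raise ValueError("empty haplogroup tree")
        self.nodes: dict[str, HaploNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ValueError(f"duplicate haplogroup name: {node.name}")
            self.nodes[node.name] = node
        roots = [n for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node in nodes:
            if node.parent is not None and node.parent not in self.nodes:
                raise ValueError(
                    f"node {node.name}: orphan parent {node.parent!r}"
                )
        self._resolve()

    def _resolve(self) -> None:
        for node in self.nodes.values():
            seen = {node.name}
            cum: set[tuple[int, str]] = set(node.defining_variants)
            depth = 0
            cur = node
            while cur.parent is not None:
                if cur.parent in seen:
                    raise ValueError(f"cycle in tree at node {cur.parent}")
                seen.add(cur.parent)
                cur = self.nodes[cur.parent]
                cum |= cur.defining_variants
                depth += 1
            node.depth = depth
            node.cumulative = frozenset(cum)

    def ancestors(self, name: str) -> list[str]:
        out = []
        cur = self.nodes[name]
        while cur.parent is not None:
            out.append(cur.parent)
            cur = self.nodes[cur.parent]
        return out

    def __len__(self):
        return len(self.nodes)

    def __contains__(self, name):
        return name in self.nodes


def load_tree(tree_path: str | Path) -> HaploTree:
    """TSV: name, parent ('-' for the root), comma-separated defining
    variants in m.-notation (column optional for marker-free nodes)."""
    nodes = []
    for line in Path(tree_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed tree line: {line!r}")
        name, parent = parts[0], parts[1]
        markers: set[tuple[int, str]] = set()
        if len(parts) > 2 and parts[2].strip():
            for token in parts[2].split(","):
                pos, _, alt = parse_m_notation(token)
                markers.add((pos, alt))
        nodes.append(
            HaploNode(name, None if parent == "-" else parent, frozenset(markers))
        )
    return HaploTree(nodes)


def load_ignore_list(path: str | Path) -> frozenset[int]:
    positions = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            positions.add(int(line))
    return frozenset(positions)


def default_tree() -> HaploTree:
    data = resources.files("mitovar") / "data"
    return load_tree(str(data / "mini_phylotree.tsv"))


def default_ignore_list() -> frozenset[int]:
    data = resources.files("mitovar") / "data"
    return load_ignore_list(str(data / "hotspot_ignore.txt"))


def assign_haplogroup(profile: SubjectProfile, tree: HaploTree,
                      mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
                      ignore: frozenset[int] | None = None) -> HaplogroupCall:
    """Best-scoring haplogroup for a subject's variant set.

    Deterministic: exhaustively scores every node; ties broken by
    depth (deeper wins) then by name.
    """
    if ignore is None:
        ignore = default_ignore_list()
    observed = {k for k in profile.variants if k[0] not in ignore}
    best: tuple[float, int, list[str], HaplogroupCall] | None = None
    for name in sorted(tree.nodes):
        node = tree.nodes[name]
        expected = {k for k in node.cumulative if k[0] not in ignore}
        matched = len(expected & observed)
        missing = len(expected) - matched
        score = matched - mismatch_penalty * missing
        call = HaplogroupCall(name, matched, len(expected), score)
        # max by (score, depth, reversed-name); sorted order makes the
        # lexicographically smaller name win exact ties
        if best is None or (score, node.depth) > (best[0], best[1]):
            best = (score, node.depth, name, call)
    assert best is not None
    return best[3]


def assign_cohort(cohort, tree: HaploTree | None = None,
                  mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
                  ignore: frozenset[int] | None = None):
    """Assign every subject in a cohort (in place); returns the cohort."""
    if tree is None:
        tree = default_tree()
    for subject in cohort:
        subject.haplogroup = assign_haplogroup(
            subject, tree, mismatch_penalty, ignore
        )
    return cohort
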