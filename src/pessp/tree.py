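"""Phylogenetic tree container and Newick serialization.

Trees are rooted data structures interpreted with unrooted semantics where
needed (an unrooted tree is stored with a trifurcating root). Internal nodes
may carry bootstrap support in percent, serialized as an integer internal
node label: ``(A:1,B:2,(C:3,D:4)95:1);``.
"""

from __future__ import annotations

from pathlib import Path


class NewickError(ValueError):
    """Malformed Newick input; carries the 0-based character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


class Node:
    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name: str | None = name
        self.length: float | None = length
        self.support: float | None = support
        self.children: list[Node] = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, n_children={len(self.children)})"


class Tree:
    """A phylogeny: leaves carry taxon ids, edges lengths, nodes support."""

    def __init__(self, root: Node):
        self.root = root
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names")
        for node, _ in self.iter_edges():
            if node.length is not None and node.length < 0:
                raise ValueError("negative branch length")
            if node.support is not None and not (0.0 <= node.support <= 100.0):
                raise ValueError("support outside [0, 100]")

    # -- traversal -------------------------------------------------------
    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_edges(self):
        """Yield (child, parent) for every edge."""
        stack = [(c, self.root) for c in reversed(self.root.children)]
        while stack:
            node, parent = stack.pop()
            yield node, parent
            stack.extend((c, node) for c in reversed(node.children))

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.preorder() if n.is_leaf]

    def clade_leafset(self, node: Node) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            else:
                stack.extend(n.children)
        return frozenset(out)

    # -- unrooted split machinery ---------------------------------------
    def bipartitions(self, include_trivial: bool = False):
        """Canonical splits of the unrooted tree.

        Each edge induces a split; the canonical representation is the side
        NOT containing the lexicographically smallest leaf. Returns a dict
        mapping frozenset -> support (float or None). With a degree-2 root
        the two root edges describe the same split and are merged.
        """
        leaves = frozenset(self.leaf_names())
        ref = min(leaves)
        n = len(leaves)
        out: dict[frozenset[str], float | None] = {}
        for node, _parent in self.iter_edges():
            clade = self.clade_leafset(node)
            side = clade if ref not in clade else leaves - clade
            if not side or side == leaves:
                continue
            if not include_trivial and (len(side) < 2 or len(side) > n - 2):
                continue
            if side not in out or out[side] is None:
                out[side] = node.support
        return out

    def topology_key(self) -> frozenset[frozenset[str]]:
        """Hashable unrooted-topology fingerprint (set of non-trivial splits)."""
        return frozenset(self.bipartitions().keys())

    # -- metrics ---------------------------------------------------------
    def leaf_distances(self):
        """Path-length distances between all leaf pairs (dict of dicts)."""
        from collections import defaultdict

        dist: dict[str, dict[str, float]] = defaultdict(dict)

        def walk(node) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.name, 0.0)]
            groups = []
            for child in node.children:
                b = child.length or 0.0
                groups.append([(leaf, d + b) for leaf, d in walk(child)])
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi]:
                        for lb, db in groups[gj]:
                            dist[la][lb] = dist[lb][la] = da + db
            return [pair for g in groups for pair in g]

        walk(self.root)
        return dist

    # -- newick ----------------------------------------------------------
    def to_newick(self) -> str:
        def fmt_len(x: float) -> str:
            s = f"{x:.6f}".rstrip("0").rstrip(".")
            return s if s else "0"

        def render(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.support is not None:
                    s += str(int(round(node.support)))
            if node.length is not None:
                s += f":{fmt_len(node.length)}"
            return s

        return render(self.root) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n", encoding="utf-8")

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        return cls(_parse_newick(text))

    @classmethod
    def read(cls, path: str | Path) -> "Tree":
        return cls.from_newick(Path(path).read_text(encoding="utf-8").strip())


_LABEL_END = set("(),:;")


def _parse_newick(text: str) -> Node:
    pos = 0
    n = len(text)

    def error(msg: str, at: int):
        raise NewickError(msg, at)

    def skip_ws():
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < n and text[pos] not in _LABEL_END and not text[pos].isspace():
            pos += 1
        return text[start:pos]

    def read_length() -> float | None:
        nonlocal pos
        if pos < n and text[pos] == ":":
            pos += 1
            start = pos
            while pos < n and (text[pos].isdigit() or text[pos] in ".-+eE"):
                pos += 1
            if start == pos:
                error("expected branch length after ':'", pos)
            try:
                return float(text[start:pos])
            except ValueError:
                error(f"bad branch length {text[start:pos]!r}", start)
        return None

    def subtree() -> Node:
        nonlocal pos
        skip_ws()
        if pos >= n:
            error("unexpected end of input", pos)
        if text[pos] == "(":
            pos += 1
            children = [subtree()]
            while True:
                skip_ws()
                if pos >= n:
                    error("unexpected end of input", pos)
                if text[pos] == ",":
                    pos += 1
                    children.append(subtree())
                elif text[pos] == ")":
                    pos += 1
                    break
                else:
                    error(f"expected ',' or ')', found {text[pos]!r}", pos)
            label = read_label()
            node = Node(children=children)
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label  # non-numeric internal label kept as name
            node.length = read_length()
            return node
        label = read_label()
        if not label:
            error(f"expected a leaf label, found {text[pos]!r}", pos)
        node = Node(name=label)
        node.length = read_length()
        return node

    root = subtree()
    skip_ws()
    if pos >= n or text[pos] != ";":
        error("expected ';'", pos)
    pos += 1
    skip_ws()
    if pos != n:
        error("trailing characters after ';'", pos)
    return root


def read_newick(path: str | Path) -> Tree:
    """Read one tree from a .nwk file."""
    return Tree.read(path)


def write_newick(tree: Tree, path: str | Path) -> None:
    """Write a tree as Newick (supports as integer internal labels)."""
    tree.write(path)
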