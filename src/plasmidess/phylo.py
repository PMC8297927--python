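"""Gene-tree machinery for plasmid/chromosome transfer classification.

Tips of a gene tree are labeled ``P`` (plasmid-encoded homolog) or ``C``
(chromosome-encoded homolog).  Under vertical inheritance the two residences
separate cleanly: a single edge of the tree splits all plasmid tips from all
chromosomal tips ("deep split").  Lateral transfer between replicon types
shows up as tips of one residence nesting inside clades of the other; the
minimum number of residence changes on the tree (small parsimony) counts the
transfer events, and the direction of each change (C->P: transfer to plasmid,
P->C: transfer/translocation to chromosome) is read off a minimal ancestral
labeling.

The module provides Newick parsing/serialization, neighbor-joining tree
construction from a distance matrix, midpoint rooting, Fitch small parsimony
with direction-resolved event inference, and the topology classifier that
bins each gene tree into ``split`` / ``transfer_to_plasmid`` /
``transfer_to_chromosome`` / ``mixed``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

P, C = "P", "C"
CATEGORIES = ("split", "transfer_to_plasmid", "transfer_to_chromosome", "mixed")


class NewickError(ValueError):
    """Malformed Newick input; carries the 0-based offending position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str = "", length: float | None = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class LabeledTree:
    """Rooted tree with branch lengths and P/C-labelable tips."""

    root: Node

    def nodes(self, order: str = "pre") -> list[Node]:
        out: list[Node] = []

        def walk(n: Node) -> None:
            if order == "pre":
                out.append(n)
            for c in n.children:
                walk(c)
            if order == "post":
                out.append(n)

        walk(self.root)
        return out

    def tips(self) -> list[Node]:
        return [n for n in self.nodes() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def n_tips(self) -> int:
        return len(self.tips())

    def copy(self) -> "LabeledTree":
        return parse_newick(serialize_newick(self, canonical=False))

    def __str__(self) -> str:
        return serialize_newick(self)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_NAME_CHARS = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.|-+#/")


def parse_newick(text: str) -> LabeledTree:
    """Parse a Newick string into a :class:`LabeledTree`.

    Raises :class:`NewickError` with the offending position on malformed
    input (unbalanced parentheses, dangling commas, missing semicolon).
    """
    s = text.strip()
    if not s:
        raise NewickError("empty input", 0)
    pos = 0

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def parse_name() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] in _NAME_CHARS:
            pos += 1
        return s[start:pos]

    def parse_length() -> float | None:
        nonlocal pos
        if peek() != ":":
            return None
        pos += 1
        start = pos
        while pos < len(s) and (s[pos].isdigit() or s[pos] in ".eE+-"):
            pos += 1
        if start == pos:
            raise NewickError("expected branch length after ':'", pos)
        try:
            return float(s[start:pos])
        except ValueError:
            raise NewickError(f"bad branch length {s[start:pos]!r}", start) from None

    def parse_subtree() -> Node:
        nonlocal pos
        if peek() == "(":
            open_pos = pos
            pos += 1
            node = Node()
            node.add(parse_subtree())
            while peek() == ",":
                pos += 1
                if peek() in ("", ")", ","):
                    raise NewickError("dangling comma", pos)
                node.add(parse_subtree())
            if peek() != ")":
                raise NewickError("unbalanced parentheses", open_pos)
            pos += 1
            node.name = parse_name()
            node.length = parse_length()
            return node
        name = parse_name()
        if not name and peek() != ":":
            raise NewickError("expected taxon name or '('", pos)
        node = Node(name)
        node.length = parse_length()
        return node

    root = parse_subtree()
    if peek() != ";":
        raise NewickError("expected ';' at end of tree", pos)
    pos += 1
    if pos != len(s):
        raise NewickError("trailing characters after ';'", pos)
    return LabeledTree(root)


def _min_tip(n: Node) -> str:
    if n.is_tip:
        return n.name
    return min(_min_tip(c) for c in n.children)


def serialize_newick(tree: LabeledTree, canonical: bool = True) -> str:
    """Serialize to Newick.

    With ``canonical=True`` children are ordered by their smallest tip name,
    which makes serialization byte-stable across round trips.  Branch lengths
    use Python's shortest round-trip float repr, so lengths survive
    parse/serialize exactly.
    """

    def fmt(n: Node) -> str:
        if n.is_tip:
            body = n.name
        else:
            kids = sorted(n.children, key=_min_tip) if canonical else n.children
            body = "(" + ",".join(fmt(c) for c in kids) + ")" + n.name
        if n.length is not None:
            body += f":{n.length!r}"
        return body

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist, names: list[str] | None = None) -> LabeledTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    On additive matrices NJ recovers the unique additive topology.  Ties in
    the Q criterion are broken toward the lowest (row, column) index pair so
    the output is deterministic.  The returned tree is unrooted, represented
    with a trifurcating root (the final three-way join); negative estimated
    branch lengths are clamped to zero.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    if np.any(D < -1e-12):
        raise ValueError("distance matrix must be non-negative")
    n = D.shape[0]
    if names is None:
        names = [f"t{i}" for i in range(n)]
    if len(names) != n:
        raise ValueError("names length mismatch")
    if n < 2:
        raise ValueError("need at least 2 taxa")

    nodes: list[Node] = [Node(nm) for nm in names]
    if n == 2:
        root = Node()
        a, b = nodes
        a.length = b.length = D[0, 1] / 2.0
        root.add(a)
        root.add(b)
        return LabeledTree(root)

    D = D.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie break: argmin of row-major scan
        flat = np.argmin(Q)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = D[ai, aj]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = Node()
        nodes[ai].length = li
        nodes[aj].length = lj
        new.add(nodes[ai])
        new.add(nodes[aj])
        # distances to the new node
        newrow = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (ai, aj):
                continue
            newrow[k] = 0.5 * (D[ai, k] + D[aj, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newrow[:-1]
        D[:-1, -1] = newrow[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    # three-point closed form for the final join
    root = Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
        root.add(nodes[idx])
    return LabeledTree(root)


# ---------------------------------------------------------------------------
# Midpoint rooting
# ---------------------------------------------------------------------------

def _adjacency(tree: LabeledTree) -> dict[Node, list[tuple[Node, float]]]:
    adj: dict[Node, list[tuple[Node, float]]] = {n: [] for n in tree.nodes()}
    for n in tree.nodes():
        for ch in n.children:
            ln = ch.length if ch.length is not None else 0.0
            adj[n].append((ch, ln))
            adj[ch].append((n, ln))
    return adj


def _rebuild_rooted(adj: dict[Node, list[tuple[Node, float]]], root: Node) -> LabeledTree:
    new_nodes: dict[Node, Node] = {}

    def build(old: Node, parent_old: Node | None, length: float | None) -> Node:
        nn = Node(old.name, length)
        new_nodes[old] = nn
        for nbr, ln in adj[old]:
            if nbr is parent_old:
                continue
            nn.add(build(nbr, old, ln))
        return nn

    r = build(root, None, None)
    return LabeledTree(r)


def tip_to_tip_paths(tree: LabeledTree) -> dict[tuple[str, str], float]:
    """All tip-to-tip path lengths (by DFS from every tip)."""
    adj = _adjacency(tree)
    tips = tree.tips()
    out: dict[tuple[str, str], float] = {}
    for start in tips:
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for t in tips:
            if t is not start:
                out[(start.name, t.name)] = dist[t]
    return out


def midpoint_root(tree: LabeledTree, tol: float = 1e-12) -> LabeledTree:
    """Root the tree at the midpoint of the longest tip-to-tip path.

    After rooting, the two largest root-to-tip distances are equal (up to
    floating error).  Raises ``ValueError`` when every branch length is zero
    (the midpoint is undefined).
    """
    if tree.n_tips() < 2:
        raise ValueError("midpoint rooting needs at least 2 tips")
    adj = _adjacency(tree)
    tips = tree.tips()

    best = (-1.0, "", "", None, None)
    # farthest pair by DFS from each tip; deterministic lexicographic tie break
    for start in sorted(tips, key=lambda t: t.name):
        dist: dict[Node, float] = {start: 0.0}
        prev: dict[Node, Node] = {}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    prev[v] = u
                    stack.append(v)
        for t in sorted(tips, key=lambda t: t.name):
            if t is start:
                continue
            key = (dist[t], start.name, t.name)
            if key[0] > best[0] + tol:
                best = (dist[t], start.name, t.name, start, t)
    total, _, _, a, b = best
    if total <= tol:
        raise ValueError("midpoint undefined: all branch lengths are zero")

    # path a -> b
    dist = {a: 0.0}
    prev = {}
    stack = [a]
    while stack:
        u = stack.pop()
        for v, ln in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + ln
                prev[v] = u
                stack.append(v)
    path = [b]
    while path[-1] is not a:
        path.append(prev[path[-1]])
    path.reverse()  # a ... b

    half = total / 2.0
    acc = 0.0
    for u, v in zip(path, path[1:]):
        ln = next(l for (w, l) in adj[u] if w is v)
        if abs(acc - half) <= 1e-9:
            return _rebuild_rooted(adj, u)
        if acc + ln > half + 1e-9:
            # midpoint inside edge (u, v): insert a new root node
            off = half - acc  # distance from u
            mid = Node()
            adj[mid] = [(u, off), (v, ln - off)]
            adj[u] = [(w, l) if w is not v else (mid, off) for (w, l) in adj[u]]
            adj[v] = [(w, l) if w is not u else (mid, ln - off) for (w, l) in adj[v]]
            return _rebuild_rooted(adj, mid)
        acc += ln
    return _rebuild_rooted(adj, path[-1])


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def labels_from_names(tree: LabeledTree) -> dict[str, str]:
    """Infer P/C labels from tip names of the form ``P_12`` / ``C_3``."""
    out = {}
    for name in tree.tip_names():
        head = name.split("_", 1)[0]
        if head not in (P, C):
            raise ValueError(f"cannot infer label from tip name {name!r}")
        out[name] = head
    return out


def _check_labels(tree: LabeledTree, labels: dict[str, str]) -> None:
    for t in tree.tips():
        if t.name not in labels:
            raise ValueError(f"unlabeled tip {t.name!r}")
        if labels[t.name] not in (P, C):
            raise ValueError(f"label for {t.name!r} must be 'P' or 'C'")


# ---------------------------------------------------------------------------
# Fitch small parsimony and event inference
# ---------------------------------------------------------------------------

def fitch_min_changes(tree: LabeledTree, labels: dict[str, str]
                      ) -> tuple[int, dict[Node, frozenset]]:
    """Minimum number of P<->C label changes on a rooted tree (Fitch).

    Returns the change count and the per-node Fitch state sets used for
    direction inference.
    """
    _check_labels(tree, labels)
    states: dict[Node, frozenset] = {}
    changes = 0
    for node in tree.nodes(order="post"):
        if node.is_tip:
            states[node] = frozenset({labels[node.name]})
            continue
        inter = None
        union: frozenset = frozenset()
        for ch in node.children:
            s = states[ch]
            inter = s if inter is None else (inter & s)
            union = union | s
        if inter:
            states[node] = inter
        else:
            states[node] = union
            changes += 1
    return changes, states


def infer_event_directions(tree: LabeledTree, states: dict[Node, frozenset],
                           root_preference: str = C,
                           ) -> tuple[list[tuple[str, Node]], bool]:
    """One minimal ancestral labeling, with its change branches and directions.

    Top-down Fitch refinement: the root takes its Fitch state if unique,
    otherwise ``root_preference`` (chromosome by default — the ancestral
    residence of essential genes); each child copies its parent's state when
    compatible, else switches.  Returns ``(events, root_ambiguous)`` where
    each event is ``("C>P" | "P>C", child_node)`` for the branch above
    ``child_node``.
    """
    root = tree.root
    root_set = states[root]
    root_ambiguous = len(root_set) > 1
    assign: dict[Node, str] = {
        root: root_preference if root_ambiguous else next(iter(root_set))
    }
    events: list[tuple[str, Node]] = []
    for node in tree.nodes(order="pre"):
        if node is root:
            continue
        ps = assign[node.parent]
        s = states[node]
        if ps in s:
            assign[node] = ps
        else:
            st = next(iter(s))  # binary character: s is a singleton here
            assign[node] = st
            events.append((f"{ps}>{st}", node))
    return events, root_ambiguous


@dataclass
class TopologyCall:
    """Classification of one gene tree into the transfer taxonomy."""

    category: str
    n_changes: int
    events: list[tuple[str, Node]] = field(default_factory=list)
    bipartition_compatible: bool = False
    root_ambiguous: bool = False

    @property
    def directions(self) -> list[str]:
        return [d for d, _ in self.events]


def bipartition_compatibility_screen(tree: LabeledTree, labels: dict[str, str]) -> bool:
    """True iff a single edge separates all P tips from all C tips.

    The deterministic necessary condition for strict vertical divergence
    (a "deep split"); uniform-label trees pass trivially.  Implemented as a
    direct edge scan, independently of the parsimony machinery.
    """
    _check_labels(tree, labels)
    tipset: dict[Node, frozenset] = {}
    for node in tree.nodes(order="post"):
        if node.is_tip:
            tipset[node] = frozenset({node.name})
        else:
            tipset[node] = frozenset().union(*(tipset[c] for c in node.children))
    all_tips = tipset[tree.root]
    lab = lambda names: {labels[n] for n in names}
    if len(lab(all_tips)) == 1:
        return True
    for node in tree.nodes():
        if node is tree.root:
            continue
        below, above = tipset[node], all_tips - tipset[node]
        if below and above and len(lab(below)) == 1 and len(lab(above)) == 1 \
                and lab(below) != lab(above):
            return True
    return False


def classify_gene_tree(tree: LabeledTree, labels: dict[str, str] | None = None
                       ) -> TopologyCall:
    """Bin a rooted, labeled gene tree into the transfer-topology taxonomy.

    * ``split`` — at most one residence change: plasmid and chromosomal
      homologs diverge cleanly (vertical evolution).
    * ``transfer_to_plasmid`` — >= 2 changes, all chromosome->plasmid.
    * ``transfer_to_chromosome`` — >= 2 changes, all plasmid->chromosome.
    * ``mixed`` — changes in both directions (deep divergence plus transfer
      events, or bidirectional transfer).
    """
    if labels is None:
        labels = labels_from_names(tree)
    n_changes, states = fitch_min_changes(tree, labels)
    events, root_ambiguous = infer_event_directions(tree, states)
    if n_changes <= 1:
        category = "split"
    else:
        dirs = {d for d, _ in events}
        if dirs == {"C>P"}:
            category = "transfer_to_plasmid"
        elif dirs == {"P>C"}:
            category = "transfer_to_chromosome"
        else:
            category = "mixed"
    return TopologyCall(
        category=category,
        n_changes=n_changes,
        events=events,
        bipartition_compatible=n_changes <= 1,
        root_ambiguous=root_ambiguous,
    )


# ---------------------------------------------------------------------------
# Exhaustive minimal-labeling enumeration (identifiability support)
# ---------------------------------------------------------------------------

def enumerate_minimal_labelings(tree: LabeledTree, labels: dict[str, str],
                                cap: int = 256) -> list[dict[Node, str]]:
    """All minimum-change ancestral labelings (Sankoff backtracking).

    Stops after ``cap`` labelings.  Used to decide whether a planted event
    history is the unique parsimony explanation, and as an oracle for the
    Fitch machinery on small trees.
    """
    _check_labels(tree, labels)
    INF = float("inf")
    cost: dict[Node, dict[str, float]] = {}
    for node in tree.nodes(order="post"):
        if node.is_tip:
            lb = labels[node.name]
            cost[node] = {P: 0.0 if lb == P else INF,
                          C: 0.0 if lb == C else INF}
        else:
            cost[node] = {
                s: sum(min(cost[ch][t] + (s != t) for t in (P, C))
                       for ch in node.children)
                for s in (P, C)
            }
    root = tree.root
    best = min(cost[root].values())
    out: list[dict[Node, str]] = []

    def backtrack(pending: list[tuple[Node, str]], assign: dict[Node, str]) -> None:
        if len(out) >= cap:
            return
        if not pending:
            out.append(dict(assign))
            return
        node, state = pending[-1]
        rest = pending[:-1]
        choices = []
        for ch in node.children:
            opts = [t for t in (P, C)
                    if cost[ch][t] + (state != t)
                    == min(cost[ch][tt] + (state != tt) for tt in (P, C))]
            choices.append((ch, opts))
        for combo in itertools.product(*(opts for _, opts in choices)):
            a2 = dict(assign)
            p2 = list(rest)
            for (ch, _), st in zip(choices, combo):
                a2[ch] = st
                if not ch.is_tip:
                    p2.append((ch, st))
            backtrack(p2, a2)

    for s in (P, C):
        if cost[root][s] == best:
            backtrack([(root, s)], {root: s})
    return out


def events_of_labeling(tree: LabeledTree, assign: dict[Node, str]
                       ) -> list[tuple[str, Node]]:
    """Change branches and directions implied by a full node labeling."""
    ev = []
    for node in tree.nodes(order="pre"):
        if node is tree.root:
            continue
        a, b = assign[node.parent], assign[node]
        if a != b:
            ev.append((f"{a}>{b}", node))
    return ev


def category_of_events(n_changes: int, directions: list[str]) -> str:
    """Taxonomy rule shared by the classifier and the generator's bookkeeping."""
    if n_changes <= 1:
        return "split"
    dirs = set(directions)
    if dirs == {"C>P"}:
        return "transfer_to_plasmid"
    if dirs == {"P>C"}:
        return "transfer_to_chromosome"
    return "mixed"
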