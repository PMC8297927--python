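"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or textbook DP,
sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

NEG = float("-inf")


def gotoh_score(a: str, b: str, matrix: str = "BLOSUM62",
                gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Affine-gap global alignment score by the three-matrix Gotoh DP.

    Convention: a gap of length L costs gap_open + (L-1)*gap_extend; end
    gaps are penalized like internal ones.
    """
    sub = substitution_matrices.load(matrix)
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to '-')
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend,
                           Iy[i - 1, j] - gap_open)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend,
                           Ix[i, j - 1] - gap_open)
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


def best_hit_pairs(scores: np.ndarray, a_names: list[str],
                   b_names: list[str]) -> set[tuple[str, str]]:
    """Reciprocal best hits on a bipartite score matrix by double loop.

    Ties for the best score yield no best hit for that gene.
    """
    out = set()
    n, m = scores.shape
    for i in range(n):
        row = scores[i]
        jbest = int(np.argmax(row))
        if (row == row[jbest]).sum() > 1:
            continue
        col = scores[:, jbest]
        ibest = int(np.argmax(col))
        if (col == col[ibest]).sum() > 1:
            continue
        if ibest == i:
            out.add(tuple(sorted((a_names[i], b_names[jbest]))))
    return out


def exhaustive_min_changes(tree, labels: dict[str, str]) -> int:
    """Minimum label changes by enumerating every internal-node labeling."""
    internals = [n for n in tree.nodes() if not n.is_tip]
    tips = tree.tips()
    best = len(tips) + len(internals)
    for combo in itertools.product("PC", repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), combo))
        for t in tips:
            assign[id(t)] = labels[t.name]
        changes = sum(
            1
            for n in tree.nodes()
            if n.parent is not None and assign[id(n)] != assign[id(n.parent)]
        )
        best = min(best, changes)
    return best


def root_to_tip_distances(tree) -> list[float]:
    """Root-to-tip path lengths of a rooted tree (plain recursion)."""
    out = []

    def walk(node, acc):
        acc = acc + (node.length or 0.0)
        if node.is_tip:
            out.append(acc)
        for c in node.children:
            walk(c, acc)

    walk(tree.root, -(tree.root.length or 0.0))
    return out


def subsequence_instances(seq, pattern, max_insertions: int) -> bool:
    """Does ``pattern`` occur in ``seq`` as an ordered subsequence with at
    most ``max_insertions`` interleaved foreign genes?  Checked by explicit
    enumeration of index combinations."""
    plen = len(pattern)
    positions = [
        [i for i, s in enumerate(seq) if s == sym] for sym in pattern
    ]
    for combo in itertools.product(*positions):
        if all(x < y for x, y in zip(combo, combo[1:])):
            span = combo[-1] - combo[0] + 1
            if span - plen <= max_insertions:
                return True
    return False


def enumerate_blocks(sequences: dict, min_length: int, quorum: int,
                     max_insertions: int, max_pattern_len: int = 6):
    """All maximal conserved blocks by brute force.

    Candidate patterns are every bounded-span subsequence of every input
    sequence (up to ``max_pattern_len``); support is recomputed with the
    enumeration matcher; maximality uses the same rule as the detector
    (no reported block is a sub-pattern of another with identical support).
    """
    candidates = set()
    for seq in sequences.values():
        L = len(seq)
        for length in range(min_length, max_pattern_len + 1):
            for idxs in itertools.combinations(range(L), length):
                if idxs[-1] - idxs[0] + 1 - length <= max_insertions:
                    pat = tuple(seq[i] for i in idxs)
                    candidates.add(min(pat, tuple(reversed(pat))))
    supported = {}
    for pat in candidates:
        rev = tuple(reversed(pat))
        sup = frozenset(
            rid for rid, seq in sequences.items()
            if subsequence_instances(seq, pat, max_insertions)
            or (rev != pat and subsequence_instances(seq, rev, max_insertions))
        )
        if len(sup) >= quorum:
            supported[pat] = sup

    def is_sub(a, b):
        def sub(x, y):
            it = iter(y)
            return all(any(s == t for t in it) for s in x)
        return sub(a, b) or sub(a, tuple(reversed(b)))

    return {
        pat: sup for pat, sup in supported.items()
        if not any(pat != o and len(o) > len(pat) and osup == sup and is_sub(pat, o)
                   for o, osup in supported.items())
    }


def ecdf_by_sorting(values):
    """ECDF by rank: F(x) = #{v <= x} / n on the sorted unique values."""
    v = sorted(values)
    n = len(v)
    xs = sorted(set(v))
    return xs, [sum(1 for u in v if u <= x) / n for x in xs]
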