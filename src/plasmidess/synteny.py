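"""Conserved syntenic blocks: recurring gene-order patterns across replicons.

A conserved syntenic block (CSB) is an ordered list of gene families that
recurs in at least ``quorum`` replicons, where each occurrence may carry up
to ``max_insertions`` foreign genes interleaved between the matched
positions.  A block matches a replicon in either strand orientation (the
pattern or its reverse); replicons are treated as linear sequences.

The detector grows frequent patterns rightward, counting occurrences with a
bounded-insertion subsequence matcher; it reports maximal blocks only (a
block contained in a longer block with identical replicon support is
suppressed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence


@dataclass(frozen=True)
class BlockInstance:
    replicon_id: str
    start: int           # index of first matched gene
    end: int             # index of last matched gene (inclusive)
    n_insertions: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class ConservedBlock:
    pattern: tuple          # ordered family ids (canonical orientation)
    instances: list[BlockInstance] = field(default_factory=list)
    quorum: int = 0

    @property
    def length(self) -> int:
        return len(self.pattern)

    def support(self) -> frozenset:
        return frozenset(i.replicon_id for i in self.instances)


def canonical_pattern(pattern: Sequence) -> tuple:
    """A pattern and its reversal denote the same block; keep the smaller."""
    fwd, rev = tuple(pattern), tuple(reversed(pattern))
    return min(fwd, rev)


def match_pattern(seq: Sequence, pattern: Sequence, max_insertions: int,
                  ) -> list[tuple[int, int, int]]:
    """Occurrences of ``pattern`` in ``seq`` as an ordered subsequence with at
    most ``max_insertions`` interleaved foreign genes.

    Returns ``(start, end, n_insertions)`` triples, one per start position
    (the earliest-completion match, which minimizes insertions for that
    start).  Forward orientation only; callers handle the reverse.
    """
    out = []
    plen = len(pattern)
    if plen == 0:
        return out
    for start in range(len(seq) - plen + 1):
        if seq[start] != pattern[0]:
            continue
        pos = start
        ok = True
        for sym in pattern[1:]:
            nxt = None
            # earliest next occurrence minimizes the total span
            for j in range(pos + 1, min(len(seq), pos + 2 + max_insertions)):
                if seq[j] == sym:
                    nxt = j
                    break
            if nxt is None:
                ok = False
                break
            pos = nxt
        if not ok:
            continue
        n_ins = (pos - start + 1) - plen
        if n_ins <= max_insertions:
            out.append((start, pos, n_ins))
    return out


def find_instances(sequences: Mapping[str, Sequence], pattern: Sequence,
                   max_insertions: int) -> list[BlockInstance]:
    """All instances of a pattern (either orientation) across replicons."""
    pat = tuple(pattern)
    rev = tuple(reversed(pat))
    inst: list[BlockInstance] = []
    for rid in sorted(sequences):
        seq = list(sequences[rid])
        found = {(s, e): n for s, e, n in match_pattern(seq, pat, max_insertions)}
        if rev != pat:
            for s, e, n in match_pattern(seq, rev, max_insertions):
                if (s, e) not in found or n < found[(s, e)]:
                    found[(s, e)] = n
        for (s, e), n in sorted(found.items()):
            inst.append(BlockInstance(rid, s, e, n))
    return inst


def _support(sequences: Mapping[str, Sequence], pattern: tuple,
             max_insertions: int) -> set:
    sup = set()
    rev = tuple(reversed(pattern))
    for rid, seq in sequences.items():
        seq = list(seq)
        if match_pattern(seq, pattern, max_insertions) or (
                rev != pattern and match_pattern(seq, rev, max_insertions)):
            sup.add(rid)
    return sup


def find_conserved_blocks(sequences: Mapping[str, Sequence],
                          min_length: int = 3, quorum: int = 2,
                          max_insertions: int = 3,
                          max_length: int | None = None,
                          ) -> list[ConservedBlock]:
    """Mine maximal conserved syntenic blocks.

    ``sequences`` maps replicon id -> gene order over the family alphabet.
    A reported block has length >= ``min_length``, occurs in >= ``quorum``
    replicons (in either orientation, with <= ``max_insertions`` foreign
    genes per occurrence), and is not an ordered sub-pattern of another
    reported block with identical replicon support.
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    if quorum < 2:
        raise ValueError("quorum must be >= 2")
    if max_insertions < 0:
        raise ValueError("max_insertions must be >= 0")
    if not sequences:
        return []
    if max_length is None:
        max_length = max((len(s) for s in sequences.values()), default=0)

    # frequent single families seed the growth
    sym_support: dict = {}
    for rid, seq in sequences.items():
        for sym in set(seq):
            sym_support.setdefault(sym, set()).add(rid)
    frequent = {s for s, sup in sym_support.items() if len(sup) >= quorum}
    alphabet = sorted(frequent)

    # grow rightward; keep any pattern whose support meets the quorum
    found: dict[tuple, set] = {}
    frontier: list[tuple] = [(s,) for s in alphabet]
    while frontier:
        nxt: list[tuple] = []
        for pat in frontier:
            for sym in alphabet:
                cand = pat + (sym,)
                if len(cand) > max_length:
                    continue
                sup = _support(sequences, cand, max_insertions)
                if len(sup) >= quorum:
                    key = canonical_pattern(cand)
                    if key not in found:
                        found[key] = sup
                    nxt.append(cand)
        frontier = nxt

    candidates = {p: sup for p, sup in found.items() if len(p) >= min_length}

    def subpattern(a: tuple, b: tuple) -> bool:
        """a is an ordered subsequence of b (or of reversed b)."""
        def sub(x: tuple, y: tuple) -> bool:
            it = iter(y)
            return all(any(s == t for t in it) for s in x)
        return sub(a, b) or sub(a, tuple(reversed(b)))

    maximal = []
    for pat, sup in candidates.items():
        dominated = any(
            pat != other and len(other) > len(pat) and osup == sup
            and subpattern(pat, other)
            for other, osup in candidates.items())
        if not dominated:
            maximal.append(pat)

    blocks = []
    for pat in sorted(maximal):
        inst = find_instances(sequences, pat, max_insertions)
        blocks.append(ConservedBlock(pattern=pat, instances=inst, quorum=quorum))
    return blocks


def block_conservation_fraction(block: ConservedBlock,
                                candidate_replicons: Sequence) -> float:
    """Fraction of candidate replicons carrying at least one block instance."""
    cands = set(candidate_replicons)
    if not cands:
        raise ValueError("candidate replicon set must be non-empty")
    return len(block.support() & cands) / len(cands)


def blocks_frame(blocks: Sequence[ConservedBlock]):
    import pandas as pd

    rows = []
    for i, b in enumerate(blocks, start=1):
        for inst in b.instances:
            rows.append({
                "block_id": f"B{i:03d}",
                "pattern": "|".join(map(str, b.pattern)),
                "length": b.length,
                "replicon_id": inst.replicon_id,
                "start": inst.start,
                "end": inst.end,
                "n_insertions": inst.n_insertions,
            })
    return pd.DataFrame(rows, columns=["block_id", "pattern", "length",
                                       "replicon_id", "start", "end",
                                       "n_insertions"])
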