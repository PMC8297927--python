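"""Plasmid protein families: rBBH -> identity filter -> Markov clustering.

The pipeline mirrors standard comparative-genomics practice for building
homologous protein families across a pangenome:

1. all-vs-all global alignment of plasmid-encoded proteins (Needleman-
   Wunsch with affine gaps, BLOSUM62, needle-like gap costs);
2. reciprocal best hits (rBBH) between replicon pairs as the orthology
   proxy, screened on a normalized alignment score (``evalue_proxy``);
3. pairs with >= 50% identical amino acids clustered into families with the
   Markov clustering algorithm (MCL);
4. chromosome-encoded homologs of each family mapped with a screen followed
   by a >= 40% identity floor, recorded per isolate.

E-values are a database-size-dependent BLAST construct; here the screen is a
normalized alignment score (raw score over the smaller self-score, so 1.0
means as good as aligning a sequence to itself).  The decisive filters are
the identity floors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
#: normalized-score screen floor standing in for the BLAST E-value cutoffs
DEFAULT_SCREEN = 0.05
FAMILY_IDENTITY_FLOOR = 50.0
CHROM_IDENTITY_FLOOR = 40.0


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected similarity between two genes from a global alignment."""

    gene_a: str
    gene_b: str
    score: float          # substitution-matrix units
    identity: float       # % identical positions over alignment length
    evalue_proxy: float   # score / min(self-score), in (-inf, 1]

    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


@dataclass
class FamilyPartition:
    """Disjoint plasmid protein families plus chromosomal-homolog map.

    ``families`` maps family id -> set of plasmid gene ids (singletons
    included); ``chrom_homologs`` maps family id -> set of
    ``(isolate_id, chromosomal gene id)`` pairs that passed the 40% floor.
    """

    families: dict[str, frozenset] = field(default_factory=dict)
    chrom_homologs: dict[str, set] = field(default_factory=dict)

    def family_of(self) -> dict[str, str]:
        return {g: f for f, members in self.families.items() for g in members}

    def n_genes(self) -> int:
        return sum(len(m) for m in self.families.values())

    def validate(self) -> None:
        seen: set = set()
        for members in self.families.values():
            if seen & members:
                raise AssertionError("families are not disjoint")
            seen |= members

    def families_frame(self) -> pd.DataFrame:
        rows = [(f, g) for f, members in sorted(self.families.items())
                for g in sorted(members)]
        return pd.DataFrame(rows, columns=["family_id", "gene_id"])

    def chrom_homologs_frame(self) -> pd.DataFrame:
        rows = [(f, iso, g) for f, pairs in sorted(self.chrom_homologs.items())
                for iso, g in sorted(pairs)]
        return pd.DataFrame(rows, columns=["family_id", "isolate_id", "chrom_gene_id"])


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    al = PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load(matrix)
    # first gapped position costs gap_open, each further one gap_extend
    al.open_gap_score = -gap_open
    al.extend_gap_score = -gap_extend
    al.mode = "global"
    return al


def _check_protein(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"illegal amino-acid characters: {sorted(bad)}")


def global_identity(seq_a: str, seq_b: str, matrix: str = DEFAULT_MATRIX,
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND,
                    ) -> tuple[float, float]:
    """Needleman-Wunsch global alignment score and percent identity.

    Affine gap costs: a gap of length L costs ``gap_open + (L-1)*gap_extend``;
    end gaps are penalized like internal ones.  Identity is identical aligned
    positions divided by total alignment length (gap columns included), x100.
    """
    _check_protein(seq_a)
    _check_protein(seq_b)
    al = _aligner(matrix, gap_open, gap_extend)
    aln = al.align(seq_a, seq_b)[0]
    counts = aln.counts()
    identity = 100.0 * counts.identities / aln.length
    return float(aln.score), identity


def self_score(seq: str, matrix: str = DEFAULT_MATRIX) -> float:
    m = substitution_matrices.load(matrix)
    return float(sum(m[a, a] for a in seq))


# ---------------------------------------------------------------------------
# All-vs-all similarity with a k-mer prescreen
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int) -> frozenset:
    if len(seq) < k:
        return frozenset({seq})
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def _candidate_pairs(seqs_a: Mapping[str, str], seqs_b: Mapping[str, str] | None,
                     k: int, min_shared: int) -> Iterable[tuple[str, str]]:
    """Pairs sharing >= min_shared k-mers (inverted-index scan)."""
    index: dict[str, list[str]] = {}
    for gid, seq in seqs_a.items():
        for km in _kmer_set(seq, k):
            index.setdefault(km, []).append(gid)
    targets = seqs_b if seqs_b is not None else seqs_a
    for gid, seq in targets.items():
        hits: dict[str, int] = {}
        for km in _kmer_set(seq, k):
            for other in index.get(km, ()):
                hits[other] = hits.get(other, 0) + 1
        for other, n in hits.items():
            if seqs_b is None and other >= gid:
                continue  # each unordered pair once; no self-comparison
            ms = min(min_shared, max(1, min(len(seq), len(seqs_a[other])) - k))
            if n >= ms:
                yield (other, gid) if seqs_b is None else (other, gid)


def all_vs_all_similarity(genes: Mapping[str, str],
                          matrix: str = DEFAULT_MATRIX,
                          gap_open: float = DEFAULT_GAP_OPEN,
                          gap_extend: float = DEFAULT_GAP_EXTEND,
                          screen_floor: float = DEFAULT_SCREEN,
                          prefilter: bool | str = "auto",
                          kmer_size: int = 4,
                          min_shared_kmers: int = 2,
                          ) -> list[SimilarityEdge]:
    """Symmetric similarity edges among a set of protein sequences.

    Self-comparisons are excluded and edges whose normalized score falls
    below ``screen_floor`` are omitted.  For large inputs a shared k-mer
    prescreen restricts which pairs are aligned (``prefilter="auto"``
    enables it beyond 10,000 pairs); homolog pairs at the identity floors of
    interest share k-mers overwhelmingly, unrelated pairs almost never.
    """
    ids = sorted(genes)
    if len(ids) < 2:
        return []
    for gid in ids:
        _check_protein(genes[gid])
    n_pairs = len(ids) * (len(ids) - 1) // 2
    use_prefilter = prefilter is True or (prefilter == "auto" and n_pairs > 10_000)
    if use_prefilter:
        pairs = sorted(set(tuple(sorted(p))
                           for p in _candidate_pairs(genes, None, kmer_size,
                                                     min_shared_kmers)))
    else:
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]

    selfs = {gid: self_score(genes[gid], matrix) for gid in ids}
    edges: list[SimilarityEdge] = []
    for a, b in pairs:
        score, ident = global_identity(genes[a], genes[b], matrix, gap_open, gap_extend)
        proxy = score / min(selfs[a], selfs[b])
        if proxy >= screen_floor:
            edges.append(SimilarityEdge(a, b, score, ident, proxy))
    return edges


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

def reciprocal_best_hits(edges: Iterable[SimilarityEdge],
                         threshold: float = DEFAULT_SCREEN,
                         groups: Mapping[str, str] | None = None,
                         ) -> set[tuple[str, str]]:
    """Unordered rBBH pairs: mutual unique best-scoring partners.

    ``groups`` maps each gene to its source unit (replicon); best hits are
    taken per (gene, foreign group), the standard per-genome BLAST notion.
    Without ``groups`` every other gene forms one pool.  A tie for best
    (equal top scores) yields no best hit for that gene/pool — conservative
    and order-independent.  Edges below ``threshold`` (normalized score) are
    ignored.
    """
    grp = (lambda g: groups[g]) if groups is not None else (lambda g: "*")
    # best[(gene, foreign group)] = (score, partner); partner None marks a tie
    best: dict[tuple[str, str], tuple[float, str | None]] = {}
    for e in edges:
        if e.evalue_proxy < threshold:
            continue
        for g, partner in ((e.gene_a, e.gene_b), (e.gene_b, e.gene_a)):
            pg = grp(partner)
            if groups is not None and pg == grp(g):
                continue  # within-replicon pairs never form rBBHs
            key = (g, pg)
            cur = best.get(key)
            if cur is None or e.score > cur[0]:
                best[key] = (e.score, partner)
            elif e.score == cur[0] and cur[1] != partner:
                best[key] = (e.score, None)  # tie -> no best hit for this pool

    out: set[tuple[str, str]] = set()
    for (g, pg), (_, partner) in best.items():
        if partner is None:
            continue
        back = best.get((partner, grp(g)))
        if back is not None and back[1] == g:
            out.add(tuple(sorted((g, partner))))
    return out


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def _mcl_component(W: np.ndarray, inflation: float, prune: float,
                   tol: float, max_iter: int) -> list[list[int]]:
    n = W.shape[0]
    M = W.astype(float).copy()
    # self-loops at each node's maximum incident weight keep heavy two-node
    # components aperiodic (loop weight 1 would be negligible against
    # identity-scale edge weights and the iteration would split the pair)
    loops = np.maximum(M.max(axis=0), 1.0)
    np.fill_diagonal(M, np.maximum(np.diag(M), loops))
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = M @ M                       # expansion
        M = np.power(M, inflation)      # inflation
        M[M < prune] = 0.0              # pruning
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        M /= colsum
        if np.max(np.abs(M - prev)) < tol:
            break
    # clusters: attractors (nonzero diagonal) and the nodes they reach;
    # attractor systems sharing a node are merged; lowest node id labels
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    attractors = [i for i in range(n) if M[i, i] > 0]
    for j in range(n):
        owners = [i for i in attractors if M[i, j] > 0]
        if not owners:
            owners = [j]
        for o in owners[1:]:
            union(owners[0], o)
        union(owners[0], j)
    clusters: dict[int, list[int]] = {}
    for j in range(n):
        clusters.setdefault(find(j), []).append(j)
    return [sorted(v) for _, v in sorted(clusters.items())]


def mcl_cluster(graph: nx.Graph, inflation: float = 2.0, prune: float = 1e-6,
                tol: float = 1e-8, max_iter: int = 200) -> list[set]:
    """Deterministic Markov clustering of a weighted undirected graph.

    Expansion (matrix squaring) alternates with entrywise inflation of a
    column-stochastic transition matrix until convergence; entries below
    ``prune`` are dropped each round.  Clusters never span connected
    components, so the iteration runs per component.  Every node is assigned
    exactly once; attractor ties are resolved toward the lowest node id.
    """
    if graph.number_of_nodes() == 0:
        return []
    if (w := nx.get_edge_attributes(graph, "weight")):
        if any(v < 0 for v in w.values()):
            raise ValueError("edge weights must be non-negative")
    out: list[set] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            out.append({nodes[0]})
            continue
        idx = {v: i for i, v in enumerate(nodes)}
        W = np.zeros((len(nodes), len(nodes)))
        for u, v, data in graph.subgraph(comp).edges(data=True):
            w_uv = float(data.get("weight", 1.0))
            W[idx[u], idx[v]] = w_uv
            W[idx[v], idx[u]] = w_uv
        for cluster in _mcl_component(W, inflation, prune, tol, max_iter):
            out.append({nodes[i] for i in cluster})
    return sorted(out, key=lambda s: sorted(s)[0] if s else "")


# ---------------------------------------------------------------------------
# Families and chromosomal homologs
# ---------------------------------------------------------------------------

def build_families(plasmid_genes: Mapping[str, str],
                   edges: Iterable[SimilarityEdge],
                   rbbh_pairs: set[tuple[str, str]],
                   identity_floor: float = FAMILY_IDENTITY_FLOOR,
                   inflation: float = 2.0) -> FamilyPartition:
    """Cluster plasmid genes into protein families.

    The similarity graph is restricted to rBBH-confirmed pairs with
    >= ``identity_floor`` percent identity, then Markov-clustered; genes
    without qualifying edges become singleton families.  Family ids are
    assigned in order of each family's smallest member id.
    """
    g = nx.Graph()
    g.add_nodes_from(plasmid_genes)
    for e in edges:
        if e.pair() in rbbh_pairs and e.identity >= identity_floor:
            g.add_edge(e.gene_a, e.gene_b, weight=e.identity)
    clusters = mcl_cluster(g, inflation=inflation)
    clusters.sort(key=lambda s: sorted(s)[0])
    width = max(5, len(str(len(clusters))))
    part = FamilyPartition()
    for i, members in enumerate(clusters, start=1):
        part.families[f"F{i:0{width}d}"] = frozenset(members)
    part.validate()
    return part


def chromosomal_homologs(partition: FamilyPartition,
                         chromosome_genes: Mapping[str, str],
                         plasmid_genes: Mapping[str, str],
                         gene_isolate: Mapping[str, str],
                         screen_threshold: float = DEFAULT_SCREEN,
                         identity_floor: float = CHROM_IDENTITY_FLOOR,
                         matrix: str = DEFAULT_MATRIX,
                         gap_open: float = DEFAULT_GAP_OPEN,
                         gap_extend: float = DEFAULT_GAP_EXTEND,
                         prefilter: bool | str = "auto",
                         kmer_size: int = 4,
                         min_shared_kmers: int = 2,
                         ) -> FamilyPartition:
    """Fill ``chrom_homologs``: per family, chromosomal genes whose best
    alignment to any member passes the screen and the >= 40% identity floor.

    Returns the same partition object with ``chrom_homologs`` populated
    (families without hits get an empty entry).
    """
    fam_of = partition.family_of()
    partition.chrom_homologs = {f: set() for f in partition.families}
    n_pairs = len(chromosome_genes) * len(plasmid_genes)
    use_prefilter = prefilter is True or (prefilter == "auto" and n_pairs > 10_000)
    if use_prefilter:
        cand = _candidate_pairs(plasmid_genes, chromosome_genes,
                                kmer_size, min_shared_kmers)
        by_chrom: dict[str, list[str]] = {}
        for pg, cg in cand:
            by_chrom.setdefault(cg, []).append(pg)
    else:
        by_chrom = {cg: list(plasmid_genes) for cg in chromosome_genes}

    selfs_p = {g: self_score(s, matrix) for g, s in plasmid_genes.items()}
    for cg, candidates in by_chrom.items():
        cseq = chromosome_genes[cg]
        cself = self_score(cseq, matrix)
        best_per_family: dict[str, tuple[float, float]] = {}  # fam -> (score, ident)
        for pg in candidates:
            fam = fam_of.get(pg)
            if fam is None:
                continue
            score, ident = global_identity(plasmid_genes[pg], cseq,
                                           matrix, gap_open, gap_extend)
            proxy = score / min(selfs_p[pg], cself)
            if proxy < screen_threshold:
                continue
            cur = best_per_family.get(fam, (float("-inf"), 0.0))
            if ident > cur[1]:
                best_per_family[fam] = (score, ident)
        for fam, (_, ident) in best_per_family.items():
            if ident >= identity_floor:
                partition.chrom_homologs[fam].add((gene_isolate[cg], cg))
    return partition


def cluster_pipeline(plasmid_genes: Mapping[str, str],
                     gene_replicon: Mapping[str, str],
                     chromosome_genes: Mapping[str, str] | None = None,
                     gene_isolate: Mapping[str, str] | None = None,
                     **kwargs) -> FamilyPartition:
    """Convenience: all-vs-all -> rBBH -> families (-> chromosomal homologs)."""
    edges = all_vs_all_similarity(plasmid_genes, **{
        k: v for k, v in kwargs.items()
        if k in ("matrix", "gap_open", "gap_extend", "screen_floor",
                 "prefilter", "kmer_size", "min_shared_kmers")})
    pairs = reciprocal_best_hits(edges, groups=gene_replicon)
    part = build_families(plasmid_genes, edges, pairs,
                          identity_floor=kwargs.get("identity_floor",
                                                    FAMILY_IDENTITY_FLOOR),
                          inflation=kwargs.get("inflation", 2.0))
    if chromosome_genes:
        if gene_isolate is None:
            raise ValueError("gene_isolate required with chromosome_genes")
        chromosomal_homologs(part, chromosome_genes, plasmid_genes, gene_isolate)
    return part
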