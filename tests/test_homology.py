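"""Homology pipeline: alignment, rBBH, MCL, families, chromosomal homologs."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from plasmidess.homology import (
    SimilarityEdge, all_vs_all_similarity, build_families,
    chromosomal_homologs, global_identity, mcl_cluster, reciprocal_best_hits,
)
from plasmidess.synth import AA, mutate, random_protein


def edges_from_matrix(scores, a_names, b_names):
    """Bipartite score matrix -> SimilarityEdge list (identity set high so
    only the scores matter)."""
    out = []
    for i, an in enumerate(a_names):
        for j, bn in enumerate(b_names):
            out.append(SimilarityEdge(an, bn, float(scores[i, j]), 100.0, 1.0))
    return out


class TestGlobalIdentity:
    def test_identical_sequences(self):
        _, ident = global_identity("AAAA", "AAAA")
        assert ident == 100.0

    def test_one_mismatch_no_gaps(self):
        _, ident = global_identity("AAAA", "AAAT")
        assert ident == 75.0

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError):
            global_identity("AXXB", "AAAA")
        with pytest.raises(ValueError):
            global_identity("", "AAAA")

    def test_score_matches_bruteforce_dp(self, rng):
        """Aligner score equals an independent Gotoh DP on random pairs."""
        for _ in range(25):
            a = random_protein(int(rng.integers(5, 31)), rng)
            b = random_protein(int(rng.integers(5, 31)), rng)
            score, _ = global_identity(a, b)
            assert score == pytest.approx(oracles.gotoh_score(a, b), abs=1e-9)

    def test_symmetric(self, rng):
        a = random_protein(20, rng)
        b = mutate(a, 0.3, rng)
        assert global_identity(a, b) == global_identity(b, a)


class TestAllVsAll:
    def test_two_identical_genes_one_edge(self):
        edges = all_vs_all_similarity({"g1": "MKVLAHTREW", "g2": "MKVLAHTREW"})
        assert len(edges) == 1
        assert edges[0].identity == 100.0

    def test_edge_count_bound(self, rng):
        genes = {f"g{i}": random_protein(30, rng) for i in range(6)}
        edges = all_vs_all_similarity(genes, screen_floor=-10.0)
        assert len(edges) <= 6 * 5 / 2

    def test_within_family_exceeds_between(self, rng):
        """Planted 3-family set: within-family identities dominate."""
        ancestors = [random_protein(80, rng) for _ in range(3)]
        genes, fam = {}, {}
        for f, anc in enumerate(ancestors):
            for k in range(3):
                gid = f"f{f}_{k}"
                genes[gid] = mutate(anc, 0.1, rng)
                fam[gid] = f
        edges = all_vs_all_similarity(genes, screen_floor=-10.0, prefilter=False)
        within = [e.identity for e in edges if fam[e.gene_a] == fam[e.gene_b]]
        between = [e.identity for e in edges if fam[e.gene_a] != fam[e.gene_b]]
        assert min(within) > max(between, default=0.0)

    def test_prefilter_agrees_with_full_scan(self, rng):
        anc = random_protein(60, rng)
        genes = {"a": anc, "b": mutate(anc, 0.2, rng),
                 "c": random_protein(60, rng)}
        full = {e.pair() for e in all_vs_all_similarity(genes, prefilter=False)}
        pre = {e.pair() for e in all_vs_all_similarity(genes, prefilter=True)}
        assert ("a", "b") in pre
        assert pre <= full


class TestReciprocalBestHits:
    def test_clean_mutual_bests(self):
        scores = np.array([[10.0, 1.0], [1.0, 9.0]])
        edges = edges_from_matrix(scores, ["A1", "A2"], ["B1", "B2"])
        groups = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        assert reciprocal_best_hits(edges, threshold=0.0, groups=groups) == {
            ("A1", "B1"), ("A2", "B2")}

    def test_asymmetric_best_excluded(self):
        # A1's best is B1, but B1's best is A2 -> no pair involving B1
        scores = np.array([[5.0, 1.0], [6.0, 2.0]])
        edges = edges_from_matrix(scores, ["A1", "A2"], ["B1", "B2"])
        groups = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        pairs = reciprocal_best_hits(edges, threshold=0.0, groups=groups)
        assert not any("B1" in p and "A1" in p for p in pairs)
        assert pairs == {("A2", "B1")}

    def test_score_tie_yields_no_hit(self):
        scores = np.array([[7.0, 7.0], [1.0, 2.0]])
        edges = edges_from_matrix(scores, ["A1", "A2"], ["B1", "B2"])
        groups = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        pairs = reciprocal_best_hits(edges, threshold=0.0, groups=groups)
        assert not any("A1" in p for p in pairs)

    def test_matches_exhaustive_scan(self, rng):
        """Random 6x6 score matrices agree with the double-loop oracle."""
        a_names = [f"A{i}" for i in range(6)]
        b_names = [f"B{i}" for i in range(6)]
        groups = {n: n[0] for n in a_names + b_names}
        for _ in range(50):
            scores = rng.integers(0, 12, size=(6, 6)).astype(float)
            edges = edges_from_matrix(scores, a_names, b_names)
            got = reciprocal_best_hits(edges, threshold=0.0, groups=groups)
            assert got == oracles.best_hit_pairs(scores, a_names, b_names)

    def test_symmetry_property(self, rng):
        scores = rng.integers(0, 9, size=(5, 5)).astype(float)
        a = [f"A{i}" for i in range(5)]
        b = [f"B{i}" for i in range(5)]
        groups = {n: n[0] for n in a + b}
        pairs = reciprocal_best_hits(edges_from_matrix(scores, a, b),
                                     threshold=0.0, groups=groups)
        for x, y in pairs:
            assert (x, y) == tuple(sorted((y, x)))


class TestMCL:
    def test_disconnected_triangles(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert mcl_cluster(g) == [{0, 1, 2}, {3, 4, 5}]

    def test_isolated_node_is_singleton(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b")
        clusters = mcl_cluster(g)
        assert {"lonely"} in clusters

    def test_empty_graph(self):
        assert mcl_cluster(nx.Graph()) == []

    def test_barbell_splits_at_bridge(self):
        """Two 5-cliques joined by one bridge split into the cliques."""
        g = nx.Graph()
        for base in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(base + i, base + j)
        g.add_edge(0, 5)
        assert mcl_cluster(g, inflation=2.0) == [set(range(5)), set(range(5, 10))]

    def test_negative_weights_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-1.0)
        with pytest.raises(ValueError):
            mcl_cluster(g)

    def test_idempotent_on_recovered_cluster(self, rng):
        """Re-clustering one recovered planted family returns it intact."""
        g = nx.Graph()
        for f in range(3):
            members = [f"f{f}_{k}" for k in range(4)]
            for i, u in enumerate(members):
                for v in members[i + 1:]:
                    g.add_edge(u, v, weight=80.0 + rng.uniform(0, 15))
        clusters = mcl_cluster(g)
        assert len(clusters) == 3
        for cl in clusters:
            sub = nx.Graph(g.subgraph(cl))
            assert mcl_cluster(sub) == [set(cl)]


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(7)
    genes, reps, fam_truth = {}, {}, {}
    for f in range(10):
        anc = random_protein(90, rng)
        for k in range(3):
            gid = f"fam{f}_g{k}"
            genes[gid] = mutate(anc, 0.08, rng)
            reps[gid] = f"plasmid{k}"  # members spread over 3 plasmids
            fam_truth[gid] = f
    return genes, reps, fam_truth


class TestFamilies:
    def test_planted_families_recovered(self, planted):
        from sklearn.metrics import adjusted_rand_score

        genes, reps, fam_truth = planted
        edges = all_vs_all_similarity(genes, prefilter=False)
        pairs = reciprocal_best_hits(edges, groups=reps)
        part = build_families(genes, edges, pairs)
        part.validate()
        fo = part.family_of()
        ids = sorted(genes)
        ari = adjusted_rand_score([fam_truth[g] for g in ids],
                                  [fo[g] for g in ids])
        assert ari == 1.0

    def test_all_low_identity_all_singletons(self, rng):
        genes = {f"g{i}": random_protein(60, rng) for i in range(5)}
        edges = all_vs_all_similarity(genes, screen_floor=-10.0, prefilter=False)
        reps = {g: g for g in genes}
        pairs = reciprocal_best_hits(edges, threshold=-10.0, groups=reps)
        part = build_families(genes, edges, pairs)
        assert all(len(m) == 1 for m in part.families.values())

    def test_duplicate_across_plasmids_same_family(self, rng):
        seq = random_protein(70, rng)
        genes = {"dupA": seq, "dupB": seq}
        reps = {"dupA": "p1", "dupB": "p2"}
        edges = all_vs_all_similarity(genes)
        pairs = reciprocal_best_hits(edges, groups=reps)
        part = build_families(genes, edges, pairs)
        assert any(m == {"dupA", "dupB"} for m in map(set, part.families.values()))

    def test_raising_floor_only_refines(self, planted):
        """A higher identity floor never merges families."""
        genes, reps, _ = planted
        edges = all_vs_all_similarity(genes, prefilter=False)
        pairs = reciprocal_best_hits(edges, groups=reps)
        coarse = build_families(genes, edges, pairs, identity_floor=50.0)
        fine = build_families(genes, edges, pairs, identity_floor=80.0)
        coarse_of = coarse.family_of()
        for members in fine.families.values():
            assert len({coarse_of[g] for g in members}) == 1


def exact_identity_mutant(seq: str, k: int, rng) -> str:
    """Substitute k evenly scattered positions (never to self).

    Scattered single-site mismatches keep the optimal global alignment
    gapless (each isolated gap would cost two gap-opens for at best one
    recovered match), so identity is exactly (len-k)/len.
    """
    out = list(seq)
    positions = np.unique(np.round(np.linspace(0, len(seq) - 1, k)).astype(int))
    assert positions.size == k
    for i in positions:
        choices = AA.replace(out[i], "")
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


class TestChromosomalHomologs:
    def _setup(self, identity_target, rng):
        """One plasmid family plus a chromosomal copy at an exact identity."""
        anc = random_protein(200, rng)
        genes = {"pm1": anc, "pm2": mutate(anc, 0.05, rng)}
        k = round(200 * (1.0 - identity_target / 100.0))
        chrom = {"chr1": exact_identity_mutant(anc, k, rng)}
        edges = all_vs_all_similarity(genes, prefilter=False)
        pairs = reciprocal_best_hits(edges, groups={"pm1": "p1", "pm2": "p2"})
        part = build_families(genes, edges, pairs)
        return part, chrom, genes

    @pytest.mark.parametrize("target,expected", [(45.0, True), (39.0, False)])
    def test_identity_floor_boundary(self, target, expected, rng):
        """Chromosomal copies at 45% identity are recorded, at 39% are not."""
        part, chrom, genes = self._setup(target, rng)
        fam = next(iter(part.families))
        _, realized = global_identity(genes["pm1"], chrom["chr1"])
        assert realized == pytest.approx(target, abs=0.5)
        chromosomal_homologs(part, chrom, genes, {"chr1": "ISO1"},
                             prefilter=False)
        assert bool(part.chrom_homologs[fam]) == expected
        if expected:
            assert part.chrom_homologs[fam] == {("ISO1", "chr1")}

    def test_family_without_hit_has_empty_entry(self, rng):
        genes = {"pm1": random_protein(80, rng)}
        chrom = {"chr1": random_protein(80, rng)}
        edges = all_vs_all_similarity({"pm1": genes["pm1"], "pm2": genes["pm1"]})
        pairs = reciprocal_best_hits(edges, groups={"pm1": "p1", "pm2": "p2"})
        part = build_families(genes, edges, pairs)
        chromosomal_homologs(part, chrom, genes, {"chr1": "ISO1"},
                             prefilter=False)
        assert all(v == set() for v in part.chrom_homologs.values())


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.sampled_from(sorted(AA)), min_size=4, max_size=12),
       st.lists(st.sampled_from(sorted(AA)), min_size=4, max_size=12))
def test_alignment_score_never_exceeds_self_score(a, b):
    """The cross score is bounded by the smaller self-alignment score."""
    from plasmidess.homology import self_score

    sa, sb = "".join(a), "".join(b)
    score, ident = global_identity(sa, sb)
    assert score <= min(self_score(sa), self_score(sb)) + 1e-9
    assert 0.0 <= ident <= 100.0
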