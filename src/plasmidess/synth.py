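"""Synthetic pangenomes, gene trees with planted transfers, and experiment
readouts.

Every downstream stage of the pipeline is exercised against data whose
ground truth is known by construction:

* :func:`generate_pangenome` emits a pangenome of isolates with chromosomes
  and plasmids whose plasmid genes carry planted protein-family membership,
  a tunable fraction of families with chromosomal homologs in the plasmid's
  own host isolate, planted essential/transposase genes and mobility
  machinery flags;
* :func:`generate_labeled_tree` emits ultrametric birth trees whose tips
  are labeled by replicon residence (P/C) after planting directed transfer
  events on branches, together with the parsimony-identifiability of the
  planted history;
* the experiment generators emit competition counts, qPCR Ct pairs and
  logistic OD series with the observation noise the corresponding
  estimators assume (Poisson/binomial plating, additive Gaussian Ct and OD
  noise).

Sequences are random amino-acid strings and homologs are per-site
substitution mutants: the identity thresholds, not phylogenetic realism,
are what the pipeline tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pangenome import CHROMOSOME, PLASMID, Gene, Pangenome, Replicon
from .phylo import (C, LabeledTree, Node, P, category_of_events,
                    enumerate_minimal_labelings, events_of_labeling,
                    fitch_min_changes, serialize_newick)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AA[i] for i in rng.integers(0, len(AA), size=length))


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Per-site substitution at rate ``divergence``; always to a different
    residue, so realized identity ~= 1 - divergence."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < divergence)
    for i in hits:
        choices = AA.replace(out[i], "")
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Pangenome generator
# ---------------------------------------------------------------------------

@dataclass
class PangenomeConfig:
    """Study conditions for the synthetic pangenome.

    Defaults emulate an *Escherichia*-like regime: isolates carrying one to
    a few plasmids; ~44% of plasmid protein families with a chromosomal
    homolog somewhere, 19% in the plasmid's own host isolate (of which a
    small minority are transposable elements and ~1% are essential-gene
    homologs); plasmid sizes lognormal around ~100 kb.
    """

    n_isolates: int = 25
    plasmids_per_isolate: tuple[int, int] = (1, 3)
    n_families: int = 500
    p_same_isolate_homolog: float = 0.19
    p_other_isolate_homolog: float = 0.25
    p_essential: float = 0.01
    p_transposase: float = 0.03
    p_amr: float = 0.10
    mobility_mix: dict = field(default_factory=lambda: {
        "conjugative": 0.25, "mobilizable": 0.30, "non_mobilizable": 0.45})
    mean_gene_len: int = 120
    mutation_rate: float = 0.12   # max per-site divergence within a family
    n_core_essential: int = 40
    n_chromosome_filler: int = 10
    plant_plasmid_only_essential: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.plasmids_per_isolate, int):
            self.plasmids_per_isolate = (self.plasmids_per_isolate,
                                         self.plasmids_per_isolate)
        probs = {
            "p_same_isolate_homolog": self.p_same_isolate_homolog,
            "p_other_isolate_homolog": self.p_other_isolate_homolog,
            "p_essential": self.p_essential,
            "p_transposase": self.p_transposase,
            "p_amr": self.p_amr,
            "mutation_rate": self.mutation_rate,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.n_isolates < 1:
            raise ValueError("n_isolates must be >= 1")
        if abs(sum(self.mobility_mix.values()) - 1.0) > 1e-9:
            raise ValueError("mobility_mix must sum to 1")
        if self.p_essential + self.p_transposase > self.p_same_isolate_homolog:
            raise ValueError("p_essential + p_transposase must not exceed "
                             "p_same_isolate_homolog")
        if self.p_same_isolate_homolog + self.p_other_isolate_homolog > 1.0:
            raise ValueError("sharing probabilities must sum to <= 1")
        lo, hi = self.plasmids_per_isolate
        if lo < 0 or hi < lo:
            raise ValueError("plasmids_per_isolate range invalid")


@dataclass
class PangenomeTruth:
    """Ground truth emitted alongside a synthetic pangenome."""

    family_membership: dict = field(default_factory=dict)  # gene -> family
    families: dict = field(default_factory=dict)           # family -> [genes]
    chrom_homologs: dict = field(default_factory=dict)     # family -> [(iso, gene)]
    sharing_class: dict = field(default_factory=dict)      # family -> class
    essential_link: dict = field(default_factory=dict)     # family -> gene symbol
    mobility: dict = field(default_factory=dict)           # plasmid -> class
    amr_plasmids: list = field(default_factory=list)
    plasmid_only_essential: list = field(default_factory=list)  # (symbol, isolate)

    @property
    def same_isolate_fraction(self) -> float:
        if not self.families:
            return 0.0
        shared = sum(1 for c in self.sharing_class.values()
                     if c in ("same_isolate", "same_isolate_transposase"))
        return shared / len(self.families)

    def sharing_counts(self) -> dict:
        out = {"none": 0, "other_isolate_only": 0, "same_isolate": 0,
               "same_isolate_transposase": 0}
        for c in self.sharing_class.values():
            out[c] += 1
        return out

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["chrom_homologs"] = {f: sorted(map(list, v))
                                  for f, v in self.chrom_homologs.items()}
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


def generate_pangenome(config: PangenomeConfig) -> tuple[Pangenome, PangenomeTruth]:
    """Generate a synthetic pangenome with planted family ground truth.

    Deterministic given ``config.seed``.  A fraction
    ``p_same_isolate_homolog`` of plasmid families receive a chromosomal
    homolog (a 40-100%-identity mutant copy) in an isolate that hosts one of
    the family's plasmid members; ``p_other_isolate_homolog`` receive one
    only in non-host isolates.  Essential-linked families derive from core
    essential genes present on every chromosome, so their hosts co-retain
    the chromosomal copy (unless ``plant_plasmid_only_essential`` removes it
    from one host, the translocation-with-loss case).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pg = Pangenome()
    truth = PangenomeTruth()

    isolates = [f"ISO{i:03d}" for i in range(1, cfg.n_isolates + 1)]
    chrom_of = {iso: f"CHR_{iso}" for iso in isolates}
    for iso in isolates:
        pg.add_replicon(Replicon(chrom_of[iso], iso, CHROMOSOME,
                                 size_kb=float(round(4600 + rng.normal(0, 100), 1))))
    lo, hi = cfg.plasmids_per_isolate
    plasmid_ids: list[str] = []
    for iso in isolates:
        k = int(rng.integers(lo, hi + 1))
        for j in range(1, k + 1):
            pid = f"p{iso}_{j}"
            size = float(round(np.exp(rng.normal(math.log(100.0), 0.6)), 1))
            pg.add_replicon(Replicon(pid, iso, PLASMID, size_kb=size))
            plasmid_ids.append(pid)

    genes: dict[str, dict] = {}  # gene_id -> kwargs for Gene
    flag_sets: dict[str, set] = {}

    def add_gene(gid: str, rep_id: str, seq: str, flags: set, name: str = "") -> None:
        rep = pg.replicons[rep_id]
        genes[gid] = dict(gene_id=gid, isolate_id=rep.isolate_id,
                          replicon_id=rep_id, replicon_type=rep.replicon_type,
                          seq=seq, name=name)
        flag_sets[gid] = set(flags)

    def gene_len() -> int:
        return int(rng.integers(int(0.7 * cfg.mean_gene_len),
                                int(1.3 * cfg.mean_gene_len) + 1))

    # core essential genes on every chromosome
    ess_names = [f"essg{i:03d}" for i in range(1, cfg.n_core_essential + 1)]
    ess_ancestor = {nm: random_protein(gene_len(), rng) for nm in ess_names}
    ess_copy_id: dict[tuple[str, str], str] = {}
    for nm in ess_names:
        for iso in isolates:
            gid = f"{nm}_{iso}"
            add_gene(gid, chrom_of[iso],
                     mutate(ess_ancestor[nm], rng.uniform(0.0, 0.05), rng),
                     {"essential"}, name=nm)
            ess_copy_id[(nm, iso)] = gid

    # chromosome filler genes (never homologous to anything)
    for iso in isolates:
        for j in range(cfg.n_chromosome_filler):
            add_gene(f"fill{j:02d}_{iso}", chrom_of[iso],
                     random_protein(gene_len(), rng), set())

    # payload plasmid families
    plasmid_iso = {pid: pg.replicons[pid].isolate_id for pid in plasmid_ids}
    ess_pool = list(ess_names)
    metg_case: tuple[str, str] | None = None
    if plasmid_ids:
        p_ess = cfg.p_essential
        p_te = cfg.p_transposase
        p_same_plain = cfg.p_same_isolate_homolog - p_ess - p_te
        p_other = cfg.p_other_isolate_homolog
        class_p = np.array([p_ess, p_te, p_same_plain, p_other,
                            1.0 - p_ess - p_te - p_same_plain - p_other])
        class_names = ["essential", "same_isolate_transposase", "same_isolate",
                       "other_isolate_only", "none"]
        for i in range(1, cfg.n_families + 1):
            fam = f"T{i:04d}"
            cls = class_names[int(rng.choice(len(class_p), p=class_p))]
            if cls == "essential" and not ess_pool:
                cls = "same_isolate"  # essential roster exhausted
            flags: set = set()
            name = ""
            if cls == "essential":
                name = ess_pool.pop(int(rng.integers(0, len(ess_pool))))
                ancestor = mutate(ess_ancestor[name], rng.uniform(0.02, 0.15), rng)
                flags = {"essential"}
                truth.essential_link[fam] = name
            else:
                ancestor = random_protein(gene_len(), rng)
                if cls == "same_isolate_transposase":
                    flags = {"transposase"}
            m = max(1, min(1 + int(rng.poisson(1.0)), len(plasmid_ids)))
            homes = list(rng.choice(plasmid_ids, size=m, replace=False))
            members = []
            for j, pid in enumerate(homes, start=1):
                gid = f"{fam}_m{j}"
                add_gene(gid, pid,
                         mutate(ancestor, rng.uniform(0.0, cfg.mutation_rate), rng),
                         set(flags))
                members.append(gid)
            truth.families[fam] = members
            for gid in members:
                truth.family_membership[gid] = fam
            host_isolates = sorted({plasmid_iso[pid] for pid in homes})

            pairs: list[tuple[str, str]] = []
            if cls == "essential":
                for iso in isolates:
                    pairs.append((iso, ess_copy_id[(name, iso)]))
                if cfg.plant_plasmid_only_essential and metg_case is None:
                    metg_case = (name, host_isolates[0])
            elif cls in ("same_isolate", "same_isolate_transposase"):
                host = host_isolates[int(rng.integers(0, len(host_isolates)))]
                gid = f"{fam}_chr"
                add_gene(gid, chrom_of[host],
                         mutate(ancestor, rng.uniform(0.05, 0.35), rng), set())
                pairs.append((host, gid))
            elif cls == "other_isolate_only":
                others = [iso for iso in isolates if iso not in host_isolates]
                if not others:
                    cls = "none"
                else:
                    other = others[int(rng.integers(0, len(others)))]
                    gid = f"{fam}_chr"
                    add_gene(gid, chrom_of[other],
                             mutate(ancestor, rng.uniform(0.05, 0.35), rng), set())
                    pairs.append((other, gid))
            truth.chrom_homologs[fam] = pairs

    # the translocation-with-loss case: one host keeps only the plasmid copy
    if metg_case is not None:
        name, iso = metg_case
        gid = ess_copy_id[(name, iso)]
        del genes[gid]
        del flag_sets[gid]
        for fam, pairs in truth.chrom_homologs.items():
            truth.chrom_homologs[fam] = [pr for pr in pairs if pr[1] != gid]
        truth.plasmid_only_essential.append((name, iso))

    # realized sharing classes from the final homolog map
    for fam, members in truth.families.items():
        host_isos = {genes[g]["isolate_id"] for g in members}
        chrom_isos = {iso for iso, _ in truth.chrom_homologs.get(fam, ())}
        is_te = any("transposase" in flag_sets[g] for g in members)
        if not chrom_isos:
            truth.sharing_class[fam] = "none"
        elif host_isos & chrom_isos:
            truth.sharing_class[fam] = ("same_isolate_transposase" if is_te
                                        else "same_isolate")
        else:
            truth.sharing_class[fam] = "other_isolate_only"

    # mobility machinery and AMR, as flags on plasmid genes
    mob_classes = sorted(cfg.mobility_mix)
    mob_probs = np.array([cfg.mobility_mix[c] for c in mob_classes])
    genes_by_rep: dict[str, list[str]] = {}
    for gid, kw in genes.items():
        genes_by_rep.setdefault(kw["replicon_id"], []).append(gid)
    for pid in plasmid_ids:
        own = sorted(genes_by_rep.get(pid, []))
        cls = mob_classes[int(rng.choice(len(mob_probs), p=mob_probs))]
        if cls == "conjugative" and len(own) >= 15:
            n_tra = min(len(own), 15 + int(rng.integers(0, 4)))
            for gid in rng.choice(own, size=n_tra, replace=False):
                flag_sets[gid].add("tra")
        elif cls == "conjugative":
            cls = "mobilizable"  # too few genes to carry a T4SS
        if cls == "mobilizable" and own:
            flag_sets[own[int(rng.integers(0, len(own)))]].add("mob")
        elif cls == "mobilizable":
            cls = "non_mobilizable"
        truth.mobility[pid] = cls
        if own and rng.random() < cfg.p_amr:
            flag_sets[own[int(rng.integers(0, len(own)))]].add("amr")
            truth.amr_plasmids.append(pid)

    # final placement: shuffle order within each replicon, assign strands
    for rep_id, rep in pg.replicons.items():
        own = sorted(g for g, kw in genes.items() if kw["replicon_id"] == rep_id)
        order = rng.permutation(len(own))
        strands = rng.choice(["+", "-"], size=len(own))
        placed = sorted(zip(order, own))
        for oi, (_, gid) in enumerate(placed):
            kw = genes[gid]
            rep.genes.append(Gene(order_index=oi, strand=str(strands[oi]),
                                  flags=frozenset(flag_sets[gid]), **kw))
    return pg, truth


# ---------------------------------------------------------------------------
# Labeled gene trees with planted transfer events
# ---------------------------------------------------------------------------

@dataclass
class PlantedHistory:
    """Ground truth for one generated gene tree."""

    tip_labels: dict                     # tip name -> P | C
    events: list                         # (direction, sorted tips below branch)
    deep_split: bool
    true_topology_class: str
    n_changes_planted: int
    identifiable: bool


def _coalescent_tree(n_tips: int, rng: np.random.Generator) -> LabeledTree:
    """Random ultrametric binary tree (all tips equidistant from the root)."""
    lineages = [Node(f"tip{i}") for i in range(n_tips)]
    height = {id(n): 0.0 for n in lineages}
    h = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        h += float(rng.exponential(1.0 / k)) + 1e-3
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = lineages[i], lineages[j]
        parent = Node()
        a.length = h - height[id(a)]
        b.length = h - height[id(b)]
        parent.add(a)
        parent.add(b)
        height[id(parent)] = h
        lineages = [n for t, n in enumerate(lineages) if t not in (i, j)]
        lineages.append(parent)
    return LabeledTree(lineages[0])


def generate_labeled_tree(n_tips: int, planted_events: Sequence[str] = (),
                          seed: int = 0, deep_split: bool = False,
                          base_label: str = C,
                          ) -> tuple[LabeledTree, PlantedHistory]:
    """Ultrametric tree with P/C tip labels from planted transfer events.

    ``planted_events`` is a sequence of directions (``"C>P"`` / ``"P>C"``)
    applied top-down on uniformly chosen branches whose parent-side state
    matches the source label; each event relabels the subtree below it.
    ``deep_split`` labels the two root subtrees P and C before any events
    (the vertical-divergence topology).  Ultrametric branch lengths make
    the generated root the midpoint root, so rooting is classification-
    neutral.  The returned history records whether the planted event set is
    the unique parsimony-minimal explanation of the tip labels
    (``identifiable``), computed by exhaustive minimal-labeling enumeration.

    Raises ``ValueError`` when an event cannot be placed (more events than
    eligible branches).
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if base_label not in (P, C):
        raise ValueError("base_label must be 'P' or 'C'")
    rng = np.random.default_rng(seed)
    tree = _coalescent_tree(n_tips, rng)
    root = tree.root

    state: dict[Node, str] = {root: base_label}
    flips: dict[Node, str] = {}  # node -> state below its branch
    if deep_split:
        left, right = root.children
        flips[left] = P
        flips[right] = C

    def current_state(node: Node) -> str:
        path = []
        n = node
        while n is not None:
            path.append(n)
            n = n.parent
        st = base_label
        for n in reversed(path):
            if n in flips:
                st = flips[n]
        return st

    def tips_below(node: Node) -> list[Node]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n)
            stack.extend(n.children)
        return out

    def ancestors(node: Node) -> set:
        out = set()
        n = node.parent
        while n is not None:
            out.add(n)
            n = n.parent
        return out

    def flips_remain_visible() -> bool:
        """Every planted flip must still show its state on some tip below."""
        return all(
            any(current_state(t) == st for t in tips_below(f))
            for f, st in flips.items())

    all_nodes = tree.nodes(order="pre")
    for direction in planted_events:
        if direction not in ("C>P", "P>C"):
            raise ValueError(f"bad event direction {direction!r}")

    def eligible(direction: str) -> list[Node]:
        src = direction[0]
        out = []
        for n in all_nodes:
            if n is root or n in flips:
                continue
            # never flip above an existing event: that would rewrite its
            # source state and erase the planted direction
            if any(n in ancestors(f) for f in flips):
                continue
            if current_state(n.parent) != src:
                continue
            flips[n] = direction[2]
            ok = flips_remain_visible()
            del flips[n]
            if ok:
                out.append(n)
        return out

    def place(remaining: list[str], picked: list[Node]) -> list[Node] | None:
        """Backtracking placement: any full assignment, in rng order."""
        if not remaining:
            return picked
        cands = eligible(remaining[0])
        for i in rng.permutation(len(cands)):
            n = cands[int(i)]
            flips[n] = remaining[0][2]
            got = place(remaining[1:], picked + [n])
            if got is not None:
                return got
            del flips[n]
        return None

    placement = place(list(planted_events), [])
    if placement is None:
        raise ValueError("cannot place events: no eligible branch assignment")
    event_records: list[tuple[str, Node]] = list(zip(planted_events, placement))

    # realize tip labels and name tips by label
    labels: dict[str, str] = {}
    counters = {P: 0, C: 0}
    for tip in tree.tips():
        st = current_state(tip)
        counters[st] += 1
        tip.name = f"{st}_{counters[st]}"
        labels[tip.name] = st

    n_planted = len(event_records) + (1 if deep_split else 0)
    if deep_split and event_records:
        true_class = "mixed"
    elif deep_split:
        true_class = "split"
    else:
        true_class = category_of_events(
            len(event_records), [d for d, _ in event_records])

    # parsimony identifiability: the planted change count must be minimal and
    # every minimum-change labeling must imply the same topology category
    m_star, _ = fitch_min_changes(tree, labels)
    identifiable = m_star == n_planted
    if identifiable and m_star >= 2:
        labelings = enumerate_minimal_labelings(tree, labels, cap=128)
        if len(labelings) >= 128:
            identifiable = False
        else:
            cats = {category_of_events(
                m_star, [d for d, _ in events_of_labeling(tree, a)])
                for a in labelings}
            identifiable = cats == {true_class}

    history = PlantedHistory(
        tip_labels=labels,
        events=[(d, tuple(sorted(t.name for t in tips_below(n))))
                for d, n in event_records],
        deep_split=deep_split,
        true_topology_class=true_class,
        n_changes_planted=n_planted,
        identifiable=identifiable,
    )
    return tree, history


# ---------------------------------------------------------------------------
# Gene-order generator (synteny inputs)
# ---------------------------------------------------------------------------

def generate_gene_orders(n_replicons: int = 10, alphabet_size: int = 30,
                         genes_per_replicon: int = 20,
                         block: Sequence | None = None,
                         block_fraction: float = 0.0,
                         insertions_per_instance: int = 0,
                         seed: int = 0) -> tuple[dict, list]:
    """Random per-replicon gene orders, optionally with a planted block.

    Returns ``(orders, carriers)`` where ``orders`` maps replicon id to a
    family-symbol sequence and ``carriers`` lists the replicons that carry
    the planted block (inserted contiguously, or with
    ``insertions_per_instance`` foreign symbols interleaved, in forward or
    reverse orientation).
    """
    rng = np.random.default_rng(seed)
    alphabet = [f"fam{i:03d}" for i in range(alphabet_size)]
    blk = list(block) if block else []
    n_carriers = int(round(block_fraction * n_replicons))
    carriers = sorted(rng.choice(n_replicons, size=n_carriers, replace=False)) \
        if blk else []
    orders: dict[str, list] = {}
    for r in range(n_replicons):
        rid = f"plasmid{r:03d}"
        background = [alphabet[i] for i in
                      rng.integers(0, alphabet_size, size=genes_per_replicon)]
        background = [s for s in background if s not in blk]
        if r in carriers:
            inst = list(blk) if rng.random() < 0.5 else list(reversed(blk))
            for _ in range(insertions_per_instance):
                pos = int(rng.integers(1, len(inst)))
                foreign = alphabet[int(rng.integers(0, alphabet_size))]
                while foreign in blk:
                    foreign = alphabet[int(rng.integers(0, alphabet_size))]
                inst.insert(pos, foreign)
            at = int(rng.integers(0, len(background) + 1))
            seq = background[:at] + inst + background[at:]
        else:
            seq = background
        orders[rid] = seq
    return orders, [f"plasmid{r:03d}" for r in carriers]


# ---------------------------------------------------------------------------
# Experiment readout generators
# ---------------------------------------------------------------------------

def generate_competition_data(w_true: float, n0_each: float = 500.0,
                              generations: float = 10.0,
                              plating_noise: bool = True, seed: int = 0,
                              n_replicates: int = 1) -> pd.DataFrame:
    """Pairwise-competition colony counts at t0 and t24.

    Both strains start 1:1; the reference grows ``2**g``-fold, the focal
    strain ``2**(w*g)``-fold (Malthusian ratio ``w``).  Plating noise is
    Poisson on every count.  Noiseless data invert exactly to ``w``.
    """
    if w_true <= 0:
        raise ValueError("w_true must be positive")
    if n0_each <= 0:
        raise ValueError("n0_each must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        a0, b0 = float(n0_each), float(n0_each)
        af = a0 * 2.0 ** (w_true * generations)
        bf = b0 * 2.0 ** generations
        if plating_noise:
            a0, af, b0, bf = (float(rng.poisson(x)) for x in (a0, af, b0, bf))
        rows.append({"replicate": rep, "count_a_t0": a0, "count_a_tf": af,
                     "count_b_t0": b0, "count_b_tf": bf})
    return pd.DataFrame(rows)


def generate_qpcr_data(pcn_true: float, eff_target: float = 2.0,
                       eff_ref: float = 2.0, ct_noise_sd: float = 0.0,
                       seed: int = 0, n_samples: int = 1,
                       ct_ref_base: float = 20.0) -> list:
    """qPCR Ct pairs satisfying ``eff**(-Ct) proportional to template``.

    The chromosomal amplicon sits at ``ct_ref_base`` cycles; the plasmid
    amplicon's Ct follows from the true copy number and both amplification
    efficiencies.  Gaussian noise of sd ``ct_noise_sd`` is added to every
    Ct independently.
    """
    from .dynamics import QpcrSample

    if pcn_true <= 0:
        raise ValueError("pcn_true must be positive")
    for e in (eff_target, eff_ref):
        if not 1.0 < e <= 2.0:
            raise ValueError("efficiencies must be in (1, 2]")
    rng = np.random.default_rng(seed)
    ct_target_true = ((ct_ref_base * math.log(eff_ref) - math.log(pcn_true))
                      / math.log(eff_target))
    out = []
    for _ in range(n_samples):
        ct_r = ct_ref_base + float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd else ct_ref_base
        ct_t = ct_target_true + float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd else ct_target_true
        out.append(QpcrSample(ct_target=max(ct_t, 0.0), ct_ref=max(ct_r, 0.0),
                              eff_target=eff_target, eff_ref=eff_ref))
    return out


def generate_growth_curve(K: float, r: float, N0: float, noise_sd: float,
                          times: Sequence[float], seed: int = 0) -> np.ndarray:
    """Logistic OD600 series ``K / (1 + ((K-N0)/N0) e^{-rt})`` plus noise.

    Readings are floored at 1e-4 (spectrophotometer floor) so noisy series
    stay positive.
    """
    if not (K > N0 > 0):
        raise ValueError("need K > N0 > 0")
    if r <= 0:
        raise ValueError("r must be positive")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    od = K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=t.size)
    return np.maximum(od, 1e-4)


def write_trees(trees: Mapping[str, LabeledTree], path: str | Path) -> None:
    """One Newick per line, ``name<TAB>newick``."""
    with open(path, "w") as fh:
        for name in sorted(trees):
            fh.write(f"{name}\t{serialize_newick(trees[name])}\n")
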