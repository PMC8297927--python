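"""Distribution statistics of plasmid protein families across replicons.

Answers the comparative questions about a pangenome once families and
chromosomal homologs are built: how are families spread over plasmids and
chromosomes, what fraction has a chromosomal homolog in the plasmid's own
host isolate ("same-isolate sharing"), which essential genes have plasmid
homologs and do their hosts co-retain the chromosomal copy, and how are
plasmids distributed over mobility classes (conjugative / mobilizable /
non-mobilizable).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .homology import FamilyPartition
from .pangenome import Pangenome, Replicon

CONJUGATIVE = "conjugative"
MOBILIZABLE = "mobilizable"
NON_MOBILIZABLE = "non_mobilizable"
MOBILITY_CLASSES = (CONJUGATIVE, MOBILIZABLE, NON_MOBILIZABLE)

#: minimum number of tra genes for the conjugative class
CONJUGATIVE_TRA_MIN = 15

SHARING_CLASSES = ("none", "other_isolate_only", "same_isolate",
                   "same_isolate_transposase")


def family_replicon_distribution(partition: FamilyPartition,
                                 pangenome: Pangenome) -> pd.DataFrame:
    """One row per family: plasmid spread, chromosomal spread, flags.

    ``n_plasmids`` counts distinct plasmid replicons with a member;
    ``n_chromosome_isolates`` counts distinct isolates with a chromosomal
    homolog of the family.
    """
    idx = pangenome.gene_index()
    rows = []
    for fam, members in sorted(partition.families.items()):
        genes = [idx[g] for g in members]
        plasmids = {g.replicon_id for g in genes}
        chrom_isolates = {iso for iso, _ in partition.chrom_homologs.get(fam, ())}
        flags = frozenset().union(*(g.flags for g in genes))
        rows.append({
            "family_id": fam,
            "n_plasmids": len(plasmids),
            "n_chromosome_isolates": len(chrom_isolates),
            "essential": "essential" in flags,
            "transposase": "transposase" in flags,
            "amr": "amr" in flags,
        })
    return pd.DataFrame(rows, columns=["family_id", "n_plasmids",
                                       "n_chromosome_isolates", "essential",
                                       "transposase", "amr"])


def same_isolate_sharing_fraction(partition: FamilyPartition,
                                  pangenome: Pangenome,
                                  ) -> tuple[float, Counter]:
    """Fraction of plasmid families with a chromosomal homolog in the host.

    Families fall into mutually exclusive, exhaustive classes: no chromosomal
    homolog at all; homolog in other isolates only; homolog in at least one
    isolate that also hosts a plasmid member ("same isolate", i.e. the
    plasmid host), with transposase families split out.  The fraction counts
    both same-isolate classes over all families.
    """
    idx = pangenome.gene_index()
    counts: Counter = Counter({c: 0 for c in SHARING_CLASSES})
    for fam, members in partition.families.items():
        genes = [idx[g] for g in members]
        host_isolates = {g.isolate_id for g in genes}
        chrom_isolates = {iso for iso, _ in partition.chrom_homologs.get(fam, ())}
        flags = frozenset().union(*(g.flags for g in genes))
        if not chrom_isolates:
            counts["none"] += 1
        elif host_isolates & chrom_isolates:
            if "transposase" in flags:
                counts["same_isolate_transposase"] += 1
            else:
                counts["same_isolate"] += 1
        else:
            counts["other_isolate_only"] += 1
    total = len(partition.families)
    if total == 0:
        return 0.0, counts
    shared = counts["same_isolate"] + counts["same_isolate_transposase"]
    return shared / total, counts


@dataclass
class EssentialPlasmidReport:
    """Plasmid homologs of essential genes and chromosomal co-retention."""

    per_gene: pd.DataFrame        # essential gene -> plasmid/isolate counts
    co_retention: pd.DataFrame    # hosting isolate -> retains chromosomal copy?

    @property
    def n_essential_with_plasmid_homolog(self) -> int:
        return int((self.per_gene["n_plasmids"] > 0).sum())

    def plasmid_only_cases(self) -> pd.DataFrame:
        return self.co_retention[~self.co_retention["chromosomal_copy_retained"]]


def essential_on_plasmids(partition: FamilyPartition, pangenome: Pangenome,
                          essential_genes: Iterable[str],
                          ) -> EssentialPlasmidReport:
    """Map essential genes to plasmid-borne homologs via the family partition.

    ``essential_genes`` are gene symbols carried by chromosomal genes of the
    pangenome (``Gene.name``).  An essential gene has a plasmid homolog when
    one of its chromosomal copies appears in some family's chromosomal-
    homolog map; that family's members are the plasmid homologs.  For every
    hosting isolate the report records whether the chromosome retains its
    own copy (all hosts are expected to, barring translocation-with-loss
    cases).
    """
    idx = pangenome.gene_index()
    chrom_by_name: dict[str, set[str]] = {}
    for g in pangenome.chromosome_genes():
        if g.name:
            chrom_by_name.setdefault(g.name, set()).add(g.gene_id)

    gene_rows, ret_rows = [], []
    for ess in sorted(set(essential_genes)):
        copies = chrom_by_name.get(ess)
        if not copies:
            warnings.warn(f"essential gene {ess!r} absent from pangenome; skipped")
            continue
        fams = {fam for fam, pairs in partition.chrom_homologs.items()
                if any(cg in copies for _, cg in pairs)}
        plasmids, isolates = set(), set()
        for fam in fams:
            for gid in partition.families[fam]:
                g = idx[gid]
                plasmids.add(g.replicon_id)
                isolates.add(g.isolate_id)
        gene_rows.append({"essential_gene": ess, "n_families": len(fams),
                          "n_plasmids": len(plasmids), "n_isolates": len(isolates)})
        iso_with_copy = {idx[cg].isolate_id for cg in copies}
        for iso in sorted(isolates):
            ret_rows.append({
                "essential_gene": ess,
                "isolate_id": iso,
                "chromosomal_copy_retained": iso in iso_with_copy,
            })
    per_gene = pd.DataFrame(gene_rows, columns=["essential_gene", "n_families",
                                                "n_plasmids", "n_isolates"])
    co_ret = pd.DataFrame(ret_rows, columns=["essential_gene", "isolate_id",
                                             "chromosomal_copy_retained"])
    return EssentialPlasmidReport(per_gene=per_gene, co_retention=co_ret)


def classify_mobility(replicon: Replicon | None = None, *,
                      n_tra: int | None = None, has_mob: bool | None = None,
                      ) -> str:
    """Mobility class of one plasmid from its annotation flags.

    >= 15 tra genes -> conjugative; else a Mob relaxase -> mobilizable; else
    non-mobilizable.  Total and deterministic.
    """
    if replicon is not None:
        n_tra = replicon.n_flagged("tra")
        has_mob = replicon.n_flagged("mob") > 0
    if n_tra is None or has_mob is None:
        raise ValueError("provide a replicon or n_tra and has_mob")
    if n_tra >= CONJUGATIVE_TRA_MIN:
        return CONJUGATIVE
    if has_mob:
        return MOBILIZABLE
    return NON_MOBILIZABLE


def essential_plasmid_summary(plasmids: Sequence[Replicon]) -> dict:
    """Median size and mobility/AMR fractions over a plasmid set.

    Intended for the plasmids carrying essential-gene homologs; an empty set
    yields an empty summary rather than an error.
    """
    if not plasmids:
        return {"n_plasmids": 0}
    sizes = np.array([p.size_kb for p in plasmids], dtype=float)
    classes = Counter(classify_mobility(p) for p in plasmids)
    n = len(plasmids)
    return {
        "n_plasmids": n,
        "median_size_kb": float(np.median(sizes)),
        "frac_conjugative": classes[CONJUGATIVE] / n,
        "frac_mobilizable": classes[MOBILIZABLE] / n,
        "frac_non_mobilizable": classes[NON_MOBILIZABLE] / n,
        "frac_amr": sum(1 for p in plasmids if p.n_flagged("amr") > 0) / n,
    }


def sharing_ecdf(distribution: pd.DataFrame,
                 column: str = "n_chromosome_isolates",
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of isolates-per-family with a chromosomal homolog.

    Returns ``(x, F)`` where ``x`` are the sorted unique values and ``F`` the
    cumulative fraction of families at or below each value; ``F`` is
    non-decreasing and ends at 1.0.
    """
    values = np.sort(np.asarray(distribution[column], dtype=float))
    if values.size == 0:
        return np.array([]), np.array([])
    x, counts = np.unique(values, return_counts=True)
    F = np.cumsum(counts) / values.size
    return x, F
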