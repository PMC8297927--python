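"""Cluster plasmid proteins into families and map chromosomal homologs.

Reads the simulated pangenome, runs the homology pipeline (all-vs-all
global alignment, reciprocal best hits, the >= 50% identity floor, Markov
clustering, then the >= 40% chromosomal-homolog screen) and reports the
family-level sharing statistics: how many families have a chromosomal
homolog at all, how many share with their own host isolate, which
essential genes have plasmid-borne homologs, and the mobility make-up of
the plasmids that carry them.

Usage: python analysis/02_cluster_families.py
(expects results/ from 01_simulate_pangenome.py)
"""

import json

import pandas as pd

from analysis_util import results_dir, say
from plasmidess import (
    Pangenome, all_vs_all_similarity, build_families, chromosomal_homologs,
    essential_on_plasmids, essential_plasmid_summary,
    family_replicon_distribution, reciprocal_best_hits,
    same_isolate_sharing_fraction, sharing_ecdf,
)


def main() -> None:
    out = results_dir()
    pg = Pangenome.read(out / "pangenome.faa",
                        out / "pangenome_annotation.tsv",
                        out / "pangenome_replicons.tsv")
    truth = json.loads((out / "pangenome_truth.json").read_text())

    pgenes = {g.gene_id: g.seq for g in pg.plasmid_genes()}
    cgenes = {g.gene_id: g.seq for g in pg.chromosome_genes()}
    grep = {g.gene_id: g.replicon_id for g in pg.plasmid_genes()}
    giso = {g.gene_id: g.isolate_id for g in pg.chromosome_genes()}

    edges = all_vs_all_similarity(pgenes)
    pairs = reciprocal_best_hits(edges, groups=grep)
    part = build_families(pgenes, edges, pairs)
    chromosomal_homologs(part, cgenes, pgenes, giso)
    say(f"clustered {len(pgenes)} plasmid proteins into "
        f"{len(part.families)} families "
        f"(planted: {len(truth['families'])})")

    part.families_frame().to_csv(out / "families.tsv", sep="\t", index=False)
    part.chrom_homologs_frame().to_csv(out / "chrom_homologs.tsv", sep="\t",
                                       index=False)

    dist = family_replicon_distribution(part, pg)
    dist.to_csv(out / "family_distribution.tsv", sep="\t", index=False)
    frac, counts = same_isolate_sharing_fraction(part, pg)
    with_homolog = 1.0 - counts["none"] / len(part.families)
    say(f"families with a chromosomal homolog anywhere: {with_homolog:.1%}; "
        f"in the host isolate: {frac:.1%} "
        f"(of which transposases: "
        f"{counts['same_isolate_transposase'] / len(part.families):.1%})")

    x, F = sharing_ecdf(dist)
    pd.DataFrame({"n_isolates": x, "cdf": F}).to_csv(
        out / "sharing_ecdf.tsv", sep="\t", index=False)

    ess_names = sorted({g.name for g in pg.chromosome_genes() if g.name})
    report = essential_on_plasmids(part, pg, ess_names)
    report.per_gene.to_csv(out / "essential_on_plasmids.tsv", sep="\t",
                           index=False)
    n_hit = report.n_essential_with_plasmid_homolog
    say(f"essential genes with a plasmid homolog: {n_hit} of "
        f"{len(ess_names)} ({n_hit / len(ess_names):.0%}); "
        f"plasmid-only hosts: {len(report.plasmid_only_cases())}")

    hit_fams = {f for f, prs in part.chrom_homologs.items()
                if any(pg.gene_index()[cg].name for _, cg in prs)}
    idx = pg.gene_index()
    ess_plasmids = sorted({idx[g].replicon_id
                           for f in hit_fams for g in part.families[f]})
    summary = essential_plasmid_summary([pg.replicons[p] for p in ess_plasmids])
    pd.Series(summary).to_csv(out / "essential_plasmid_summary.tsv", sep="\t")
    if summary["n_plasmids"]:
        say(f"plasmids carrying essential homologs: {summary['n_plasmids']} "
            f"(median {summary['median_size_kb']:.0f} kb, "
            f"{summary['frac_non_mobilizable']:.0%} non-mobile, "
            f"{summary['frac_amr']:.0%} AMR)")


if __name__ == "__main__":
    main()
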