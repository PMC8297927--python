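"""Simulate the study pangenome.

Generates the default synthetic *Escherichia*-like pangenome — 25 isolates
carrying 1-3 plasmids each, 500 plasmid protein families of which 19% have
a chromosomal homolog in their host isolate (including ~1% essential-gene
homologs and ~3% transposable elements), plus per-plasmid mobility and AMR
flags — and writes the FASTA/annotation tables and the ground-truth sidecar
that the later stages consume.

Usage: python analysis/01_simulate_pangenome.py [--seed 0]
"""

import argparse

from analysis_util import results_dir, say
from plasmidess import PangenomeConfig, generate_pangenome


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    out = results_dir()
    cfg = PangenomeConfig(seed=args.seed)
    pg, truth = generate_pangenome(cfg)
    pg.write(out / "pangenome.faa", out / "pangenome_annotation.tsv",
             out / "pangenome_replicons.tsv")
    truth.to_json(out / "pangenome_truth.json")

    n_plasmids = len(pg.plasmids())
    say(f"pangenome: {cfg.n_isolates} isolates, {n_plasmids} plasmids, "
        f"{len(list(pg.genes()))} genes "
        f"({len(pg.plasmid_genes())} plasmid-encoded)")
    say(f"planted families: {len(truth.families)}; sharing classes "
        f"{truth.sharing_counts()}")
    say(f"planted same-isolate sharing fraction: "
        f"{truth.same_isolate_fraction:.3f}")
    say(f"wrote pangenome.faa / pangenome_annotation.tsv / "
        f"pangenome_truth.json under {out}")


if __name__ == "__main__":
    main()
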