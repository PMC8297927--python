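"""Mine conserved syntenic blocks from plasmid gene orders.

Plants an ssb-like five-gene neighborhood (partitioning gene, two
SOS-inhibition genes and flanking partners travel together) in 64% of a
set of synthetic plasmids, then mines gene-order patterns with an
insertion budget of 3 and reports each block's conservation fraction.

Usage: python analysis/03_find_syntenic_blocks.py [--seed 0]
"""

import argparse

from analysis_util import results_dir, say
from plasmidess import block_conservation_fraction, find_conserved_blocks
from plasmidess.synteny import blocks_frame, canonical_pattern
from plasmidess.synth import generate_gene_orders

SSB_BLOCK = ["ssb", "parB", "psiA", "psiB", "mobC"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-plasmids", type=int, default=25)
    args = ap.parse_args()

    out = results_dir()
    orders, carriers = generate_gene_orders(
        n_replicons=args.n_plasmids, alphabet_size=40, genes_per_replicon=22,
        block=SSB_BLOCK, block_fraction=0.64, insertions_per_instance=1,
        seed=args.seed)
    say(f"{args.n_plasmids} plasmid gene orders; planted "
        f"{'-'.join(SSB_BLOCK)} neighborhood in {len(carriers)} of them")

    blocks = find_conserved_blocks(orders, min_length=3, quorum=5,
                                   max_insertions=3)
    blocks_frame(blocks).to_csv(out / "syntenic_blocks.tsv", sep="\t",
                                index=False)
    say(f"found {len(blocks)} conserved blocks (min length 3, quorum 5, "
        f"<= 3 insertions)")
    target = canonical_pattern(SSB_BLOCK)
    for b in blocks:
        frac = block_conservation_fraction(b, sorted(orders))
        marker = "  <- planted neighborhood" if b.pattern == target else ""
        say(f"  {'-'.join(b.pattern)}: {len(b.support())} plasmids "
            f"({frac:.0%} conserved){marker}")


if __name__ == "__main__":
    main()
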