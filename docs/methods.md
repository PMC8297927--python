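# Methods

## Scope and design

The package has two arms. The comparative-genomics arm measures how
plasmid-encoded protein families are shared with chromosomes across a
pangenome and classifies gene trees into plasmid↔chromosome transfer
topologies. The experimental arm quantifies plasmid persistence:
segregational loss, relative fitness, copy number, growth, and
serial-transfer population dynamics. Both run against synthetic data whose
ground truth is planted by construction; the generators define the study
conditions and every estimator is tested for recovery of what was planted.

## Synthetic pangenome

`PangenomeConfig` defaults describe an *Escherichia*-like regime chosen
once: 25 isolates with 1–3 plasmids each; 500 plasmid protein families;
19% of families with a chromosomal homolog in the plasmid's own host
isolate (`p_same_isolate_homolog`, of which ~1% essential-linked and ~3%
transposable elements), a further 25% with homologs only in other isolates
— so ~44% have a chromosomal homolog somewhere; plasmid sizes lognormal
with median ~100 kb; mobility mix 25% conjugative / 30% mobilizable / 45%
non-mobilizable; 10% of plasmids carry an AMR flag.

Protein sequences are random 20-letter strings (length ~N(120, ±30%
uniform)); homologs are per-site substitution mutants, never reverting, so
realized identity ≈ 1 − divergence. Divergence bands are calibrated to the
pipeline's decision thresholds, not to phylogenetic realism: family
members diverge ≤12% from their ancestor (pairwise identity ≥ ~75%, safely
above the 50% clustering floor), chromosomal copies 5–35% (pairwise
identity to members ≥ ~57%, safely above the 40% homolog floor), and
unrelated families are independent random sequences (identity far below
either floor). Essential-linked families derive from core essential genes
present on every chromosome (each essential gene used at most once, so
essential families never merge); their hosts therefore co-retain the
chromosomal copy, except under `plant_plasmid_only_essential`, which
removes one host's chromosomal copy — the translocation-with-loss case.
Transfer-machinery (tra/mob) and AMR genes are represented as flags on
plasmid genes rather than as extra gene families: the mobility classifier
consumes flags only, and this keeps the family count equal to
`n_families` so the planted sharing fraction is interpretable. A
conjugative plasmid needs ≥15 genes to carry its tra flags; smaller
plasmids drawn as conjugative are downgraded to mobilizable.

What the generator does **not** emulate: indels and alignment-length
variation, codon-level evolution, gene gain/loss along a phylogeny,
paralog families, IS-element copy-number dynamics, and any correlation
between plasmid size, mobility and gene content. Passing tests therefore
show that the pipeline's decision logic (thresholds, clustering, counting)
is correct under its stated assumptions — not that those thresholds are
optimal for real proteomes.

## Homology pipeline

All-vs-all global alignment uses Needleman–Wunsch with affine gaps via
Biopython's PairwiseAligner: BLOSUM62, gap open 10, gap extend 0.5 (a gap
of length L costs 10 + 0.5·(L−1)); end gaps are penalized like internal
ones; identity is identical aligned positions over total alignment length.
The test suite checks the scores against an independent three-matrix Gotoh
DP. BLAST E-values are database-size-dependent, so the screening stage
uses a normalized score instead (`evalue_proxy` = raw score divided by the
smaller self-score; 1.0 means as good as self), with a reporting floor of
0.05; the decisive filters are the identity floors (≥50% for family edges,
≥40% for chromosomal homologs). For large inputs a shared-4-mer prescreen
(≥2 shared 4-mers, auto-enabled beyond 10,000 pairs) restricts which pairs
are aligned; at the identity levels the generator plants, the probability
of a true pair failing the prescreen is ~1e-4, and unrelated pairs pass it
with probability ~3e-3.

Reciprocal best hits are computed per replicon pair (the standard
per-genome notion): gene *a* pairs with *b* iff each is the other's unique
best-scoring hit within the other's replicon. Ties for best yield no hit —
conservative and order-independent.

MCL runs on the rBBH-confirmed, identity-filtered graph (edge weight =
percent identity): column-stochastic transition matrix, expansion (matrix
squaring) alternating with entrywise inflation (default 2.0), pruning at
1e-6, convergence when the max entry change < 1e-8, ≤200 iterations,
computed per connected component (clusters never span components).
Self-loops are set to each node's maximum incident weight; with identity-
scale weights a unit loop would be negligible and the iteration would
split two-node families (near-periodic chain). Attractor ties are resolved
toward the lowest node id, making the partition deterministic. Unclustered
genes become singleton families.

## Replicon statistics

Sharing classes per family are mutually exclusive and exhaustive: *none*
(no chromosomal homolog), *other-isolate-only*, *same-isolate* (a
chromosomal homolog in an isolate hosting one of the family's plasmid
members — the dosage-conflict configuration), with transposase families
split out of the same-isolate class. Mobility: ≥15 tra genes →
conjugative, else Mob → mobilizable, else non-mobilizable; whether a
conjugative call should also require Mob is unstated in the field's
convention, so the tra count takes precedence here. Essential-gene
reporting links essential gene symbols to families through the
chromosomal-homolog map and records, per hosting isolate, whether the
chromosome retains its own copy.

## Synteny

A conserved syntenic block is an ordered family pattern occurring in ≥
quorum replicons, each occurrence carrying ≤ `max_insertions` foreign
genes between its matched positions, in either orientation; replicons are
linear (no wraparound). The miner grows frequent patterns rightward —
support is anti-monotone under extension, so rightward growth from single
symbols is exhaustive — and counts occurrences with a greedy
earliest-completion matcher (optimal for a fixed start). Only maximal
blocks are reported (a block that is an ordered sub-pattern of a longer
block with identical replicon support is suppressed). The insertion budget
defaults to 3; the test suite proves agreement with a brute-force
enumerator of all bounded-span subsequence patterns on small inputs.

## Gene-tree classification

Trees are parsed and serialized by a small recursive-descent Newick module
(position-reporting errors; canonical child ordering by smallest tip name;
shortest round-trip float repr, so serialization is byte-stable and
lengths survive exactly — dendropy serves as the cross-check oracle in
tests). Neighbor joining uses the standard Q-criterion with lowest-index
tie-breaking; midpoint rooting places the root halfway along the longest
tip-to-tip path (found by exhaustive DFS; deterministic lexicographic tie
break), splitting an edge or re-rooting at a node as needed.

Classification is Fitch small parsimony on the binary
plasmid/chromosome character: `n_changes` is the minimum number of
residence switches; a top-down refinement picks one minimal ancestral
labeling, resolving a root tie to chromosome (the ancestral residence of
essential genes), flagged `root_ambiguous`. Categories: ≤1 change →
*split* (a clean divergence and a single transfer are topologically
indistinguishable); ≥2 changes all C→P → *transfer to plasmid*; all P→C →
*transfer to chromosome*; both directions → *mixed*. The deterministic
bipartition screen (some single edge separates all P from all C tips) is
equivalent to `n_changes` ≤ 1 and replaces statistical topology testing,
which is out of scope. Translocation-with-loss cases surface through the
co-retention report of the statistics module rather than as a separate
tree category.

The tree generator emits ultrametric coalescent trees, so the generated
root *is* the midpoint root and rooting is classification-neutral; planted
events are directed subtree flips placed by backtracking so that every
event remains visible in the tip labels and no event sits above another.
Each history carries an `identifiability` flag: the planted change count
must equal the parsimony minimum and every minimum-change labeling
(enumerated by a counting Sankoff with backtracking, capped at 128) must
imply the planted category. Classifier-recovery guarantees are stated on
the identifiable subset — an unidentifiable history (e.g. a deep split
plus one same-side event, which parsimony reads as two transfers) is not a
classifier failure.

## Dynamics

The deterministic serial-transfer recursion for the plasmid-host frequency
is, per generation,

    p' = w·p·(1−λ) / (w·p·(1−λ) + w·p·λ·s + (1−p)),   s = 0 if essential else 1

with λ the per-division segregational loss rate and w the relative
fitness; for w = 1, non-essential, this collapses to p_g = p0·(1−λ)^g
exactly, which is the closed form the overnight loss assay inverts
(λ = 1 − (1−F)^(1/g), F the loss frequency over g ≈ 8.5 generations).
Fractional generations use per-unit-generation rates (w^f, 1−(1−λ)^f), so
the closed form holds for real-valued g.

The stochastic simulator tracks integer plasmid⁺/plasmid⁻ counts through
each cycle: Poisson offspring (factor 2w per generation for carriers),
binomial segregational loss (segregants die when the plasmid is
essential), regrowth for log2(1/dilution) ≈ 16.6 generations, then a
binomial bottleneck of n_saturation·dilution cells (default 10⁴) drawn at
the grown frequency — the culture saturates before every transfer, so the
transferred cell number is fixed, as in the experimental protocol.
Measured generation counts in such experiments run slightly below the
dilution-implied value; `generations_per_transfer` overrides the default
when matching a measured count. The observation layer replica-plates ~500
colonies (adaptively topped up to 1000 when the estimate falls below 0.5)
at transfer 0, every 7th transfer and the last. An antibiotic-rescue mode
sets the plasmid-free count to zero at chosen transfers. Replicate-mean
trajectories converge to the deterministic recursion (checked at 3
Monte-Carlo SE); the simulator does not model within-cell copy-number
segregation, multimer resolution, or compensatory mutation.

Relative fitness is the Malthusian ratio w = ln(A_f/A_0)/ln(B_f/B_0) over
one competition cycle; plasmid copy number is the efficiency-corrected
comparative-Ct estimate PCN = E_ref^Ct_ref / E_tgt^Ct_tgt (template scales
as E^−Ct; equal efficiencies give E^ΔCt); growth curves are fit by
multi-start Levenberg–Marquardt least squares to
N(t) = K/(1 + ((K−N0)/N0)e^(−rt)), with tight (1e-13) tolerances so
noiseless curves invert to ≤1e-6 relative error. An optional copy-number-
dependent fitness cost w(PCN) = 1 − c·PCN can be composed by the caller;
it is off by default because only the direction of the PCN–fitness
relationship is established, not a functional form.

## Numerical choices and degenerate inputs

Alignment rejects empty sequences and non-standard residues. The NJ
builder requires a symmetric, zero-diagonal, non-negative matrix and
clamps negative estimated branch lengths to zero. Midpoint rooting raises
on all-zero branch lengths (midpoint undefined). Fitch raises on unlabeled
tips. Loss-rate inversion is undefined at F = 1. The logistic fit raises
on flat series, fewer than 5 points, or non-convergence after restarts.
Empty plasmid sets yield empty summaries, not errors. All generators and
the simulator take explicit seeds; identical configuration plus seed gives
byte-identical output everywhere.

## Problem sizes

Default analysis and verification sizes are chosen to exercise every code
path at desk scale: 500-family pangenomes (~1,000 plasmid proteins,
~1,450 chromosomal), 200–500 gene trees of 8–32 tips, 25-replicon
gene-order sets, 60–100 simulator replicates. All are generator parameters
and scale up directly.
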