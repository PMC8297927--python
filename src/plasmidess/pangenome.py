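"""Pangenome data model and on-disk formats.

A :class:`Pangenome` is the universe every genomic stage consumes: isolates
hold replicons (one chromosome plus zero or more plasmids), replicons hold
ordered protein-coding genes with amino-acid sequences and annotation flags.

On disk a pangenome is a protein FASTA plus a gene-annotation TSV with columns
``gene_id, isolate_id, replicon_id, replicon_type, order_index, strand,
length_aa, flags`` (flags comma-separated from ``essential, amr, transposase,
mob, tra``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CHROMOSOME = "chromosome"
PLASMID = "plasmid"

#: annotation flags understood by the downstream statistics
KNOWN_FLAGS = frozenset({"essential", "amr", "transposase", "mob", "tra"})


@dataclass
class Gene:
    gene_id: str
    isolate_id: str
    replicon_id: str
    replicon_type: str  # chromosome | plasmid
    order_index: int
    strand: str  # '+' | '-'
    seq: str  # amino acids
    flags: frozenset = frozenset()
    name: str = ""  # gene symbol (e.g. for essential genes), optional

    @property
    def length_aa(self) -> int:
        return len(self.seq)


@dataclass
class Replicon:
    replicon_id: str
    isolate_id: str
    replicon_type: str
    size_kb: float
    genes: list[Gene] = field(default_factory=list)

    @property
    def is_plasmid(self) -> bool:
        return self.replicon_type == PLASMID

    def n_flagged(self, flag: str) -> int:
        return sum(1 for g in self.genes if flag in g.flags)


@dataclass
class Pangenome:
    """Container of isolates -> replicons -> ordered genes."""

    replicons: dict[str, Replicon] = field(default_factory=dict)

    def add_replicon(self, rep: Replicon) -> None:
        if rep.replicon_id in self.replicons:
            raise ValueError(f"duplicate replicon id {rep.replicon_id!r}")
        self.replicons[rep.replicon_id] = rep

    # -- views -------------------------------------------------------------
    def genes(self) -> Iterator[Gene]:
        for rep in self.replicons.values():
            yield from rep.genes

    def plasmids(self) -> list[Replicon]:
        return [r for r in self.replicons.values() if r.is_plasmid]

    def chromosomes(self) -> list[Replicon]:
        return [r for r in self.replicons.values() if not r.is_plasmid]

    def plasmid_genes(self) -> list[Gene]:
        return [g for r in self.plasmids() for g in r.genes]

    def chromosome_genes(self) -> list[Gene]:
        return [g for r in self.chromosomes() for g in r.genes]

    def gene_index(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes()}

    def isolate_ids(self) -> list[str]:
        return sorted({r.isolate_id for r in self.replicons.values()})

    # -- I/O ---------------------------------------------------------------
    def to_annotation_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g.gene_id,
                "isolate_id": g.isolate_id,
                "replicon_id": g.replicon_id,
                "replicon_type": g.replicon_type,
                "order_index": g.order_index,
                "strand": g.strand,
                "length_aa": g.length_aa,
                "flags": ",".join(sorted(g.flags)),
                "name": g.name,
            }
            for g in self.genes()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "isolate_id", "replicon_id", "replicon_type",
                "order_index", "strand", "length_aa", "flags", "name",
            ],
        )

    def replicon_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "replicon_id": r.replicon_id,
                    "isolate_id": r.isolate_id,
                    "replicon_type": r.replicon_type,
                    "size_kb": r.size_kb,
                    "n_genes": len(r.genes),
                }
                for r in self.replicons.values()
            ]
        )

    def write(self, fasta_path: str | Path, annotation_path: str | Path,
              replicon_path: str | Path | None = None) -> None:
        records = [
            SeqRecord(Seq(g.seq), id=g.gene_id, description="")
            for g in self.genes()
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        self.to_annotation_frame().to_csv(annotation_path, sep="\t", index=False)
        if replicon_path is not None:
            self.replicon_frame().to_csv(replicon_path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta_path: str | Path, annotation_path: str | Path,
             replicon_path: str | Path | None = None) -> "Pangenome":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        ann = pd.read_csv(annotation_path, sep="\t", keep_default_na=False)
        sizes: dict[str, float] = {}
        if replicon_path is not None:
            rf = pd.read_csv(replicon_path, sep="\t")
            sizes = dict(zip(rf["replicon_id"], rf["size_kb"]))
        pg = cls()
        for (rep_id, iso, rtype), grp in ann.groupby(
                ["replicon_id", "isolate_id", "replicon_type"], sort=True):
            rep = Replicon(rep_id, iso, rtype, size_kb=float(sizes.get(rep_id, 0.0)))
            for row in grp.sort_values("order_index").to_dict("records"):
                flags = frozenset(f for f in str(row["flags"]).split(",") if f)
                rep.genes.append(Gene(
                    gene_id=row["gene_id"], isolate_id=iso, replicon_id=rep_id,
                    replicon_type=rtype, order_index=int(row["order_index"]),
                    strand=row["strand"], seq=seqs[row["gene_id"]], flags=flags,
                    name=str(row.get("name", "") or ""),
                ))
            pg.add_replicon(rep)
        return pg

    def gene_orders(self, plasmids_only: bool = True) -> dict[str, list[str]]:
        """Per-replicon gene id lists in chromosomal order."""
        reps = self.plasmids() if plasmids_only else list(self.replicons.values())
        return {
            r.replicon_id: [g.gene_id for g in sorted(r.genes, key=lambda g: g.order_index)]
            for r in reps
        }


def subset_by_flag(genes: Iterable[Gene], flag: str) -> list[Gene]:
    return [g for g in genes if flag in g.flags]
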