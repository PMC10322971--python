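"""Core data containers shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; the GFF3 writer and
reader translate to/from the 1-based inclusive convention at the boundary.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class Gene:
    """A protein-coding gene (or tRNA feature) on one contig.

    ``family`` carries the ancestral family id when the genome came out of the
    forge; for real annotations it is filled in by the pangenome stage.
    ``product`` is the functional label (e.g. "integrase", "virB4", or a
    hypothetical-protein placeholder) used by the module detectors.
    """

    locus: str
    contig: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "+"
    family: Optional[str] = None
    product: str = "hypothetical protein"
    kind: str = "CDS"  # CDS or tRNA

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty gene interval for {self.locus}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, contigs: dict[str, str]) -> str:
        s = contigs[self.contig][self.start:self.end]
        return revcomp(s) if self.strand == "-" else s

    def protein(self, contigs: dict[str, str]) -> str:
        nt = self.sequence(contigs)
        nt = nt[: len(nt) - len(nt) % 3]
        return str(Seq(nt).translate()).rstrip("*")


@dataclass
class AnnotatedGenome:
    """Assembly + gene models (+ optional per-base depth), the universal input.

    ``circular`` lists contig names with circular topology (e.g. a plasmid
    replicon). ``depth`` maps contig name to a per-base int array.
    """

    name: str
    contigs: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    depth: Optional[dict[str, np.ndarray]] = None
    circular: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(f"gene {g.locus} on unknown contig {g.contig}")

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def genes_on(self, contig: str) -> list[Gene]:
        return sorted((g for g in self.genes if g.contig == contig),
                      key=lambda g: g.start)

    def gene(self, locus: str) -> Gene:
        for g in self.genes:
            if g.locus == locus:
                return g
        raise KeyError(f"no locus {locus} in {self.name}")

    def proteome(self) -> dict[str, str]:
        """locus -> amino-acid sequence for all CDS genes."""
        return {g.locus: g.protein(self.contigs)
                for g in self.genes if g.kind == "CDS"}

    def gc(self) -> float:
        return gc_fraction("".join(self.contigs.values()))

    # ---- flat-file I/O -------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(s), id=n, description="")
                for n, s in self.contigs.items()]
        SeqIO.write(recs, str(path), "fasta")

    def write_proteins(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(p), id=locus, description="")
                for locus, p in self.proteome().items()]
        SeqIO.write(recs, str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for n, s in self.contigs.items():
                fh.write(f"##sequence-region {n} 1 {len(s)}\n")
            for g in sorted(self.genes, key=lambda g: (g.contig, g.start)):
                attrs = f"ID={g.locus};product={g.product}"
                if g.family is not None:
                    attrs += f";family={g.family}"
                if g.contig in self.circular:
                    attrs += ";circular_replicon=true"
                fh.write("\t".join([
                    g.contig, "mobilome", g.kind,
                    str(g.start + 1), str(g.end), ".", g.strand, "0", attrs,
                ]) + "\n")

    def write_depth_bedgraph(self, path: str | Path) -> None:
        if self.depth is None:
            raise ValueError("no depth track")
        with open(path, "w") as fh:
            for contig, track in self.depth.items():
                run_start = 0
                for i in range(1, len(track) + 1):
                    if i == len(track) or track[i] != track[run_start]:
                        fh.write(f"{contig}\t{run_start}\t{i}\t{int(track[run_start])}\n")
                        run_start = i

    @classmethod
    def read(cls, name: str, fasta: str | Path, gff3: str | Path | None = None,
             bedgraph: str | Path | None = None) -> "AnnotatedGenome":
        contigs = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(fasta), "fasta")}
        genes: list[Gene] = []
        circular: set[str] = set()
        if gff3 is not None:
            for lineno, line in enumerate(open(gff3), 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{gff3}:{lineno}: malformed GFF3 record")
                contig, _, kind, start, end, _, strand, _, attrs = parts
                ad = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
                genes.append(Gene(
                    locus=ad.get("ID", f"gene{lineno}"), contig=contig,
                    start=int(start) - 1, end=int(end), strand=strand,
                    family=ad.get("family"), kind=kind,
                    product=ad.get("product", "hypothetical protein")))
                if ad.get("circular_replicon") == "true":
                    circular.add(contig)
        depth = None
        if bedgraph is not None:
            depth = {n: np.zeros(len(s), dtype=np.int32) for n, s in contigs.items()}
            for line in open(bedgraph):
                contig, start, end, val = line.split()
                depth[contig][int(start):int(end)] = int(val)
        return cls(name=name, contigs=contigs, genes=genes, depth=depth,
                   circular=circular)


@dataclass
class Segment:
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty segment")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthRecord:
    """Ground truth for one planted element; the acceptance oracle."""

    strain: str
    element_id: str
    kind: str  # ICE | GI | Tn | plasmid | IS
    segments: list[Segment]
    genes: list[str]
    dr_seq: str = ""
    attL: Optional[tuple[str, int, int]] = None  # (contig, start, end)
    attR: Optional[tuple[str, int, int]] = None
    pre_insertion_site: str = ""  # sequence context of the empty (attB) site

    def to_row(self) -> dict:
        return {
            "strain": self.strain,
            "element_id": self.element_id,
            "kind": self.kind,
            "segments": ";".join(f"{s.contig}:{s.start}-{s.end}({s.strand})"
                                 for s in self.segments),
            "genes": ",".join(self.genes),
            "dr_seq": self.dr_seq,
        }


@dataclass
class ISEvent:
    """One IS transposition: an extra copy landing at a new genomic site.

    ``position`` is the 0-based target position on the reference; a target
    site duplication of ``dr_len`` bp copies ref[position:position+dr_len]
    to both sides of the inserted IS.
    """

    is_id: str
    contig: str
    position: int
    dr_len: int = 8
    target_gene: Optional[str] = None
    allele_fraction: float = 1.0
    support_left: int = 0
    support_right: int = 0


@dataclass
class ReadRecord:
    """A minimal SAM-convention alignment record (single-end)."""

    qname: str
    rname: str
    pos: int           # 0-based leftmost aligned position
    cigar: str         # e.g. "100M", "60M40S", "40S60M"
    seq: str
    mapq: int = 60

    @property
    def flag(self) -> int:
        return 0

    def cigar_ops(self) -> list[tuple[int, str]]:
        ops, n = [], ""
        for c in self.cigar:
            if c.isdigit():
                n += c
            else:
                ops.append((int(n), c))
                n = ""
        return ops

    @property
    def ref_end(self) -> int:
        return self.pos + sum(n for n, op in self.cigar_ops() if op in "MDN")


def write_sam(records: Iterable[ReadRecord], contigs: dict[str, str],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for n, s in contigs.items():
            fh.write(f"@SQ\tSN:{n}\tLN:{len(s)}\n")
        for r in records:
            fh.write("\t".join([
                r.qname, str(r.flag), r.rname, str(r.pos + 1), str(r.mapq),
                r.cigar, "*", "0", "0", r.seq, "*",
            ]) + "\n")


def read_sam(path: str | Path) -> list[ReadRecord]:
    records = []
    for line in open(path):
        if line.startswith("@"):
            continue
        f = line.rstrip("\n").split("\t")
        records.append(ReadRecord(qname=f[0], rname=f[2], pos=int(f[3]) - 1,
                                  cigar=f[5], seq=f[9], mapq=int(f[4])))
    return records


def as_dict(obj) -> dict:
    return dataclasses.asdict(obj)
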