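"""Element typing from functional-module inventories; plasmid utilities.

Typing is a pure rule over the module inventory and the element's context:
an integrated element with an integrase plus a substantially complete
conjugation machinery (>= 5 distinct virB components, or relaxase plus
coupling protein) is an ICE; an integrase without conjugation genes marks a
genomic island; transposase-bounded elements without integrase/tRNA att are
transposons; a rep-bearing circular (or stand-alone oriV-positive) replicon
is a plasmid; anything else is reported as a fragment. Plasmid support
includes terminal-overlap circularization of stand-alone contigs, an oriV
motif scan (DnaA box, IHF site), and in-silico restriction digestion.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .boundaries import iupac_regex
from .model import revcomp

VIRB_COMPONENTS = tuple(f"virb{i}" for i in range(1, 12))
DNAA_BOX = "TTATCCACA"
IHF_MOTIF = "WATCAANNNNTTR"
T4SS_COMPLETE = 5  # distinct virB components for a "complete" conjugation set


@dataclass
class ModuleInventory:
    integrases: list[str] = field(default_factory=list)
    transposases: list[str] = field(default_factory=list)
    virb: set[str] = field(default_factory=set)       # e.g. {"virB4", ...}
    relaxase: list[str] = field(default_factory=list)
    coupling: list[str] = field(default_factory=list)  # t4cp / virD4
    toxin_antitoxin: list[str] = field(default_factory=list)
    partition: list[str] = field(default_factory=list)
    replication: list[str] = field(default_factory=list)
    dnaa_boxes: list[int] = field(default_factory=list)  # positions near rep
    ihf_sites: list[int] = field(default_factory=list)
    cargo: list[str] = field(default_factory=list)

    @property
    def conjugation_complete(self) -> bool:
        return len(self.virb) >= T4SS_COMPLETE or \
            (bool(self.relaxase) and bool(self.coupling))


_LABEL_RULES = (
    ("integrases", re.compile(r"integrase|\brita|\britb|\britc")),
    ("transposases", re.compile(r"transposase|\btnp")),
    ("relaxase", re.compile(r"relaxase|vird2|\bmob")),
    ("coupling", re.compile(r"t4cp|vird4|coupling")),
    ("toxin_antitoxin", re.compile(
        r"toxin|vapb|vapc|maze|mazf|yafq|phd|doc\b|higa")),
    ("partition", re.compile(r"\bpara|\bparb|\bparg|partition")),
    ("replication", re.compile(r"\brep\b|replicase|replication protein")),
)


def detect_modules(proteins: dict[str, str],
                   sequence: Optional[str] = None,
                   gene_coords: Optional[dict[str, tuple[int, int]]] = None,
                   oriv_window: int = 500) -> ModuleInventory:
    """Populate the inventory from product labels (locus -> label).

    When the element sequence and gene coordinates are given, DnaA boxes
    (<= 1 mismatch) and IHF motifs are scanned within ``oriv_window`` bp of
    each replication gene.
    """
    inv = ModuleInventory()
    for locus, label in proteins.items():
        low = label.lower()
        m = re.search(r"virb(\d+)", low)
        if m and 1 <= int(m.group(1)) <= 11:
            inv.virb.add(f"virB{int(m.group(1))}")
            continue
        for attr, pat in _LABEL_RULES:
            if pat.search(low):
                getattr(inv, attr).append(locus)
                break
        else:
            inv.cargo.append(locus)

    if sequence and gene_coords and inv.replication:
        for locus in inv.replication:
            if locus not in gene_coords:
                continue
            a, b = gene_coords[locus]
            lo, hi = max(0, a - oriv_window), min(len(sequence), b + oriv_window)
            window = sequence[lo:hi]
            inv.dnaa_boxes += [lo + p for p in
                               _approx_sites(window, DNAA_BOX, 1)]
            pat = iupac_regex(IHF_MOTIF)
            for strand_seq, flip in ((window, False), (revcomp(window), True)):
                for m2 in pat.finditer(strand_seq):
                    pos = m2.start() if not flip else \
                        len(window) - m2.end()
                    inv.ihf_sites.append(lo + pos)
        inv.dnaa_boxes = sorted(set(inv.dnaa_boxes))
        inv.ihf_sites = sorted(set(inv.ihf_sites))
    return inv


def _approx_sites(seq: str, motif: str, max_mismatch: int) -> list[int]:
    out = []
    for strand_seq in (seq, revcomp(seq)):
        for i in range(len(strand_seq) - len(motif) + 1):
            mm = sum(1 for a, b in zip(motif, strand_seq[i:i + len(motif)])
                     if a != b)
            if mm <= max_mismatch:
                pos = i if strand_seq is seq else len(seq) - i - len(motif)
                out.append(pos)
    return sorted(set(out))


@dataclass
class ElementContext:
    integrated: bool = True
    circular: bool = False
    att_present: bool = False
    standalone_contig: bool = False
    at_trna: bool = False

    def __post_init__(self) -> None:
        if self.integrated and self.circular:
            raise ValueError("element cannot be both integrated and circular")


@dataclass
class ElementType:
    label: str   # ICE | GI | Tn | plasmid | fragment
    notes: str = ""


def type_element(inv: ModuleInventory, ctx: ElementContext) -> ElementType:
    has_int = bool(inv.integrases)
    has_tnp = bool(inv.transposases)
    has_rep = bool(inv.replication)
    oriv = bool(inv.dnaa_boxes or inv.ihf_sites)
    if has_rep and (ctx.circular or (ctx.standalone_contig and oriv)):
        return ElementType("plasmid", "rep with circular/oriV evidence")
    if ctx.integrated and has_int and inv.conjugation_complete:
        return ElementType("ICE", "integrase + conjugation module")
    if has_int:
        return ElementType("GI", "integrase/recombinase without conjugation")
    if has_tnp and not ctx.at_trna:
        return ElementType("Tn", "transposase-bounded, no integrase/tRNA att")
    return ElementType("fragment", "no diagnostic module")


# ---- circularization ---------------------------------------------------


class AmbiguousOverlapError(ValueError):
    pass


@dataclass
class CircularizationResult:
    topology: str                # "circular" | "linear"
    sequence: str                # trimmed when circular
    overlap: int = 0


def circularize_contig(contig: str, min_overlap: int = 50,
                       max_mismatch: int = 0) -> CircularizationResult:
    """Detect an assembly-duplicated terminus (prefix == suffix) and trim it.

    The longest qualifying overlap is removed; two non-nested candidate
    overlaps (different implied circle lengths that are not rotations of a
    common period) raise an ambiguity error.
    """
    n = len(contig)
    candidates = []
    for k in range(min(n // 2, n - 1), min_overlap - 1, -1):
        if max_mismatch == 0:
            if contig[:k] == contig[n - k:]:
                candidates.append(k)
        else:
            mm = sum(1 for a, b in zip(contig[:k], contig[n - k:]) if a != b)
            if mm <= max_mismatch:
                candidates.append(k)
    if not candidates:
        return CircularizationResult("linear", contig)
    k = candidates[0]
    for other in candidates[1:]:
        # nested overlaps from local periodicity are fine; distinct ones not
        if (k - other) % max(1, _min_period(contig[:k])) != 0:
            raise AmbiguousOverlapError(
                f"overlap candidates {k} and {other} disagree")
    return CircularizationResult("circular", contig[:n - k], overlap=k)


def _min_period(s: str) -> int:
    for p in range(1, len(s) + 1):
        if all(s[i] == s[i % p] for i in range(len(s))):
            return p
    return len(s)


# ---- restriction digest ------------------------------------------------


def digest(sequence: str, topology: str, site: str = "GGATCC",
           cut_offset: int = 1) -> list[int]:
    """Fragment lengths (sorted) from cutting at every site occurrence.

    Circular molecules with n sites yield n fragments summing to the
    length; linear molecules yield n + 1. A circular molecule with no site
    returns a single full-length (uncut) record.
    """
    pat = iupac_regex(site)
    seq = sequence.upper()
    n = len(seq)
    if topology == "circular":
        doubled = seq + seq[:len(site) - 1]
        cuts = sorted((m.start() + cut_offset) % n
                      for m in pat.finditer(doubled) if m.start() < n)
        if not cuts:
            return [n]
        frags = [(b - a) % n or n for a, b in
                 zip(cuts, cuts[1:] + [cuts[0]])]
        return sorted(frags)
    cuts = sorted(m.start() + cut_offset for m in pat.finditer(seq))
    bounds = [0] + cuts + [n]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]) if b > a)
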