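"""Element boundary inference, att-site reconstruction, and in-silico PCR.

Around every seed hit the pipeline gathers per-gene contextual evidence
(GC-content deviation, read-depth anomaly, pangenome compartment, and
mobility-signature flags), extends the candidate outward over consecutive
flexible/exclusive genes — tolerating single interspersed core genes, and
stopping at two consecutive core genes — merges multi-contig segments that
cover disjoint parts of the same seed element, aligns the terminal windows
to recover the direct repeat, and reconstructs the att quartet (attL/attR on
the chromosome, attB for the excised state, attP for the circular
intermediate). A primer-based amplicon predictor supports PCR validation
designs for each site.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .census import SeedHit
from .model import AnnotatedGenome, Gene, Segment, gc_fraction, revcomp
from .pangenome import FamilyTable

SIGNATURE_TERMS = ("integrase", "transposase", "recombinase", "virb",
                   "relaxase", "mob", "t4cp", "trag", "traj", "rep",
                   "para", "parb", "parg", "toxin", "antitoxin", "vapb",
                   "vapc", "excisionase")


@dataclass
class GeneEvidence:
    locus: str
    contig: str
    index: int                       # position among genes on its contig
    gc_z: float
    depth_z: Optional[float]
    compartment: str                 # core | soft-core | flexible | exclusive | unassigned
    signature: bool
    strand: str


@dataclass
class EvidenceTrack:
    genome: str
    per_gene: dict[str, GeneEvidence]
    depth_available: bool

    def on_contig(self, contig: str) -> list[GeneEvidence]:
        return sorted((e for e in self.per_gene.values() if e.contig == contig),
                      key=lambda e: e.index)


def contextual_profile(genome: AnnotatedGenome,
                       table: Optional[FamilyTable] = None,
                       depth: Optional[dict[str, np.ndarray]] = None
                       ) -> EvidenceTrack:
    """Per-gene evidence: GC z-score against the gene-wise GC distribution,
    depth z-score against the chromosome median, compartment, signature."""
    comp_of: dict[str, str] = {}
    if table is not None:
        for (strain, locus), fam in table.of_locus().items():
            if strain == genome.name:
                comp_of[locus] = fam.compartment

    cds = [g for g in genome.genes if g.kind == "CDS"]
    # the GC background comes from the core genes when compartments are
    # known (horizontally acquired genes are the outliers being flagged and
    # must not widen the reference spread); otherwise robust stats over all
    background = [g for g in cds if comp_of.get(g.locus) == "core"] or cds
    gcs = np.array([gc_fraction(g.sequence(genome.contigs))
                    for g in background])
    mu = float(np.median(gcs))
    sd = max(1.4826 * float(np.median(np.abs(gcs - mu))), 1e-6)

    depth = depth if depth is not None else genome.depth
    med = mad = None
    if depth is not None:
        chrom = max(genome.contigs, key=lambda c: len(genome.contigs[c]))
        track = depth[chrom]
        med = float(np.median(track))
        mad = float(np.median(np.abs(track - med))) or 1.0

    per_gene: dict[str, GeneEvidence] = {}
    index_on: dict[str, int] = {}
    for g in sorted(genome.genes, key=lambda g: (g.contig, g.start)):
        idx = index_on.get(g.contig, 0)
        index_on[g.contig] = idx + 1
        gz = 0.0
        if g.kind == "CDS":
            gz = (gc_fraction(g.sequence(genome.contigs)) - mu) / sd
        dz = None
        if depth is not None and g.contig in depth:
            gene_med = float(np.median(depth[g.contig][g.start:g.end]))
            dz = (gene_med - med) / (1.4826 * mad)
        product = g.product.lower()
        per_gene[g.locus] = GeneEvidence(
            locus=g.locus, contig=g.contig, index=idx, gc_z=gz, depth_z=dz,
            compartment=comp_of.get(g.locus, "unassigned"),
            signature=any(t in product for t in SIGNATURE_TERMS),
            strand=g.strand)
    return EvidenceTrack(genome=genome.name, per_gene=per_gene,
                         depth_available=depth is not None)


@dataclass
class AttQuartet:
    dr_seq: str
    dr_length: int
    attL: tuple[str, int, int]
    attR: tuple[str, int, int]
    attB: str                        # reconstructed empty-site sequence
    attP: str                        # reconstructed excised-circle junction
    integration_feature: str = ""
    mismatches: int = 0


@dataclass
class CandidateElement:
    element_id: str
    segments: list[Segment]
    genes: list[str]
    seed_elements: list[str] = field(default_factory=list)
    att: Optional[AttQuartet] = None
    element_type: str = "fragment"
    confidence: str = "high"
    support: float = 0.0

    @property
    def n_genes(self) -> int:
        return len(self.genes)


MOBILE = {"flexible", "exclusive"}


def _extend(genes: list[Gene], evidence: EvidenceTrack, lo: int, hi: int,
            core_run_stop: int = 2) -> tuple[int, int]:
    """Grow [lo, hi] over flexible/exclusive genes; runs of fewer than
    ``core_run_stop`` consecutive core genes are absorbed."""

    def mobile(i: int) -> bool:
        ev = evidence.per_gene.get(genes[i].locus)
        return ev is not None and ev.compartment in MOBILE

    def grow(i: int, step: int) -> int:
        edge = i
        while True:
            j = edge + step
            if not 0 <= j < len(genes):
                return edge
            if mobile(j):
                edge = j
                continue
            # look past a short core run
            run_end = j
            run = 0
            while 0 <= run_end < len(genes) and not mobile(run_end):
                run += 1
                if run >= core_run_stop:
                    return edge
                run_end += step
            if not 0 <= run_end < len(genes):
                return edge
            edge = run_end
    return grow(lo, -1), grow(hi, +1)


def reconstruct_elements(seed_hits: dict[str, list[SeedHit]],
                         genome: AnnotatedGenome,
                         evidence: EvidenceTrack,
                         window: int = 10,
                         min_merge_coverage: float = 0.5,
                         seed_sizes: Optional[dict[str, int]] = None
                         ) -> list[CandidateElement]:
    """Delimit candidate elements around seed hits.

    ``seed_hits`` maps seed element id -> hits in this genome. Seeds within
    ``window`` genes of each other merge into one candidate; candidates on
    contigs that are entirely flexible/exclusive absorb the whole contig;
    segments on different contigs that match disjoint parts of the same seed
    at >= ``min_merge_coverage`` combined are merged into one element.
    """
    locus_gene = {g.locus: g for g in genome.genes}
    by_contig: dict[str, list[Gene]] = {}
    for g in sorted(genome.genes, key=lambda g: (g.contig, g.start)):
        by_contig.setdefault(g.contig, []).append(g)

    # seed gene indices per (contig, seed element): clusters never span
    # hits of unrelated seeds, so adjacent distinct elements stay separate
    seeded: dict[tuple[str, str], list[int]] = {}
    for elem_id, hits in seed_hits.items():
        for h in hits:
            g = locus_gene.get(h.target_locus)
            if g is None:
                continue
            idx = by_contig[g.contig].index(g)
            seeded.setdefault((g.contig, elem_id), []).append(idx)

    raw: list[CandidateElement] = []
    for (contig, elem_id), marks in sorted(seeded.items()):
        genes = by_contig[contig]
        marks.sort()
        clusters: list[list[int]] = [[marks[0]]]
        for m in marks[1:]:
            if m - clusters[-1][-1] <= window:
                clusters[-1].append(m)
            else:
                clusters.append([m])
        all_mobile = all(
            evidence.per_gene[g.locus].compartment in MOBILE
            for g in genes if g.kind == "CDS" and g.locus in evidence.per_gene)
        for cl in clusters:
            if all_mobile:
                lo, hi = 0, len(genes) - 1
            else:
                lo, hi = _extend(genes, evidence, cl[0], cl[-1])
            span = genes[lo:hi + 1]
            ev = [evidence.per_gene[g.locus] for g in span
                  if g.locus in evidence.per_gene]
            support = float(np.mean([
                (e.compartment in MOBILE) + e.signature +
                (abs(e.gc_z) >= 2) +
                (e.depth_z is not None and abs(e.depth_z) >= 2)
                for e in ev])) if ev else 0.0
            raw.append(CandidateElement(
                element_id="tmp",
                segments=[Segment(contig, span[0].start, span[-1].end)],
                genes=[g.locus for g in span],
                seed_elements=[elem_id],
                confidence="low" if len(span) == 1 else "high",
                support=support))

    raw = _merge_overlapping(raw)
    for n, c in enumerate(raw, start=1):
        c.element_id = f"cand{n:02d}"
    merged = _merge_segments(raw, seed_hits, min_merge_coverage, seed_sizes)
    merged.sort(key=lambda c: (-c.support, c.element_id))
    return merged


def _merge_overlapping(cands: list[CandidateElement]) -> list[CandidateElement]:
    """Union same-contig candidates whose gene spans overlap (one physical
    region matched by several seed elements is one element)."""
    out: list[CandidateElement] = []
    for c in sorted(cands, key=lambda c: (c.segments[0].contig,
                                          c.segments[0].start)):
        if out:
            prev = out[-1]
            ps, cs = prev.segments[0], c.segments[0]
            if ps.contig == cs.contig and cs.start < ps.end:
                out[-1] = CandidateElement(
                    element_id=prev.element_id,
                    segments=[Segment(ps.contig, ps.start,
                                      max(ps.end, cs.end))],
                    genes=sorted(set(prev.genes) | set(c.genes)),
                    seed_elements=sorted(set(prev.seed_elements) |
                                         set(c.seed_elements)),
                    confidence=prev.confidence,
                    support=max(prev.support, c.support))
                continue
        out.append(c)
    return out


def _merge_segments(cands: list[CandidateElement],
                    seed_hits: dict[str, list[SeedHit]],
                    min_cov: float,
                    seed_sizes: Optional[dict[str, int]]
                    ) -> list[CandidateElement]:
    """Merge candidates on different contigs that cover disjoint portions of
    the same seed element with sufficient combined coverage."""
    out = list(cands)
    changed = True
    while changed:
        changed = False
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                a, b = out[i], out[j]
                shared = set(a.seed_elements) & set(b.seed_elements)
                if not shared:
                    continue
                if {s.contig for s in a.segments} & {s.contig for s in b.segments}:
                    continue
                ok = False
                for e in shared:
                    qa = {h.query for h in seed_hits.get(e, ())
                          if h.target_locus in a.genes}
                    qb = {h.query for h in seed_hits.get(e, ())
                          if h.target_locus in b.genes}
                    if not qa or not qb or (qa & qb):
                        continue
                    total = seed_sizes.get(e) if seed_sizes else None
                    cov = (len(qa | qb) / total) if total else 1.0
                    if cov >= min_cov:
                        ok = True
                        break
                if ok:
                    out[i] = CandidateElement(
                        element_id=a.element_id,
                        segments=a.segments + b.segments,
                        genes=a.genes + b.genes,
                        seed_elements=sorted(set(a.seed_elements) |
                                             set(b.seed_elements)),
                        confidence=a.confidence,
                        support=max(a.support, b.support))
                    del out[j]
                    changed = True
                    break
            if changed:
                break
    return out


# ---- att sites ---------------------------------------------------------


def find_att_sites(candidate: CandidateElement, genome: AnnotatedGenome,
                   min_dr: int = 12, max_mismatch: int = 1,
                   search_window: int = 1000) -> Optional[AttQuartet]:
    """Recover the direct repeat shared by the two element termini.

    The windows just outside/inside each terminus are scanned for the
    longest repeat of >= ``min_dr`` bp with <= ``max_mismatch`` mismatches,
    seeded on exact 8-mers and extended. attB/attP are then reconstructed by
    in-silico excision. Returns None when the element spans several contigs
    with unresolved termini or no qualifying repeat exists.
    """
    if len({s.contig for s in candidate.segments}) != 1:
        return None
    contig = candidate.segments[0].contig
    seq = genome.contigs[contig]
    start = min(s.start for s in candidate.segments)
    end = max(s.end for s in candidate.segments)

    lw_a = max(0, start - search_window)
    left = seq[lw_a:min(len(seq), start + search_window // 4)]
    rw_a = max(0, end - search_window // 4)
    right = seq[rw_a:min(len(seq), end + search_window)]

    rep = _best_repeat(left, right, min_dr, max_mismatch)
    if rep is None:
        return None
    l_off, r_off, length, mism = rep
    l_start = lw_a + l_off
    r_start = rw_a + r_off
    if r_start <= l_start:
        return None
    dr = seq[l_start:l_start + length]

    # excision: keep one repeat copy, remove [end of left DR, end of right DR)
    attB = seq[:l_start + length] + seq[r_start + length:]
    circle = seq[l_start + length:r_start + length]
    attP = circle[-min(200, len(circle)):] + circle[:min(200, len(circle))]

    feature = ""
    best_d = None
    for g in genome.genes_on(contig):
        if g.kind == "tRNA" or "integrase" in g.product.lower():
            d = min(abs(g.end - l_start), abs(g.start - (r_start + length)))
            if best_d is None or d < best_d:
                best_d, feature = d, g.product if g.kind == "tRNA" else g.locus
    return AttQuartet(dr_seq=dr, dr_length=length,
                      attL=(contig, l_start, l_start + length),
                      attR=(contig, r_start, r_start + length),
                      attB=attB, attP=attP, integration_feature=feature,
                      mismatches=mism)


def _best_repeat(left: str, right: str, min_len: int, max_mismatch: int,
                 seed: int = 8) -> Optional[tuple[int, int, int, int]]:
    """Longest shared repeat between two windows: (left_off, right_off,
    length, mismatches)."""
    if min_len < seed:
        seed = max(4, min_len)
    index: dict[str, list[int]] = {}
    for i in range(len(left) - seed + 1):
        index.setdefault(left[i:i + seed], []).append(i)
    best = None
    budgets = (max_mismatch, 0) if max_mismatch else (0,)
    for j in range(len(right) - seed + 1):
        for i in index.get(right[j:j + seed], ()):
            for budget in budgets:  # greedy bridging can shadow exact runs
                li, rj, length, mism = _extend_pair(left, right, i, j,
                                                    budget)
                # short repeats must be exact: a mismatch-tolerant match
                # near the minimum length is indistinguishable from chance
                if length < min_len or (mism > 0 and length < 2 * min_len):
                    continue
                if best is None or (mism, -length) < (best[3], -best[2]):
                    best = (li, rj, length, mism)
    return best


def _extend_pair(a: str, b: str, i: int, j: int, max_mismatch: int
                 ) -> tuple[int, int, int, int]:
    """Extend an exact seed at (i, j) in both directions, sharing the
    mismatch budget; boundary mismatches are trimmed off."""
    mism = 0
    fwd = 0
    while i + fwd < len(a) and j + fwd < len(b):
        if a[i + fwd] == b[j + fwd]:
            fwd += 1
        elif (mism < max_mismatch and i + fwd + 1 < len(a)
              and j + fwd + 1 < len(b)
              and a[i + fwd + 1] == b[j + fwd + 1]):
            mism += 1
            fwd += 1
        else:
            break
    back = 0
    while i - back - 1 >= 0 and j - back - 1 >= 0:
        if a[i - back - 1] == b[j - back - 1]:
            back += 1
        elif (mism < max_mismatch and i - back - 2 >= 0 and j - back - 2 >= 0
              and a[i - back - 2] == b[j - back - 2]):
            mism += 1
            back += 1
        else:
            break
    li, lj, length = i - back, j - back, back + fwd
    while length > 0 and a[li + length - 1] != b[lj + length - 1]:
        length -= 1
        mism -= 1
    while length > 0 and a[li] != b[lj]:
        li += 1
        lj += 1
        length -= 1
        mism -= 1
    return li, lj, length, max(0, mism)


# ---- in-silico PCR -----------------------------------------------------

IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]",
         "S": "[GC]", "W": "[AT]", "K": "[GT]", "M": "[AC]", "B": "[CGT]",
         "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]"}


def iupac_regex(pattern: str) -> re.Pattern:
    try:
        return re.compile("".join(IUPAC[c] for c in pattern.upper()))
    except KeyError as e:
        raise ValueError(f"invalid IUPAC code {e.args[0]!r}") from None


@dataclass
class Amplicon:
    template: str
    start: int
    end: int      # may exceed template length on circular templates
    length: int
    fwd_primer: str
    rev_primer: str


class AmbiguousPrimerError(ValueError):
    pass


def _primer_sites(seq: str, primer: str, max_mismatch: int) -> list[int]:
    """Start positions where the primer matches the + strand of seq."""
    if max_mismatch == 0:
        return [m.start() for m in re.finditer(f"(?={re.escape(primer)})", seq)]
    out = []
    for i in range(len(seq) - len(primer) + 1):
        mm = sum(1 for a, b in zip(primer, seq[i:i + len(primer)]) if a != b)
        if mm <= max_mismatch:
            out.append(i)
    return out


def insilico_pcr(templates: dict[str, str], fwd: str, rev: str,
                 max_mismatch: int = 0, max_len: int = 6000,
                 circular: Optional[set[str]] = None) -> list[Amplicon]:
    """Predict amplicons from opposing-orientation primer matches.

    Amplicon length is the distance between the outer 5' ends, inclusive.
    Circular templates are searched across the origin.
    """
    if min(len(fwd), len(rev)) < 15:
        raise ValueError("primers must be >= 15 nt")
    circular = circular or set()
    out = []
    for name, seq in templates.items():
        search = seq + seq[:max_len] if name in circular else seq
        for f_primer, r_primer in ((fwd, rev), (rev, fwd)):
            plus = _primer_sites(search, f_primer, max_mismatch)
            minus = _primer_sites(search, revcomp(r_primer), max_mismatch)
            if len(plus) > 100 or len(minus) > 100:
                raise AmbiguousPrimerError(f"too many binding sites on {name}")
            for p in plus:
                if name in circular and p >= len(seq):
                    continue
                for q in minus:
                    end = q + len(r_primer)
                    if p < end and end - p <= max_len:
                        out.append(Amplicon(template=name, start=p, end=end,
                                            length=end - p, fwd_primer=f_primer,
                                            rev_primer=r_primer))
    out.sort(key=lambda a: (a.template, a.start, a.length))
    return out
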