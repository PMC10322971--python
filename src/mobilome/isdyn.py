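"""Insertion-sequence inventory and transposition dynamics from resequencing.

``scan_is_copies`` counts IS copies in an assembly (default thresholds: 90%
minimum similarity over 100% of the IS length). ``detect_insertions``
consumes SAM-convention alignment records, clusters soft-clipped reads whose
clipped tails match IS termini, and pairs left/right junction clusters into
transposition events whose offset gives the target-site duplication length.
``track_alleles`` follows mutant/wild junction read counts across serial
passages, and ``replicon_depth_fold`` reports median-depth ratios (e.g. the
plasmid copy-number fold over the chromosome).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .model import AnnotatedGenome, ISEvent, ReadRecord, Segment, revcomp


@dataclass
class ISCopy:
    is_id: str
    contig: str
    start: int
    end: int
    strand: str
    identity: float


def scan_is_copies(genome: AnnotatedGenome, is_library: dict[str, str],
                   min_similarity: float = 0.90,
                   min_coverage: float = 1.00) -> dict[str, list[ISCopy]]:
    """Inventory IS copies by iterative best-placement and masking.

    Each IS is aligned to each contig (both strands); the best placement is
    recorded and masked, and the search repeats until the placement falls
    below the similarity or coverage thresholds. Overlapping hits merge.
    """
    if not is_library:
        raise ValueError("empty IS library")
    out: dict[str, list[ISCopy]] = {name: [] for name in is_library}
    for name, is_seq in is_library.items():
        L = len(is_seq)
        for cname, cseq in genome.contigs.items():
            work = cseq
            while True:
                best = None
                for strand, q in (("+", is_seq), ("-", revcomp(is_seq))):
                    res = edlib.align(q, work, mode="HW", task="locations")
                    if res["editDistance"] < 0:
                        continue
                    s, e = res["locations"][0]
                    ident = 1.0 - res["editDistance"] / L
                    if best is None or ident > best[3]:
                        best = (strand, s, e + 1, ident)
                if best is None:
                    break
                strand, s, e, ident = best
                if ident < min_similarity or (e - s) < min_coverage * L:
                    break
                out[name].append(ISCopy(name, cname, s, e, strand, ident))
                work = work[:s] + "N" * (e - s) + work[e:]
    for name in out:
        out[name] = _merge_copies(sorted(out[name],
                                         key=lambda c: (c.contig, c.start)))
    return out


def _merge_copies(copies: list[ISCopy]) -> list[ISCopy]:
    merged: list[ISCopy] = []
    for c in copies:
        if merged and merged[-1].contig == c.contig and \
                c.start < merged[-1].end:
            prev = merged[-1]
            merged[-1] = ISCopy(prev.is_id, prev.contig, prev.start,
                                max(prev.end, c.end), prev.strand,
                                max(prev.identity, c.identity))
        else:
            merged.append(c)
    return merged


# ---- transposition calling --------------------------------------------


def _clip_tail(read: ReadRecord) -> Optional[tuple[str, int, str]]:
    """(side, junction position, clipped sequence) for a soft-clipped read.

    side "L": clip at the read's right end -> junction at ref_end (reads
    running into the IS from the left). side "R": clip at the read's left
    end -> junction at pos.
    """
    ops = read.cigar_ops()
    if len(ops) < 2:
        return None
    if ops[-1][1] == "S" and ops[0][1] == "M":
        n = ops[-1][0]
        return ("L", read.ref_end, read.seq[-n:])
    if ops[0][1] == "S" and ops[-1][1] == "M":
        n = ops[0][0]
        return ("R", read.pos, read.seq[:n])
    return None


def _matches_terminus(clip: str, side: str, is_seq: str,
                      max_edit_frac: float = 0.1) -> bool:
    """Does the clipped tail continue into the IS (either orientation)?"""
    n = len(clip)
    refs = []
    if side == "L":  # clip should match an IS start
        refs = [is_seq[:n], revcomp(is_seq)[:n]]
    else:            # clip should match an IS end
        refs = [is_seq[-n:], revcomp(is_seq)[-n:]]
    maxe = max(1, int(max_edit_frac * n))
    for r in refs:
        if edlib.align(clip, r, mode="NW", k=maxe)["editDistance"] >= 0:
            return True
    return False


def detect_insertions(genome: AnnotatedGenome, reads: Sequence[ReadRecord],
                      is_library: dict[str, str], min_support: int = 5,
                      pairing_window: int = 15,
                      known_copies: Optional[dict[str, list[ISCopy]]] = None
                      ) -> list[ISEvent]:
    """Call new IS insertions from clipped junction reads.

    Left clusters (reads clipped on the right, tails matching an IS
    terminus) pair with right clusters within ``pairing_window`` bp; the
    left-minus-right offset is the target-site duplication length. Both
    junctions need ``min_support`` reads. Insertions inside existing copies
    of the same IS (``known_copies``) are ignored as reference alignments.
    """
    if not reads:
        return []
    for r in reads:
        if r.rname not in genome.contigs:
            raise ValueError(f"read {r.qname} aligned to unknown contig")
    clusters: dict[tuple[str, str, str, int], int] = {}
    for read in reads:
        tail = _clip_tail(read)
        if tail is None:
            continue
        side, pos, clip = tail
        if len(clip) < 8:
            continue
        for is_id, is_seq in is_library.items():
            if _matches_terminus(clip, side, is_seq):
                key = (read.rname, is_id, side, pos)
                clusters[key] = clusters.get(key, 0) + 1
                break

    events: list[ISEvent] = []
    lefts = {k: v for k, v in clusters.items() if k[2] == "L"}
    rights = {k: v for k, v in clusters.items() if k[2] == "R"}
    used: set[tuple] = set()
    for (contig, is_id, _, lpos), lcount in sorted(lefts.items()):
        best = None
        for (c2, i2, _, rpos), rcount in rights.items():
            if c2 != contig or i2 != is_id:
                continue
            if 0 <= lpos - rpos <= pairing_window and (c2, i2, rpos) not in used:
                if best is None or abs(lpos - rpos) < abs(best[0] - rpos):
                    best = (lpos, rpos, rcount)
        if best is None:
            continue
        lpos_, rpos, rcount = best
        if lcount < min_support or rcount < min_support:
            continue
        if known_copies:
            near = any(c.start - pairing_window <= rpos <= c.end + pairing_window
                       for c in known_copies.get(is_id, ())
                       if c.contig == contig)
            if near:
                continue
        used.add((contig, is_id, rpos))
        target = None
        for g in genome.genes_on(contig):
            if g.start <= rpos < g.end:
                target = g.locus
                break
        total = lcount + rcount
        events.append(ISEvent(is_id=is_id, contig=contig, position=rpos,
                              dr_len=lpos_ - rpos, target_gene=target,
                              support_left=lcount, support_right=rcount,
                              allele_fraction=1.0))
    # fill in allele fractions from wild-type spanning reads
    for ev in events:
        mut = ev.support_left + ev.support_right
        wild = _spanning_wild(reads, ev)
        ev.allele_fraction = mut / (mut + wild) if mut + wild else 0.0
    return events


def _spanning_wild(reads: Sequence[ReadRecord], ev: ISEvent,
                   clip_min: int = 8) -> int:
    """Reads spanning the whole target site without clipping, doubled to be
    commensurate with the two junction read sets.

    The flanking margin shrinks with the duplication length so that the
    genomic window producing countable wild reads has the same width as the
    window producing countable junction reads (clip >= ``clip_min``),
    keeping the fraction estimator unbiased.
    """
    margin = max(0, clip_min - (ev.dr_len + 1) // 2)
    n = 0
    for r in reads:
        if r.rname != ev.contig or "S" in r.cigar:
            continue
        if r.pos + margin <= ev.position and \
                r.ref_end - margin >= ev.position + ev.dr_len:
            n += 1
    return 2 * n


# ---- allele trajectories ----------------------------------------------


@dataclass
class PassagePoint:
    passage: int
    fraction: float
    mutant_reads: int
    wild_reads: int
    detected: bool


@dataclass
class PassageSeries:
    event: ISEvent
    points: list[PassagePoint]
    loss_passage: Optional[int] = None

    @property
    def fractions(self) -> list[float]:
        return [p.fraction for p in self.points]


def track_alleles(event: ISEvent, passage_reads: dict[int, Sequence[ReadRecord]],
                  is_library: dict[str, str],
                  min_support: int = 5) -> PassageSeries:
    """Mutant-allele fraction per ordered passage; loss is called at the
    first undetected passage after a detected one."""
    points = []
    for passage in sorted(passage_reads):
        reads = passage_reads[passage]
        mut = 0
        for read in reads:
            tail = _clip_tail(read)
            if tail is None:
                continue
            side, pos, clip = tail
            if len(clip) < 8:
                continue
            expected = event.position + event.dr_len if side == "L" \
                else event.position
            if read.rname == event.contig and abs(pos - expected) <= 1 and \
                    _matches_terminus(clip, side, is_library[event.is_id]):
                mut += 1
        wild = _spanning_wild(reads, event)
        total = mut + wild
        points.append(PassagePoint(
            passage=passage, fraction=mut / total if total else 0.0,
            mutant_reads=mut, wild_reads=wild,
            detected=mut >= min_support))
    loss = None
    seen = False
    for p in points:
        if p.detected:
            seen = True
        elif seen:
            loss = p.passage
            break
    return PassageSeries(event=event, points=points, loss_passage=loss)


# ---- depth folds -------------------------------------------------------


def replicon_depth_fold(depth: dict[str, np.ndarray],
                        replicons: dict[str, list[Segment]],
                        chromosome: Optional[str] = None) -> dict[str, float]:
    """Median replicon depth / median chromosome depth per replicon."""
    if chromosome is None:
        chromosome = max(depth, key=lambda c: len(depth[c]))
    chrom_med = float(np.median(depth[chromosome]))
    if chrom_med == 0:
        raise ValueError("zero chromosome depth")
    out = {}
    for name, segs in replicons.items():
        vals = np.concatenate([depth[s.contig][s.start:s.end] for s in segs])
        out[name] = float(np.median(vals)) / chrom_med
    return out
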