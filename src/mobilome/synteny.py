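"""Synteny-block reconstruction from reciprocal-best-hit anchors.

Anchors are unique reciprocal best protein hits between two genomes. A block
is a maximal run of anchors that is colinear on both genomes with at most
``delta`` intervening genes between consecutive anchors on either genome and
a consistent relative orientation; blocks need at least two anchors. The
coverage fraction at a given delta is the number of anchored genes inside
blocks divided by the gene count, averaged over the two genomes (a
reference-directed mode is also provided).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .align import best_hit, kmer_index
from .model import AnnotatedGenome

DELTAS = tuple(range(2, 11))


@dataclass
class Block:
    anchors: list[tuple[int, int]]  # (gene index in a, gene index in b)
    orientation: int                # +1 colinear, -1 inverted

    @property
    def size(self) -> int:
        return len(self.anchors)


@dataclass
class SyntenyResult:
    pair: tuple[str, str]
    coverage: dict[int, float]
    blocks: dict[int, list[Block]] = field(default_factory=dict)

    @property
    def mean_coverage(self) -> float:
        return sum(self.coverage.values()) / len(self.coverage)


def rbh_anchors(a: AnnotatedGenome, b: AnnotatedGenome
                ) -> list[tuple[str, str]]:
    """Unique reciprocal best hits between the two proteomes (paralog-free)."""
    pa, pb = a.proteome(), b.proteome()
    if not pa or not pb:
        raise ValueError("unannotated genome")
    ia, ib = kmer_index(pa), kmer_index(pb)
    fwd = {}
    for qname, qseq in pa.items():
        h = best_hit(qname, qseq, pb, ib)
        if h:
            fwd[qname] = h.target
    pairs = []
    for qname, tname in fwd.items():
        back = best_hit(tname, pb[tname], pa, ia)
        if back and back.target == qname:
            pairs.append((qname, tname))
    # drop targets claimed by more than one query
    from collections import Counter
    tc = Counter(t for _, t in pairs)
    return [(q, t) for q, t in pairs if tc[t] == 1]


def chain_blocks(anchors: list[tuple[int, int, int]], delta: int
                 ) -> list[Block]:
    """Greedy maximal-run chaining of anchors sorted by genome-a order.

    Each anchor is (ia, ib, orient) where orient is +1 when the two genes
    are on equivalent strands and -1 otherwise. Consecutive anchors join a
    block when the index gap on both genomes is <= delta + 1 in the block's
    direction and the orientation agrees.
    """
    anchors = sorted(anchors)
    blocks: list[Block] = []
    cur: list[tuple[int, int, int]] = []
    direction = 0
    for anc in anchors:
        if not cur:
            cur = [anc]
            direction = 0
            continue
        ia0, ib0, o0 = cur[-1]
        ia1, ib1, o1 = anc
        step_b = ib1 - ib0
        ok = (ia1 - ia0 <= delta + 1) and (o1 == o0) and step_b != 0 and \
            abs(step_b) <= delta + 1 and \
            (direction == 0 or (step_b > 0) == (direction > 0)) and \
            ((step_b > 0) if o1 > 0 else (step_b < 0))
        if ok:
            if direction == 0:
                direction = 1 if step_b > 0 else -1
            cur.append(anc)
        else:
            blocks.append(Block([(x, y) for x, y, _ in cur],
                                direction or cur[0][2]))
            cur = [anc]
            direction = 0
    if cur:
        blocks.append(Block([(x, y) for x, y, _ in cur],
                            direction or cur[0][2]))
    return [b for b in blocks if b.size >= 2]


def synteny_coverage(a: AnnotatedGenome, b: AnnotatedGenome,
                     deltas: tuple[int, ...] = DELTAS,
                     mode: str = "mean") -> SyntenyResult:
    """Coverage fractions for each delta; ``mode`` is "mean" (average of
    both genomes) or "directed" (denominator = genome a only)."""
    ga = [g for g in sorted(a.genes, key=lambda g: (g.contig, g.start))
          if g.kind == "CDS"]
    gb = [g for g in sorted(b.genes, key=lambda g: (g.contig, g.start))
          if g.kind == "CDS"]
    pos_a = {g.locus: i for i, g in enumerate(ga)}
    pos_b = {g.locus: i for i, g in enumerate(gb)}
    strand_a = {g.locus: g.strand for g in ga}
    strand_b = {g.locus: g.strand for g in gb}

    anchors = []
    for qa, qb in rbh_anchors(a, b):
        orient = 1 if strand_a[qa] == strand_b[qb] else -1
        anchors.append((pos_a[qa], pos_b[qb], orient))

    coverage, blocks = {}, {}
    for delta in deltas:
        bl = chain_blocks(anchors, delta)
        n_anch = sum(b_.size for b_ in bl)
        if mode == "directed":
            coverage[delta] = n_anch / len(ga) if ga else 0.0
        else:
            cov_a = n_anch / len(ga) if ga else 0.0
            cov_b = n_anch / len(gb) if gb else 0.0
            coverage[delta] = (cov_a + cov_b) / 2
        blocks[delta] = bl
    return SyntenyResult(pair=(a.name, b.name), coverage=coverage,
                         blocks=blocks)


def pairwise_mean_coverage(genomes: list[AnnotatedGenome]
                           ) -> dict[tuple[str, str], float]:
    return {(a.name, b.name): synteny_coverage(a, b).mean_coverage
            for a, b in itertools.combinations(genomes, 2)}
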