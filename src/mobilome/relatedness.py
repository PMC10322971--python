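"""Pairwise genome relatedness (ANIb- and dDDH-style) and group delimitation.

ANIb follows the fragment-based recipe: the query is chopped into 1020-bp
windows, each placed locally in the subject, and hits with >= 30% identity
over >= 70% fragment coverage are averaged; both directions are computed and
the mean reported. The dDDH-style index transforms the alignment distance
d = 1 - (summed identities / summed HSP length) through a logistic curve
whose coefficients live in :class:`DdhModel` (calibrated to the canonical
anchors: ~100% for identical genomes, 70% at the species-boundary distance).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .align import infix_hsp
from .model import AnnotatedGenome

FRAGMENT = 1020
MIN_IDENTITY = 0.30
MIN_COVERAGE = 0.70
SEED_WORD = 16  # exact word a fragment must share with the subject


class UndefinedRelatedness(ValueError):
    """No fragment survived filtering; ANI/dDDH are undefined, not zero."""


@dataclass
class DdhModel:
    """Logistic map from alignment distance to a hybridization percentage.

    ``ddh = 100 / (1 + exp(-(intercept + slope * d)))``. Defaults anchor
    identical genomes near 100% and place 70% at d = 0.0385.
    """

    intercept: float = 6.9068
    slope: float = -157.39

    def ddh(self, d: float) -> float:
        return 100.0 / (1.0 + math.exp(-(self.intercept + self.slope * d)))


@dataclass
class DelimitationThresholds:
    ani_species: float = 96.0
    ddh_species: float = 70.0
    sublineage_gap: float = 0.5  # ANI points


@dataclass
class RelatednessResult:
    pair: tuple[str, str]
    anib: Optional[float] = None       # percent
    dddh: Optional[float] = None       # percent
    d_statistic: Optional[float] = None
    n_fragments_used: int = 0


def _fragments(seq: str, size: int) -> list[str]:
    frags = [seq[i:i + size] for i in range(0, len(seq), size)]
    return [f for f in frags if len(f) >= 100]


def _kmer_positions(seqs: list[str], k: int) -> dict[str, tuple[int, int]]:
    """First occurrence (contig index, position) of every subject word."""
    out: dict[str, tuple[int, int]] = {}
    for ci, s in enumerate(seqs):
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if w not in out:
                out[w] = (ci, i)
    return out


def _directional(a: AnnotatedGenome, b: AnnotatedGenome, fragment: int
                 ) -> tuple[float, float, int, int]:
    """(mean identity of kept hits, sum identities, sum hsp len, n kept)."""
    from .model import revcomp
    subject = list(b.contigs.values())
    # BLAST-style seeding: a fragment with no exact shared word has no hit
    # (keeping non-homologous sequence out of the identity average), and a
    # matching word localizes the alignment to a window around the seed
    index = _kmer_positions(subject, SEED_WORD)
    idents, sum_id, sum_len, kept = [], 0, 0, 0
    for frag in _fragments("".join(a.contigs.values()), fragment):
        seed = None
        for s in (frag, revcomp(frag)):
            for i in range(0, len(s) - SEED_WORD + 1, 4):
                hit = index.get(s[i:i + SEED_WORD])
                if hit is not None:
                    seed = (hit, i)
                    break
            if seed:
                break
        if seed is None:
            continue
        (ci, pos), qoff = seed
        contig = subject[ci]
        lo = max(0, pos - qoff - 200)
        hi = min(len(contig), pos + (len(frag) - qoff) + 200)
        best = infix_hsp(frag, contig[lo:hi])
        if best is None or best.identity < MIN_IDENTITY or \
                best.q_cov < MIN_COVERAGE:
            # rare fallback: scan every subject contig in full
            best = None
            for c in subject:
                h = infix_hsp(frag, c)
                if h and (best is None or h.identity > best.identity):
                    best = h
        if best is None:
            continue
        if best.identity >= MIN_IDENTITY and best.q_cov >= MIN_COVERAGE:
            idents.append(best.identity)
            sum_id += best.identities
            sum_len += best.aln_len
            kept += 1
    if not kept:
        raise UndefinedRelatedness(f"no fragment of {a.name} aligned to {b.name}")
    return float(np.mean(idents)), sum_id, sum_len, kept


def anib_pair(a: AnnotatedGenome, b: AnnotatedGenome,
              fragment: int = FRAGMENT) -> RelatednessResult:
    if not a.contigs or not b.contigs:
        raise ValueError("empty assembly")
    ab = _directional(a, b, fragment)
    ba = _directional(b, a, fragment)
    return RelatednessResult(pair=(a.name, b.name),
                             anib=100.0 * (ab[0] + ba[0]) / 2,
                             n_fragments_used=ab[3] + ba[3])


def ddh_pair(a: AnnotatedGenome, b: AnnotatedGenome,
             fragment: int = FRAGMENT,
             model: Optional[DdhModel] = None) -> RelatednessResult:
    model = model or DdhModel()
    ab = _directional(a, b, fragment)
    ba = _directional(b, a, fragment)
    sum_id, sum_len = ab[1] + ba[1], ab[2] + ba[2]
    if sum_len == 0:
        raise UndefinedRelatedness("zero total HSP length")
    d = 1.0 - sum_id / sum_len
    return RelatednessResult(pair=(a.name, b.name), dddh=model.ddh(d),
                             d_statistic=d,
                             n_fragments_used=ab[3] + ba[3])


def relate_all(genomes: list[AnnotatedGenome],
               fragment: int = FRAGMENT,
               model: Optional[DdhModel] = None) -> list[RelatednessResult]:
    model = model or DdhModel()
    out = []
    for a, b in itertools.combinations(genomes, 2):
        ab = _directional(a, b, fragment)
        ba = _directional(b, a, fragment)
        sum_id, sum_len = ab[1] + ba[1], ab[2] + ba[2]
        d = 1.0 - sum_id / sum_len
        out.append(RelatednessResult(
            pair=(a.name, b.name), anib=100.0 * (ab[0] + ba[0]) / 2,
            dddh=model.ddh(d), d_statistic=d,
            n_fragments_used=ab[3] + ba[3]))
    return out


@dataclass
class Delimitation:
    species: list[set[str]]
    sublineages: list[set[str]]           # within the largest species
    ambiguous: set[str] = field(default_factory=set)


def _ani_matrix(results: list[RelatednessResult]) -> tuple[list[str], np.ndarray]:
    strains = sorted({s for r in results for s in r.pair})
    idx = {s: i for i, s in enumerate(strains)}
    m = np.full((len(strains), len(strains)), np.nan)
    np.fill_diagonal(m, 100.0)
    for r in results:
        i, j = idx[r.pair[0]], idx[r.pair[1]]
        m[i, j] = m[j, i] = r.anib
    if np.isnan(m).any():
        raise ValueError("incomplete pairwise matrix")
    return strains, m


def delimit_groups(results: list[RelatednessResult],
                   thresholds: Optional[DelimitationThresholds] = None
                   ) -> Delimitation:
    """Species = components linked above the ANI threshold; sublineages =
    the single-linkage cut whose within/between ANI separation exceeds the
    configured gap. Strains whose comparisons straddle the gap are flagged."""
    thresholds = thresholds or DelimitationThresholds()
    strains, m = _ani_matrix(results)
    n = len(strains)
    if n == 1:
        return Delimitation(species=[{strains[0]}], sublineages=[{strains[0]}])

    # species: connected components over the ANI threshold
    adj = m >= thresholds.ani_species
    unvisited = set(range(n))
    species: list[set[int]] = []
    while unvisited:
        stack = [unvisited.pop()]
        comp = set(stack)
        while stack:
            u = stack.pop()
            for v in list(unvisited):
                if adj[u, v]:
                    unvisited.discard(v)
                    comp.add(v)
                    stack.append(v)
        species.append(comp)
    species.sort(key=len, reverse=True)

    main = sorted(species[0])
    sub = _sublineages(m[np.ix_(main, main)], thresholds.sublineage_gap)
    sublineages = [{strains[main[i]] for i in grp} for grp in sub]

    ambiguous: set[str] = set()
    if len(sublineages) > 1:
        label = {}
        for gi, grp in enumerate(sub):
            for i in grp:
                label[i] = gi
        for i in range(len(main)):
            within = [m[main[i], main[j]] for j in range(len(main))
                      if i != j and label[j] == label[i]]
            between = [m[main[i], main[j]] for j in range(len(main))
                       if label[j] != label[i]]
            if within and between and \
                    max(between) > min(within) - thresholds.sublineage_gap:
                ambiguous.add(strains[main[i]])
    return Delimitation(species=[{strains[i] for i in c} for c in species],
                        sublineages=sublineages, ambiguous=ambiguous)


def _sublineages(m: np.ndarray, gap: float) -> list[list[int]]:
    n = len(m)
    if n < 2:
        return [list(range(n))]
    dist = 100.0 - m
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="single")
    heights = sorted(z[:, 2])
    # cut at the largest merge-height jump if it exceeds the gap
    jumps = [(heights[i + 1] - heights[i], heights[i])
             for i in range(len(heights) - 1)]
    if not jumps:
        return [list(range(n))]
    best_jump, below = max(jumps, key=lambda t: t[0])
    if best_jump < gap:
        return [list(range(n))]
    labels = hierarchy.fcluster(z, t=below + best_jump / 2,
                                criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return sorted(groups.values(), key=lambda g: (-len(g), g))


def matrix_frame(results: list[RelatednessResult], metric: str = "anib"):
    import pandas as pd
    strains = sorted({s for r in results for s in r.pair})
    df = pd.DataFrame(100.0 if metric in ("anib", "dddh") else 0.0,
                      index=strains, columns=strains)
    for r in results:
        v = getattr(r, metric)
        df.loc[r.pair[0], r.pair[1]] = v
        df.loc[r.pair[1], r.pair[0]] = v
    return df
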