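"""Alignment backends.

Nucleotide work uses edlib (banded Myers bit-vector edit distance): ``infix``
for fragment-vs-genome local placement and ``global_identity`` for
like-for-like comparison. Protein search is a k-mer-seeded candidate filter
followed by edlib global alignment rescored with BLOSUM62; e-values come from
the Karlin-Altschul formula with standard gapped BLOSUM62 parameters. The
backend sits behind small functions so an external aligner could be swapped
in without touching callers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import edlib
from Bio.Align import substitution_matrices

from .model import revcomp

# Gapped BLOSUM62 Karlin-Altschul parameters (gap open 11, extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1


@lru_cache(maxsize=1)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


@dataclass
class Hsp:
    """A local alignment summary: identity is matches / alignment columns."""

    identities: int
    aln_len: int
    q_cov: float
    t_start: int
    t_end: int
    strand: str = "+"
    score: float = 0.0

    @property
    def identity(self) -> float:
        return self.identities / self.aln_len if self.aln_len else 0.0


def _nice_counts(nice: str) -> tuple[int, int]:
    """(#matches, #columns) from an edlib 'nice' cigar-free alignment."""
    matches = nice.count("=")
    return matches, len(nice)


def _cigar_counts(cigar: str) -> tuple[int, int]:
    """(#matches, #alignment columns) from an extended edlib cigar."""
    matches = cols = 0
    n = ""
    for c in cigar:
        if c.isdigit():
            n += c
        else:
            k = int(n)
            n = ""
            cols += k
            if c == "=":
                matches += k
    return matches, cols


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops, n = [], ""
    for c in cigar:
        if c.isdigit():
            n += c
        else:
            ops.append((int(n), c))
            n = ""
    return ops


# per-column scores used to trim the edit-distance alignment down to its
# best local window (BLASTN-like: match rewarded, mismatch/gap penalized)
_OP_SCORE = {"=": 2.0, "X": -3.0, "I": -4.0, "D": -4.0}


def _best_local_window(ops: list[tuple[int, str]]) -> list[tuple[int, str]]:
    """Maximum-scoring contiguous run window (Kadane over cigar runs)."""
    best_score, best = 0.0, (0, 0)
    cur_score, cur_start = 0.0, 0
    for i, (n, op) in enumerate(ops):
        s = cur_score + n * _OP_SCORE[op]
        if s <= 0:
            cur_score, cur_start = 0.0, i + 1
        else:
            cur_score = s
            if cur_score > best_score:
                best_score, best = cur_score, (cur_start, i + 1)
    return ops[best[0]:best[1]]


def infix_hsp(query: str, target: str, both_strands: bool = True) -> Optional[Hsp]:
    """Best local placement of the query inside the target.

    The semi-global edit-distance alignment is trimmed to its
    maximum-scoring local window, so a query whose flank has no homolog in
    the target loses coverage (``q_cov``) rather than diluting identity —
    the behavior a local aligner's HSP would show.
    """
    best: Optional[Hsp] = None
    for strand, q in (("+", query), ("-", revcomp(query))) if both_strands \
            else (("+", query),):
        res = edlib.align(q, target, mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        kept = _best_local_window(_cigar_ops(res["cigar"]))
        matches = sum(n for n, op in kept if op == "=")
        cols = sum(n for n, op in kept)
        q_used = sum(n for n, op in kept if op in "=XI")
        if not cols:
            continue
        s, e = res["locations"][0]
        hsp = Hsp(identities=matches, aln_len=cols,
                  q_cov=q_used / len(query) if query else 0.0,
                  t_start=s, t_end=e + 1, strand=strand)
        if best is None or hsp.identities > best.identities:
            best = hsp
    return best


def global_identity(a: str, b: str) -> float:
    """Fraction of matching columns in a global (NW) alignment."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches, cols = _cigar_counts(res["cigar"])
    return matches / cols if cols else 0.0


def _aligned_pairs(a: str, b: str) -> list[tuple[str, str]]:
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return list(zip(nice["query_aligned"], nice["target_aligned"]))


def blosum_score(a: str, b: str) -> float:
    """Gapped BLOSUM62 score of the edlib global alignment of two proteins."""
    mat = _blosum62()
    score = 0.0
    in_gap = False
    for x, y in _aligned_pairs(a, b):
        if x == "-" or y == "-":
            score -= GAP_EXTEND if in_gap else GAP_OPEN
            in_gap = True
        else:
            in_gap = False
            try:
                score += mat[x, y]
            except (KeyError, IndexError):
                pass
    return score


def evalue(score: float, query_len: int, db_len: int) -> float:
    """Karlin-Altschul expect value for a raw gapped score."""
    if score <= 0:
        return float("inf")
    bits = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)
    return query_len * db_len * 2.0 ** (-bits)


# ---- k-mer prefiltered protein search ---------------------------------


def kmer_index(proteins: dict[str, str], k: int = 4) -> dict[str, set[str]]:
    idx: dict[str, set[str]] = {}
    for name, seq in proteins.items():
        for i in range(len(seq) - k + 1):
            idx.setdefault(seq[i:i + k], set()).add(name)
    return idx


def candidate_targets(query: str, idx: dict[str, set[str]], k: int = 4,
                      min_shared: int = 2) -> set[str]:
    counts: dict[str, int] = {}
    for i in range(len(query) - k + 1):
        for name in idx.get(query[i:i + k], ()):
            counts[name] = counts.get(name, 0) + 1
    return {n for n, c in counts.items() if c >= min_shared}


@dataclass
class ProteinHit:
    query: str
    target: str
    identity: float    # fraction
    coverage: float    # aligned fraction of the query
    score: float
    evalue: float


def search_proteome(query_id: str, query: str, proteome: dict[str, str],
                    idx: Optional[dict[str, set[str]]] = None,
                    evalue_max: float = 1e-3) -> list[ProteinHit]:
    """All significant hits of one query protein against a proteome."""
    if not query:
        return []
    if idx is None:
        idx = kmer_index(proteome)
    db_len = sum(len(p) for p in proteome.values())
    hits = []
    for tname in candidate_targets(query, idx):
        tseq = proteome[tname]
        score = blosum_score(query, tseq)
        ev = evalue(score, len(query), db_len)
        if ev <= evalue_max:
            ident = global_identity(query, tseq)
            cov = min(len(query), len(tseq)) / len(query)
            hits.append(ProteinHit(query=query_id, target=tname,
                                   identity=ident, coverage=min(cov, 1.0),
                                   score=score, evalue=ev))
    hits.sort(key=lambda h: (h.evalue, -h.score, h.target))
    return hits


def best_hit(query_id: str, query: str, proteome: dict[str, str],
             idx=None, evalue_max: float = 1e-3) -> Optional[ProteinHit]:
    hits = search_proteome(query_id, query, proteome, idx, evalue_max)
    return hits[0] if hits else None
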