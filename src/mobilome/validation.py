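"""End-to-end validation trials on forged complexes.

Each trial forges a ground-truthed synthetic dataset under the standard
study conditions, runs the relevant pipeline stages, and scores the result
against the truth records. These routines back both the test suite and the
reproduction script; every number they return is computed at call time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import boundaries, census, isdyn, pangenome, relatedness
from .forge import (ComplexConfig, ForgedComplex, forge_complex,
                    simulate_reseq, standard_complex)
from .model import AnnotatedGenome, ISEvent, Segment, revcomp


@dataclass
class BoundaryTrial:
    precision: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)
    dr_exact: list[bool] = field(default_factory=list)
    sublineages_ok: Optional[bool] = None


def _score_strain(cx: ForgedComplex, table, seeds, target: AnnotatedGenome,
                  trial: BoundaryTrial, check_dr: bool,
                  min_dr: int = 12) -> None:
    track = boundaries.contextual_profile(target, table)
    hits = {s.element_id: census.seed_search(s, target) for s in seeds}
    cands = boundaries.reconstruct_elements(
        hits, target, track,
        seed_sizes={s.element_id: len(s.proteins) for s in seeds})
    for rec in cx.truth_for(target.name):
        if rec.kind == "plasmid":
            continue
        truth = set(rec.genes)
        best = None
        for c in cands:
            if truth & set(c.genes):
                if best is None or len(truth & set(c.genes)) > \
                        len(truth & set(best.genes)):
                    best = c
        if best is None:
            trial.precision.append(0.0)
            trial.recall.append(0.0)
            continue
        got = set(best.genes)
        trial.precision.append(len(got & truth) / len(got))
        trial.recall.append(len(got & truth) / len(truth))
        if check_dr and len(rec.dr_seq) >= min_dr and \
                len({s.contig for s in best.segments}) == 1:
            att = boundaries.find_att_sites(best, target, min_dr=min_dr)
            trial.dr_exact.append(att is not None and
                                  att.dr_seq == rec.dr_seq)


def boundary_recovery_trial(seed: int, n_per_group: int = 4,
                            with_relatedness: bool = False) -> BoundaryTrial:
    """Forge one standard complex; reconstruct its planted elements in the
    drafted strain and one intact carrier using another carrier's elements
    as seeds; score gene-level precision/recall and exact DR recovery."""
    cx = standard_complex(seed, n_per_group=n_per_group)
    table = pangenome.cluster_from_genomes(cx.genomes)
    pangenome.compartmentalize(table, cx.groups)

    carriers = [g.name for g in cx.genomes if cx.groups[g.name] == "A"]
    drafted = next(g.name for g in cx.genomes if len(g.contigs) > 2)
    donor = next(s for s in carriers if s != drafted)
    targets = [drafted] + [s for s in carriers
                           if s not in (drafted, donor)][:1]

    seeds = []
    for rec in cx.truth_for(donor):
        if rec.kind == "plasmid":
            continue
        seeds.append(census.seed_from_truth(rec.element_id,
                                            cx.genome(donor), rec.genes))
    trial = BoundaryTrial()
    for name in targets:
        _score_strain(cx, table, seeds, cx.genome(name), trial,
                      check_dr=(name != drafted))
    if with_relatedness:
        res = relatedness.relate_all(cx.genomes)
        delim = relatedness.delimit_groups(res)
        want = {frozenset(s for s in cx.groups if cx.groups[s] == x)
                for x in "AB"}
        trial.sublineages_ok = \
            {frozenset(g) for g in delim.sublineages} == want
    return trial


def hamming_anib_trial(seed: int, n: int = 30_000, rate: float = 0.02
                       ) -> tuple[float, float]:
    """(measured ANIb, Hamming-oracle identity) for a pair differing by
    exactly round(rate*n) substitutions placed uniformly."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=n)
    other = seq.copy()
    pos = rng.choice(n, size=int(round(rate * n)), replace=False)
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for p in pos:
        other[p] = alt[other[p]]
    a = AnnotatedGenome("a", {"c": "".join(seq)})
    b = AnnotatedGenome("b", {"c": "".join(other)})
    return relatedness.anib_pair(a, b).anib, 100.0 * (1 - len(pos) / n)


def transposition_trial(seed: int, depth: float = 30.0,
                        fraction: float = 1.0) -> dict:
    """Simulate one replicative transposition and call it back."""
    rng = np.random.default_rng(seed)
    chrom = "".join(rng.choice(list("ACGT"), 15_000))
    is_seq = "".join(rng.choice(list("ACGT"), 1_200))
    from .model import Gene
    genes = [Gene(f"g{i:02d}", "chr", i * 1000 + 100, i * 1000 + 950)
             for i in range(14)]
    g = AnnotatedGenome("h", {"chr": chrom}, genes=genes)
    pos = int(rng.integers(2_000, 13_000))
    target = next((x.locus for x in genes if x.start <= pos < x.end), None)
    ev = ISEvent("ISx", "chr", pos, dr_len=8, allele_fraction=fraction)
    bundle = simulate_reseq(g, [ev], depth=depth, seed=seed + 1,
                            is_library={"ISx": is_seq})
    called = isdyn.detect_insertions(g, bundle.reads, {"ISx": is_seq})
    ok = (len(called) == 1 and abs(called[0].position - pos) <= 1
          and called[0].target_gene == target)
    return {"recovered": ok,
            "position_error": abs(called[0].position - pos) if called else None,
            "fraction": called[0].allele_fraction if called else None}


def allele_fraction_trials(seed: int, n_sims: int = 100,
                           fraction: float = 0.5, depth: float = 40.0
                           ) -> dict:
    """Mean estimated fraction over repeated simulations, with the binomial
    standard error implied by the mean informative read count."""
    rng = np.random.default_rng(seed)
    chrom = "".join(rng.choice(list("ACGT"), 12_000))
    is_seq = "".join(rng.choice(list("ACGT"), 1_200))
    g = AnnotatedGenome("h", {"chr": chrom})
    ev = ISEvent("ISx", "chr", 6_000, dr_len=8, allele_fraction=fraction)
    fractions, totals = [], []
    for i in range(n_sims):
        bundle = simulate_reseq(g, [ev], depth=depth, seed=seed * 7919 + i,
                                is_library={"ISx": is_seq})
        series = isdyn.track_alleles(ev, {1: bundle.reads}, {"ISx": is_seq})
        p = series.points[0]
        fractions.append(p.fraction)
        totals.append(p.mutant_reads + p.wild_reads)
    mean_total = float(np.mean(totals))
    se_mean = float(np.sqrt(fraction * (1 - fraction) / mean_total / n_sims))
    return {"mean": float(np.mean(fractions)), "truth": fraction,
            "se_mean": se_mean, "n_sims": n_sims}


def depth_fold_trial(seed: int, fold: float, depth: float = 30.0) -> float:
    rng = np.random.default_rng(seed)
    g = AnnotatedGenome("x", {"chr": "".join(rng.choice(list("ACGT"), 20_000)),
                              "pls": "".join(rng.choice(list("ACGT"), 4_000))},
                        circular={"pls"})
    bundle = simulate_reseq(g, [], depth=depth, plasmid_fold=fold, seed=seed)
    folds = isdyn.replicon_depth_fold(bundle.depth,
                                      {"pls": [Segment("pls", 0, 4_000)]},
                                      chromosome="chr")
    return folds["pls"]


def pstc_locus_geometry(seed: int, product: int = 954, is_len: int = 1302,
                        dr_len: int = 8) -> dict:
    """Build a phosphate-permease-like locus, design a primer pair giving a
    wild-type product of ``product`` bp, plant an IS with a target-site
    duplication inside the amplicon, and measure both allele amplicons."""
    rng = np.random.default_rng(seed)
    locus = "".join(rng.choice(list("ACGT"), 4_000))
    f_start = 1_000
    fwd = locus[f_start:f_start + 20]
    rev = revcomp(locus[f_start + product - 20:f_start + product])
    wt = boundaries.insilico_pcr({"wt": locus}, fwd, rev)
    p = f_start + product // 2
    mutant = locus[:p + dr_len] + \
        "".join(rng.choice(list("ACGT"), is_len)) + locus[p:]
    mut = boundaries.insilico_pcr({"mut": mutant}, fwd, rev)
    return {"wildtype": wt[0].length if len(wt) == 1 else None,
            "mutant": mut[0].length if len(mut) == 1 else None}


def plasmid_circularization_geometry(seed: int, circle_len: int = 17_826,
                                     overlap: int = 120) -> dict:
    """A plasmid-sized replicon written with an assembly-duplicated
    terminus: recircularize it and digest with BamHI sites spaced as on the
    reference replicon."""
    from .classify import circularize_contig, digest
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), circle_len)).replace("GGATCC",
                                                                "GGATAC")
    site = "GGATCC"
    for p in (0, 3_077, 3_077 + 4_155):
        seq = seq[:p] + site + seq[p + 6:]
    res = circularize_contig(seq + seq[:overlap])
    frags = digest(res.sequence, res.topology, site)
    return {"topology": res.topology, "length": len(res.sequence),
            "fragments": frags}
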