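"""Ground-truthed synthetic species complexes with planted mobile elements.

The forge emulates a two-sublineage bacterial species complex: clonal strains
diverge from a shared ancestor by substitutions only (which keeps identity
oracles exact), planted elements (ICE / genomic island / transposon / plasmid
/ IS) carry GC-shifted cargo and target-site direct repeats, drafts are cut
at intergenic positions, and a resequencing simulator emits junction reads
and Poisson depth tracks for IS-transposition calling.

Every operation takes one integer seed; internal streams are split with
``numpy.random.SeedSequence.spawn`` so the outputs are byte-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (AnnotatedGenome, Gene, ISEvent, ReadRecord, Segment,
                    TruthRecord, gc_fraction, revcomp)

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOPS = {"TAA", "TAG", "TGA"}

# tRNA features seeded into every ancestral chromosome; the anticodon-style
# names double as integration-site labels for planted islands.
TRNA_NAMES = ("tRNA-Arg-TCT", "tRNA-Ala-GGC", "tRNA-Thr-TGT", "tRNA-Gly-CCC")


class ConfigurationError(ValueError):
    pass


@dataclass
class ComplexConfig:
    n_strains_per_group: int = 4
    ancestral_length: int = 50_000
    gene_length_mean: int = 900
    within_group_divergence: float = 0.005
    between_group_divergence: float = 0.03
    gc_background: float = 0.585
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.within_group_divergence, self.between_group_divergence):
            if not 0 <= d <= 0.2:
                raise ConfigurationError(f"divergence {d} outside [0, 0.2]")
        if self.between_group_divergence < self.within_group_divergence:
            raise ConfigurationError(
                "between_group_divergence must be >= within_group_divergence")
        if not 0.3 < self.gc_background < 0.7:
            raise ConfigurationError("gc_background must be in (0.3, 0.7)")
        if self.n_strains_per_group < 1:
            raise ConfigurationError("need >= 1 strain per group")


@dataclass
class ElementSpec:
    element_id: str
    element_kind: str  # ICE | GI | Tn | plasmid | IS
    length: int
    n_genes: int
    cargo_gc_offset: float = 0.0
    integration_site: str = ""
    dr_length: int = 0
    module_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.element_kind not in {"ICE", "GI", "Tn", "plasmid", "IS"}:
            raise ConfigurationError(f"unknown kind {self.element_kind}")
        if self.dr_length < 0:
            raise ConfigurationError("dr_length must be >= 0")
        if self.n_genes < 1:
            raise ConfigurationError("need >= 1 cargo gene")
        if self.length < self.n_genes * 120:
            raise ConfigurationError("length inconsistent with gene count")
        labels = [m.lower() for m in self.module_genes]
        if self.element_kind == "ICE":
            if not any("integrase" in m for m in labels) or \
                    not any(m.startswith("virb") for m in labels):
                raise ConfigurationError("ICE spec needs integrase and virB")
        if self.element_kind == "plasmid" and \
                not any(m.startswith("rep") for m in labels):
            raise ConfigurationError("plasmid spec needs rep")


@dataclass
class ForgedComplex:
    config: ComplexConfig
    genomes: list[AnnotatedGenome]
    groups: dict[str, str]                       # strain -> "A" | "B"
    mutations: dict[str, np.ndarray]             # strain -> mutated root positions
    truth: list[TruthRecord] = field(default_factory=list)

    def genome(self, strain: str) -> AnnotatedGenome:
        for g in self.genomes:
            if g.name == strain:
                return g
        raise KeyError(strain)

    def truth_for(self, strain: str) -> list[TruthRecord]:
        return [t for t in self.truth if t.strain == strain]


# ---- sequence primitives ----------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)]


def _random_orf(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """In-frame open reading frame without internal stop codons."""
    out = ["ATG"]
    while len(out) < n_codons:
        cod = _random_seq(rng, 3, gc).tobytes().decode()
        if cod not in STOPS:
            out.append(cod)
    return "".join(out)


def _mutate(seq: np.ndarray, rng: np.random.Generator,
            rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Substitute round(rate * len) distinct sites; always to a new base."""
    n = int(round(rate * len(seq)))
    if n == 0:
        return seq.copy(), np.empty(0, dtype=np.int64)
    pos = rng.choice(len(seq), size=n, replace=False)
    out = seq.copy()
    shift = rng.integers(1, 4, size=n)
    idx = np.searchsorted(BASES, out[pos])
    out[pos] = BASES[(idx + shift) % 4]
    return out, np.sort(pos)


# ---- forge_complex -----------------------------------------------------


def _build_ancestor(rng: np.random.Generator, cfg: ComplexConfig
                    ) -> tuple[np.ndarray, list[dict]]:
    """Ancestral chromosome plus a positional gene plan shared by strains."""
    chunks: list[str] = []
    plan: list[dict] = []
    pos = 0
    fam = 0
    trna_iter = iter(TRNA_NAMES)
    trna_every = max(1, cfg.ancestral_length //
                     (cfg.gene_length_mean + 125) // (len(TRNA_NAMES) + 1))
    while pos < cfg.ancestral_length:
        spacer = int(rng.integers(50, 201))
        chunks.append(_random_seq(rng, spacer, cfg.gc_background)
                      .tobytes().decode())
        pos += spacer
        fam += 1
        if fam % trna_every == 0 and (name := next(trna_iter, None)):
            seq = _random_seq(rng, 76, cfg.gc_background).tobytes().decode()
            plan.append({"start": pos, "end": pos + 76, "strand": "+",
                         "family": f"T{fam:04d}", "kind": "tRNA",
                         "product": name})
            chunks.append(seq)
            pos += 76
            continue
        jitter = 1.0 + rng.uniform(-0.2, 0.2)
        n_codons = max(40, int(cfg.gene_length_mean * jitter / 3))
        orf = _random_orf(rng, n_codons, cfg.gc_background)
        strand = "+" if rng.random() < 0.5 else "-"
        plan.append({"start": pos, "end": pos + len(orf), "strand": strand,
                     "family": f"F{fam:04d}", "kind": "CDS",
                     "product": "hypothetical protein"})
        chunks.append(orf if strand == "+" else revcomp(orf))
        pos += len(orf)
    seq = np.frombuffer("".join(chunks).encode(), dtype="S1").copy()
    return seq, plan


def forge_complex(config: ComplexConfig) -> ForgedComplex:
    """Two sublineages of clonal strains descending from one ancestor.

    Group ancestors each diverge from the root by
    ``(between - within) / 2`` substitutions/site and strains from their
    group ancestor by ``within / 2``, so that expected pairwise differences
    are ``within`` inside a group and ``between`` across groups.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    s_anc, s_groups, s_strains = ss.spawn(3)
    root, plan = _build_ancestor(np.random.default_rng(s_anc), config)

    half_between = (config.between_group_divergence -
                    config.within_group_divergence) / 2
    half_within = config.within_group_divergence / 2

    genomes: list[AnnotatedGenome] = []
    groups: dict[str, str] = {}
    mutations: dict[str, np.ndarray] = {}
    grp_rngs = [np.random.default_rng(s) for s in s_groups.spawn(2)]
    strain_seeds = s_strains.spawn(2 * config.n_strains_per_group)
    k = 0
    for gi, gname in enumerate("AB"):
        ganc, gmut = _mutate(root, grp_rngs[gi], half_between)
        for si in range(config.n_strains_per_group):
            strain = f"S{gname}{si + 1:02d}"
            rng = np.random.default_rng(strain_seeds[k]); k += 1
            seq, smut = _mutate(ganc, rng, half_within)
            contig = f"{strain}_chr"
            genes = [Gene(locus=f"{strain}_{i + 1:04d}", contig=contig,
                          start=p["start"], end=p["end"], strand=p["strand"],
                          family=p["family"], product=p["product"],
                          kind=p["kind"])
                     for i, p in enumerate(plan)]
            genomes.append(AnnotatedGenome(
                name=strain, contigs={contig: seq.tobytes().decode()},
                genes=genes))
            groups[strain] = gname
            mutations[strain] = np.union1d(gmut, smut)
    return ForgedComplex(config=config, genomes=genomes, groups=groups,
                         mutations=mutations)


# ---- plant_element -----------------------------------------------------

_MODULE_PAD = ("hypothetical protein", "hypothetical protein",
               "DUF domain protein", "hypothetical protein")


def _cargo(rng: np.random.Generator, spec: ElementSpec, gc: float,
           strain: str) -> tuple[str, list[dict]]:
    """Cargo sequence + relative gene plan at the spec's GC offset."""
    gc_c = min(0.95, max(0.05, gc + spec.cargo_gc_offset))
    spacer_total = 60 * (spec.n_genes + 1)
    gene_len = max(120, (spec.length - spacer_total) // spec.n_genes)
    n_codons = max(40, gene_len // 3)
    labels = list(spec.module_genes)
    while len(labels) < spec.n_genes:
        labels.append(_MODULE_PAD[len(labels) % len(_MODULE_PAD)])
    chunks: list[str] = []
    plan: list[dict] = []
    pos = 0
    for i in range(spec.n_genes):
        spacer = int(rng.integers(40, 81))
        chunks.append(_random_seq(rng, spacer, gc_c).tobytes().decode())
        pos += spacer
        orf = _random_orf(rng, n_codons, gc_c)
        strand = "+" if rng.random() < 0.7 else "-"
        plan.append({"start": pos, "end": pos + len(orf), "strand": strand,
                     "product": labels[i],
                     "family": f"MGE_{spec.element_id}_{i + 1:02d}"})
        chunks.append(orf if strand == "+" else revcomp(orf))
        pos += len(orf)
    chunks.append(_random_seq(rng, int(rng.integers(40, 81)), gc_c)
                  .tobytes().decode())
    return "".join(chunks), plan


def _find_site(genome: AnnotatedGenome, label: str) -> Gene:
    """Locate an integration site by locus tag, product (tRNA name), or
    ancestral family id (which is shared across forged strains)."""
    for g in genome.genes:
        if label in (g.locus, g.product, g.family):
            return g
    raise LookupError(f"integration site {label!r} not found in {genome.name}")


def plant_element(genome: AnnotatedGenome, spec: ElementSpec, seed: int,
                  base_gc: Optional[float] = None
                  ) -> tuple[AnnotatedGenome, TruthRecord]:
    """Insert an element downstream of its integration site.

    The ``dr_length`` bp immediately following the insertion point are
    duplicated so that identical direct repeats flank the cargo (attL/attR);
    excising the element and one repeat copy restores the original
    chromosome exactly. Plasmid specs instead add a separate circular
    replicon and leave the chromosome untouched.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gc = genome.gc() if base_gc is None else base_gc
    cargo, plan = _cargo(rng, spec, gc, genome.name)

    if spec.element_kind == "plasmid":
        contig = f"{genome.name}_p_{spec.element_id}"
        genes = list(genome.genes)
        loci = []
        for i, p in enumerate(plan):
            locus = f"{genome.name}_{spec.element_id}_{i + 1:02d}"
            loci.append(locus)
            genes.append(Gene(locus=locus, contig=contig, start=p["start"],
                              end=p["end"], strand=p["strand"],
                              family=p["family"], product=p["product"]))
        new = AnnotatedGenome(name=genome.name,
                              contigs={**genome.contigs, contig: cargo},
                              genes=genes, depth=genome.depth,
                              circular=genome.circular | {contig})
        rec = TruthRecord(strain=genome.name, element_id=spec.element_id,
                          kind="plasmid",
                          segments=[Segment(contig, 0, len(cargo))],
                          genes=loci)
        return new, rec

    site = _find_site(genome, spec.integration_site)
    chrom = genome.contigs[site.contig]
    p = site.end + 5  # intergenic: spacers are >= 40 bp
    d = spec.dr_length
    dr = chrom[p:p + d]
    # keep the planted repeat maximal: the cargo's outermost bases must not
    # coincidentally extend the duplicated target site
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}
    if d and cargo and p + d < len(chrom) and cargo[0] == chrom[p + d]:
        cargo = alt[cargo[0]] + cargo[1:]
    if d and cargo and p > 0 and cargo[-1] == chrom[p - 1]:
        cargo = cargo[:-1] + alt[cargo[-1]]
    new_chrom = chrom[:p + d] + cargo + chrom[p:]
    shift = len(cargo) + d

    genes = []
    for g in genome.genes:
        if g.contig != site.contig or g.end <= p:
            genes.append(g)
        else:
            genes.append(Gene(locus=g.locus, contig=g.contig,
                              start=g.start + shift, end=g.end + shift,
                              strand=g.strand, family=g.family,
                              product=g.product, kind=g.kind))
    loci = []
    for i, pl in enumerate(plan):
        locus = f"{genome.name}_{spec.element_id}_{i + 1:02d}"
        loci.append(locus)
        genes.append(Gene(locus=locus, contig=site.contig,
                          start=p + d + pl["start"], end=p + d + pl["end"],
                          strand=pl["strand"], family=pl["family"],
                          product=pl["product"]))

    new = AnnotatedGenome(name=genome.name,
                          contigs={**genome.contigs, site.contig: new_chrom},
                          genes=genes, depth=None,
                          circular=set(genome.circular))
    ctx = 400
    rec = TruthRecord(
        strain=genome.name, element_id=spec.element_id,
        kind=spec.element_kind,
        segments=[Segment(site.contig, p + d, p + d + len(cargo))],
        genes=loci, dr_seq=dr,
        attL=(site.contig, p, p + d) if d else None,
        attR=(site.contig, p + d + len(cargo),
              p + 2 * d + len(cargo)) if d else None,
        pre_insertion_site=chrom[max(0, p - ctx):p + d + ctx])
    return new, rec


def _shift_truth(truth: list[TruthRecord], strain: str, contig: str,
                 pos: int, delta: int) -> None:
    """Update stored truth coordinates after an insertion of ``delta`` bp at
    ``pos`` on one strain's contig."""
    def sh(x: int) -> int:
        return x + delta if x >= pos else x

    for t in truth:
        if t.strain != strain:
            continue
        t.segments = [Segment(s.contig, sh(s.start), sh(s.end), s.strand)
                      if s.contig == contig else s for s in t.segments]
        for attr in ("attL", "attR"):
            att = getattr(t, attr)
            if att is not None and att[0] == contig:
                setattr(t, attr, (contig, sh(att[1]), sh(att[2])))


def plant_in_group(cx: ForgedComplex, spec: ElementSpec, seed: int,
                   group: str = "A") -> None:
    """Plant one element, with identical cargo, into every strain of a
    sublineage (in place). The element becomes part of that group's shared
    flexible genome; truth records of previously planted elements are
    coordinate-shifted past the new insertion."""
    for i, g in enumerate(cx.genomes):
        if cx.groups[g.name] != group:
            continue
        planted, rec = plant_element(g, spec, seed,
                                     base_gc=cx.config.gc_background)
        if rec.kind != "plasmid":
            seg = rec.segments[0]
            ins_pos = seg.start - len(rec.dr_seq)
            delta = (seg.end - seg.start) + len(rec.dr_seq)
            _shift_truth(cx.truth, g.name, seg.contig, ins_pos, delta)
        cx.genomes[i] = planted
        cx.truth.append(rec)


# ---- make_draft --------------------------------------------------------


class InfeasibleError(ValueError):
    pass


def make_draft(genome: AnnotatedGenome, n_breaks: int, min_contig: int,
               seed: int, truth: Optional[list[TruthRecord]] = None,
               force_break_in: Optional[str] = None
               ) -> tuple[AnnotatedGenome, list[TruthRecord]]:
    """Fragment the chromosome at intergenic positions into draft contigs.

    Breaks never fall inside genes, so annotations survive remapping;
    ``force_break_in`` places one break between two cargo genes of the named
    planted element so that it splits across contigs. Truth records are
    rewritten into per-contig coordinates.
    """
    truth = truth or []
    if n_breaks < 0:
        raise ValueError("n_breaks must be >= 0")
    chrom_name = next(iter(genome.contigs))
    chrom = genome.contigs[chrom_name]
    if min_contig * (n_breaks + 1) > len(chrom):
        raise InfeasibleError("min_contig x contigs exceeds genome length")
    if n_breaks == 0 and force_break_in is None:
        return genome, truth

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gs = genome.genes_on(chrom_name)
    gaps = [((gs[i].end + gs[i + 1].start) // 2, gs[i].end, gs[i + 1].start)
            for i in range(len(gs) - 1)]

    forced: list[int] = []
    if force_break_in is not None:
        rec = next(t for t in truth if t.element_id == force_break_in
                   and t.strain == genome.name)
        inner = [m for m, a, b in gaps
                 if rec.segments[0].start < m < rec.segments[0].end]
        if not inner:
            raise InfeasibleError(f"no intergenic gap inside {force_break_in}")
        forced.append(inner[len(inner) // 2])

    spans = [(s.start, s.end) for t in truth if t.strain == genome.name
             for s in t.segments if s.contig == chrom_name]
    candidates = [m for m, _, _ in gaps if m not in forced
                  and not any(a <= m < b for a, b in spans)]
    rng.shuffle(candidates)
    breaks = sorted(forced)
    want = max(n_breaks, len(forced))
    for m in candidates:
        if len(breaks) >= want:
            break
        trial = sorted(breaks + [m])
        bounds = [0] + trial + [len(chrom)]
        if min(b - a for a, b in zip(bounds, bounds[1:])) >= min_contig:
            breaks = trial
    if len(breaks) < want:
        raise InfeasibleError("could not place requested breaks")

    bounds = [0] + breaks + [len(chrom)]
    pieces = list(zip(bounds, bounds[1:]))
    contigs: dict[str, str] = {}
    offsets: list[tuple[str, int, int]] = []
    for i, (a, b) in enumerate(pieces):
        cname = f"{genome.name}_c{i + 1:02d}"
        contigs[cname] = chrom[a:b]
        offsets.append((cname, a, b))
    for n, s in genome.contigs.items():  # keep plasmids and extra replicons
        if n != chrom_name:
            contigs[n] = s

    def remap(pos: int) -> tuple[str, int]:
        for cname, a, b in offsets:
            if a <= pos < b:
                return cname, pos - a
        cname, a, b = offsets[-1]
        return cname, pos - a

    genes = []
    for g in genome.genes:
        if g.contig != chrom_name:
            genes.append(g)
            continue
        cname, start = remap(g.start)
        genes.append(Gene(locus=g.locus, contig=cname, start=start,
                          end=start + g.length, strand=g.strand,
                          family=g.family, product=g.product, kind=g.kind))

    new_truth = []
    for t in truth:
        if t.strain != genome.name:
            new_truth.append(t)
            continue
        segs = []
        for s in t.segments:
            if s.contig != chrom_name:
                segs.append(s)
                continue
            cuts = [c for c in breaks if s.start < c < s.end]
            for a, b in zip([s.start] + cuts, cuts + [s.end]):
                cname, ra = remap(a)
                segs.append(Segment(cname, ra, ra + (b - a), s.strand))

        def _remap_att(att):
            if att is None or att[0] != chrom_name:
                return att
            cname, ra = remap(att[1])
            return (cname, ra, ra + (att[2] - att[1]))

        new_truth.append(TruthRecord(
            strain=t.strain, element_id=t.element_id, kind=t.kind,
            segments=segs, genes=t.genes, dr_seq=t.dr_seq,
            attL=_remap_att(t.attL), attR=_remap_att(t.attR),
            pre_insertion_site=t.pre_insertion_site))

    draft = AnnotatedGenome(name=genome.name, contigs=contigs, genes=genes,
                            circular=set(genome.circular))
    return draft, new_truth


# ---- simulate_reseq ----------------------------------------------------


@dataclass
class ReseqBundle:
    reads: list[ReadRecord]
    depth: dict[str, np.ndarray]
    events: list[ISEvent]


class CoordinateError(ValueError):
    pass


def simulate_reseq(genome: AnnotatedGenome, events: list[ISEvent],
                   depth: float = 30.0, plasmid_fold: float = 1.0,
                   read_len: int = 150, seed: int = 0,
                   is_library: Optional[dict[str, str]] = None,
                   min_clip: int = 8) -> ReseqBundle:
    """Poisson depth tracks plus junction reads for IS insertions.

    For each event, reads are drawn from the mutant haplotype (reference with
    the IS plus its target-site duplication inserted) at rate
    ``depth * allele_fraction`` and from the wild haplotype at the
    complementary rate, within a window around the insertion point. Reads
    crossing a new junction carry soft-clipped IS tails in SAM convention.
    """
    ss = np.random.SeedSequence(seed)
    s_depth, s_reads = ss.spawn(2)
    rng_d = np.random.default_rng(s_depth)
    depth_track = {}
    for cname, cseq in genome.contigs.items():
        lam = depth * (plasmid_fold if cname in genome.circular else 1.0)
        depth_track[cname] = rng_d.poisson(lam, size=len(cseq)).astype(np.int32)

    is_library = is_library or {}
    reads: list[ReadRecord] = []
    rng = np.random.default_rng(s_reads)
    for ev in events:
        if ev.contig not in genome.contigs:
            raise CoordinateError(f"unknown contig {ev.contig}")
        ref = genome.contigs[ev.contig]
        if not 0 <= ev.position < len(ref):
            raise CoordinateError(f"event position {ev.position} off contig")
        is_seq = is_library.get(ev.is_id)
        if is_seq is None:
            raise CoordinateError(f"IS {ev.is_id} not in library")
        p, d = ev.position, ev.dr_len
        mut = ref[:p + d] + is_seq + ref[p:]
        win_a = max(0, p - 300)
        win_b = min(len(ref), p + d + 300)

        def sample(hap: str, lam: float, mutant: bool, span: tuple[int, int]):
            # interior positions see expected depth == lam regardless of
            # window width: reads/position = n * read_len / start_width
            a, b = span
            start_width = max(1, b - a - read_len)
            n = rng.poisson(lam * start_width / read_len)
            starts = rng.integers(a, a + start_width, size=n)
            for j, s0 in enumerate(starts):
                sub = hap[s0:s0 + read_len]
                tag = "m" if mutant else "w"
                qname = f"{ev.is_id}_{ev.contig}_{p}_{tag}{j}"
                if not mutant:
                    reads.append(ReadRecord(qname, ev.contig, int(s0),
                                            f"{len(sub)}M", sub))
                    continue
                # mutant haplotype coordinates: IS occupies [p+d, p+d+L)
                L = len(is_seq)
                e0 = s0 + len(sub)
                if e0 <= p + d:          # entirely left of the IS
                    reads.append(ReadRecord(qname, ev.contig, int(s0),
                                            f"{len(sub)}M", sub))
                elif s0 >= p + d + L:    # entirely right of the IS
                    reads.append(ReadRecord(qname, ev.contig,
                                            int(s0) - d - L,
                                            f"{len(sub)}M", sub))
                elif s0 < p + d and e0 > p + d:  # crosses the left junction
                    m = p + d - s0
                    c = len(sub) - m
                    if m >= min_clip and c >= min_clip:
                        reads.append(ReadRecord(qname, ev.contig, int(s0),
                                                f"{m}M{c}S", sub))
                elif s0 < p + d + L < e0:        # crosses the right junction
                    c = p + d + L - s0
                    m = len(sub) - c
                    if m >= min_clip and c >= min_clip:
                        reads.append(ReadRecord(qname, ev.contig, p,
                                                f"{c}S{m}M", sub))

        f = ev.allele_fraction
        sample(mut, depth * f, True, (win_a, win_b + d + len(is_seq)))
        sample(ref, depth * (1 - f), False, (win_a, win_b))
    return ReseqBundle(reads=reads, depth=depth_track, events=list(events))


STANDARD_ELEMENTS = (
    ElementSpec("iE01", "ICE", 9000, 9, cargo_gc_offset=-0.05,
                integration_site="tRNA-Ala-GGC", dr_length=48,
                module_genes=["integrase", "virB1", "virB4", "virB5",
                              "virB6", "virB9", "virB11",
                              "relaxase VirD2 MOBP", "t4cp2 coupling protein"]),
    ElementSpec("iE02", "GI", 6000, 6, cargo_gc_offset=0.05,
                integration_site="tRNA-Arg-TCT", dr_length=48,
                module_genes=["integrase", "merR transcriptional regulator",
                              "mercury resistance protein"]),
    ElementSpec("iE03", "Tn", 3600, 3, cargo_gc_offset=-0.04,
                integration_site="", dr_length=8,
                module_genes=["Tn7-like transposase TnsA",
                              "Tn7-like transposase TnsB",
                              "restriction endonuclease"]),
)

STANDARD_PLASMID = ElementSpec(
    "pE01", "plasmid", 6000, 6, cargo_gc_offset=-0.02,
    module_genes=["rep replication protein", "parA partition protein",
                  "vapB antitoxin", "vapC toxin",
                  "hcp hydroxylamine reductase", "nnrS protein"])


def standard_complex(seed: int, n_per_group: int = 4,
                     with_plasmid: bool = True,
                     split_element: Optional[str] = "iE01",
                     config: Optional[ComplexConfig] = None
                     ) -> ForgedComplex:
    """The reference study condition: a two-sublineage complex whose group-A
    strains share three integrated elements (an ICE at tRNA-Ala, a
    high-GC genomic island at tRNA-Arg, a transposon in a backbone gene)
    and a multi-copy plasmid; one group-A strain is fragmented into a draft
    that splits the ICE across two contigs."""
    cfg = config or ComplexConfig(n_strains_per_group=n_per_group,
                                  rng_seed=seed)
    cx = forge_complex(cfg)
    specs = []
    for sp in STANDARD_ELEMENTS:
        site = sp.integration_site
        if not site:  # transposon targets a mid-chromosome backbone gene
            cds = [g for g in cx.genomes[0].genes if g.kind == "CDS"]
            site = cds[len(cds) * 2 // 3].family
        specs.append(ElementSpec(sp.element_id, sp.element_kind, sp.length,
                                 sp.n_genes, sp.cargo_gc_offset, site,
                                 sp.dr_length, list(sp.module_genes)))
    for j, sp in enumerate(specs):
        plant_in_group(cx, sp, seed * 31 + j, group="A")
    if with_plasmid:
        plant_in_group(cx, STANDARD_PLASMID, seed * 31 + 7, group="A")
    if split_element:
        victim = next(g.name for g in cx.genomes
                      if cx.groups[g.name] == "A")
        draft, truth = make_draft(cx.genome(victim), n_breaks=3,
                                  min_contig=2000, seed=seed * 31 + 11,
                                  truth=cx.truth,
                                  force_break_in=split_element)
        cx.genomes[[g.name for g in cx.genomes].index(victim)] = draft
        cx.truth = truth
    return cx


def write_bundle(cx: ForgedComplex, outdir, seeds: Optional[dict] = None
                 ) -> None:
    """Write a forged complex as pipeline-ready flat files.

    ``seeds`` maps element id -> (source strain, [gene loci]); their protein
    sets are exported under ``seeds/`` for the census stage.
    """
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in cx.genomes:
        g.write_fasta(outdir / f"{g.name}.fna")
        g.write_gff3(outdir / f"{g.name}.gff3")
    with open(outdir / "groups.tsv", "w") as fh:
        fh.write("strain\tgroup\n")
        for s, grp in sorted(cx.groups.items()):
            fh.write(f"{s}\t{grp}\n")
    if cx.truth:
        import pandas as pd
        pd.DataFrame([t.to_row() for t in cx.truth]).to_csv(
            outdir / "truth.tsv", sep="\t", index=False)
    if seeds:
        sd = outdir / "seeds"
        sd.mkdir(exist_ok=True)
        rows = []
        for elem_id, (strain, loci) in sorted(seeds.items()):
            g = cx.genome(strain)
            prot = g.proteome()
            with open(sd / f"{elem_id}.faa", "w") as fh:
                for l in loci:
                    if l in prot:
                        fh.write(f">{l}\n{prot[l]}\n")
            rows.append({"element_id": elem_id, "source_strain": strain,
                         "type": "GI", "integration_site": ""})
        import pandas as pd
        pd.DataFrame(rows).to_csv(sd / "seeds.tsv", sep="\t", index=False)


def linearize_circle(seq: str, dup: int) -> str:
    """Write a circular replicon as a linear contig with a duplicated
    terminus of ``dup`` bp (the artefact that contig circularization
    detects and trims)."""
    return seq + seq[:dup]
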