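"""Seed-element census: map known-element proteins onto target genomes.

Each seed element is an ordered protein set from a characterized integrated
MGE. Its proteins are searched against every target proteome (hits retained
at e-value < 0.001), orthology is confirmed by a reciprocal best hit back
into the seed's source proteome, and the per-strain percent coverage of each
seed fills an occurrence matrix (present at >= 95%). Strains are then
clustered on their coverage profiles (average linkage, Euclidean).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .align import best_hit, kmer_index, search_proteome
from .model import AnnotatedGenome

EVALUE_CENSUS = 1e-3      # retention cut-off for the census
EVALUE_DISPLAY = 1e-10    # stricter cut-off for clustering display
OCCURRENCE = 95.0         # percent coverage for an occurrence call


@dataclass
class SeedElement:
    element_id: str
    source_strain: str
    proteins: dict[str, str]             # ordered locus -> aa sequence
    declared_type: str = "GI"
    integration_site: str = ""

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"seed {self.element_id} has no proteins")


@dataclass
class SeedHit:
    query: str
    target_locus: str
    evalue: float
    identity: float
    coverage: float
    rbh_confirmed: bool = False


def seed_search(seed: SeedElement, target: AnnotatedGenome,
                evalue_max: float = EVALUE_CENSUS,
                source_proteome: Optional[dict[str, str]] = None
                ) -> list[SeedHit]:
    """Best retained hit per seed protein, RBH-confirmed against the source.

    When ``source_proteome`` is omitted the seed's own protein set stands in
    for its source proteome (sufficient for self-consistency of the RBH
    check on forged data).
    """
    proteome = target.proteome()
    if not proteome:
        raise ValueError(f"{target.name} has no protein annotations")
    t_idx = kmer_index(proteome)
    src = source_proteome if source_proteome is not None else dict(seed.proteins)
    s_idx = kmer_index(src)
    hits = []
    for qname, qseq in seed.proteins.items():
        found = search_proteome(qname, qseq, proteome, t_idx, evalue_max)
        if not found:
            continue
        h = found[0]
        back = best_hit(h.target, proteome[h.target], src, s_idx, evalue_max)
        rbh = back is not None and back.target == qname
        hits.append(SeedHit(query=qname, target_locus=h.target,
                            evalue=h.evalue, identity=h.identity,
                            coverage=h.coverage, rbh_confirmed=rbh))
    return hits


@dataclass
class CoverageMatrix:
    frame: pd.DataFrame                  # elements x strains, percent
    occurrence: pd.DataFrame             # boolean, >= OCCURRENCE
    hits: dict[tuple[str, str], list[SeedHit]] = field(default_factory=dict)
    newick: str = ""
    strain_order: list[str] = field(default_factory=list)


def coverage_matrix(seeds: list[SeedElement],
                    strains: list[AnnotatedGenome],
                    evalue_max: float = EVALUE_CENSUS,
                    require_rbh: bool = True,
                    occurrence: float = OCCURRENCE) -> CoverageMatrix:
    names = sorted(g.name for g in strains)
    by_name = {g.name: g for g in strains}
    data = np.zeros((len(seeds), len(names)))
    all_hits: dict[tuple[str, str], list[SeedHit]] = {}
    for i, seed in enumerate(seeds):
        for j, sname in enumerate(names):
            hits = seed_search(seed, by_name[sname], evalue_max)
            kept = [h for h in hits if h.rbh_confirmed or not require_rbh]
            all_hits[(seed.element_id, sname)] = kept
            data[i, j] = 100.0 * len({h.query for h in kept}) / len(seed.proteins)
    frame = pd.DataFrame(data, index=[s.element_id for s in seeds],
                         columns=names)
    occ = frame >= occurrence
    newick, order = _cluster_strains(frame)
    return CoverageMatrix(frame=frame, occurrence=occ, hits=all_hits,
                          newick=newick, strain_order=order)


def _cluster_strains(frame: pd.DataFrame) -> tuple[str, list[str]]:
    names = list(frame.columns)
    if len(names) < 2:
        return f"({names[0]});" if names else ";", names
    rows = frame.T.to_numpy()
    z = hierarchy.linkage(pdist(rows, metric="euclidean"), method="average")
    tree = hierarchy.to_tree(z)

    def nwk(node) -> str:
        if node.is_leaf():
            return names[node.id]
        return f"({nwk(node.left)},{nwk(node.right)}):{node.dist:.4f}"

    order = [names[i] for i in hierarchy.leaves_list(z)]
    return nwk(tree) + ";", order


def seed_from_truth(element_id: str, genome: AnnotatedGenome,
                    gene_loci: list[str], declared_type: str = "GI",
                    integration_site: str = "") -> SeedElement:
    """Build a seed element from a genome's own annotated element genes."""
    prot = genome.proteome()
    return SeedElement(element_id=element_id, source_strain=genome.name,
                       proteins={l: prot[l] for l in gene_loci if l in prot},
                       declared_type=declared_type,
                       integration_site=integration_site)
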