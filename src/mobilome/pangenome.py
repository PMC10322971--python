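"""Protein-family clustering across strains and pangenome compartments.

Families are connected components of the all-vs-all protein similarity
graph (edges kept at >= 75% alignment coverage, e-value <= 1e-5, and an
identity floor). Compartments follow the usual census: *core* families occur
in every strain, *exclusive* families in exactly one, *soft-core* families
in >= 95% but not all (folded into flexible for counting), and *flexible*
families in more than one but < 95% of strains. A family is
*group-exclusive* for a sublineage when present in > 90% of that
sublineage's strains and absent from every other strain.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .align import (blosum_score, candidate_targets, evalue, global_identity,
                    kmer_index)
from .model import AnnotatedGenome

SOFT_CORE = 0.95
GROUP_MAJORITY = 0.90


@dataclass
class Family:
    family_id: str
    members: list[tuple[str, str]]          # (strain, locus)
    compartment: str = ""                    # core | soft-core | flexible | exclusive
    mean_identity: Optional[float] = None    # percent, within family
    group_exclusive: Optional[str] = None    # sublineage name or None

    @property
    def strains(self) -> set[str]:
        return {s for s, _ in self.members}


@dataclass
class FamilyTable:
    families: list[Family]
    strains: list[str]

    def of_locus(self) -> dict[tuple[str, str], Family]:
        return {m: f for f in self.families for m in f.members}

    def occupancy(self) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.strains)}
        m = np.zeros((len(self.families), len(self.strains)), dtype=bool)
        for r, f in enumerate(self.families):
            for s in f.strains:
                m[r, idx[s]] = True
        return m

    def counts(self) -> dict[str, int]:
        out = {"core": 0, "soft-core": 0, "flexible": 0, "exclusive": 0}
        for f in self.families:
            out[f.compartment] += 1
        return out


def cluster_families(proteomes: dict[str, dict[str, str]],
                     min_coverage: float = 0.75,
                     evalue_max: float = 1e-5,
                     identity_floor: float = 0.5) -> FamilyTable:
    """Connected-component clustering of the cross-strain similarity graph."""
    if len(proteomes) < 2:
        raise ValueError("need >= 2 proteomes")
    for s, p in proteomes.items():
        if not p:
            raise ValueError(f"empty proteome for {s}")
    nodes = [(s, l) for s, prots in sorted(proteomes.items())
             for l in sorted(prots)]
    seqs = {(s, l): proteomes[s][l] for s, l in nodes}
    db_len = sum(len(v) for v in seqs.values())
    flat = {f"{s}\t{l}": v for (s, l), v in seqs.items()}
    idx = kmer_index(flat)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (s, l) in nodes:
        q = seqs[(s, l)]
        for cand in candidate_targets(q, idx):
            cs, cl = cand.split("\t")
            if (cs, cl) <= (s, l):
                continue
            t = flat[cand]
            cov = min(len(q), len(t)) / max(len(q), len(t))
            if cov < min_coverage:
                continue
            ident = global_identity(q, t)
            if ident < identity_floor:
                continue
            if evalue(blosum_score(q, t), len(q), db_len) > evalue_max:
                continue
            g.add_edge((s, l), (cs, cl), identity=ident)

    families = []
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(comps):
        members = sorted(comp)
        idents = [g.edges[u, v]["identity"] * 100
                  for u, v in itertools.combinations(members, 2)
                  if g.has_edge(u, v)]
        families.append(Family(
            family_id=f"PF{i + 1:05d}", members=members,
            mean_identity=float(np.mean(idents)) if idents else None))
    table = FamilyTable(families=families, strains=sorted(proteomes))
    assert sum(len(f.members) for f in table.families) == len(nodes), \
        "families must partition the proteomes"
    return table


def cluster_from_genomes(genomes: list[AnnotatedGenome], **kw) -> FamilyTable:
    return cluster_families({g.name: g.proteome() for g in genomes}, **kw)


def compartmentalize(table: FamilyTable,
                     groups: Optional[dict[str, str]] = None,
                     group_majority: float = GROUP_MAJORITY,
                     soft_core: float = SOFT_CORE) -> FamilyTable:
    """Assign core / soft-core / flexible / exclusive labels in place, plus
    per-sublineage exclusivity flags when a strain->group map is given."""
    n = len(table.strains)
    if groups is not None:
        missing = set(table.strains) - set(groups)
        if missing:
            raise ValueError(f"strains missing from group map: {missing}")
    for f in table.families:
        k = len(f.strains)
        if k == n:
            f.compartment = "core"
        elif k == 1:
            f.compartment = "exclusive"
        elif k >= soft_core * n:
            f.compartment = "soft-core"
        else:
            f.compartment = "flexible"
        if groups is not None:
            f.group_exclusive = None
            for gname in sorted(set(groups.values())):
                g_strains = {s for s, gg in groups.items() if gg == gname}
                inside = len(f.strains & g_strains)
                outside = len(f.strains - g_strains)
                if outside == 0 and inside > group_majority * len(g_strains):
                    f.group_exclusive = gname
    return table


def census_counts(table: FamilyTable) -> dict[str, int]:
    """Exclusive vs flexible counting with soft-core folded into flexible."""
    c = table.counts()
    return {"core": c["core"],
            "flexible": c["flexible"] + c["soft-core"],
            "exclusive": c["exclusive"]}


def family_identity_stats(table: FamilyTable,
                          proteomes: dict[str, dict[str, str]],
                          groups: Optional[dict[str, str]] = None,
                          scope: str = "species") -> dict[str, list[float]]:
    """Per-family mean pairwise identities (percent) within a scope.

    ``scope="species"`` compares members across all strains;
    ``scope="within-group"`` returns one distribution per sublineage plus a
    "cross-group" distribution of inter-sublineage pairs.
    """
    out: dict[str, list[float]] = {}

    def pair_idents(members, pred):
        vals = []
        for (s1, l1), (s2, l2) in itertools.combinations(members, 2):
            if pred(s1, s2):
                vals.append(100 * global_identity(proteomes[s1][l1],
                                                  proteomes[s2][l2]))
        return vals

    for f in table.families:
        if len(f.members) < 2:
            continue
        if scope == "species":
            v = pair_idents(f.members, lambda a, b: True)
            if v:
                out.setdefault("species", []).append(float(np.mean(v)))
        else:
            assert groups is not None
            for gname in sorted(set(groups.values())):
                v = pair_idents(f.members,
                                lambda a, b: groups[a] == groups[b] == gname)
                if v:
                    out.setdefault(gname, []).append(float(np.mean(v)))
            v = pair_idents(f.members, lambda a, b: groups[a] != groups[b])
            if v:
                out.setdefault("cross-group", []).append(float(np.mean(v)))
    return out
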