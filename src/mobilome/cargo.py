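"""Mobilome cargo census: functional profile of MGE-associated families.

A protein family is MGE-associated when any of its members sits inside a
reconstructed candidate element and the family is flexible or exclusive.
Each such family gets an occurrence-pattern label — *exclusive* (one strain),
*intra-lineage* (several strains, all one sublineage), *inter-lineage*
(strains from both) — and a caller-provided functional category (COG-style
single letters a-u, or "unknown").
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .boundaries import CandidateElement
from .pangenome import FamilyTable

log = logging.getLogger(__name__)

CATEGORY_VOCAB = set("abcdefghijklmnopqrstu") | {"unknown"}
MOBILE = {"flexible", "exclusive", "soft-core"}


@dataclass
class CargoCensus:
    records: pd.DataFrame            # one row per MGE-associated family
    mobilome_fraction: float         # of the whole pangenome (families)
    n_mge_families: int
    pattern_counts: dict[str, int] = field(default_factory=dict)

    def by_category(self) -> pd.DataFrame:
        if self.records.empty:
            return pd.DataFrame()
        return (self.records.groupby(["category", "pattern"])
                .size().unstack(fill_value=0))


def census(table: FamilyTable,
           elements: dict[str, list[CandidateElement]],
           labels: Optional[dict[str, str]] = None,
           groups: Optional[dict[str, str]] = None) -> CargoCensus:
    """Census the MGE-associated gene cargo.

    ``elements`` maps strain -> reconstructed candidates in that strain;
    ``labels`` maps family id -> functional category; ``groups`` maps
    strain -> sublineage for the occurrence patterns.
    """
    labels = labels or {}
    in_element: set[tuple[str, str]] = set()
    for strain, cands in elements.items():
        for c in cands:
            in_element.update((strain, locus) for locus in c.genes)

    rows = []
    for fam in table.families:
        if fam.compartment not in MOBILE:
            continue
        if not any(m in in_element for m in fam.members):
            continue
        label = labels.get(fam.family_id, "unknown")
        if label not in CATEGORY_VOCAB:
            log.warning("category %r outside vocabulary; coerced to unknown",
                        label)
            label = "unknown"
        strains = fam.strains
        if len(strains) == 1:
            pattern = "exclusive"
        elif groups and len({groups[s] for s in strains}) == 1:
            pattern = "intra-lineage"
        else:
            pattern = "inter-lineage"
        rows.append({"family": fam.family_id, "compartment": fam.compartment,
                     "category": label, "pattern": pattern,
                     "n_strains": len(strains)})

    df = pd.DataFrame(rows, columns=["family", "compartment", "category",
                                     "pattern", "n_strains"])
    counts = df["pattern"].value_counts().to_dict() if not df.empty else {}
    total = len(table.families)
    return CargoCensus(records=df,
                       mobilome_fraction=len(df) / total if total else 0.0,
                       n_mge_families=len(df), pattern_counts=counts)
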