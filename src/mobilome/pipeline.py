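"""Stage orchestration: run the full analysis over a directory of inputs.

The input layout is one FASTA (``<strain>.fna``) plus one GFF3
(``<strain>.gff3``) per strain, optional ``<strain>.bedgraph`` depth tracks
and ``<strain>.sam`` read alignments, an optional ``seeds/`` directory with
one protein FASTA per seed element plus ``seeds.tsv`` metadata, and optional
``groups.tsv`` (strain, sublineage) and ``labels.tsv`` (family, category)
tables. Stages run in dependency order and every report embeds the
configuration that produced it.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from . import boundaries, cargo, census, classify, isdyn, pangenome, relatedness
from . import synteny as synteny_mod
from .model import AnnotatedGenome, read_sam

log = logging.getLogger("mobilome")


@dataclass
class RunConfig:
    input_dir: str = "."
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"
    stages: list[str] = field(default_factory=lambda: [
        "relate", "synteny", "pangenome", "census", "reconstruct",
        "classify", "cargo", "isdyn"])
    ani_fragment: int = 1020
    ani_species: float = 96.0
    ddh_species: float = 70.0
    sublineage_gap: float = 0.5
    census_evalue: float = 1e-3
    occurrence: float = 95.0
    window: int = 10
    min_dr: int = 12
    dr_max_mismatch: int = 1
    is_min_similarity: float = 0.90
    is_min_coverage: float = 1.00
    min_support: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(open(path)) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_genomes(input_dir: str | Path) -> list[AnnotatedGenome]:
    input_dir = Path(input_dir)
    genomes = []
    for fasta in sorted(input_dir.glob("*.fna")):
        strain = fasta.stem
        gff = input_dir / f"{strain}.gff3"
        bg = input_dir / f"{strain}.bedgraph"
        genomes.append(AnnotatedGenome.read(
            strain, fasta, gff if gff.exists() else None,
            bg if bg.exists() else None))
    return genomes


def load_seeds(input_dir: str | Path,
               genomes: list[AnnotatedGenome]) -> list[census.SeedElement]:
    seed_dir = Path(input_dir) / "seeds"
    meta_path = seed_dir / "seeds.tsv"
    if not meta_path.exists():
        return []
    meta = pd.read_csv(meta_path, sep="\t")
    seeds = []
    for _, row in meta.iterrows():
        fasta = seed_dir / f"{row['element_id']}.faa"
        proteins = {rec.id: str(rec.seq)
                    for rec in SeqIO.parse(str(fasta), "fasta")}
        seeds.append(census.SeedElement(
            element_id=row["element_id"], source_strain=row["source_strain"],
            proteins=proteins, declared_type=row.get("type", "GI"),
            integration_site=str(row.get("integration_site", ""))))
    return seeds


def _load_map(path: Path, key: str, val: str) -> Optional[dict[str, str]]:
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df[key].astype(str), df[val].astype(str)))


def run_pipeline(config: RunConfig) -> dict:
    logging.basicConfig(level=config.log_level)
    in_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    genomes = load_genomes(in_dir)
    if not genomes:
        raise FileNotFoundError(f"no *.fna inputs in {in_dir}")
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema": "mobilome-report/1", "config": config.to_dict(),
                    "strains": [g.name for g in genomes]}
    groups = _load_map(in_dir / "groups.tsv", "strain", "group")

    table = None
    if "relate" in config.stages:
        log.info("relatedness: %d genomes", len(genomes))
        results = relatedness.relate_all(genomes, fragment=config.ani_fragment)
        relatedness.matrix_frame(results, "anib").to_csv(
            out / "anib.tsv", sep="\t")
        relatedness.matrix_frame(results, "dddh").to_csv(
            out / "dddh.tsv", sep="\t")
        delim = relatedness.delimit_groups(results, relatedness.
                                           DelimitationThresholds(
                                               config.ani_species,
                                               config.ddh_species,
                                               config.sublineage_gap))
        report["relatedness"] = {
            "species": [sorted(s) for s in delim.species],
            "sublineages": [sorted(s) for s in delim.sublineages],
            "ambiguous": sorted(delim.ambiguous)}
        if groups is None and len(delim.sublineages) > 1:
            groups = {s: f"G{i + 1}" for i, grp in enumerate(delim.sublineages)
                      for s in grp}

    if "synteny" in config.stages:
        cov = synteny_mod.pairwise_mean_coverage(genomes)
        pd.DataFrame([{"a": a, "b": b, "mean_coverage": v}
                      for (a, b), v in cov.items()]).to_csv(
            out / "synteny.tsv", sep="\t", index=False)
        report["synteny"] = {f"{a}|{b}": round(v, 4)
                             for (a, b), v in cov.items()}

    if "pangenome" in config.stages:
        table = pangenome.cluster_from_genomes(genomes)
        pangenome.compartmentalize(table, groups)
        rows = [{"family": f.family_id, "strain": s, "locus": l,
                 "compartment": f.compartment}
                for f in table.families for s, l in f.members]
        pd.DataFrame(rows).to_csv(out / "families.tsv", sep="\t", index=False)
        report["pangenome"] = {**table.counts(),
                               "n_families": len(table.families)}

    seeds = load_seeds(in_dir, genomes)
    matrix = None
    if "census" in config.stages and seeds:
        matrix = census.coverage_matrix(seeds, genomes,
                                        evalue_max=config.census_evalue,
                                        occurrence=config.occurrence)
        matrix.frame.to_csv(out / "coverage_matrix.tsv", sep="\t")
        (out / "strain_clusters.nwk").write_text(matrix.newick + "\n")
        report["census"] = {"n_seeds": len(seeds),
                            "occurrences": int(matrix.occurrence.values.sum())}

    elements: dict[str, list[boundaries.CandidateElement]] = {}
    if "reconstruct" in config.stages and matrix is not None and table is not None:
        seed_sizes = {s.element_id: len(s.proteins) for s in seeds}
        for g in genomes:
            track = boundaries.contextual_profile(g, table)
            hits = {s.element_id: matrix.hits.get((s.element_id, g.name), [])
                    for s in seeds}
            elements[g.name] = boundaries.reconstruct_elements(
                hits, g, track, window=config.window, seed_sizes=seed_sizes)
            for cand in elements[g.name]:
                cand.att = boundaries.find_att_sites(
                    cand, g, min_dr=config.min_dr,
                    max_mismatch=config.dr_max_mismatch)
        report["elements"] = {
            s: [{"id": c.element_id, "n_genes": c.n_genes,
                 "segments": len(c.segments),
                 "dr": c.att.dr_seq if c.att else None}
                for c in cands]
            for s, cands in elements.items()}

    if "classify" in config.stages and elements:
        typed = {}
        for g in genomes:
            prods = {gene.locus: gene.product for gene in g.genes}
            for cand in elements.get(g.name, []):
                inv = classify.detect_modules(
                    {l: prods.get(l, "") for l in cand.genes})
                ctx = classify.ElementContext(
                    integrated=True, att_present=cand.att is not None,
                    at_trna="tRNA" in (cand.att.integration_feature
                                       if cand.att else ""))
                cand.element_type = classify.type_element(inv, ctx).label
                typed.setdefault(g.name, []).append(
                    {"id": cand.element_id, "type": cand.element_type})
        report["classify"] = typed

    if "cargo" in config.stages and elements and table is not None:
        labels = _load_map(in_dir / "labels.tsv", "family", "category")
        cc = cargo.census(table, elements, labels, groups)
        cc.records.to_csv(out / "cargo_census.tsv", sep="\t", index=False)
        report["cargo"] = {"mobilome_fraction": round(cc.mobilome_fraction, 4),
                           "n_mge_families": cc.n_mge_families,
                           "patterns": cc.pattern_counts}

    if "isdyn" in config.stages:
        lib_path = in_dir / "is_library.fna"
        if lib_path.exists():
            lib = {r.id: str(r.seq) for r in SeqIO.parse(str(lib_path), "fasta")}
            isd = {}
            for g in genomes:
                copies = isdyn.scan_is_copies(
                    g, lib, config.is_min_similarity, config.is_min_coverage)
                entry = {"copies": {k: len(v) for k, v in copies.items()}}
                sam = in_dir / f"{g.name}.sam"
                if sam.exists():
                    events = isdyn.detect_insertions(
                        g, read_sam(sam), lib, min_support=config.min_support,
                        known_copies=copies)
                    entry["events"] = [
                        {"is": e.is_id, "contig": e.contig, "pos": e.position,
                         "target": e.target_gene, "dr_len": e.dr_len,
                         "fraction": round(e.allele_fraction, 3)}
                        for e in events]
                isd[g.name] = entry
            report["isdyn"] = isd

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True)
                                     + "\n")
    return report
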