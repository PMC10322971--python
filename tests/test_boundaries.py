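"""Boundary inference, att-site reconstruction, and in-silico PCR."""
import numpy as np
import pytest

from mobilome import boundaries, census
from mobilome.boundaries import (AmbiguousPrimerError, CandidateElement,
                                 contextual_profile, find_att_sites,
                                 insilico_pcr, reconstruct_elements)
from mobilome.model import AnnotatedGenome, Segment, revcomp


@pytest.fixture(scope="module")
def tracks(small_complex, family_table):
    return {g.name: contextual_profile(g, family_table)
            for g in small_complex.genomes}


@pytest.fixture(scope="module")
def sa02_candidates(small_complex, family_table, tracks):
    rec = next(t for t in small_complex.truth_for("SA01")
               if t.element_id == "iE01")
    seed = census.seed_from_truth("iE01", small_complex.genome("SA01"),
                                  rec.genes)
    target = small_complex.genome("SA02")
    hits = census.seed_search(seed, target)
    cands = reconstruct_elements({"iE01": hits}, target, tracks["SA02"],
                                 seed_sizes={"iE01": len(seed.proteins)})
    return cands


class TestContextualProfile:
    def test_gc_shifted_cargo_flagged(self, small_complex, tracks):
        """Planted cargo at +-5% GC: most cargo genes get |z| >= 2."""
        rec = next(t for t in small_complex.truth_for("SA02")
                   if t.element_id == "iE02")  # +5% GC island
        track = tracks["SA02"]
        zs = [abs(track.per_gene[l].gc_z) for l in rec.genes]
        assert np.mean([z >= 2 for z in zs]) > 0.8

    def test_backbone_core_gene_has_null_flags(self, small_complex, tracks):
        track = tracks["SA02"]
        g = small_complex.genome("SA02")
        core_loci = [ev.locus for ev in track.per_gene.values()
                     if ev.compartment == "core"]
        assert core_loci
        quiet = [l for l in core_loci
                 if abs(track.per_gene[l].gc_z) < 2
                 and not track.per_gene[l].signature]
        assert len(quiet) / len(core_loci) > 0.9

    def test_plasmid_depth_anomaly_flagged(self, rng):
        chrom = "".join(rng.choice(list("ACGT"), 6000))
        pls = "".join(rng.choice(list("ACGT"), 2000))
        from mobilome.model import Gene
        genes = [Gene("g1", "chr", 100, 1000), Gene("p1", "pls", 100, 1000)]
        g = AnnotatedGenome("x", {"chr": chrom, "pls": pls}, genes=genes,
                            circular={"pls"})
        depth = {"chr": np.full(6000, 30), "pls": np.full(2000, 180)}
        track = contextual_profile(g, depth=depth)
        assert track.per_gene["p1"].depth_z > 2
        assert abs(track.per_gene["g1"].depth_z) < 1

    def test_missing_depth_marked_absent_not_zero(self, small_complex,
                                                  tracks):
        track = tracks["SA01"]
        assert not track.depth_available
        assert all(ev.depth_z is None for ev in track.per_gene.values())


class TestReconstruction:
    def test_boundaries_within_one_gene_of_truth(self, small_complex,
                                                 sa02_candidates):
        rec = next(t for t in small_complex.truth_for("SA02")
                   if t.element_id == "iE01")
        truth = set(rec.genes)
        best = max(sa02_candidates,
                   key=lambda c: len(set(c.genes) & truth))
        got = set(best.genes)
        assert len(got - truth) <= 1 and len(truth - got) <= 1

    def test_no_seeds_gives_empty_list(self, small_complex, tracks):
        g = small_complex.genome("SB01")
        assert reconstruct_elements({}, g, tracks["SB01"]) == []

    def test_seed_surrounded_by_core_yields_low_confidence_single_gene(
            self, small_complex, family_table, tracks):
        """A hit on a backbone core gene cannot extend anywhere."""
        g = small_complex.genome("SB01")
        track = tracks["SB01"]
        core_locus = next(l for l, ev in track.per_gene.items()
                          if ev.compartment == "core" and ev.index > 3)
        fake = [census.SeedHit(query="q1", target_locus=core_locus,
                               evalue=1e-20, identity=1.0, coverage=1.0,
                               rbh_confirmed=True)]
        cands = reconstruct_elements({"sx": fake}, g, track)
        assert len(cands) == 1
        assert cands[0].n_genes == 1
        assert cands[0].confidence == "low"

    def test_split_element_merged_across_contigs(self, study_complex,
                                                 family_table):
        """The drafted strain's ICE (2 contigs) merges into one candidate."""
        from mobilome import pangenome
        cx = study_complex
        table = pangenome.cluster_from_genomes(cx.genomes)
        pangenome.compartmentalize(table, cx.groups)
        drafted = next(g for g in cx.genomes if len(g.contigs) > 2)
        rec = next(t for t in cx.truth_for(drafted.name)
                   if t.element_id == "iE01")
        assert len(rec.segments) == 2
        donor = next(g.name for g in cx.genomes
                     if cx.groups[g.name] == "A" and g.name != drafted.name)
        seed_rec = next(t for t in cx.truth_for(donor)
                        if t.element_id == "iE01")
        seed = census.seed_from_truth("iE01", cx.genome(donor),
                                      seed_rec.genes)
        hits = census.seed_search(seed, drafted)
        track = contextual_profile(drafted, table)
        cands = reconstruct_elements({"iE01": hits}, drafted, track,
                                     seed_sizes={"iE01": len(seed.proteins)})
        merged = [c for c in cands if len(c.segments) >= 2]
        assert merged
        got = set(merged[0].genes)
        truth = set(rec.genes)
        assert len(got & truth) / len(truth) >= 0.9


class TestAttSites:
    def test_planted_exact_dr_recovered_and_excision_restores(
            self, small_complex, sa02_candidates):
        rec = next(t for t in small_complex.truth_for("SA02")
                   if t.element_id == "iE01")
        best = max(sa02_candidates,
                   key=lambda c: len(set(c.genes) & set(rec.genes)))
        g = small_complex.genome("SA02")
        att = find_att_sites(best, g)
        assert att is not None
        assert att.dr_seq == rec.dr_seq
        assert att.mismatches == 0
        # in-silico excision reproduces the pre-insertion locus
        assert rec.pre_insertion_site in att.attB
        # attP joins the element termini across one DR copy
        assert rec.dr_seq in att.attP

    def test_no_dr_planted_reports_none(self, small_complex, family_table):
        from mobilome.forge import ElementSpec, plant_element
        host = small_complex.genome("SB01")
        spec = ElementSpec("nodr", "GI", 4000, 4,
                           integration_site="tRNA-Gly-CCC", dr_length=0,
                           module_genes=["integrase"])
        planted, rec = plant_element(host, spec, seed=77)
        cand = CandidateElement(
            element_id="c1", segments=[Segment(rec.segments[0].contig,
                                               rec.segments[0].start,
                                               rec.segments[0].end)],
            genes=list(rec.genes))
        att = find_att_sites(cand, planted)
        assert att is None

    def test_multicontig_candidate_skipped(self, small_complex):
        cand = CandidateElement(
            element_id="c1",
            segments=[Segment("a", 0, 100), Segment("b", 0, 100)],
            genes=[])
        g = AnnotatedGenome("x", {"a": "A" * 200, "b": "C" * 200})
        assert find_att_sites(cand, g) is None


class TestInsilicoPcr:
    def _locus(self, rng, n=3000):
        return "".join(rng.choice(list("ACGT"), n))

    def test_wildtype_and_insertion_amplicons_differ_by_is_plus_dr(self,
                                                                   rng):
        """Mirrors a permease-locus screen: 954-bp wild-type product, and
        2264 bp once a 1302-bp IS with an 8-bp target duplication lands
        inside the amplicon."""
        locus = self._locus(rng, 3000)
        f_start, product = 1000, 954
        fwd = locus[f_start:f_start + 20]
        rev = revcomp(locus[f_start + product - 20:f_start + product])
        wt = insilico_pcr({"wt": locus}, fwd, rev)
        assert [a.length for a in wt] == [954]
        is_seq = self._locus(rng, 1302)
        p, d = 1400, 8
        mutant = locus[:p + d] + is_seq + locus[p:]
        mut = insilico_pcr({"mut": mutant}, fwd, rev)
        assert [a.length for a in mut] == [954 + 1302 + 8]
        assert mut[0].length - wt[0].length == len(is_seq) + d

    def test_no_binding_sites_gives_empty_result(self, rng):
        locus = self._locus(rng)
        assert insilico_pcr({"t": locus}, "ACGTACGTACGTACGTA",
                            "TGCATGCATGCATGCAT") == []

    def test_circular_template_amplifies_across_origin(self, rng):
        circ = self._locus(rng, 2000)
        fwd = circ[1900:1920]
        rev = revcomp(circ[180:200])
        hits = insilico_pcr({"c": circ}, fwd, rev, circular={"c"})
        assert [a.length for a in hits] == [300]
        assert insilico_pcr({"c": circ}, fwd, rev) == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            insilico_pcr({"t": "ACGT" * 100}, "ACGTACGT", "ACGTACGTACGTACGT")

    def test_degenerate_primer_everywhere_is_ambiguous(self):
        with pytest.raises(AmbiguousPrimerError):
            insilico_pcr({"t": "A" * 5000}, "A" * 15, "T" * 15,
                         max_mismatch=0)
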