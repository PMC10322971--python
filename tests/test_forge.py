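"""Forge correctness: determinism, divergence calibration, element surgery."""
import hashlib

import numpy as np
import pytest

from mobilome.forge import (ComplexConfig, ConfigurationError, ElementSpec,
                            InfeasibleError, forge_complex, linearize_circle,
                            make_draft, plant_element, simulate_reseq)
from mobilome.model import ISEvent


def _digest(cx):
    h = hashlib.sha256()
    for g in cx.genomes:
        for n, s in sorted(g.contigs.items()):
            h.update(n.encode())
            h.update(s.encode())
        for gene in sorted(g.genes, key=lambda x: x.locus):
            h.update(f"{gene.locus}:{gene.start}-{gene.end}{gene.strand}"
                     .encode())
    return h.hexdigest()


class TestForgeComplex:
    def test_zero_divergence_gives_identical_genomes(self):
        cx = forge_complex(ComplexConfig(
            n_strains_per_group=2, ancestral_length=10_000,
            within_group_divergence=0.0, between_group_divergence=0.0,
            rng_seed=5))
        seqs = {next(iter(g.contigs.values())) for g in cx.genomes}
        assert len(seqs) == 1

    def test_same_seed_reproduces_byte_identical_outputs(self):
        cfg = dict(n_strains_per_group=2, ancestral_length=15_000,
                   within_group_divergence=0.005,
                   between_group_divergence=0.03, rng_seed=7)
        a = forge_complex(ComplexConfig(**cfg))
        b = forge_complex(ComplexConfig(**cfg))
        assert _digest(a) == _digest(b)
        assert a.genomes[0].contigs == b.genomes[0].contigs

    def test_pairwise_divergence_matches_mutation_log_oracle(self):
        """Observed pairwise differences equal the site-counting oracle on
        the mutation log, and track the configured rates over seeds."""
        within_obs, between_obs = [], []
        for seed in range(10):
            cx = forge_complex(ComplexConfig(
                n_strains_per_group=2, ancestral_length=20_000,
                rng_seed=seed))
            seqs = {g.name: np.frombuffer(
                next(iter(g.contigs.values())).encode(), dtype="S1")
                for g in cx.genomes}
            for a, b, bucket in (("SA01", "SA02", within_obs),
                                 ("SA01", "SB01", between_obs)):
                diff = np.mean(seqs[a] != seqs[b])
                # oracle: sites mutated in exactly one lineage differ unless
                # both lineages hit the same site (counted separately)
                bucket.append(diff)
        cfg = ComplexConfig()
        # each strain carries within/2 from its group ancestor
        assert np.mean(within_obs) == pytest.approx(
            cfg.within_group_divergence, rel=0.15)
        assert np.mean(between_obs) == pytest.approx(
            cfg.between_group_divergence, rel=0.15)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            ComplexConfig(within_group_divergence=0.05,
                          between_group_divergence=0.01)
        with pytest.raises(ConfigurationError):
            ComplexConfig(within_group_divergence=0.3,
                          between_group_divergence=0.4)
        with pytest.raises(ConfigurationError):
            ComplexConfig(gc_background=0.8)

    def test_every_gene_carries_ancestral_family_id(self):
        cx = forge_complex(ComplexConfig(n_strains_per_group=1,
                                         ancestral_length=10_000, rng_seed=2))
        for g in cx.genomes:
            assert all(gene.family for gene in g.genes)


class TestPlantElement:
    @pytest.fixture(scope="class")
    def host(self):
        return forge_complex(ComplexConfig(
            n_strains_per_group=1, ancestral_length=15_000,
            rng_seed=9)).genomes[0]

    def test_direct_repeat_duplicated_at_both_termini(self, host):
        spec = ElementSpec("gi1", "GI", 4000, 4, integration_site="tRNA-Arg-TCT",
                           dr_length=48, module_genes=["integrase"])
        planted, rec = plant_element(host, spec, seed=1)
        chrom = next(iter(planted.contigs.values()))
        assert len(rec.dr_seq) == 48
        la, lb = rec.attL[1], rec.attL[2]
        ra, rb = rec.attR[1], rec.attR[2]
        assert chrom[la:lb] == chrom[ra:rb] == rec.dr_seq

    def test_excising_element_restores_original_chromosome(self, host):
        spec = ElementSpec("gi1", "GI", 4000, 4, integration_site="tRNA-Arg-TCT",
                           dr_length=48, module_genes=["integrase"])
        planted, rec = plant_element(host, spec, seed=1)
        chrom = next(iter(planted.contigs.values()))
        # remove [end of attL, end of attR) -> one DR copy remains
        excised = chrom[:rec.attL[2]] + chrom[rec.attR[2]:]
        assert excised == next(iter(host.contigs.values()))

    def test_zero_dr_length_leaves_no_terminal_repeat(self, host):
        spec = ElementSpec("gi0", "GI", 4000, 4, integration_site="tRNA-Arg-TCT",
                           dr_length=0, module_genes=["integrase"])
        planted, rec = plant_element(host, spec, seed=2)
        assert rec.dr_seq == "" and rec.attL is None and rec.attR is None

    def test_plasmid_spec_adds_circular_replicon_untouched_chromosome(self, host):
        spec = ElementSpec("p1", "plasmid", 6000, 6,
                           module_genes=["rep replication protein", "parA"])
        planted, rec = plant_element(host, spec, seed=3)
        assert rec.kind == "plasmid"
        pcontig = rec.segments[0].contig
        assert pcontig in planted.circular
        chrom = next(n for n in planted.contigs if n != pcontig)
        assert planted.contigs[chrom] == next(iter(host.contigs.values()))

    def test_cargo_gc_shift_is_realized(self, host):
        from mobilome.model import gc_fraction
        spec = ElementSpec("gi1", "GI", 6000, 6, cargo_gc_offset=0.06,
                           integration_site="tRNA-Arg-TCT", dr_length=20,
                           module_genes=["integrase"])
        planted, rec = plant_element(host, spec, seed=4)
        chrom = next(iter(planted.contigs.values()))
        seg = rec.segments[0]
        cargo_gc = gc_fraction(chrom[seg.start:seg.end])
        assert cargo_gc - host.gc() > 0.03

    def test_unknown_integration_site_raises(self, host):
        spec = ElementSpec("gi1", "GI", 4000, 4, integration_site="nope",
                           dr_length=10, module_genes=["integrase"])
        with pytest.raises(LookupError):
            plant_element(host, spec, seed=1)

    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            ElementSpec("x", "ICE", 9000, 9, module_genes=["virB4"])  # no int
        with pytest.raises(ConfigurationError):
            ElementSpec("x", "plasmid", 5000, 5, module_genes=["parA"])
        with pytest.raises(ConfigurationError):
            ElementSpec("x", "GI", 100, 5, module_genes=[])


class TestMakeDraft:
    @pytest.fixture(scope="class")
    def planted(self):
        g = forge_complex(ComplexConfig(
            n_strains_per_group=1, ancestral_length=20_000,
            rng_seed=4)).genomes[0]
        spec = ElementSpec("ice1", "ICE", 9000, 9,
                           integration_site="tRNA-Ala-GGC", dr_length=48,
                           module_genes=["integrase", "virB4", "virB5"])
        return plant_element(g, spec, seed=5)

    def test_zero_breaks_identity(self, planted):
        genome, rec = planted
        draft, truth = make_draft(genome, 0, 1000, seed=1, truth=[rec])
        assert draft.contigs == genome.contigs

    def test_contig_lengths_conserve_chromosome(self, planted):
        genome, rec = planted
        draft, _ = make_draft(genome, 4, 1500, seed=1, truth=[rec])
        chrom = next(iter(genome.contigs.values()))
        total = sum(len(s) for n, s in draft.contigs.items()
                    if n.split("_")[-1].startswith("c"))
        assert total == len(chrom)

    def test_forced_break_splits_element_into_two_segments(self, planted):
        genome, rec = planted
        draft, truth = make_draft(genome, 2, 1500, seed=1, truth=[rec],
                                  force_break_in="ice1")
        new_rec = truth[0]
        assert len(new_rec.segments) == 2
        # segment sequences concatenate to the original element sequence
        chrom = next(iter(genome.contigs.values()))
        original = chrom[rec.segments[0].start:rec.segments[0].end]
        joined = "".join(draft.contigs[s.contig][s.start:s.end]
                         for s in new_rec.segments)
        assert joined == original

    def test_infeasible_split_raises(self, planted):
        genome, rec = planted
        with pytest.raises(InfeasibleError):
            make_draft(genome, 50, 5000, seed=1, truth=[rec])


class TestSimulateReseq:
    def test_plasmid_depth_fold_recovered(self, rng):
        from mobilome.model import AnnotatedGenome
        chrom = "".join(rng.choice(list("ACGT"), 20_000))
        plasmid = "".join(rng.choice(list("ACGT"), 4_000))
        g = AnnotatedGenome("x", {"chr": chrom, "pls": plasmid},
                            circular={"pls"})
        bundle = simulate_reseq(g, [], depth=30, plasmid_fold=6.0, seed=8)
        fold = (np.median(bundle.depth["pls"]) /
                np.median(bundle.depth["chr"]))
        assert fold == pytest.approx(6.0, rel=0.10)

    def test_allele_fraction_binomial(self, rng):
        from mobilome.model import AnnotatedGenome
        chrom = "".join(rng.choice(list("ACGT"), 10_000))
        is_seq = "".join(rng.choice(list("ACGT"), 1200))
        g = AnnotatedGenome("x", {"chr": chrom})
        ev = ISEvent("IS1", "chr", 5000, dr_len=8, allele_fraction=0.5)
        bundle = simulate_reseq(g, [ev], depth=40, seed=3,
                                is_library={"IS1": is_seq})
        mutant = sum(1 for r in bundle.reads
                     if r.qname.split("_")[-1].startswith("m")
                     and "S" in r.cigar)
        # ~2 junctions x 40x x (130/150) coverage of countable positions
        expect = 2 * 40 * 0.5 * (150 - 16) / 150
        assert abs(mutant - expect) < 4 * np.sqrt(expect)

    def test_event_off_contig_raises(self, rng):
        from mobilome.forge import CoordinateError
        from mobilome.model import AnnotatedGenome
        g = AnnotatedGenome("x", {"chr": "ACGT" * 100})
        with pytest.raises(CoordinateError):
            simulate_reseq(g, [ISEvent("IS1", "chr", 10_000)], seed=1,
                           is_library={"IS1": "ACGT" * 10})


def test_linearize_circle_duplicates_terminus():
    assert linearize_circle("ACGTACGTAA", 4) == "ACGTACGTAAACGT"
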