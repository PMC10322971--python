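"""Typing rules, module detection, circularization, restriction digestion."""
import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobilome.classify import (AmbiguousOverlapError, ElementContext,
                               ModuleInventory, circularize_contig, digest,
                               detect_modules, type_element)
from mobilome.forge import linearize_circle


class TestDetectModules:
    def test_ice_labels_complete_conjugation_module(self):
        labels = {"g1": "integrase", "g2": "virB1", "g3": "virB4",
                  "g4": "virB5", "g5": "virB6", "g6": "virB9",
                  "g7": "virB11", "g8": "relaxase VirD2 MOBP",
                  "g9": "t4cp2 coupling protein"}
        inv = detect_modules(labels)
        assert inv.integrases == ["g1"]
        assert inv.virb == {"virB1", "virB4", "virB5", "virB6", "virB9",
                            "virB11"}
        assert inv.relaxase and inv.coupling
        assert inv.conjugation_complete

    def test_empty_protein_list_gives_empty_inventory(self):
        inv = detect_modules({})
        assert not any([inv.integrases, inv.transposases, inv.virb,
                        inv.relaxase, inv.replication])

    def test_unlabeled_proteins_counted_as_cargo(self):
        inv = detect_modules({"g1": "hypothetical protein"})
        assert inv.cargo == ["g1"]

    def test_oriv_motifs_found_near_rep(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 3000))
        # plant one DnaA box (1 mismatch) and one IHF site near the rep gene
        dnaa = "TTATCCACA"
        mutated = "TTATGCACA"
        ihf = "AATCAAGGGGTTA"  # matches WATCAANNNNTTR
        seq = seq[:1100] + mutated + seq[1109:1400] + ihf + seq[1413:]
        inv = detect_modules({"rep1": "rep replication protein"},
                             sequence=seq,
                             gene_coords={"rep1": (1200, 1350)})
        assert 1100 in inv.dnaa_boxes
        assert 1400 in inv.ihf_sites


def _inventory(has_int, has_tnp, has_virb, has_rep):
    inv = ModuleInventory()
    if has_int:
        inv.integrases = ["i"]
    if has_tnp:
        inv.transposases = ["t"]
    if has_virb:
        inv.virb = {f"virB{i}" for i in (1, 3, 4, 5, 9)}
    if has_rep:
        inv.replication = ["r"]
    return inv


def _rule_oracle(inv, ctx):
    """Independent restatement of the published decision rules."""
    conj = len(inv.virb) >= 5 or (inv.relaxase and inv.coupling)
    if inv.replication and (ctx.circular or
                            (ctx.standalone_contig and
                             (inv.dnaa_boxes or inv.ihf_sites))):
        return "plasmid"
    if ctx.integrated and inv.integrases and conj:
        return "ICE"
    if inv.integrases:
        return "GI"
    if inv.transposases and not ctx.at_trna:
        return "Tn"
    return "fragment"


class TestTypeElement:
    def test_rules_match_exhaustive_enumeration(self):
        for has_int, has_tnp, has_virb, has_rep, circular in \
                itertools.product([0, 1], repeat=5):
            inv = _inventory(has_int, has_tnp, has_virb, has_rep)
            ctx = ElementContext(integrated=not circular, circular=circular)
            assert type_element(inv, ctx).label == _rule_oracle(inv, ctx)

    def test_integrase_only_island_at_trna_is_gi(self):
        inv = _inventory(1, 0, 0, 0)
        ctx = ElementContext(at_trna=True, att_present=True)
        assert type_element(inv, ctx).label == "GI"

    def test_forged_ice_inventory_types_as_ice(self, small_complex):
        g = small_complex.genome("SA01")
        rec = next(t for t in small_complex.truth_for("SA01")
                   if t.element_id == "iE01")
        labels = {x.locus: x.product for x in g.genes if x.locus in rec.genes}
        inv = detect_modules(labels)
        assert type_element(inv, ElementContext(att_present=True,
                                                at_trna=True)).label == "ICE"

    def test_contradictory_context_rejected(self):
        with pytest.raises(ValueError):
            ElementContext(integrated=True, circular=True)


class TestCircularize:
    def test_duplicated_terminus_detected_and_trimmed(self, rng):
        circle = "".join(rng.choice(list("ACGT"), 5000))
        lin = linearize_circle(circle, 120)
        res = circularize_contig(lin)
        assert res.topology == "circular"
        assert res.overlap == 120
        assert res.sequence == circle

    def test_random_linear_contig_stays_linear(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 4000))
        assert circularize_contig(seq).topology == "linear"

    def test_rotated_trim_reproduces_same_circle(self, rng):
        circle = "".join(rng.choice(list("ACGT"), 3000))
        rotated = circle[500:] + circle[:500]
        res = circularize_contig(linearize_circle(rotated, 80))
        assert res.topology == "circular" and len(res.sequence) == 3000


def _naive_circular_digest(seq, site):
    """Position-scanning oracle over the doubled sequence."""
    n = len(seq)
    cuts = sorted({(i + 1) % n for i in range(n)
                   if (seq + seq)[i:i + len(site)] == site})
    if not cuts:
        return [n]
    return sorted(((b - a) % n) or n
                  for a, b in zip(cuts, cuts[1:] + [cuts[0]]))


class TestDigest:
    def test_fragments_sum_to_length_and_match_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), 2000))
            frags = digest(seq, "circular", "GGATCC")
            assert frags == _naive_circular_digest(seq, "GGATCC")
            assert sum(frags) == len(seq)

    def test_paper_geometry_three_bamhi_fragments(self, rng):
        """A 17,826-bp circle with sites spaced to give 3,077 / 4,155 /
        10,594-bp products."""
        backbone = "".join(rng.choice(list("ACGT"), 17_826))
        backbone = backbone.replace("GGATCC", "GGATAC")
        site = "GGATCC"
        pos = [0, 3_077, 3_077 + 4_155]
        seq = backbone
        for p in pos:
            seq = seq[:p] + site + seq[p + 6:]
        frags = digest(seq, "circular", site)
        assert frags == [3_077, 4_155, 10_594]
        assert sum(frags) == 17_826

    def test_linear_has_one_more_fragment_than_sites(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 3000)).replace("GGATCC", "AAAAAA")
        seq = seq[:1000] + "GGATCC" + seq[1006:]
        assert len(digest(seq, "linear", "GGATCC")) == 2

    def test_no_site_circle_returns_full_length(self):
        assert digest("ATATATAT" * 100, "circular", "GGATCC") == [800]

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            digest("ACGT" * 10, "linear", "GGAT?C")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=400),
           st.sampled_from(["GGATCC", "GAATTC", "GRATYC"]))
    def test_conservation_property(self, seq, site):
        assert sum(digest(seq, "circular", site)) == len(seq)
        assert sum(digest(seq, "linear", site)) == len(seq)
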