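"""IS inventory, transposition calling, allele trajectories, depth folds."""
import numpy as np
import pytest

from mobilome.forge import simulate_reseq
from mobilome.isdyn import (detect_insertions, replicon_depth_fold,
                            scan_is_copies, track_alleles)
from mobilome.model import AnnotatedGenome, Gene, ISEvent, Segment


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="module")
def is_seq():
    return _dna(np.random.default_rng(99), 1200)


def _genome_with_copies(rng, is_seq, n_copies, mutate_one_to=None):
    parts, pos = [], []
    for i in range(n_copies):
        parts.append(_dna(rng, 3000))
        copy = is_seq
        if mutate_one_to is not None and i == 0:
            k = int(round((1 - mutate_one_to) * len(is_seq)))
            arr = list(copy)
            for p in rng.choice(len(arr), size=k, replace=False):
                arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
            copy = "".join(arr)
        start = sum(len(x) for x in parts)
        pos.append(start)
        parts.append(copy)
    parts.append(_dna(rng, 3000))
    return AnnotatedGenome("g", {"chr": "".join(parts)}), pos


class TestScanCopies:
    def test_five_exact_copies_counted(self, rng, is_seq):
        g, _ = _genome_with_copies(rng, is_seq, 5)
        copies = scan_is_copies(g, {"ISx": is_seq})
        assert len(copies["ISx"]) == 5

    def test_threshold_semantics_for_degraded_copy(self, rng, is_seq):
        g, _ = _genome_with_copies(rng, is_seq, 3, mutate_one_to=0.85)
        strict = scan_is_copies(g, {"ISx": is_seq}, min_similarity=0.90)
        loose = scan_is_copies(g, {"ISx": is_seq}, min_similarity=0.80)
        assert len(strict["ISx"]) == 2
        assert len(loose["ISx"]) == 3

    def test_count_monotone_nonincreasing_in_similarity(self, rng, is_seq):
        g, _ = _genome_with_copies(rng, is_seq, 4, mutate_one_to=0.93)
        counts = [len(scan_is_copies(g, {"ISx": is_seq},
                                     min_similarity=s)["ISx"])
                  for s in (0.80, 0.90, 0.95, 0.99)]
        assert counts == sorted(counts, reverse=True)

    def test_reverse_strand_copy_found(self, rng, is_seq):
        from mobilome.model import revcomp
        seq = _dna(rng, 2000) + revcomp(is_seq) + _dna(rng, 2000)
        g = AnnotatedGenome("g", {"chr": seq})
        copies = scan_is_copies(g, {"ISx": is_seq})
        assert len(copies["ISx"]) == 1 and copies["ISx"][0].strand == "-"

    def test_empty_library_rejected(self, rng):
        g = AnnotatedGenome("g", {"chr": _dna(rng, 1000)})
        with pytest.raises(ValueError):
            scan_is_copies(g, {})


class TestDetectInsertions:
    def _host(self, rng):
        chrom = _dna(rng, 12_000)
        genes = [Gene(f"g{i:02d}", "chr", i * 1000 + 100, i * 1000 + 950)
                 for i in range(11)]
        return AnnotatedGenome("h", {"chr": chrom}, genes=genes)

    def test_single_event_recovered_at_exact_position(self, rng, is_seq):
        g = self._host(rng)
        ev = ISEvent("ISx", "chr", 5500, dr_len=8)
        bundle = simulate_reseq(g, [ev], depth=40, seed=7,
                                is_library={"ISx": is_seq})
        called = detect_insertions(g, bundle.reads, {"ISx": is_seq})
        assert len(called) == 1
        assert abs(called[0].position - 5500) <= 1
        assert called[0].dr_len == 8
        assert called[0].target_gene == "g05"
        assert called[0].allele_fraction > 0.9

    def test_no_events_simulation_calls_nothing(self, rng, is_seq):
        g = self._host(rng)
        bundle = simulate_reseq(g, [], depth=30, seed=3,
                                is_library={"ISx": is_seq})
        assert detect_insertions(g, bundle.reads, {"ISx": is_seq}) == []

    def test_low_support_not_called(self, rng, is_seq):
        g = self._host(rng)
        ev = ISEvent("ISx", "chr", 5500, dr_len=8, allele_fraction=0.1)
        bundle = simulate_reseq(g, [ev], depth=10, seed=5,
                                is_library={"ISx": is_seq})
        called = detect_insertions(g, bundle.reads, {"ISx": is_seq},
                                   min_support=5)
        assert called == []

    def test_unknown_contig_in_reads_rejected(self, rng, is_seq):
        from mobilome.model import ReadRecord
        g = self._host(rng)
        bad = [ReadRecord("r1", "nope", 0, "100M", "A" * 100)]
        with pytest.raises(ValueError):
            detect_insertions(g, bad, {"ISx": is_seq})


class TestTrackAlleles:
    def test_fifty_fifty_mixture_estimated_within_binomial_error(self, rng,
                                                                 is_seq):
        chrom = _dna(rng, 12_000)
        g = AnnotatedGenome("h", {"chr": chrom})
        ev = ISEvent("ISx", "chr", 6000, dr_len=8, allele_fraction=0.5)
        fractions = []
        for seed in range(20):
            bundle = simulate_reseq(g, [ev], depth=40, seed=seed,
                                    is_library={"ISx": is_seq})
            series = track_alleles(ev, {1: bundle.reads}, {"ISx": is_seq})
            fractions.append(series.points[0].fraction)
        # ~70 informative reads per replicate -> s.e. of the mean ~ 0.013
        assert np.mean(fractions) == pytest.approx(0.5, abs=0.04)

    def test_decay_schedule_loss_called_at_first_undetected_passage(
            self, rng, is_seq):
        chrom = _dna(rng, 12_000)
        g = AnnotatedGenome("h", {"chr": chrom})
        schedule = [1.0, 0.6, 0.3, 0.1, 0.0, 0.0]
        passage_reads = {}
        for i, f in enumerate(schedule, start=1):
            ev = ISEvent("ISx", "chr", 6000, dr_len=8, allele_fraction=f)
            bundle = simulate_reseq(g, [ev], depth=50, seed=100 + i,
                                    is_library={"ISx": is_seq})
            passage_reads[i] = bundle.reads
        ev0 = ISEvent("ISx", "chr", 6000, dr_len=8)
        series = track_alleles(ev0, passage_reads, {"ISx": is_seq})
        fr = series.fractions
        assert fr[0] > 0.9 and fr[4] == 0.0
        assert sorted(fr, reverse=True) == fr
        assert series.loss_passage == 5


class TestDepthFold:
    def test_exact_fold_on_constant_tracks(self):
        depth = {"chr": np.full(10_000, 10), "pls": np.full(2_000, 60)}
        folds = replicon_depth_fold(depth, {"pls": [Segment("pls", 0, 2000)]},
                                    chromosome="chr")
        assert folds["pls"] == 6.0

    @pytest.mark.parametrize("fold", [5.0, 6.0])
    def test_poisson_sampled_fold_within_ten_percent(self, rng, fold):
        g = AnnotatedGenome("x", {"chr": _dna(rng, 20_000),
                                  "pls": _dna(rng, 4_000)},
                            circular={"pls"})
        bundle = simulate_reseq(g, [], depth=30, plasmid_fold=fold,
                                seed=int(fold))
        folds = replicon_depth_fold(bundle.depth,
                                    {"pls": [Segment("pls", 0, 4000)]},
                                    chromosome="chr")
        assert folds["pls"] == pytest.approx(fold, rel=0.10)
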