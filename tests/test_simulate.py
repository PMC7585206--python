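"""Synthetic transcriptome, intermediates, read and matrix simulation."""
import numpy as np
import pytest
from scipy import stats

from spliceorder.fragments import detect_order_pairs
from spliceorder.matrix import PairCountMatrix, retention_percentage
from spliceorder.model import SplicingOrder
from spliceorder.simulate import (
    SimReadConfig,
    SimTranscriptomeConfig,
    assign_random_orders,
    enumerate_intermediates,
    erase_pairs,
    generate_transcriptome,
    simulate_fragments,
    simulate_matrix,
    write_fasta,
    write_gtf,
)


class TestTranscriptome:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimTranscriptomeConfig(n_transcripts=5)
        outs = []
        for tag in ("a", "b"):
            genome, models = generate_transcriptome(cfg, seed=42)
            fa, gtf = tmp_path / f"{tag}.fa", tmp_path / f"{tag}.gtf"
            write_fasta(genome, str(fa))
            write_gtf(models, str(gtf))
            outs.append((fa.read_bytes(), gtf.read_bytes()))
        assert outs[0] == outs[1]

    def test_counts_and_length_bounds(self):
        cfg = SimTranscriptomeConfig(n_transcripts=10, intron_count_min=3, intron_count_max=5)
        genome, models = generate_transcriptome(cfg, seed=0)
        assert len(models) == 10
        for m in models:
            assert 3 <= m.n_introns <= 5
            for i in m.introns:
                assert cfg.intron_length_min <= i.length <= cfg.intron_length_max
        # transcripts do not overlap
        spans = sorted((m.span.start, m.span.end) for m in models)
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))

    def test_round_trip_through_gtf_parser(self, tmp_path):
        from spliceorder.annotation import parse_annotation

        genome, models = generate_transcriptome(SimTranscriptomeConfig(n_transcripts=4), 3)
        path = tmp_path / "sim.gtf"
        write_gtf(models, str(path))
        parsed = {m.transcript_id: m for m in parse_annotation(str(path))}
        for m in models:
            p = parsed[m.transcript_id]
            assert p.strand == m.strand
            assert [(e.start, e.end) for e in p.exons] == [(e.start, e.end) for e in m.exons]
            assert [(i.index, i.interval.start) for i in p.introns] == [
                (i.index, i.interval.start) for i in m.introns
            ]


class TestRandomOrders:
    def test_seed_reproducibility(self):
        _, models = generate_transcriptome(SimTranscriptomeConfig(n_transcripts=6), 1)
        assert assign_random_orders(models, 9) == assign_random_orders(models, 9)

    def test_uniform_over_permutations(self):
        """Chi-square goodness of fit over the 6 orders of a 3-intron transcript."""
        rng = np.random.default_rng(5)
        from collections import Counter

        tally = Counter(tuple(rng.permutation(3) + 1) for _ in range(60_000))
        # same draw path as assign_random_orders: rng.permutation per transcript
        observed = np.array([tally[p] for p in sorted(tally)])
        assert len(observed) == 6
        chi2 = ((observed - 10_000.0) ** 2 / 10_000.0).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=5)


class TestIntermediates:
    def test_species_count_and_lengths(self, four_intron_transcript):
        theta = SplicingOrder((2, 4, 1, 3))
        species = enumerate_intermediates(four_intron_transcript, theta)
        assert len(species) == 5
        assert species[0].length == len(four_intron_transcript.span)
        assert species[-1].length == sum(len(e) for e in four_intron_transcript.exons)
        lengths = [s.length for s in species]
        assert lengths == sorted(lengths, reverse=True)

    def test_first_species_lacks_only_first_intron_of_theta(self, four_intron_transcript):
        theta = SplicingOrder((2, 1, 3, 4))
        s1 = enumerate_intermediates(four_intron_transcript, theta)[1]
        intron2 = four_intron_transcript.intron_by_index(2).interval
        assert s1.spliced_introns == [(intron2.start, intron2.end)]


class TestReadSimulation:
    def test_unspliced_species_has_no_gaps(self, four_intron_transcript, rng):
        theta = SplicingOrder((1, 2, 3, 4))
        cfg = SimReadConfig(mode="long_read", read_length=2000, fragment_mean=2000, depth=50)
        frags = simulate_fragments(four_intron_transcript, theta, cfg, rng)
        species0 = [f for f in frags if ":s0:" in f.fragment_id]
        assert species0 and all(not f.gaps for f in species0)

    def test_gaps_match_annotated_introns_exactly(self, four_intron_transcript, rng):
        theta = SplicingOrder((3, 1, 4, 2))
        cfg = SimReadConfig(mode="short_pe", read_length=100, fragment_mean=400, depth=50)
        annotated = {(i.interval.start, i.interval.end) for i in four_intron_transcript.introns}
        for f in simulate_fragments(four_intron_transcript, theta, cfg, rng):
            assert set(f.gaps) <= annotated

    def test_detected_pairs_consistent_with_theta(self, four_intron_transcript, rng):
        """Round-trip oracle: simulated evidence never contradicts the true order."""
        theta = SplicingOrder((2, 4, 1, 3))
        rank = theta.rank
        cfg = SimReadConfig(mode="long_read", read_length=900, fragment_mean=900, depth=300)
        frags = simulate_fragments(four_intron_transcript, theta, cfg, rng)
        assert len(frags) > 1000
        n_pairs = 0
        for f in frags:
            for obs in detect_order_pairs(f, four_intron_transcript):
                n_pairs += 1
                assert rank[obs.earlier_intron - 1] < rank[obs.later_intron - 1]
        assert n_pairs > 0

    def test_paired_modes_emit_two_mates(self, four_intron_transcript, rng):
        from spliceorder.simulate import simulate_reads

        theta = SplicingOrder((1, 2, 3, 4))
        cfg = SimReadConfig(mode="mate_pair", read_length=80, fragment_mean=600, depth=20)
        reads = simulate_reads(four_intron_transcript, theta, cfg, rng)
        assert {r.mate for r in reads} <= {1, 2}

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimReadConfig(mode="short_pe", read_length=500, fragment_mean=400)
        with pytest.raises(ValueError):
            SimReadConfig(mode="nanopore")


class TestMatrixSimulation:
    def test_inconsistent_direction_always_zero(self, rng):
        theta = SplicingOrder((3, 1, 2))
        rank = theta.rank
        for _ in range(20):
            cm = simulate_matrix(3, theta, 15.0, rng)
            for i in range(1, 4):
                for j in range(1, 4):
                    if i != j and rank[i - 1] > rank[j - 1]:
                        assert cm[i, j] == 0

    def test_poisson_mean(self, rng):
        draws = [simulate_matrix(2, SplicingOrder((1, 2)), 15.0, rng)[1, 2]
                 for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(15.0, abs=0.5)

    def test_seed_reproducibility(self):
        a = simulate_matrix(5, SplicingOrder((5, 4, 3, 2, 1)), 15.0, 11)
        b = simulate_matrix(5, SplicingOrder((5, 4, 3, 2, 1)), 15.0, 11)
        assert np.array_equal(a.A, b.A)


class TestErasePairs:
    @pytest.fixture
    def full(self, rng):
        return simulate_matrix(4, SplicingOrder((2, 1, 4, 3)), 15.0, rng)

    def test_boundaries(self, full):
        assert np.array_equal(erase_pairs(full, 1.0, 0).A, full.A)
        assert not erase_pairs(full, 0.0, 0).A.any()

    def test_exact_pair_count(self, full):
        out = erase_pairs(full, 0.5, 3)
        assert retention_percentage(out) == pytest.approx(0.5)

    def test_retention_tracks_fraction(self, rng):
        cm = simulate_matrix(7, SplicingOrder(tuple(range(1, 8))), 15.0, rng)
        out = erase_pairs(cm, 0.8, rng)
        assert retention_percentage(out) == pytest.approx((21 - round(0.2 * 21)) / 21)
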