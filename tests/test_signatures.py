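"""Length/positional profiles, overlap histograms and ping-pong statistics."""

import math

import numpy as np
import pytest

from pirnakit.io import CollapsedReadSet, ConfigError
from pirnakit.mapping import ExactMatchIndex, HitTable, assign_weights, map_perfect
from pirnakit.signatures import (
    OverlapHistogram,
    length_distribution,
    overlap_histogram,
    pingpong_result,
    pingpong_z,
    positional_nt_freq,
    twofold_rule,
)


def make_hits(entries, counts=None):
    """Build a HitTable directly from (strand, five_prime, count, weight) rows."""
    n = len(entries)
    # unique placeholder 20-mers (binary index spelled in A/C)
    seqs = [format(i, "020b").replace("0", "A").replace("1", "C") for i in range(n)]
    counts = np.array([e[2] for e in entries])
    reads = CollapsedReadSet(seqs, counts)
    strand = np.array([e[0] for e in entries], dtype="U1")
    L = 20
    fp = np.array([e[1] for e in entries])
    start = np.where(strand == "+", fp, fp - L + 1)
    table = HitTable(
        reads=reads,
        ref_names=["ref"],
        seq_index=np.arange(n),
        ref_index=np.zeros(n, dtype=int),
        strand=strand,
        start=start,
        end=start + L,
        hit_counts=np.ones(n, dtype=int),
        weights=np.array([e[3] for e in entries], dtype=float),
    )
    return table


class TestLengthDistribution:
    def test_by_read_count_vs_unique(self):
        reads = CollapsedReadSet(["A" * 30, "C" * 28], np.array([3, 1]))
        by_count = length_distribution(reads, "by_read_count")
        assert by_count.to_dict() == {28: 1, 30: 3}
        by_unique = length_distribution(reads, "by_unique_sequence")
        assert by_unique.to_dict() == {28: 1, 30: 1}

    def test_simulated_mode_at_30(self):
        rng = np.random.default_rng(0)
        lengths = np.clip(np.round(rng.normal(30, 1.5, size=100_000)), 24, 33).astype(int)
        # unique sequences per length bucket via synthetic reads
        seqs = {}
        for L, n in zip(*np.unique(lengths, return_counts=True)):
            seqs["A" * int(L)] = int(n)
        reads = CollapsedReadSet(list(seqs), np.array(list(seqs.values())))
        dist = length_distribution(reads, "by_read_count")
        assert dist.idxmax() == 30


class TestPositionalFreq:
    def test_all_u_start(self):
        reads = CollapsedReadSet(["T" * 30], np.array([1]))
        prof = positional_nt_freq(reads)
        assert prof.rate_1U == 1.0

    def test_unique_sequence_weighting(self):
        reads = CollapsedReadSet(["T" + "ACG" * 8, "A" + "ACG" * 8], np.array([9, 1]))
        prof = positional_nt_freq(reads, weighting="unique")
        assert prof.rate_1U == pytest.approx(0.5)
        prof_c = positional_nt_freq(reads, weighting="count")
        assert prof_c.rate_1U == pytest.approx(0.9)

    def test_binomial_recovery_of_configured_rate(self):
        rng = np.random.default_rng(1)
        n = 100_000
        firsts = np.where(rng.random(n) < 0.8, "T", "G")
        seqs = set()
        reads = []
        for i, b in enumerate(firsts):
            reads.append(b + format(i, "024b").replace("0", "A").replace("1", "C"))
        rs = CollapsedReadSet.from_sequences(reads)
        prof = positional_nt_freq(rs, weighting="unique")
        assert abs(prof.rate_1U - 0.8) < 0.02

    def test_positions_beyond_read_length_excluded(self):
        reads = CollapsedReadSet(["T" * 20, "G" * 30], np.array([1, 1]))
        prof = positional_nt_freq(reads)
        assert prof.freqs.loc[25, "G"] == 1.0  # only the 30-mer reaches position 25
        assert prof.freqs.loc[10, "T"] == 0.5


class TestOverlapHistogram:
    def test_pingpong_pair_geometry(self):
        table = make_hits([("+", 100, 2, 1.0), ("-", 109, 3, 1.0)])
        hist = overlap_histogram(table)
        assert hist.s(10) == pytest.approx(6.0)
        assert hist.scores.sum() == pytest.approx(6.0)

    def test_orientation_contract_negative_overlap(self):
        table = make_hits([("-", 100, 2, 1.0), ("+", 109, 3, 1.0)])
        hist = overlap_histogram(table)
        assert hist.scores.sum() == 0.0
        assert hist.is_empty

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        entries = [
            ("+" if rng.random() < 0.5 else "-", int(rng.integers(50, 4950)),
             int(rng.integers(1, 4)), float(rng.choice([1.0, 0.5, 0.25])))
            for _ in range(n)
        ]
        table = make_hits(entries)
        hist = overlap_histogram(table, o_max=20)
        oracle = np.zeros(20)
        for s_str, s_fp, s_c, s_w in entries:
            if s_str != "+":
                continue
            for a_str, a_fp, a_c, a_w in entries:
                if a_str != "-":
                    continue
                o = a_fp - s_fp + 1
                if 1 <= o <= 20:
                    oracle[o - 1] += (s_c * s_w) * (a_c * a_w)
        np.testing.assert_allclose(hist.scores, oracle, atol=1e-9)


class TestPingPongZ:
    def test_flat_histogram_gives_zero(self):
        hist = OverlapHistogram(np.full(20, 5.0), n_pairs=100)
        assert pingpong_z(hist) == 0.0

    def test_zero_variance_background_is_nan_and_falls_back(self):
        scores = np.zeros(20)
        scores[9] = 100.0
        hist = OverlapHistogram(scores, n_pairs=10)
        assert math.isnan(pingpong_z(hist))
        res = pingpong_result(hist)
        assert res.twofold and res.evident

    def test_hand_computed_example(self):
        # bins 1-9 = 8, bin 10 = 30, bins 11-20 = 12
        scores = np.array([8.0] * 9 + [30.0] + [12.0] * 10)
        hist = OverlapHistogram(scores, n_pairs=1)
        background = [8.0] * 9 + [12.0] * 10
        mu = sum(background) / 19
        sd = math.sqrt(sum((x - mu) ** 2 for x in background) / 18)
        assert pingpong_z(hist) == pytest.approx((30 - mu) / sd)
        assert pingpong_z(hist) == pytest.approx(9.70, abs=0.01)

    def test_invariant_under_uniform_scaling(self):
        rng = np.random.default_rng(2)
        scores = rng.random(20) * 10
        h1 = OverlapHistogram(scores, 1)
        h2 = OverlapHistogram(scores * 37.5, 1)
        assert pingpong_z(h1) == pytest.approx(pingpong_z(h2))

    def test_short_histogram_rejected(self):
        with pytest.raises(ConfigError):
            pingpong_z(OverlapHistogram(np.ones(10), 1))


class TestTwofoldRule:
    @pytest.mark.parametrize(
        "s10,next_highest,expected",
        [(20.0, 10.0, True), (19.0, 10.0, False), (0.0, 0.0, False)],
    )
    def test_boundary_inclusive(self, s10, next_highest, expected):
        scores = np.zeros(20)
        scores[9] = s10
        scores[4] = next_highest
        assert twofold_rule(OverlapHistogram(scores, 1)) is expected


class TestNullAndAlternative:
    """Behavior of z under uniform placement vs planted ping-pong pairs."""

    @staticmethod
    def _uniform_hits(rng, n=600, span=50_000):
        entries = [
            ("+" if rng.random() < 0.5 else "-", int(rng.integers(30, span)), 1, 1.0)
            for _ in range(n)
        ]
        return make_hits(entries)

    @staticmethod
    def _planted_hits(rng, n_pairs, n_background=300, span=50_000):
        entries = []
        for _ in range(n_pairs):
            p = int(rng.integers(30, span))
            entries.append(("+", p, 1, 1.0))
            entries.append(("-", p + 9, 1, 1.0))
        for _ in range(n_background):
            entries.append(
                ("+" if rng.random() < 0.5 else "-", int(rng.integers(30, span)), 1, 1.0)
            )
        return make_hits(entries)

    def test_null_z_mostly_small(self):
        small = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            z = pingpong_z(overlap_histogram(self._uniform_hits(rng)))
            if not math.isfinite(z) or abs(z) < 2:
                small += 1
        assert small >= 27  # >= 90% of null runs below |z| = 2

    def test_planted_pairs_give_large_z(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            z = pingpong_z(overlap_histogram(self._planted_hits(rng, n_pairs=200)))
            assert z > 5
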