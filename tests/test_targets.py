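"""Gene coverage, per-gene ping-pong and the homolog-overlap permutation test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pirnakit.io import CollapsedReadSet, GeneModel, reverse_complement
from pirnakit.targets import (
    build_transcriptome,
    call_targets,
    gene_coverage,
    gene_pingpong,
    homolog_overlap_test,
    map_to_transcripts,
)


def _random_tx(rng, L=3_000):
    return "".join(rng.choice(list("ACGT"), size=L))


class TestGeneCoverage:
    def test_rpm_definition_and_threshold(self):
        rng = np.random.default_rng(0)
        tx = {"G1": _random_tx(rng)}
        seqs = [tx["G1"][40 * i : 40 * i + 30] for i in range(12)]
        reads = CollapsedReadSet(seqs, np.ones(12, dtype=int))
        table = map_to_transcripts(reads, tx)
        cov = gene_coverage(table, total_mapped_reads=1_000_000)
        assert cov.loc["G1", "rpm"] == pytest.approx(12.0)
        results = call_targets(table, 1_000_000, rpm_threshold=10.0)
        assert results[0].rpm >= 10.0

    def test_below_threshold_excluded(self):
        rng = np.random.default_rng(1)
        tx = {"G1": _random_tx(rng)}
        seqs = [tx["G1"][40 * i : 40 * i + 30] for i in range(9)]
        reads = CollapsedReadSet(seqs, np.ones(9, dtype=int))
        table = map_to_transcripts(reads, tx)
        results = call_targets(table, 1_000_000, rpm_threshold=10.0)
        assert results[0].is_target is False
        assert results[0].pingpong is None  # never tested for a signature

    def test_zero_library_size_rejected(self):
        rng = np.random.default_rng(2)
        tx = {"G1": _random_tx(rng)}
        reads = CollapsedReadSet([tx["G1"][:30]], np.array([1]))
        with pytest.raises(ValueError):
            gene_coverage(map_to_transcripts(reads, tx), 0)

    def test_longest_isoform_selected(self):
        genome = {"chr1": _random_tx(np.random.default_rng(3), 10_000)}
        short = GeneModel("G1", "T1", "chr1", "+", [(100, 400)])
        long = GeneModel("G1", "T2", "chr1", "+", [(100, 400), (1_000, 1_800)])
        tx, models = build_transcriptome([short, long], genome)
        assert models["G1"].transcript_id == "T2"
        assert len(tx["G1"]) == 1_100


class TestGenePingpong:
    def _pair_table(self, rng, n_pairs, n_sense_only=0):
        tx_seq = _random_tx(rng, 5_000)
        tx = {"G1": tx_seq}
        seqs = []
        for _ in range(n_pairs):
            p = int(rng.integers(100, 4_800))
            L = int(rng.integers(26, 31))
            sense = tx_seq[p : p + L]
            anti = reverse_complement(tx_seq[p + 10 - L : p + 10])  # 5' at p+9
            seqs += [sense, anti]
        for _ in range(n_sense_only):
            p = int(rng.integers(100, 4_800))
            seqs.append(tx_seq[p : p + 28])
        reads = CollapsedReadSet.from_sequences(seqs)
        return map_to_transcripts(reads, tx)

    def test_planted_pairs_make_target(self):
        table = self._pair_table(np.random.default_rng(7), n_pairs=500)
        res = gene_pingpong(table, "G1")
        assert res.twofold and res.evident
        assert res.z > 5

    def test_sense_only_gene_not_target(self):
        rng = np.random.default_rng(8)
        tx_seq = _random_tx(rng, 5_000)
        seqs = [tx_seq[int(rng.integers(0, 4_900)) :][:28] for _ in range(300)]
        reads = CollapsedReadSet.from_sequences(seqs)
        table = map_to_transcripts(reads, {"G1": tx_seq})
        res = gene_pingpong(table, "G1")
        assert res.histogram.is_empty
        assert not res.evident


def exact_one_to_one(NA, NB, n1, n2, targets_a_matched, x_obs):
    """Exact E(X) and tail by full enumeration (one-to-one pairing i<->i)."""
    xs = []
    for A in itertools.combinations(range(NA), n1):
        for B in itertools.combinations(range(NB), n2):
            x = len(set(A) & set(B))  # partner of i is i
            xs.append(x)
    xs = np.array(xs)
    return xs.mean(), float((xs >= x_obs).mean())


class TestHomologOverlap:
    def test_spec_toy_example(self):
        universe = [f"g{i}" for i in range(4)]
        other = [f"h{i}" for i in range(4)]
        homology = list(zip(universe, other))
        res = homolog_overlap_test(
            ["g0", "g1"], ["h0", "h1"], homology, universe, other,
            draws=200_000, seed=0,
        )
        assert res.observed == 2
        assert res.expected == pytest.approx(1.0, abs=0.01)
        assert res.p_value == pytest.approx(1 / 6, abs=0.01)

    def test_disjoint_overlap_p_one(self):
        ua = [f"a{i}" for i in range(6)]
        ub = [f"b{i}" for i in range(6)]
        homology = [("a0", "b0")]
        res = homolog_overlap_test(["a1"], ["b1"], homology, ua, ub, draws=1_000, seed=1)
        assert res.observed == 0
        assert res.p_value == 1.0

    def test_seeded_runs_bit_reproducible(self):
        ua = [f"a{i}" for i in range(20)]
        ub = [f"b{i}" for i in range(20)]
        hom = list(zip(ua, ub))
        r1 = homolog_overlap_test(ua[:5], ub[:5], hom, ua, ub, draws=10_000, seed=42)
        r2 = homolog_overlap_test(ua[:5], ub[:5], hom, ua, ub, draws=10_000, seed=42)
        assert (r1.expected, r1.p_value) == (r2.expected, r2.p_value)

    def test_target_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            homolog_overlap_test(["x"], [], [], ["a"], ["b"], draws=10, seed=0)

    @pytest.mark.parametrize("seed", range(3))
    def test_calibration_against_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        NA = NB = 8
        n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        ua = [f"a{i}" for i in range(NA)]
        ub = [f"b{i}" for i in range(NB)]
        hom = list(zip(ua, ub))
        ta = [f"a{i}" for i in range(n1)]
        tb = [f"b{i}" for i in range(n2)]
        draws = 50_000
        res = homolog_overlap_test(ta, tb, hom, ua, ub, draws=draws, seed=seed)
        e_exact, p_exact = exact_one_to_one(NA, NB, n1, n2, None, res.observed)
        var = stats.hypergeom(NA, n1, n2).var()
        assert abs(res.expected - e_exact) < 3 * math.sqrt(var / draws) + 1e-9
        se_p = math.sqrt(p_exact * (1 - p_exact) / draws)
        assert abs(res.p_value - p_exact) < 3 * se_p + 2 / draws

    def test_many_to_many_collapsed_on_a_side(self):
        ua = ["a0", "a1"]
        ub = ["b0", "b1", "b2"]
        hom = [("a0", "b0"), ("a0", "b1"), ("a1", "b2")]
        res = homolog_overlap_test(["a0"], ["b0", "b1"], hom, ua, ub, draws=1_000, seed=0)
        assert res.observed == 1  # a0 counted once despite two drawn homologs
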