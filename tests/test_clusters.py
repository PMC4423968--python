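"""Sliding-window cluster detection against a brute-force oracle, plus
directionality, content and TE strand-bias checks."""

import numpy as np
import pandas as pd
import pytest

from pirnakit.clusters import (
    ClusterCall,
    ClusterParams,
    call_directionality,
    cluster_content,
    scan_clusters,
    te_strand_bias,
)
from pirnakit.io import CollapsedReadSet, GeneModel, RepeatAnnotation
from pirnakit.mapping import HitTable


def synth_hits(rows, ref_names, counts=None, weights=None):
    """HitTable from (ref_idx, strand, five_prime, length, pirna_like) rows.

    pirna_like reads are 24-32 nt with a 5' T; others are 20 nt starting G.
    """
    n = len(rows)
    seqs = []
    for i, (_, _, _, length, pirna_like) in enumerate(rows):
        tag = format(i, "b").replace("0", "A").replace("1", "C")
        head = "T" if pirna_like else "G"
        body = (head + "A" * 9).ljust(10, "A")
        seqs.append((body + tag).ljust(length, "G")[:length])
    assert len(set(seqs)) == n
    counts = np.ones(n, dtype=np.int64) if counts is None else np.asarray(counts)
    weights = np.ones(n, dtype=float) if weights is None else np.asarray(weights)
    reads = CollapsedReadSet(seqs, counts)
    strand = np.array([r[1] for r in rows], dtype="U1")
    fp = np.array([r[2] for r in rows])
    length = np.array([r[3] for r in rows])
    start = np.where(strand == "+", fp, fp - length + 1)
    return HitTable(
        reads=reads,
        ref_names=ref_names,
        seq_index=np.arange(n),
        ref_index=np.array([r[0] for r in rows]),
        strand=strand,
        start=start,
        end=start + length,
        hit_counts=np.ones(n, dtype=np.int64),
        weights=weights,
    )


def brute_force_scan(hits, genome_lengths, params: ClusterParams):
    """Naive re-implementation of the window rules: loop every window."""
    mass = hits.hit_mass
    fp = hits.five_prime
    lengths = hits.reads.lengths
    size_ok = np.array([(24 <= lengths[s] <= 32) for s in hits.seq_index])
    bias_ok = np.array(
        [
            hits.reads.sequences[s][0] == "T"
            or (len(hits.reads.sequences[s]) >= 10 and hits.reads.sequences[s][9] == "A")
            for s in hits.seq_index
        ]
    )

    def window_starts(L):
        n_bins = (L + params.step - 1) // params.step
        n_win = n_bins - params.window // params.step + 1
        return [i * params.step for i in range(max(0, n_win))]

    all_masses = []
    per_chrom = {}
    for ci, chrom in enumerate(hits.ref_names):
        L = genome_lengths.get(chrom)
        if L is None or L < params.window:
            continue
        rows = []
        on = hits.ref_index == ci
        for ws in window_starts(L):
            we = ws + params.window
            sel = on & (fp >= ws) & (fp < we)
            m = float(mass[sel].sum())
            rows.append((ws, m, float(mass[sel & size_ok].sum()), float(mass[sel & bias_ok].sum())))
            all_masses.append(m)
        per_chrom[chrom] = (L, rows)
    if not per_chrom:
        return []
    bg_density = float(np.median(all_masses)) / (params.window / 1000.0)
    thr = params.density_factor * bg_density
    calls = []
    for chrom, (L, rows) in per_chrom.items():
        qual = []
        for ws, m, m_size, m_bias in rows:
            dens = m / (params.window / 1000.0)
            if (
                m >= params.min_window_mass
                and dens >= thr
                and (m > 0 and m_size / m >= params.pirna_size_frac)
                and (m > 0 and m_bias / m >= params.bias_frac)
            ):
                qual.append(ws)
        merged = []
        for ws in qual:
            we = ws + params.window
            if merged and ws <= merged[-1][1] + params.step:
                merged[-1][1] = we
            else:
                merged.append([ws, we])
        ci = hits.ref_names.index(chrom)
        on_chrom = hits.ref_index == ci
        for s, e in merged:
            e = min(e, L)
            inside = on_chrom & (fp >= s) & (fp < e)
            if not inside.any():
                continue
            ts = max(0, int(hits.start[inside].min()))
            te = min(L, int(hits.end[inside].max()))
            if te - ts >= params.min_size:
                calls.append((chrom, ts, te))
    return sorted(calls)


class TestScanOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_windows(self, seed):
        rng = np.random.default_rng(seed)
        L = 60_000
        params = ClusterParams(min_size=5_000, min_window_mass=3.0)
        rows = []
        # one dense piRNA-like block + uniform background
        bs = int(rng.integers(5_000, 40_000))
        blen = int(rng.integers(6_000, 15_000))
        for _ in range(int(rng.integers(200, 400))):
            p = int(rng.integers(bs, bs + blen))
            rows.append((0, "+" if rng.random() < 0.8 else "-", p, 30, True))
        for _ in range(int(rng.integers(10, 40))):
            rows.append(
                (0, "+" if rng.random() < 0.5 else "-", int(rng.integers(0, L - 40)),
                 30 if rng.random() < 0.5 else 20, rng.random() < 0.5)
            )
        hits = synth_hits(rows, ["chrA"])
        calls = scan_clusters(hits, {"chrA": L}, params)
        got = sorted((c.chrom, c.start, c.end) for c in calls)
        assert got == brute_force_scan(hits, {"chrA": L}, params)

    def test_planted_region_recovered_within_1kb(self):
        rng = np.random.default_rng(42)
        L = 100_000
        rows = []
        # planted 20-kb region at 50 reads/kb over 0.1/kb background
        for _ in range(1000):
            rows.append((0, "+" if rng.random() < 0.9 else "-",
                         int(rng.integers(50_000, 70_000)), 30, True))
        for _ in range(10):
            rows.append((0, "+", int(rng.integers(0, L - 40)), 30, True))
        hits = synth_hits(rows, ["chrA"])
        calls = scan_clusters(hits, {"chrA": L}, ClusterParams())
        assert len(calls) == 1
        assert abs(calls[0].start - 50_000) <= 1000
        assert abs(calls[0].end - 70_000) <= 1000

    def test_sub_10kb_dense_region_not_called(self):
        rng = np.random.default_rng(1)
        rows = [(0, "+", int(rng.integers(20_000, 28_000)), 30, True) for _ in range(500)]
        hits = synth_hits(rows, ["chrA"])
        assert scan_clusters(hits, {"chrA": 100_000}, ClusterParams()) == []

    def test_empty_chromosome(self):
        hits = synth_hits([], ["chrA"])
        assert scan_clusters(hits, {"chrA": 50_000}, ClusterParams()) == []

    def test_invariant_to_hit_order(self):
        rng = np.random.default_rng(5)
        rows = [(0, "+", int(rng.integers(30_000, 45_000)), 30, True) for _ in range(600)]
        rows += [(0, "-", int(rng.integers(0, 99_000)), 30, True) for _ in range(20)]
        hits = synth_hits(rows, ["chrA"])
        perm = rng.permutation(len(rows))
        shuffled = synth_hits([rows[i] for i in perm], ["chrA"])
        a = [(c.start, c.end, c.directionality) for c in scan_clusters(hits, {"chrA": 100_000})]
        b = [(c.start, c.end, c.directionality) for c in scan_clusters(shuffled, {"chrA": 100_000})]
        assert a == b

    def test_window_smaller_than_step_rejected(self):
        with pytest.raises(Exception):
            ClusterParams(window=50, step=100)


class TestDirectionality:
    def _cluster_with_split(self, frac_plus):
        n = 400
        n_plus = int(round(n * frac_plus))
        rows = [(0, "+", 1000 + 7 * i, 30, True) for i in range(n_plus)]
        rows += [(0, "-", 1200 + 7 * i, 30, True) for i in range(n - n_plus)]
        hits = synth_hits(rows, ["chrA"])
        call = ClusterCall("chrA", 0, 20_000)
        return call_directionality(call, hits), rows

    def test_ninety_percent_plus_is_mono_plus(self):
        assert self._cluster_with_split(0.9)[0] == "mono_plus"

    def test_sixty_forty_is_bidirectional(self):
        assert self._cluster_with_split(0.6)[0] == "bidirectional"

    def test_exact_threshold_is_mono(self):
        assert self._cluster_with_split(0.75)[0] == "mono_plus"

    def test_divergent_arms_detected(self):
        # minus reads left of 10 kb, plus reads right of it: switch point found
        rows = [(0, "-", 2000 + 11 * i, 30, True) for i in range(300)]
        rows += [(0, "+", 12_000 + 11 * i, 30, True) for i in range(300)]
        hits = synth_hits(rows, ["chrA"])
        call = ClusterCall("chrA", 0, 20_000)
        assert call_directionality(call, hits) == "bidirectional"
        assert call.arm_strands == ("-", "+")
        assert abs(call.switch_point - 11_000) <= 2000
        assert call.main_strand_at(3000) == "-"
        assert call.main_strand_at(15_000) == "+"


class TestClusterContent:
    def _repeats(self, rows):
        return RepeatAnnotation(
            pd.DataFrame(rows, columns=RepeatAnnotation.COLUMNS)
        )

    def test_antisense_gene_and_exon_share(self):
        cluster = ClusterCall("chrA", 0, 20_000, directionality="mono_plus")
        gene = GeneModel("G1", "T1", "chrA", "-", [(5_000, 7_000)])
        out = cluster_content([cluster], [gene], RepeatAnnotation.empty(), {"chrA": 100_000})
        row = out.iloc[0]
        assert row.exon_frac == pytest.approx(0.10)
        assert "G1|protein_coding|antisense" in row.embedded_genes
        assert row.n_antisense_genes == 1

    def test_te_enrichment_ratio(self):
        # family at 20% of cluster bp but 10% of genome bp -> ratio 2
        cluster = ClusterCall("chrA", 0, 20_000, directionality="mono_plus")
        rows = [("chrA", 0, 4_000, "+", "FAM", "LTR/X", 10.0),
                ("chrA", 50_000, 56_000, "+", "FAM", "LTR/X", 10.0)]
        out = cluster_content([cluster], [], self._repeats(rows), {"chrA": 100_000})
        assert out.attrs["te_enrichment"]["FAM"] == pytest.approx(0.2 / 0.1)
        assert out.iloc[0].te_frac == pytest.approx(0.2)

    def test_no_annotations_all_zero(self):
        cluster = ClusterCall("chrA", 0, 10_000)
        out = cluster_content([cluster], [], RepeatAnnotation.empty(), {"chrA": 50_000})
        row = out.iloc[0]
        assert row.te_frac == 0 and row.exon_frac == 0 and row.embedded_genes == ""


class TestTEStrandBias:
    def _setup(self, copy_strands, read_strands):
        cluster = ClusterCall("chrA", 0, 50_000, directionality="mono_plus")
        rm_rows = [
            ("chrA", 1_000 + 2_000 * i, 1_500 + 2_000 * i, s, "FAM", "LTR/X", 5.0)
            for i, s in enumerate(copy_strands)
        ]
        repeats = RepeatAnnotation(pd.DataFrame(rm_rows, columns=RepeatAnnotation.COLUMNS))
        rows = [
            (0, rs, 1_100 + 2_000 * i, 30, True)
            for i, rs in enumerate(read_strands)
        ]
        hits = synth_hits(rows, ["chrA"])
        return [cluster], repeats, hits

    def test_fully_sense(self):
        clusters, repeats, hits = self._setup(["+"] * 4, ["+"] * 4)
        out = te_strand_bias(clusters, repeats, hits)
        assert out.iloc[0].copy_sense_fraction == 1.0
        assert out.iloc[0].read_sense_fraction == 1.0

    def test_half_half(self):
        clusters, repeats, hits = self._setup(["+", "+", "-", "-"], ["+", "-", "+", "-"])
        out = te_strand_bias(clusters, repeats, hits)
        assert out.iloc[0].copy_sense_fraction == 0.5
        assert out.iloc[0].read_sense_fraction == 0.5
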