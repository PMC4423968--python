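"""ncRNA classification precedence and genomic feature partition."""

import numpy as np
import pandas as pd
import pytest

from pirnakit.annotate import classify_ncrna, partition_genomic, te_composition
from pirnakit.io import CollapsedReadSet, ConfigError, GeneModel, RepeatAnnotation, reverse_complement
from pirnakit.mapping import ExactMatchIndex, assign_weights, map_perfect


def rm(rows):
    return RepeatAnnotation(pd.DataFrame(rows, columns=RepeatAnnotation.COLUMNS))


class TestClassifyNcrna:
    _rng = np.random.default_rng(123)
    TRNA = "T" + "".join(_rng.choice(list("ACGT"), size=72))
    RRNA = "G" + "".join(_rng.choice(list("ACGT"), size=120))

    def test_mirna_match_excluded_from_pirna(self):
        mir = "TGAGGTAGTAGGTTGTATAGTT"
        reads = CollapsedReadSet([mir], np.array([5]))
        labels = classify_ncrna(reads, {"miRNA": {"mir-1": mir}})
        assert labels[0] == "miRNA"

    def test_trna_wins_over_rrna(self):
        shared = "ACGTACGTACGTACGTACGTACGT"
        sets = {
            "tRNA": {"t": "GG" + shared + "CC"},
            "rRNA": {"r": "TT" + shared + "AA"},
        }
        reads = CollapsedReadSet([shared], np.array([1]))
        assert classify_ncrna(reads, sets)[0] == "tRNA"

    def test_unmatched_is_putative_pirna(self):
        reads = CollapsedReadSet(["TTTTGGGGCCCCAAAATTTTGGGG"], np.array([1]))
        assert classify_ncrna(reads, {"tRNA": {"t": self.TRNA}})[0] == "putative_piRNA"

    def test_sense_only_matching(self):
        frag = self.TRNA[5:35]
        anti = reverse_complement(frag)
        reads = CollapsedReadSet([frag, anti], np.array([1, 1]))
        labels = classify_ncrna(reads, {"tRNA": {"t": self.TRNA}})
        assert labels[0] == "tRNA"
        assert labels[1] == "putative_piRNA"

    def test_unknown_label_rejected(self):
        reads = CollapsedReadSet(["A" * 24], np.array([1]))
        with pytest.raises(ConfigError):
            classify_ncrna(reads, {"lncRNA": {"x": "A" * 100}})

    def test_idempotent_and_order_independent(self):
        seqs = [self.TRNA[i : i + 25] for i in range(0, 30, 6)]
        reads = CollapsedReadSet(seqs, np.ones(len(seqs), dtype=int))
        sets1 = {"tRNA": {"t": self.TRNA}, "rRNA": {"r": self.RRNA}}
        sets2 = {"rRNA": {"r": self.RRNA}, "tRNA": {"t": self.TRNA}}
        assert list(classify_ncrna(reads, sets1)) == list(classify_ncrna(reads, sets2))


def _mapped_hits(genome, seqs, counts=None):
    reads = CollapsedReadSet(seqs, np.asarray(counts if counts is not None else np.ones(len(seqs), dtype=int)))
    return assign_weights(map_perfect(reads, ExactMatchIndex(genome)))


class TestPartition:
    def _genome(self):
        rng = np.random.default_rng(9)
        return {"chr1": "".join(rng.choice(list("ACGT"), size=30_000))}

    def test_labels_and_share_conservation(self):
        genome = self._genome()
        g = genome["chr1"]
        gene = GeneModel("G", "T", "chr1", "+", [(1_000, 2_000), (3_000, 4_000)])
        pseudo = GeneModel("P", "PT", "chr1", "+", [(10_000, 11_000)], biotype="pseudogene")
        repeats = rm([("chr1", 20_000, 21_000, "+", "FAM", "LTR/X", 5.0)])
        seqs = [
            g[1_100:1_130],        # exon, sense
            reverse_complement(g[2_500:2_530]),  # intron, antisense
            g[10_200:10_230],      # pseudogene, sense
            g[20_100:20_130],      # TE, sense
            g[25_000:25_030],      # intergenic
        ]
        hits = _mapped_hits(genome, seqs)
        part = partition_genomic(hits, [gene, pseudo], repeats, {"chr1": 30_000})
        labels = {tuple(sorted(set(part.hit_labels)))}
        assert part.shares.sum() == pytest.approx(1.0, abs=1e-9)
        by_label = dict(zip(part.hit_labels, hits.seq_index))
        assert "exon_sense" in part.hit_labels
        assert "intron_antisense" in part.hit_labels
        assert "pseudogene_sense" in part.hit_labels
        assert "TE_sense" in part.hit_labels
        assert "intergenic" in part.hit_labels

    def test_te_precedence_over_exon(self):
        genome = self._genome()
        g = genome["chr1"]
        gene = GeneModel("G", "T", "chr1", "+", [(20_000, 22_000)])
        repeats = rm([("chr1", 20_000, 21_000, "-", "FAM", "LTR/X", 5.0)])
        hits = _mapped_hits(genome, [g[20_100:20_130]])
        part = partition_genomic(hits, [gene], repeats, {"chr1": 30_000})
        assert part.hit_labels[0] == "TE_antisense"  # plus read vs minus TE


class TestTEComposition:
    def test_toy_shares(self):
        rng = np.random.default_rng(4)
        background = "".join(rng.choice(list("ACGT"), size=10_000))
        te = "".join(rng.choice(list("ACGT"), size=1_000))
        genome = {"chr1": background[:4_000] + te + background[5_000:]}
        repeats = rm([("chr1", 4_000, 5_000, "+", "FAM", "SINE/x", 12.0)])
        seqs = [genome["chr1"][4_000 + 30 * i : 4_030 + 30 * i] for i in range(10)]
        hits = _mapped_hits(genome, seqs)
        out = te_composition(hits, repeats, {"chr1": 10_000})
        row = out.set_index("family").loc["FAM"]
        assert out.attrs["te_read_share"] == pytest.approx(1.0)
        assert row.genomic_bp_share == pytest.approx(0.1)
        assert row.read_share == pytest.approx(1.0)
        assert row.mean_divergence == pytest.approx(12.0)

    def test_sense_antisense_split(self):
        rng = np.random.default_rng(8)
        te = "".join(rng.choice(list("ACGT"), size=1_000))
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=3_000)) + te}
        repeats = rm([("chr1", 3_000, 4_000, "+", "FAM", "SINE/x", 3.0)])
        sense = [genome["chr1"][3_000 + 40 * i : 3_030 + 40 * i] for i in range(5)]
        anti = [reverse_complement(s) for s in
                (genome["chr1"][3_500 + 40 * i : 3_530 + 40 * i] for i in range(5))]
        hits = _mapped_hits(genome, sense + anti)
        out = te_composition(hits, repeats, {"chr1": 4_000}).set_index("family")
        assert out.loc["FAM", "read_share_sense"] == pytest.approx(0.5)
        assert out.loc["FAM", "read_share_antisense"] == pytest.approx(0.5)

    def test_invariant_to_te_copy_duplication(self):
        """Duplicating a TE copy with its reads leaves weighted shares unchanged."""
        rng = np.random.default_rng(12)
        te = "".join(rng.choice(list("ACGT"), size=600))
        bg1 = "".join(rng.choice(list("ACGT"), size=2_000))
        bg2 = "".join(rng.choice(list("ACGT"), size=2_000))
        seqs = [te[50 + 37 * i : 80 + 37 * i] for i in range(8)]

        genome1 = {"chr1": bg1 + te + bg2}
        rep1 = rm([("chr1", 2_000, 2_600, "+", "FAM", "SINE/x", 5.0)])
        out1 = te_composition(_mapped_hits(genome1, seqs), rep1, {"chr1": 4_600})

        genome2 = {"chr1": bg1 + te + bg2 + te}  # second identical copy
        rep2 = rm([
            ("chr1", 2_000, 2_600, "+", "FAM", "SINE/x", 5.0),
            ("chr1", 4_600, 5_200, "+", "FAM", "SINE/x", 5.0),
        ])
        out2 = te_composition(_mapped_hits(genome2, seqs), rep2, {"chr1": 5_200})

        a = out1.set_index("family").loc["FAM"]
        b = out2.set_index("family").loc["FAM"]
        assert a.read_share == pytest.approx(1.0)
        assert b.read_share == pytest.approx(a.read_share)
        assert b.read_share_sense == pytest.approx(a.read_share_sense)


def test_partition_on_simulation_sums_to_one(small_sim, small_hits):
    artifacts, _, _ = small_sim
    part = partition_genomic(
        small_hits, artifacts.genes, artifacts.repeats,
        {n: len(s) for n, s in artifacts.genome.items()},
    )
    assert part.shares.sum() == pytest.approx(1.0, abs=1e-9)
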