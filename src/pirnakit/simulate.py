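"""Seeded simulator of toy genomes, annotations and small-RNA reads.

The generator plants every structure the analysis pipeline is designed to
detect, with full ground truth: piRNA clusters (mono- and bidirectional)
emitting 1U-biased primary reads with ~Gaussian lengths peaking at 30 nt;
ping-pong pairs in which a secondary read sits on the opposite strand with
its 5' end exactly 10 nt inside the primary's 5' end (10A-biased by the
pairing rule below); TE families copied around the genome with per-copy
divergence and a configurable insertion-strand bias inside clusters
(repeated copies create genuine multimappers); protein-coding genes,
including genes embedded antisense within clusters; tRNA genes sourcing
5' tRNA halves; and uniform degradation contaminants.

Because a secondary's position-10 base is by construction the complement of
its guide's 5' base, the 10A rate of secondaries equals the 1U rate of the
paired primaries. Independent 1U/10A targets are therefore realized by
giving paired primaries P(5'T) = p_10A and unpaired primaries the
complementary rate that keeps the overall primary 1U at p_1U.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CollapsedReadSet,
    GeneModel,
    RawRead,
    RepeatAnnotation,
    reverse_complement,
    write_fasta,
    write_gtf,
    write_repeatmasker,
)

__all__ = [
    "SimulationConfig",
    "PlantedCluster",
    "GenomeArtifacts",
    "ReadTruth",
    "make_genome",
    "simulate_reads",
    "write_artifacts",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TRNA_TYPES = (
    "Asp-GTC",
    "Glu-TTC",
    "Glu-CTC",
    "Gly-CCC",
    "Gly-GCC",
    "Lys-CTT",
    "Val-CAC",
    "His-GTG",
)
# abundance weights of the tRNA types above: a few types dominate the tRF pool
DEFAULT_TRNA_WEIGHTS = (0.30, 0.25, 0.20, 0.13, 0.10, 0.01, 0.005, 0.005)


@dataclass
class SimulationConfig:
    """All knobs of the simulated study, with the default study conditions."""

    # genome
    n_chroms: int = 2
    chrom_len: int = 2_500_000
    # clusters
    n_clusters: int = 3
    cluster_size_range: tuple[int, int] = (15_000, 40_000)
    n_bidirectional: int = 1
    embed_antisense_gene: bool = True
    # primary cluster transcripts are single-stranded: antisense read mass in
    # a mono cluster arises only through ping-pong secondaries
    cluster_main_frac: float = 1.0
    # transposable elements
    te_family_names: tuple[str, ...] = ("SINE_A", "LINE_B", "LTR_C", "DNA_D")
    te_classes: tuple[str, ...] = ("SINE/tRNA", "LINE/L1", "LTR/ERV1", "DNA/hAT")
    te_lengths: tuple[int, ...] = (160, 280, 400, 220)
    te_copies_in_clusters: int = 40  # per family
    te_copies_outside: int = 60  # per family
    # extra-cluster TE copies stay out of the clusters and this flanking
    # margin: identical copies abutting a cluster would collect multimapped
    # cluster-read mass and make the planted boundary ill-defined
    cluster_te_margin: int = 2_000
    te_divergence_range: tuple[float, float] = (0.0, 30.0)
    te_insertion_bias: tuple[float, ...] = (0.8, 0.7, 0.6, 0.5)
    # genes
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len_range: tuple[int, int] = (300, 900)
    intron_len_range: tuple[int, int] = (400, 1500)
    embedded_gene_exon_len: int = 1200
    # ncRNA references
    trna_types: tuple[str, ...] = DEFAULT_TRNA_TYPES
    trna_weights: tuple[float, ...] = DEFAULT_TRNA_WEIGHTS
    trna_len: int = 72
    n_mirnas: int = 5
    # reads
    depth: int = 200_000
    length_mean: float = 30.0
    length_sd: float = 1.5
    length_clip: tuple[int, int] = (24, 33)
    p_1U: float = 0.8
    pingpong_fraction: float = 0.3  # fraction of piRNA reads that are secondaries
    p_10A: float = 0.7
    contaminant_fraction: float = 0.05
    trf_fraction: float = 0.05
    mirna_fraction: float = 0.02
    adapter3: str = "CTGTAGGCACCATCAAT"
    append_adapter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_1U, self.p_10A, self.pingpong_fraction, self.contaminant_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.pingpong_fraction + self.contaminant_fraction > 1.0:
            raise ValueError("pingpong_fraction + contaminant_fraction exceeds 1")


@dataclass
class PlantedCluster:
    chrom: str
    start: int
    end: int
    directionality: str  # mono_plus | mono_minus | bidirectional
    main_strand: str
    switch_point: int | None = None  # bidirectional only; arms are (-, +)
    embedded_gene: str | None = None

    @property
    def size(self) -> int:
        return self.end - self.start

    def strand_at(self, pos: int) -> str:
        if self.directionality != "bidirectional":
            return self.main_strand
        return "-" if pos < self.switch_point else "+"


@dataclass
class GenomeArtifacts:
    genome: dict[str, str]
    repeats: RepeatAnnotation
    genes: list[GeneModel]
    trnas: dict[str, str]
    ncrna_sets: dict[str, dict[str, str]]
    clusters: list[PlantedCluster]
    config: SimulationConfig
    te_consensus: dict[str, str] = None


@dataclass
class ReadTruth:
    """Per-read provenance: one row per simulated read."""

    table: pd.DataFrame  # read_id, klass, chrom, five_prime, strand, origin

    def counts_by_class(self) -> pd.Series:
        return self.table["klass"].value_counts()


class _Allocator:
    """Places non-overlapping intervals on a chromosome."""

    def __init__(self, length: int, rng: np.random.Generator):
        self.length = length
        self.rng = rng
        self.taken: list[tuple[int, int]] = []

    def place(
        self,
        size: int,
        lo: int = 0,
        hi: int | None = None,
        tries: int = 200,
        forbidden: list[tuple[int, int]] | None = None,
    ) -> int:
        hi = self.length if hi is None else hi
        if hi - lo < size:
            raise ValueError("placement window smaller than requested interval")
        for _ in range(tries):
            s = int(self.rng.integers(lo, hi - size + 1))
            e = s + size
            if all(e <= ts or s >= te for ts, te in self.taken) and (
                not forbidden or all(e <= ts or s >= te for ts, te in forbidden)
            ):
                self.taken.append((s, e))
                return s
        raise ValueError(
            f"could not place a {size}-bp interval disjointly after {tries} tries"
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, divergence_pct: float) -> str:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    idx = lut[codes]
    hit = rng.random(len(seq)) < divergence_pct / 100.0
    shift = rng.integers(1, 4, size=len(seq))
    idx = np.where(hit, (idx + shift) % 4, idx)
    return _BASES[idx].tobytes().decode()


def make_genome(config: SimulationConfig, seed: int | None = None) -> GenomeArtifacts:
    """Build the toy genome and all annotations, deterministically per seed."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    rng_bg, rng_cluster, rng_te, rng_gene, rng_trna, _ = rngs

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chroms = {
        name: bytearray(_random_seq(rng_bg, config.chrom_len), "ascii")
        for name in chrom_names
    }
    allocators = {name: _Allocator(config.chrom_len, rng_cluster) for name in chrom_names}

    # ---- clusters (region layer: disjoint among themselves and genes)
    clusters: list[PlantedCluster] = []
    for ci in range(config.n_clusters):
        chrom = chrom_names[ci % len(chrom_names)]
        size = int(rng_cluster.integers(*config.cluster_size_range))
        start = allocators[chrom].place(size)
        if ci < config.n_bidirectional:
            direction = "bidirectional"
            main = "+"
            switch = start + size // 2
        else:
            direction = "mono_plus" if rng_cluster.random() < 0.5 else "mono_minus"
            main = "+" if direction == "mono_plus" else "-"
            switch = None
        clusters.append(
            PlantedCluster(
                chrom=chrom, start=start, end=start + size,
                directionality=direction, main_strand=main, switch_point=switch,
            )
        )

    # sequence layer: TEs / genes / tRNA loci must not overlap each other
    seq_alloc = {name: _Allocator(config.chrom_len, rng_te) for name in chrom_names}

    # ---- genes (annotations over background; placed before TEs so exons
    # stay TE-free and every configured gene finds room)
    genes: list[GeneModel] = []
    for gi in range(config.n_genes):
        chrom = chrom_names[int(rng_gene.integers(len(chrom_names)))]
        n_exons = int(rng_gene.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng_gene.integers(*config.exon_len_range, size=n_exons)
        intron_lens = rng_gene.integers(*config.intron_len_range, size=max(0, n_exons - 1))
        span = int(exon_lens.sum() + intron_lens.sum())
        try:
            start = allocators[chrom].place(span)
            seq_alloc[chrom].place(span, lo=start, hi=start + span)
        except ValueError:
            continue
        exons = []
        pos = start
        for i, L in enumerate(exon_lens):
            exons.append((pos, pos + int(L)))
            pos += int(L) + (int(intron_lens[i]) if i < len(intron_lens) else 0)
        strand = "+" if rng_gene.random() < 0.5 else "-"
        biotype = "pseudogene" if gi % 6 == 5 else "protein_coding"
        model = GeneModel(
            gene_id=f"GENE{gi:03d}", transcript_id=f"GENE{gi:03d}.t1",
            chrom=chrom, strand=strand, exons=exons, biotype=biotype,
        )
        if biotype == "protein_coding" and model.spliced_length > 400:
            model.cds = (exons[0][0] + 150, exons[-1][1] - 150)
        genes.append(model)

    # embedded antisense genes inside clusters (single large exon: every
    # cluster read over the exon is also a transcript read)
    if config.embed_antisense_gene:
        for ci, c in enumerate(clusters):
            L = config.embedded_gene_exon_len
            try:
                start = seq_alloc[c.chrom].place(L, lo=c.start + 1000, hi=c.end - 1000)
            except ValueError:
                continue
            local_main = c.strand_at(start + L // 2)
            strand = "-" if local_main == "+" else "+"
            gid = f"EMB{ci:02d}"
            genes.append(
                GeneModel(
                    gene_id=gid, transcript_id=f"{gid}.t1", chrom=c.chrom,
                    strand=strand, exons=[(start, start + L)], biotype="protein_coding",
                )
            )
            c.embedded_gene = gid

    # ---- TE copies (fill remaining sequence space; crowded placements drop)
    consensus = {
        fam: _random_seq(rng_te, L)
        for fam, L in zip(config.te_family_names, config.te_lengths)
    }
    te_rows = []
    for fi, fam in enumerate(config.te_family_names):
        L = config.te_lengths[fi]
        beta = config.te_insertion_bias[fi]
        for inside in (True, False):
            n = config.te_copies_in_clusters if inside else config.te_copies_outside
            if inside and not clusters:
                continue
            for _ in range(n):
                if inside:
                    c = clusters[int(rng_te.integers(len(clusters)))]
                    chrom = c.chrom
                    try:
                        start = seq_alloc[chrom].place(L, lo=c.start, hi=c.end)
                    except ValueError:
                        continue  # crowded cluster; copy dropped
                    local_main = c.strand_at(start + L // 2)
                    sense = rng_te.random() < beta
                    strand = local_main if sense else ("-" if local_main == "+" else "+")
                else:
                    chrom = chrom_names[int(rng_te.integers(len(chrom_names)))]
                    zones = [
                        (c.start - config.cluster_te_margin, c.end + config.cluster_te_margin)
                        for c in clusters
                        if c.chrom == chrom
                    ]
                    try:
                        start = seq_alloc[chrom].place(L, forbidden=zones)
                    except ValueError:
                        continue
                    strand = "+" if rng_te.random() < 0.5 else "-"
                div = float(rng_te.uniform(*config.te_divergence_range))
                copy = _mutate(rng_te, consensus[fam], div)
                if strand == "-":
                    copy = reverse_complement(copy)
                chroms[chrom][start : start + L] = copy.encode()
                te_rows.append(
                    dict(
                        chrom=chrom, start=start, end=start + L, strand=strand,
                        family=fam, te_class=config.te_classes[fi], divergence=div,
                    )
                )
    repeats = (
        RepeatAnnotation(pd.DataFrame(te_rows).sort_values(["chrom", "start"]).reset_index(drop=True))
        if te_rows
        else RepeatAnnotation.empty()
    )

    # ---- tRNA genes and other ncRNA references
    trnas: dict[str, str] = {}
    for t in config.trna_types:
        seq = _random_seq(rng_trna, config.trna_len)
        # genuine tRNA halves are strongly 1U: start most types with T
        if rng_trna.random() < 0.9:
            seq = "T" + seq[1:]
        trnas[t] = seq
        chrom = chrom_names[int(rng_trna.integers(len(chrom_names)))]
        start = seq_alloc[chrom].place(config.trna_len)
        chroms[chrom][start : start + config.trna_len] = seq.encode()
    mirnas = {}
    for i in range(config.n_mirnas):
        seq = _random_seq(rng_trna, 22)
        mirnas[f"mir-{i + 1}"] = seq
        chrom = chrom_names[int(rng_trna.integers(len(chrom_names)))]
        start = seq_alloc[chrom].place(22)
        chroms[chrom][start : start + 22] = seq.encode()
    ncrna_sets = {
        "miRNA": mirnas,
        "tRNA": trnas,
        "rRNA": {"rRNA_18S": _random_seq(rng_trna, 1200)},
        "snoRNA": {"SNORD_1": _random_seq(rng_trna, 120)},
        "snRNA": {"U6": _random_seq(rng_trna, 100)},
    }

    genome = {name: bytes(b).decode() for name, b in chroms.items()}
    genes.sort(key=lambda g: (g.chrom, g.start))
    return GenomeArtifacts(
        genome=genome, repeats=repeats, genes=genes, trnas=trnas,
        ncrna_sets=ncrna_sets, clusters=clusters, config=config,
        te_consensus=consensus,
    )


def _draw_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    L = int(round(rng.normal(config.length_mean, config.length_sd)))
    return int(np.clip(L, *config.length_clip))


def _read_at(genome: dict[str, str], chrom: str, five_prime: int, strand: str, L: int) -> str | None:
    seq = genome[chrom]
    if strand == "+":
        s, e = five_prime, five_prime + L
    else:
        s, e = five_prime - L + 1, five_prime + 1
    if s < 0 or e > len(seq):
        return None
    frag = seq[s:e]
    return frag if strand == "+" else reverse_complement(frag)


def simulate_reads(
    artifacts: GenomeArtifacts, config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[list[RawRead], ReadTruth]:
    """Draw the read library from the genome artifacts with full provenance."""
    config = config or artifacts.config
    seed = config.seed + 1 if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genome = artifacts.genome
    clusters = artifacts.clusters

    n_contam = int(round(config.contaminant_fraction * config.depth))
    n_trf = int(round(config.trf_fraction * config.depth))
    n_mirna = int(round(config.mirna_fraction * config.depth))
    n_pi = config.depth - n_contam - n_trf - n_mirna
    f = config.pingpong_fraction
    n_primary = int(round(n_pi / (1.0 + f))) if f > 0 else n_pi
    n_secondary = n_pi - n_primary
    if n_primary > 0:
        p_t_unpaired = (
            (config.p_1U * n_primary - config.p_10A * n_secondary)
            / max(1, n_primary - n_secondary)
            if n_primary > n_secondary
            else config.p_1U
        )
        p_t_unpaired = float(np.clip(p_t_unpaired, 0.0, 1.0))
    paired_flags = np.zeros(n_primary, dtype=bool)
    if n_secondary:
        paired_flags[rng.choice(n_primary, size=n_secondary, replace=False)] = True

    sizes = np.array([c.size for c in clusters], dtype=float)
    probs = sizes / sizes.sum() if len(clusters) else None

    records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []

    def emit(seq: str, klass: str, chrom: str, fp: int, strand: str, origin: str) -> None:
        rid = f"read{len(records):07d}"
        out = seq + config.adapter3 if config.append_adapter else seq
        records.append((rid, out))
        truth_rows.append(
            dict(read_id=rid, klass=klass, chrom=chrom, five_prime=fp, strand=strand, origin=origin)
        )

    # ---- primary + secondary piRNA reads (vectorized rejection sampling:
    # positions are redrawn until the 5' base matches the wanted 1U state)
    if clusters and n_primary:
        starts = np.array([c.start for c in clusters])
        ends = np.array([c.end for c in clusters])
        is_bi = np.array([c.directionality == "bidirectional" for c in clusters])
        switch = np.array(
            [c.switch_point if c.switch_point is not None else 0 for c in clusters]
        )
        main_plus = np.array([c.main_strand == "+" for c in clusters])
        chrom_of = [c.chrom for c in clusters]
        codes = {name: np.frombuffer(seq.encode(), dtype=np.uint8) for name, seq in genome.items()}
        chrom_ids = {name: i for i, name in enumerate(genome)}
        cluster_chrom_id = np.array([chrom_ids[c] for c in chrom_of])

        want_t = np.where(
            paired_flags,
            rng.random(n_primary) < config.p_10A,
            rng.random(n_primary) < p_t_unpaired,
        )
        ci = np.zeros(n_primary, dtype=np.intp)
        Ls = np.zeros(n_primary, dtype=np.intp)
        fps = np.zeros(n_primary, dtype=np.int64)
        plus = np.zeros(n_primary, dtype=bool)
        need = np.arange(n_primary)
        for _ in range(80):
            if len(need) == 0:
                break
            m = len(need)
            c_i = rng.choice(len(clusters), size=m, p=probs)
            L = np.clip(
                np.round(rng.normal(config.length_mean, config.length_sd, size=m)),
                *config.length_clip,
            ).astype(np.intp)
            span = ends[c_i] - starts[c_i] - L
            pos = starts[c_i] + (rng.random(m) * span).astype(np.int64)
            mid = pos + L // 2
            local_plus = np.where(is_bi[c_i], mid >= switch[c_i], main_plus[c_i])
            flip = rng.random(m) >= config.cluster_main_frac
            p = local_plus ^ flip
            fp = np.where(p, pos, pos + L - 1)
            # 5' base is T <=> genome base is T (+ strand) or A (- strand)
            have_t = np.zeros(m, dtype=bool)
            for name, cid in chrom_ids.items():
                on = cluster_chrom_id[c_i] == cid
                if on.any():
                    g = codes[name][fp[on]]
                    have_t[on] = np.where(p[on], g == ord("T"), g == ord("A"))
            ok = have_t == want_t[need]
            acc = need[ok]
            ci[acc], Ls[acc], fps[acc], plus[acc] = c_i[ok], L[ok], fp[ok], p[ok]
            need = need[~ok]
        done = np.ones(n_primary, dtype=bool)
        done[need] = False

        for i in np.flatnonzero(done):
            chrom = chrom_of[ci[i]]
            strand = "+" if plus[i] else "-"
            seq = _read_at(genome, chrom, int(fps[i]), strand, int(Ls[i]))
            emit(seq, "primary", chrom, int(fps[i]), strand, f"cluster@{chrom}")
            if paired_flags[i]:
                L2 = _draw_length(rng, config)
                sfp = int(fps[i]) + (9 if plus[i] else -9)
                sstrand = "-" if plus[i] else "+"
                sseq = _read_at(genome, chrom, sfp, sstrand, L2)
                if sseq is not None and "N" not in sseq:
                    emit(sseq, "secondary", chrom, sfp, sstrand, f"pair_of:{len(records) - 1}")

    # ---- 5' tRNA halves
    t_names = list(config.trna_types)
    t_w = np.asarray(config.trna_weights, dtype=float)
    t_w = t_w / t_w.sum()
    for _ in range(n_trf):
        t = t_names[int(rng.choice(len(t_names), p=t_w))]
        L = int(np.clip(int(round(rng.normal(32, 1.0))), 28, min(34, len(artifacts.trnas[t]))))
        seq = artifacts.trnas[t][:L]
        emit(seq, "trf", "", -1, "+", f"tRNA:{t}")

    # ---- miRNA reads
    mirna_names = list(artifacts.ncrna_sets["miRNA"])
    for _ in range(n_mirna):
        name = mirna_names[int(rng.integers(len(mirna_names)))]
        emit(artifacts.ncrna_sets["miRNA"][name], "mirna", "", -1, "+", f"miRNA:{name}")

    # ---- degradation contaminants: random genome fragments + tRNA interiors
    chrom_names = list(genome)
    for _ in range(n_contam):
        if rng.random() < 0.2:
            t = t_names[int(rng.integers(len(t_names)))]
            ref = artifacts.trnas[t]
            L = int(rng.integers(18, 31))
            start = int(rng.integers(4, len(ref) - L))
            emit(ref[start : start + L], "contaminant", "", -1, "+", f"tRNA_interior:{t}")
        else:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            L = int(rng.integers(18, 35))
            strand = "+" if rng.random() < 0.5 else "-"
            pos = int(rng.integers(0, len(genome[chrom]) - L))
            fp = pos if strand == "+" else pos + L - 1
            seq = _read_at(genome, chrom, fp, strand, L)
            if seq is None:
                continue
            emit(seq, "contaminant", chrom, fp, strand, "genome")

    reads = [RawRead(rid, seq) for rid, seq in records]
    truth = ReadTruth(pd.DataFrame(truth_rows))
    return reads, truth


def write_artifacts(
    artifacts: GenomeArtifacts,
    reads: list[RawRead],
    truth: ReadTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit the simulation in exactly the formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "reads": outdir / "reads.fa",
        "repeats": outdir / "repeats.out",
        "genes": outdir / "genes.gtf",
        "truth": outdir / "read_truth.tsv",
        "clusters": outdir / "planted_clusters.tsv",
    }
    write_fasta(artifacts.genome.items(), paths["genome"])
    write_fasta(((r.id, r.sequence) for r in reads), paths["reads"])
    write_repeatmasker(artifacts.repeats, paths["repeats"])
    write_gtf(artifacts.genes, paths["genes"])
    truth.table.to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame(
        [
            dict(
                chrom=c.chrom, start=c.start, end=c.end,
                directionality=c.directionality, main_strand=c.main_strand,
                embedded_gene=c.embedded_gene or "",
            )
            for c in artifacts.clusters
        ]
    ).to_csv(paths["clusters"], sep="\t", index=False)
    for label, refs in artifacts.ncrna_sets.items():
        p = outdir / f"ncrna_{label}.fa"
        write_fasta(refs.items(), p)
        paths[f"ncrna_{label}"] = p
    return paths
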