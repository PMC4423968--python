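"""End-to-end pipeline: preprocessing -> annotation -> mapping -> statistics.

Stage order mirrors the analysis the package implements: adapter clipping
and size filtering, ncRNA classification (sense matches to labeled reference
sets), perfect-match genome mapping of the putative piRNAs with multimapper
weighting, sequence signatures (lengths, 1U/10A, ping-pong), cluster
detection and content, genomic feature partition, gene-target calling on
spliced transcripts, and tRF profiling. Every table is written as TSV with a
provenance header (version, seed, parameter hash) and a stage-count ledger
tracks reads through the funnel: raw -> size-filtered -> ncRNA-classified ->
genome-mapped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import classify_ncrna, partition_genomic, te_composition
from .clusters import ClusterParams, cluster_content, scan_clusters, te_strand_bias
from .io import (
    CollapsedReadSet,
    ConfigError,
    clip_and_filter,
    parse_gtf,
    parse_repeatmasker,
    read_fasta,
    read_fasta_dict,
)
from .mapping import ExactMatchIndex, HitTable, assign_weights, map_perfect
from .signatures import (
    length_distribution,
    overlap_histogram,
    pingpong_result,
    positional_nt_freq,
)
from .targets import build_transcriptome, call_targets, map_to_transcripts, targets_table
from .trf import trf_profile

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("pirnakit")

NCRNA_LABELS = ("miRNA", "tRNA", "rRNA", "snoRNA", "snRNA")


@dataclass
class PipelineConfig:
    """Paths and flattened parameters of a full pipeline run."""

    reads_fasta: str
    genome_fasta: str
    outdir: str
    ncrna_fastas: dict[str, str] = field(default_factory=dict)  # class -> path
    repeats_out: str | None = None
    genes_gtf: str | None = None
    # preprocessing
    adapter3: str = "CTGTAGGCACCATCAAT"
    min_len: int = 18
    max_len: int = 34
    adapter_seed: int = 8
    prefix_strip: int = 0
    # mapping
    k: int = 12
    # signatures
    o_max: int = 20
    z_threshold: float | None = None
    # clusters
    cluster_min_size: int = 10_000
    cluster_window: int = 1_000
    cluster_step: int = 100
    cluster_density_factor: float = 10.0
    cluster_min_window_mass: float = 5.0
    cluster_pirna_size_frac: float = 0.75
    cluster_bias_frac: float = 0.5
    cluster_mono_threshold: float = 0.75
    # targets
    rpm_threshold: float = 10.0
    draws: int = 1_000_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            min_size=self.cluster_min_size,
            window=self.cluster_window,
            step=self.cluster_step,
            density_factor=self.cluster_density_factor,
            min_window_mass=self.cluster_min_window_mass,
            pirna_size_frac=self.cluster_pirna_size_frac,
            bias_frac=self.cluster_bias_frac,
            mono_threshold=self.cluster_mono_threshold,
        )

    def validate(self) -> None:
        for label, p in [("reads_fasta", self.reads_fasta), ("genome_fasta", self.genome_fasta)]:
            if not p or not Path(p).exists():
                raise ConfigError(f"{label} does not exist: {p!r}")
        for cls_label, p in self.ncrna_fastas.items():
            if cls_label not in NCRNA_LABELS:
                raise ConfigError(f"unknown ncRNA class {cls_label!r}")
            if not Path(p).exists():
                raise ConfigError(f"ncRNA FASTA missing: {p}")
        for p in (self.repeats_out, self.genes_gtf):
            if p and not Path(p).exists():
                raise ConfigError(f"input missing: {p}")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ConfigError("invalid length window")

    def params_hash(self) -> str:
        # the hash fingerprints the analysis, not where its outputs land
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    ledger: dict[str, float]
    reads: CollapsedReadSet
    labels: np.ndarray
    genome_hits: HitTable
    clusters: list
    tables: dict[str, Path]


def _header(config: PipelineConfig) -> str:
    return (
        f"# pirnakit {__version__}; seed={config.seed}; "
        f"params_hash={config.params_hash()}\n"
    )


def _write(df: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = False) -> Path:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index)
    return path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the report bundle into ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    fh = logging.FileHandler(outdir / "run.log")
    logger.addHandler(fh)
    tables: dict[str, Path] = {}
    ledger: dict[str, float] = {}

    current = {"stage": "init"}

    def stage(name: str):
        current["stage"] = name
        logger.info("[pirnakit] stage: %s", name)

    try:
        # ---- 1. preprocessing -------------------------------------------
        stage("clip_and_filter")
        raw = read_fasta(config.reads_fasta)
        reads = clip_and_filter(
            raw,
            adapter3=config.adapter3,
            min_len=config.min_len,
            max_len=config.max_len,
            adapter_seed=config.adapter_seed,
            prefix_strip=config.prefix_strip,
        )
        ledger["raw_reads"] = len(raw)
        ledger["size_filtered_reads"] = reads.total_reads
        ledger["unique_sequences"] = len(reads)
        reads.write_tsv(outdir / "collapsed_reads.tsv")
        tables["collapsed_reads"] = outdir / "collapsed_reads.tsv"

        # ---- 2. ncRNA classification ------------------------------------
        stage("classify_ncrna")
        ncrna_sets = {
            label: read_fasta_dict(path) for label, path in config.ncrna_fastas.items()
        }
        labels = classify_ncrna(reads, ncrna_sets, k=config.k)
        class_counts = {
            label: int(reads.counts[labels == label].sum())
            for label in list(NCRNA_LABELS) + ["putative_piRNA"]
        }
        for label, n in class_counts.items():
            ledger[f"class_{label}"] = n
        _write(
            pd.Series(class_counts, name="reads").rename_axis("class").reset_index(),
            outdir / "ncrna_classes.tsv",
            config,
        )
        tables["ncrna_classes"] = outdir / "ncrna_classes.tsv"

        pirna_mask = labels == "putative_piRNA"
        pirna = reads.subset(pirna_mask)
        ledger["putative_pirna_reads"] = pirna.total_reads

        # ---- 3. genome mapping ------------------------------------------
        stage("map_genome")
        genome = read_fasta_dict(config.genome_fasta)
        index = ExactMatchIndex(genome, k=config.k)
        hits = assign_weights(map_perfect(pirna, index, orientation="both"))
        ledger["genome_mapped_reads"] = hits.total_mapped_reads
        ledger["genomic_hits"] = len(hits)
        ledger["weighted_mass"] = hits.total_weighted_mass
        hits.to_bed(outdir / "genome_hits.bed")
        tables["genome_hits"] = outdir / "genome_hits.bed"

        # ---- 4. signatures ----------------------------------------------
        stage("signatures")
        mapped = pirna.subset(hits.mapped_mask)
        ld = length_distribution(mapped, weights="by_read_count")
        _write(ld.reset_index(), outdir / "length_distribution.tsv", config)
        prof5 = positional_nt_freq(mapped, anchor="five_prime")
        _write(prof5.freqs, outdir / "positional_freq_5p.tsv", config, index=True)
        prof3 = positional_nt_freq(mapped, anchor="three_prime")
        _write(prof3.freqs, outdir / "positional_freq_3p.tsv", config, index=True)
        hist = overlap_histogram(hits, o_max=config.o_max)
        pp = pingpong_result(hist, z_threshold=config.z_threshold)
        pp_rows = [
            dict(
                context="global",
                n_pairs=hist.n_pairs,
                z=pp.z,
                twofold=pp.twofold,
                evident=pp.evident,
                **{f"s{o}": hist.s(o) for o in range(1, config.o_max + 1)},
            )
        ]
        ledger["pingpong_z_global"] = pp.z
        tables["length_distribution"] = outdir / "length_distribution.tsv"

        # ---- 5. annotation-dependent stages -----------------------------
        repeats = parse_repeatmasker(config.repeats_out) if config.repeats_out else None
        genes = parse_gtf(config.genes_gtf) if config.genes_gtf else []
        genome_lengths = {n: len(s) for n, s in genome.items()}

        if repeats is not None:
            stage("te_composition")
            te_table = te_composition(hits, repeats, genome_lengths)
            _write(te_table, outdir / "te_composition.tsv", config)
            tables["te_composition"] = outdir / "te_composition.tsv"
            ledger["te_read_share"] = te_table.attrs["te_read_share"]
            # TE-restricted ping-pong
            from intervaltree import IntervalTree

            trees: dict[str, IntervalTree] = {}
            for row in repeats.records.itertuples(index=False):
                trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
            fp = hits.five_prime
            te_mask = np.fromiter(
                (
                    bool(trees.get(hits.ref_names[hits.ref_index[i]], IntervalTree()).at(int(fp[i])))
                    for i in range(len(hits))
                ),
                dtype=bool,
                count=len(hits),
            )
            te_hist = overlap_histogram(hits.subset(te_mask), o_max=config.o_max)
            te_pp = pingpong_result(te_hist, z_threshold=config.z_threshold)
            pp_rows.append(
                dict(
                    context="TE",
                    n_pairs=te_hist.n_pairs,
                    z=te_pp.z,
                    twofold=te_pp.twofold,
                    evident=te_pp.evident,
                    **{f"s{o}": te_hist.s(o) for o in range(1, config.o_max + 1)},
                )
            )
            ledger["pingpong_z_te"] = te_pp.z

        if repeats is not None and genes:
            stage("partition_genomic")
            part = partition_genomic(hits, genes, repeats, genome_lengths)
            _write(
                part.shares.rename("share").rename_axis("feature").reset_index(),
                outdir / "feature_partition.tsv",
                config,
            )
            tables["feature_partition"] = outdir / "feature_partition.tsv"

        _write(pd.DataFrame(pp_rows), outdir / "pingpong.tsv", config)
        tables["pingpong"] = outdir / "pingpong.tsv"

        # ---- 6. clusters -------------------------------------------------
        stage("scan_clusters")
        params = config.cluster_params()
        calls = scan_clusters(hits, genome_lengths, params, genome=genome)
        ledger["n_clusters"] = len(calls)
        if repeats is not None:
            content = cluster_content(calls, genes, repeats, genome_lengths)
            _write(content, outdir / "clusters.tsv", config)
            bias = te_strand_bias(calls, repeats, hits)
            _write(bias, outdir / "te_strand_bias.tsv", config)
            tables["clusters"] = outdir / "clusters.tsv"
            tables["te_strand_bias"] = outdir / "te_strand_bias.tsv"
        else:
            _write(
                pd.DataFrame(
                    [
                        dict(
                            chrom=c.chrom, start=c.start, end=c.end, size=c.size,
                            directionality=c.directionality,
                            weighted_mass=c.weighted_mass,
                        )
                        for c in calls
                    ]
                ),
                outdir / "clusters.tsv",
                config,
            )
            tables["clusters"] = outdir / "clusters.tsv"

        # ---- 7. gene targets ---------------------------------------------
        results = []
        if genes:
            stage("call_targets")
            transcripts, models = build_transcriptome(
                [g for g in genes if g.biotype == "protein_coding"], genome
            )
            tx_hits = map_to_transcripts(
                pirna, transcripts, genomic_weights=hits.weights, k=config.k
            )
            total_mapped = max(1, hits.total_mapped_reads)
            results = call_targets(
                tx_hits,
                total_mapped,
                models=models,
                rpm_threshold=config.rpm_threshold,
                z_threshold=config.z_threshold,
            )
            _write(targets_table(results), outdir / "gene_targets.tsv", config)
            tables["gene_targets"] = outdir / "gene_targets.tsv"
            ledger["n_target_genes"] = sum(r.is_target for r in results)

        # ---- 8. tRF profiling --------------------------------------------
        if "tRNA" in ncrna_sets:
            stage("trf_profile")
            trna_reads = reads.subset(labels == "tRNA")
            if len(trna_reads):
                t_hits = assign_weights(map_perfect(trna_reads, index, orientation="both"))
                profile = trf_profile(trna_reads, ncrna_sets["tRNA"], t_hits, repeats)
                _write(
                    profile.type_shares.rename("share").rename_axis("trna_type").reset_index(),
                    outdir / "trf_type_shares.tsv",
                    config,
                )
                _write(
                    profile.start_histogram.rename("mass").rename_axis("position").reset_index(),
                    outdir / "trf_start_positions.tsv",
                    config,
                )
                tables["trf_type_shares"] = outdir / "trf_type_shares.tsv"
                ledger["trf_rate_1U"] = profile.rate_1U
                ledger["trf_five_prime_share"] = profile.five_prime_share

        # ---- 9. report ----------------------------------------------------
        stage("report")
        summary = pd.Series(ledger, name="value").rename_axis("quantity").reset_index()
        _write(summary, outdir / "summary.tsv", config)
        tables["summary"] = outdir / "summary.tsv"
        with open(outdir / "summary.txt", "w") as out:
            out.write(_header(config))
            for k, v in ledger.items():
                out.write(f"{k}\t{v}\n")
    except Exception as exc:  # annotate failures with the failing stage
        logger.error("[pirnakit] stage %r failed: %s", current["stage"], exc)
        raise RuntimeError(f"pipeline stage {current['stage']!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(fh)
        fh.close()

    return PipelineResult(
        config=config,
        ledger=ledger,
        reads=reads,
        labels=labels,
        genome_hits=hits,
        clusters=calls,
        tables=tables,
    )
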