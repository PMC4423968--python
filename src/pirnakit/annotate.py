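"""Read classification against ncRNA references and genomic feature partition.

Small-RNA libraries are contaminated with fragments of abundant structural
ncRNAs. Reads are therefore matched in sense orientation against labeled
ncRNA reference sets (miRNA, tRNA, rRNA, snoRNA, snRNA) before any piRNA
analysis; only unmatched reads count as putative piRNAs. Genomic hits of the
putative piRNAs are then partitioned over annotation features (TE, exon,
intron, pseudogene, intergenic) by the position of the read 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import CollapsedReadSet, ConfigError, GeneModel, RepeatAnnotation
from .mapping import ExactMatchIndex, HitTable, map_perfect

__all__ = [
    "NCRNA_PRECEDENCE",
    "classify_ncrna",
    "FeaturePartition",
    "partition_genomic",
    "te_composition",
]

NCRNA_PRECEDENCE = ("miRNA", "tRNA", "rRNA", "snoRNA", "snRNA")


def classify_ncrna(
    reads: CollapsedReadSet,
    ncrna_sets: dict[str, dict[str, str]],
    precedence: tuple[str, ...] = NCRNA_PRECEDENCE,
    k: int = 12,
) -> np.ndarray:
    """Assign each unique sequence one label: an ncRNA class or putative_piRNA.

    A sequence matching any entry of a class's reference set in sense
    orientation gets that class; on multi-class matches the earlier class in
    ``precedence`` wins. ``ncrna_sets`` maps class label to ``{name: seq}``.
    """
    unknown = set(ncrna_sets) - set(precedence)
    if unknown:
        raise ConfigError(f"ncRNA sets with unrecognized labels: {sorted(unknown)}")
    rank = {cls: r for r, cls in enumerate(precedence)}
    combined: dict[str, str] = {}
    ref_class: list[str] = []
    for cls in precedence:
        for name, seq in ncrna_sets.get(cls, {}).items():
            combined[f"{cls}::{name}"] = seq
            ref_class.append(cls)
    labels = np.array(["putative_piRNA"] * len(reads), dtype=object)
    if not combined:
        return labels
    index = ExactMatchIndex(combined, k=k)
    for i, seq in enumerate(reads.sequences):
        matches = index.find(seq, orientation="sense_only")
        if matches:
            labels[i] = min((ref_class[r] for r, _, _ in matches), key=rank.get)
    return labels


@dataclass
class FeaturePartition:
    """Per-hit feature labels and weighted share per label (summing to 1)."""

    hit_labels: np.ndarray  # parallel to the hit table's rows
    shares: pd.Series  # label -> weighted fraction of mapped mass

    LABELS = (
        "TE_sense",
        "TE_antisense",
        "exon_sense",
        "exon_antisense",
        "intron_sense",
        "intron_antisense",
        "pseudogene_sense",
        "pseudogene_antisense",
        "intergenic",
    )


def _feature_trees(genes: list[GeneModel], repeats: RepeatAnnotation):
    te: dict[str, IntervalTree] = {}
    for row in repeats.records.itertuples(index=False):
        te.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row)
    exon: dict[str, IntervalTree] = {}
    intron: dict[str, IntervalTree] = {}
    pseudo: dict[str, IntervalTree] = {}
    for g in genes:
        if g.biotype == "pseudogene":
            for s, e in g.exons:
                pseudo.setdefault(g.chrom, IntervalTree()).addi(s, e, g.strand)
        elif g.biotype == "protein_coding":
            for s, e in g.exons:
                exon.setdefault(g.chrom, IntervalTree()).addi(s, e, g.strand)
            for s, e in g.introns():
                intron.setdefault(g.chrom, IntervalTree()).addi(s, e, g.strand)
    return te, exon, intron, pseudo


def partition_genomic(
    hits: HitTable,
    genes: list[GeneModel],
    repeats: RepeatAnnotation,
    genome_lengths: dict[str, int] | None = None,
) -> FeaturePartition:
    """Label every genomic hit by the feature containing its 5' position.

    Precedence on overlapping annotations: TE > protein-coding exon > intron
    > pseudogene; otherwise intergenic. Orientation is the read strand
    relative to the feature strand. Shares are weighted by count x weight and
    sum to 1 over all labels.
    """
    if np.isnan(hits.weights[hits.mapped_mask]).any():
        raise ValueError("assign_weights must run before partitioning")
    te, exon, intron, pseudo = _feature_trees(genes, repeats)
    fp = hits.five_prime
    if genome_lengths is not None:
        for i in range(len(hits)):
            L = genome_lengths[hits.ref_names[hits.ref_index[i]]]
            if not (0 <= fp[i] < L):
                raise ValueError(f"hit 5' position {fp[i]} beyond chromosome bounds")
    labels = np.empty(len(hits), dtype=object)
    for i in range(len(hits)):
        chrom = hits.ref_names[hits.ref_index[i]]
        p = int(fp[i])
        strand = hits.strand[i]
        label = "intergenic"
        ivs = te.get(chrom, IntervalTree()).at(p) if chrom in te else ()
        if ivs:
            iv = min(ivs, key=lambda v: v.begin)
            orient = "sense" if strand == iv.data.strand else "antisense"
            label = f"TE_{orient}"
        else:
            for name, trees in (("exon", exon), ("intron", intron), ("pseudogene", pseudo)):
                ivs = trees.get(chrom, IntervalTree()).at(p) if chrom in trees else ()
                if ivs:
                    iv = min(ivs, key=lambda v: v.begin)
                    orient = "sense" if strand == iv.data else "antisense"
                    label = f"{name}_{orient}"
                    break
        labels[i] = label
    mass = hits.hit_mass
    total = float(mass.sum())
    shares = pd.Series(0.0, index=list(FeaturePartition.LABELS))
    if total > 0:
        for lab in FeaturePartition.LABELS:
            shares[lab] = float(mass[labels == lab].sum()) / total
    return FeaturePartition(hit_labels=labels, shares=shares)


def te_composition(
    hits: HitTable,
    repeats: RepeatAnnotation,
    genome_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-TE-family read and genome composition.

    For every family: weighted read share of total mapped mass, split into
    sense/antisense relative to the TE consensus (read strand vs copy
    strand), the genomic bp fraction occupied by the family, and the
    read-mass-weighted mean divergence of the matched copies. The overall TE
    share of mapped reads is stored in ``attrs["te_read_share"]``.
    """
    trees: dict[str, IntervalTree] = {}
    for row in repeats.records.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row)
    fp = hits.five_prime
    mass = hits.hit_mass
    total = float(mass.sum())
    genome_bp = sum(genome_lengths.values())

    stats: dict[str, dict[str, float]] = {}
    te_mass = 0.0
    for i in range(len(hits)):
        chrom = hits.ref_names[hits.ref_index[i]]
        tree = trees.get(chrom)
        if tree is None:
            continue
        ivs = tree.at(int(fp[i]))
        if not ivs:
            continue
        iv = min(ivs, key=lambda v: v.begin)
        row = iv.data
        m = float(mass[i])
        te_mass += m
        st = stats.setdefault(
            row.family,
            dict(sense=0.0, antisense=0.0, te_class=row.te_class, div_mass=0.0),
        )
        key = "sense" if hits.strand[i] == row.strand else "antisense"
        st[key] += m
        st["div_mass"] += m * row.divergence

    fam_bp = (
        repeats.records.assign(bp=lambda d: d.end - d.start).groupby("family")["bp"].sum()
        if len(repeats.records)
        else pd.Series(dtype=float)
    )
    rows = []
    for fam in sorted(set(fam_bp.index) | set(stats)):
        st = stats.get(fam, dict(sense=0.0, antisense=0.0, te_class="", div_mass=0.0))
        fam_mass = st["sense"] + st["antisense"]
        if not st["te_class"] and len(repeats.records):
            match = repeats.records.loc[repeats.records["family"] == fam, "te_class"]
            st["te_class"] = match.iloc[0] if len(match) else ""
        rows.append(
            dict(
                family=fam,
                te_class=st["te_class"],
                read_share=(fam_mass / total) if total else 0.0,
                read_share_sense=(st["sense"] / total) if total else 0.0,
                read_share_antisense=(st["antisense"] / total) if total else 0.0,
                genomic_bp_share=float(fam_bp.get(fam, 0)) / genome_bp if genome_bp else 0.0,
                mean_divergence=(st["div_mass"] / fam_mass) if fam_mass else float("nan"),
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["te_read_share"] = (te_mass / total) if total else 0.0
    return out
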