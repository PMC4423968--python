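"""piRNA cluster detection and characterization.

Clusters are found by a sliding-window scan over the weighted 5'-end density
of mapped reads (window 1 kb, step 0.1 kb, minimum merged size 10 kb by
default). A window qualifies when its density exceeds a multiple of the
robust genome-wide background density and its reads look like piRNAs (size
and 1U/10A composition); qualifying windows are merged and short merged
regions discarded. Directionality, sequence content (TE / gene / pseudogene
shares, TE enrichment and divergence) and TE insertion-strand bias are
computed per call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import ConfigError, GeneModel, RepeatAnnotation
from .mapping import HitTable

__all__ = [
    "ClusterParams",
    "ClusterCall",
    "scan_clusters",
    "call_directionality",
    "cluster_content",
    "te_strand_bias",
]


@dataclass
class ClusterParams:
    """Tunable parameters of the sliding-window scan.

    min_size / window / step are in bp. A window qualifies if its weighted
    mass is at least ``min_window_mass`` reads, its density (mass per kb) is
    at least ``density_factor`` times the background density (median window
    mass over the genome, N-gap windows excluded), at least
    ``pirna_size_frac`` of its mass comes from 24-32 nt reads, and at least
    ``bias_frac`` from reads with a 5' U or a position-10 A.
    """

    min_size: int = 10_000
    window: int = 1_000
    step: int = 100
    density_factor: float = 10.0
    min_window_mass: float = 5.0
    pirna_size_frac: float = 0.75
    bias_frac: float = 0.5
    mono_threshold: float = 0.75
    gap_min_run: int = 100  # N runs at least this long are excluded from background

    def __post_init__(self) -> None:
        if self.window < self.step:
            raise ConfigError("window must be >= step")
        if self.window % self.step != 0:
            raise ConfigError("window must be a multiple of step")


@dataclass
class ClusterCall:
    chrom: str
    start: int
    end: int  # 0-based half-open
    directionality: str = "mono_plus"  # mono_plus | mono_minus | bidirectional
    weighted_mass: float = 0.0
    main_strand_fraction: float = 0.0
    # for bidirectional clusters: position of the strand switch and the
    # dominant strand of each arm (left of / right of the switch point)
    switch_point: int | None = None
    arm_strands: tuple[str, str] = ("+", "+")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def main_strand(self) -> str:
        return "-" if self.directionality == "mono_minus" else "+"

    def main_strand_at(self, pos: int) -> str:
        """Dominant read strand at a position inside the cluster.

        For mono-directional clusters this is the cluster main strand; for
        bidirectional clusters it is the dominant strand of the arm the
        position falls in.
        """
        if self.directionality != "bidirectional" or self.switch_point is None:
            return self.main_strand
        return self.arm_strands[0] if pos < self.switch_point else self.arm_strands[1]


def _read_flags(reads) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence piRNA-size (24-32 nt) and 1U-or-10A flags."""
    lengths = reads.lengths
    size_ok = (lengths >= 24) & (lengths <= 32)
    bias_ok = np.fromiter(
        (s[0] == "T" or (len(s) >= 10 and s[9] == "A") for s in reads.sequences),
        dtype=bool,
        count=len(reads.sequences),
    )
    return size_ok, bias_ok


def _gap_windows(seq: str | None, n_bins: int, params: ClusterParams) -> np.ndarray:
    """Boolean mask of step-bins overlapping an assembly gap (long N run)."""
    mask = np.zeros(n_bins, dtype=bool)
    if not seq:
        return mask
    for m in re.finditer("N{%d,}" % params.gap_min_run, seq):
        lo = m.start() // params.step
        hi = min(n_bins - 1, (m.end() - 1) // params.step)
        mask[lo : hi + 1] = True
    return mask


def scan_clusters(
    hits: HitTable,
    genome_lengths: dict[str, int],
    params: ClusterParams | None = None,
    genome: dict[str, str] | None = None,
) -> list[ClusterCall]:
    """Sliding-window cluster scan over all chromosomes.

    Returns merged qualifying regions of at least ``params.min_size`` bp,
    sorted by coordinate, each with directionality called.
    """
    params = params or ClusterParams()
    if np.isnan(hits.weights[hits.mapped_mask]).any():
        raise ValueError("assign_weights must run before cluster scanning")
    size_ok, bias_ok = _read_flags(hits.reads)
    mass = hits.hit_mass
    fp = hits.five_prime
    bins_per_window = params.window // params.step

    # per-chromosome binned mass vectors
    chrom_bins: dict[str, dict[str, np.ndarray]] = {}
    window_masses = []  # pooled qualifying-stat denominator for the background
    for ci, chrom in enumerate(hits.ref_names):
        L = genome_lengths.get(chrom)
        if L is None or L < params.window:
            continue
        n_bins = (L + params.step - 1) // params.step
        sel = hits.ref_index == ci
        pos_bin = (fp[sel] // params.step).astype(np.int64)
        total = np.bincount(pos_bin, weights=mass[sel], minlength=n_bins)
        good_size = np.bincount(
            pos_bin, weights=mass[sel] * size_ok[hits.seq_index[sel]], minlength=n_bins
        )
        good_bias = np.bincount(
            pos_bin, weights=mass[sel] * bias_ok[hits.seq_index[sel]], minlength=n_bins
        )
        plus = np.bincount(
            pos_bin, weights=mass[sel] * (hits.strand[sel] == "+"), minlength=n_bins
        )
        gap = _gap_windows(genome.get(chrom) if genome else None, n_bins, params)
        chrom_bins[chrom] = dict(
            total=total, good_size=good_size, good_bias=good_bias, plus=plus, gap=gap
        )
        # sliding window sums at every step offset
        win = _window_sums(total, bins_per_window)
        gap_win = _window_sums(gap.astype(float), bins_per_window) > 0
        window_masses.append(win[~gap_win])
    if not chrom_bins:
        return []
    pooled = np.concatenate(window_masses)
    background_density = float(np.median(pooled)) / (params.window / 1000.0)
    density_threshold = params.density_factor * background_density

    calls: list[ClusterCall] = []
    for chrom, b in chrom_bins.items():
        win_total = _window_sums(b["total"], bins_per_window)
        win_size = _window_sums(b["good_size"], bins_per_window)
        win_bias = _window_sums(b["good_bias"], bins_per_window)
        gap_win = _window_sums(b["gap"].astype(float), bins_per_window) > 0
        dens = win_total / (params.window / 1000.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_size = np.where(win_total > 0, win_size / win_total, 0.0)
            frac_bias = np.where(win_total > 0, win_bias / win_total, 0.0)
        qual = (
            (win_total >= params.min_window_mass)
            & (dens >= density_threshold)
            & (frac_size >= params.pirna_size_frac)
            & (frac_bias >= params.bias_frac)
            & ~gap_win
        )
        L = genome_lengths[chrom]
        ci = hits.ref_names.index(chrom)
        on_chrom = hits.ref_index == ci
        for ws, we in _merge_windows(np.flatnonzero(qual), params, L):
            # trim the merged window span to its actual read support: the
            # window grid pads dense regions by up to window-step per side
            inside = on_chrom & (fp >= ws) & (fp < we)
            if not inside.any():
                continue
            ts = max(0, int(hits.start[inside].min()))
            te = min(L, int(hits.end[inside].max()))
            if te - ts < params.min_size:
                continue
            calls.append(ClusterCall(chrom=chrom, start=ts, end=te))
    calls.sort(key=lambda c: (c.chrom, c.start))
    for call in calls:
        call_directionality(call, hits, mono_threshold=params.mono_threshold)
    return calls


def _window_sums(bins: np.ndarray, k: int) -> np.ndarray:
    """Sum of k consecutive step-bins at every offset (= sliding window sums)."""
    c = np.concatenate(([0.0], np.cumsum(bins)))
    if len(bins) < k:
        return np.empty(0)
    return c[k:] - c[:-k]


def _merge_windows(qual_idx: np.ndarray, params: ClusterParams, chrom_len: int):
    """Merge qualifying windows that overlap or abut within one step."""
    if len(qual_idx) == 0:
        return
    starts = qual_idx * params.step
    cur_s = int(starts[0])
    cur_e = cur_s + params.window
    for s in starts[1:]:
        s = int(s)
        if s <= cur_e + params.step:
            cur_e = s + params.window
        else:
            yield cur_s, min(cur_e, chrom_len)
            cur_s, cur_e = s, s + params.window
    yield cur_s, min(cur_e, chrom_len)


def call_directionality(
    cluster: ClusterCall, hits: HitTable, mono_threshold: float = 0.75
) -> str:
    """Mono-directional if >= ``mono_threshold`` of weighted mass is on one strand."""
    ci = hits.ref_names.index(cluster.chrom)
    fp = hits.five_prime
    inside = (hits.ref_index == ci) & (fp >= cluster.start) & (fp < cluster.end)
    mass = hits.hit_mass[inside]
    total = float(mass.sum())
    plus = float(mass[hits.strand[inside] == "+"].sum())
    cluster.weighted_mass = total
    if total == 0:
        cluster.directionality = "bidirectional"
        cluster.main_strand_fraction = 0.0
        return cluster.directionality
    frac_plus = plus / total
    main_frac = max(frac_plus, 1.0 - frac_plus)
    cluster.main_strand_fraction = main_frac
    if main_frac >= mono_threshold:
        cluster.directionality = "mono_plus" if frac_plus >= 0.5 else "mono_minus"
    else:
        cluster.directionality = "bidirectional"
        _find_switch_point(cluster, hits.five_prime[inside], mass, hits.strand[inside])
    return cluster.directionality


def _find_switch_point(
    cluster: ClusterCall, pos: np.ndarray, mass: np.ndarray, strand: np.ndarray
) -> None:
    """Strand-switch point of a bidirectional cluster.

    Chooses the split position maximizing strand consistency (left-arm mass
    on one strand plus right-arm mass on the other); ties resolve to the
    leftmost split.
    """
    order = np.argsort(pos, kind="stable")
    pos, mass, strand = pos[order], mass[order], strand[order]
    plus_c = np.concatenate(([0.0], np.cumsum(np.where(strand == "+", mass, 0.0))))
    minus_c = np.concatenate(([0.0], np.cumsum(np.where(strand == "-", mass, 0.0))))
    # candidate splits: before each read and after the last
    best_score, best_i, best_arms = -1.0, 0, ("+", "-")
    for i in range(len(pos) + 1):
        lp, lm = plus_c[i], minus_c[i]
        rp, rm = plus_c[-1] - lp, minus_c[-1] - lm
        for arms in (("-", "+"), ("+", "-")):
            score = (lm if arms[0] == "-" else lp) + (rp if arms[1] == "+" else rm)
            if score > best_score:
                best_score, best_i, best_arms = score, i, arms
    cluster.switch_point = int(pos[best_i]) if best_i < len(pos) else cluster.end
    cluster.arm_strands = best_arms


def _overlap_bp(tree: IntervalTree, start: int, end: int) -> int:
    return sum(min(iv.end, end) - max(iv.begin, start) for iv in tree.overlap(start, end))


def cluster_content(
    clusters: list[ClusterCall],
    genes: list[GeneModel],
    repeats: RepeatAnnotation,
    genome_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-cluster sequence content and genome-relative TE enrichment.

    Returns one row per cluster with bp shares of TE, protein-coding exon,
    pseudogene and uncharacterized sequence, the list of embedded genes with
    orientation relative to the cluster main strand, and per-family TE
    enrichment ratios (share in clusters / share in genome) in the attrs.
    """
    te_trees: dict[str, IntervalTree] = {}
    fam_trees: dict[tuple[str, str], IntervalTree] = {}
    for row in repeats.records.itertuples(index=False):
        te_trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row)
        fam_trees.setdefault((row.chrom, row.family), IntervalTree()).addi(row.start, row.end)
    exon_trees: dict[str, IntervalTree] = {}
    pseudo_trees: dict[str, IntervalTree] = {}
    gene_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom, []).append(g)
        target = pseudo_trees if g.biotype == "pseudogene" else exon_trees
        if g.biotype in ("protein_coding", "pseudogene"):
            for s, e in g.exons:
                target.setdefault(g.chrom, IntervalTree()).addi(s, e)

    genome_bp = sum(genome_lengths.values())
    fam_genome_bp = (
        repeats.records.assign(bp=lambda d: d.end - d.start).groupby("family")["bp"].sum()
        if len(repeats.records)
        else pd.Series(dtype=float)
    )

    rows = []
    fam_cluster_bp: dict[str, int] = {}
    total_cluster_bp = 0
    for c in clusters:
        total_cluster_bp += c.size
        te_tree = te_trees.get(c.chrom, IntervalTree())
        te_bp = 0
        div_sum = 0.0
        for iv in te_tree.overlap(c.start, c.end):
            ov = min(iv.end, c.end) - max(iv.begin, c.start)
            te_bp += ov
            div_sum += ov * iv.data.divergence
            fam_cluster_bp[iv.data.family] = fam_cluster_bp.get(iv.data.family, 0) + ov
        exon_bp = _overlap_bp(exon_trees.get(c.chrom, IntervalTree()), c.start, c.end)
        pseudo_bp = _overlap_bp(pseudo_trees.get(c.chrom, IntervalTree()), c.start, c.end)
        embedded = []
        for g in gene_by_chrom.get(c.chrom, []):
            if g.start < c.end and g.end > c.start:
                local_main = c.main_strand_at((g.start + g.end) // 2)
                orient = "sense" if g.strand == local_main else "antisense"
                embedded.append((g.gene_id, g.biotype, orient))
        other_bp = max(0, c.size - min(c.size, te_bp + exon_bp + pseudo_bp))
        rows.append(
            dict(
                chrom=c.chrom,
                start=c.start,
                end=c.end,
                size=c.size,
                directionality=c.directionality,
                weighted_mass=c.weighted_mass,
                te_frac=min(1.0, te_bp / c.size),
                exon_frac=min(1.0, exon_bp / c.size),
                pseudogene_frac=min(1.0, pseudo_bp / c.size),
                other_frac=other_bp / c.size,
                mean_te_divergence=(div_sum / te_bp) if te_bp else float("nan"),
                embedded_genes=";".join(f"{g}|{b}|{o}" for g, b, o in embedded),
                n_antisense_genes=sum(1 for _, _, o in embedded if o == "antisense"),
            )
        )
    out = pd.DataFrame(rows)
    enrich = {}
    for fam, cbp in fam_cluster_bp.items():
        g_share = float(fam_genome_bp.get(fam, 0)) / genome_bp if genome_bp else 0.0
        c_share = cbp / total_cluster_bp if total_cluster_bp else 0.0
        enrich[fam] = (c_share / g_share) if g_share > 0 else float("inf")
    out.attrs["te_enrichment"] = enrich
    return out


def te_strand_bias(
    clusters: list[ClusterCall],
    repeats: RepeatAnnotation,
    hits: HitTable,
) -> pd.DataFrame:
    """Insertion-strand bias of TE copies inside clusters vs read strand bias.

    For each TE family: the fraction of its copies inside clusters that are
    inserted sense to the cluster main strand, and the fraction of the
    family's in-cluster read mass that is sense to the TE consensus (read
    strand equal to copy strand). The Spearman rank correlation across
    families is stored in ``attrs["spearman"]`` when >= 2 families qualify.
    """
    cluster_trees: dict[str, IntervalTree] = {}
    for c in clusters:
        cluster_trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, c)
    fp = hits.five_prime
    mass = hits.hit_mass
    chrom_index = {n: i for i, n in enumerate(hits.ref_names)}

    copy_stats: dict[str, list[int]] = {}  # family -> [n_sense, n_total]
    read_stats: dict[str, list[float]] = {}  # family -> [sense_mass, total_mass]
    for row in repeats.records.itertuples(index=False):
        tree = cluster_trees.get(row.chrom)
        if tree is None:
            continue
        hit_clusters = tree.overlap(row.start, row.end)
        if not hit_clusters:
            continue
        cluster = min(hit_clusters, key=lambda iv: iv.begin).data
        st = copy_stats.setdefault(row.family, [0, 0])
        st[1] += 1
        if row.strand == cluster.main_strand_at((row.start + row.end) // 2):
            st[0] += 1
        ci = chrom_index.get(row.chrom)
        if ci is None:
            continue
        inside = (
            (hits.ref_index == ci) & (fp >= row.start) & (fp < row.end)
        )
        if inside.any():
            rs = read_stats.setdefault(row.family, [0.0, 0.0])
            m = mass[inside]
            rs[1] += float(m.sum())
            rs[0] += float(m[hits.strand[inside] == row.strand].sum())

    rows = []
    for fam, (n_sense, n_total) in sorted(copy_stats.items()):
        smass, tmass = read_stats.get(fam, (0.0, 0.0))
        rows.append(
            dict(
                family=fam,
                n_copies=n_total,
                copy_sense_fraction=n_sense / n_total,
                read_mass=tmass,
                read_sense_fraction=(smass / tmass) if tmass else float("nan"),
            )
        )
    out = pd.DataFrame(rows)
    usable = out.dropna(subset=["read_sense_fraction"]) if len(out) else out
    if len(usable) >= 2:
        rho, p = stats.spearmanr(usable["copy_sense_fraction"], usable["read_sense_fraction"])
        out.attrs["spearman"] = float(rho)
        out.attrs["spearman_p"] = float(p)
    return out
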