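"""Gene-level piRNA target calling and the cross-species homolog overlap test.

Reads are mapped to spliced transcripts (one transcript per gene, the
longest). A gene passes the coverage filter at >= 10 weighted reads per
million mapped reads and is called a target when the 5'-overlap histogram of
its sense/antisense reads shows an evident ping-pong signature. Target lists
from two species are compared through their homology table with a
Monte-Carlo permutation test: random gene sets of the observed sizes are
drawn from each species' universe and the cross-species homolog overlap
recomputed per draw, yielding E(X) and a one-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CollapsedReadSet, GeneModel, spliced_sequence
from .mapping import ExactMatchIndex, HitTable, map_perfect
from .signatures import OverlapHistogram, PingPongResult, overlap_histogram, pingpong_result

__all__ = [
    "GeneTargetResult",
    "OverlapTestResult",
    "build_transcriptome",
    "map_to_transcripts",
    "gene_coverage",
    "gene_pingpong",
    "call_targets",
    "homolog_overlap_test",
]

RPM_THRESHOLD = 10.0


@dataclass
class GeneTargetResult:
    gene_id: str
    rpm: float
    sense_mass: float
    antisense_mass: float
    pingpong: PingPongResult | None
    is_target: bool
    region_density: dict[str, float] = field(default_factory=dict)  # reads/kb per region


@dataclass
class OverlapTestResult:
    observed: int
    expected: float
    p_value: float
    draws: int
    seed: int


def build_transcriptome(
    genes: list[GeneModel], genome: dict[str, str]
) -> tuple[dict[str, str], dict[str, GeneModel]]:
    """Spliced transcript sequences, one per gene (longest spliced form)."""
    best: dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.gene_id)
        if cur is None or g.spliced_length > cur.spliced_length:
            best[g.gene_id] = g
    seqs = {gid: spliced_sequence(m, genome) for gid, m in best.items()}
    return seqs, best


def map_to_transcripts(
    reads: CollapsedReadSet,
    transcripts: dict[str, str],
    genomic_weights: np.ndarray | None = None,
    weight_mode: str = "genomic",
    k: int = 12,
) -> HitTable:
    """Map reads to spliced transcripts, both orientations.

    Sense hits (+) match the mRNA; antisense hits (-) match its reverse
    complement. With ``weight_mode="genomic"`` each sequence keeps its
    genomic multimapper weight (falling back to 1/transcript-hit-count for
    sequences without genomic hits); ``weight_mode="transcript"`` weights by
    the reciprocal transcript hit count instead.
    """
    index = ExactMatchIndex(transcripts, k=k)
    table = map_perfect(reads, index, orientation="both")
    t_counts = table.hit_counts
    with np.errstate(divide="ignore"):
        t_w = np.where(t_counts > 0, 1.0 / np.maximum(t_counts, 1), np.nan)
    if weight_mode == "transcript" or genomic_weights is None:
        table.weights = t_w
    elif weight_mode == "genomic":
        table.weights = np.where(np.isfinite(genomic_weights), genomic_weights, t_w)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    return table


def gene_coverage(table: HitTable, total_mapped_reads: int) -> pd.DataFrame:
    """Weighted coverage per gene in reads-per-million-mapped (rpm).

    ``total_mapped_reads`` is the library size (genome-mapped read count).
    One row per gene with weighted mass, sense/antisense split and rpm.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total mapped read count must be positive")
    mass = table.hit_mass
    rows = []
    for gi, gene in enumerate(table.ref_names):
        on_gene = table.ref_index == gi
        m = mass[on_gene]
        sense = float(m[table.strand[on_gene] == "+"].sum())
        anti = float(m[table.strand[on_gene] == "-"].sum())
        total = sense + anti
        rows.append(
            dict(
                gene_id=gene,
                weighted_mass=total,
                sense_mass=sense,
                antisense_mass=anti,
                rpm=total * 1e6 / total_mapped_reads,
            )
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _region_densities(
    table: HitTable, gene_index: int, model: GeneModel | None
) -> dict[str, float]:
    """Weighted reads per kb of 5'UTR / CDS / 3'UTR in transcript coordinates."""
    if model is None or model.cds is None:
        return {}
    # transcript-coordinate CDS bounds
    exon_lens = [e - s for s, e in model.exons]
    tx_len = sum(exon_lens)
    cs, ce = model.cds
    def to_tx(gpos: int) -> int:
        off = 0
        for (s, e), L in zip(model.exons, exon_lens):
            if gpos < e:
                return off + max(0, gpos - s)
            off += L
        return tx_len
    lo, hi = to_tx(cs), to_tx(ce)
    if model.strand == "-":
        lo, hi = tx_len - hi, tx_len - lo
    regions = {"utr5": (0, lo), "cds": (lo, hi), "utr3": (hi, tx_len)}
    on_gene = table.ref_index == gene_index
    fp = table.five_prime[on_gene]
    m = table.hit_mass[on_gene]
    out = {}
    for name, (s, e) in regions.items():
        if e <= s:
            out[name] = float("nan")
            continue
        sel = (fp >= s) & (fp < e)
        out[name] = float(m[sel].sum()) / ((e - s) / 1000.0)
    return out


def gene_pingpong(
    table: HitTable, gene_id: str, o_max: int = 20, z_threshold: float | None = None
) -> PingPongResult:
    """Ping-pong signature of one gene's reads in transcript coordinates."""
    gi = table.ref_names.index(gene_id)
    sub = table.subset(table.ref_index == gi)
    hist = overlap_histogram(sub, o_max=o_max)
    return pingpong_result(hist, z_threshold=z_threshold)


def call_targets(
    table: HitTable,
    total_mapped_reads: int,
    models: dict[str, GeneModel] | None = None,
    rpm_threshold: float = RPM_THRESHOLD,
    z_threshold: float | None = None,
) -> list[GeneTargetResult]:
    """Coverage filter + per-gene ping-pong call over all transcripts.

    Genes with rpm >= ``rpm_threshold`` (boundary inclusive) are tested for
    an evident ping-pong signature; ``is_target`` requires both.
    """
    cov = gene_coverage(table, total_mapped_reads)
    results = []
    for gi, gene in enumerate(table.ref_names):
        row = cov.loc[gene]
        covered = row["rpm"] >= rpm_threshold
        pp = None
        is_target = False
        if covered:
            pp = gene_pingpong(table, gene, z_threshold=z_threshold)
            is_target = bool(pp.evident)
        results.append(
            GeneTargetResult(
                gene_id=gene,
                rpm=float(row["rpm"]),
                sense_mass=float(row["sense_mass"]),
                antisense_mass=float(row["antisense_mass"]),
                pingpong=pp,
                is_target=is_target,
                region_density=_region_densities(
                    table, gi, models.get(gene) if models else None
                ),
            )
        )
    return results


def targets_table(results: list[GeneTargetResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dict(
            gene_id=r.gene_id,
            rpm=r.rpm,
            sense_mass=r.sense_mass,
            antisense_mass=r.antisense_mass,
            is_target=r.is_target,
        )
        if r.pingpong is not None:
            row["z"] = r.pingpong.z
            row["twofold"] = r.pingpong.twofold
            for o in range(1, r.pingpong.histogram.o_max + 1):
                row[f"s{o}"] = r.pingpong.histogram.s(o)
        for k, v in r.region_density.items():
            row[f"{k}_reads_per_kb"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def homolog_overlap_test(
    targets_a: list[str],
    targets_b: list[str],
    homology: list[tuple[str, str]] | pd.DataFrame,
    universe_a: list[str],
    universe_b: list[str],
    draws: int = 1_000_000,
    seed: int = 0,
    batch: int = 20_000,
) -> OverlapTestResult:
    """Monte-Carlo test of cross-species target-gene overlap.

    X = number of species-A target genes with at least one homolog among the
    species-B targets. Each draw samples |targets_a| and |targets_b| genes
    uniformly without replacement from the universes and recomputes X.
    E(X) is the mean over draws; the p-value uses the add-one estimator
    (#draws with X >= X_obs + 1) / (draws + 1), so it is never zero.
    """
    if isinstance(homology, pd.DataFrame):
        homology = list(homology.itertuples(index=False, name=None))
    ua = {g: i for i, g in enumerate(universe_a)}
    ub = {g: i for i, g in enumerate(universe_b)}
    for g in targets_a:
        if g not in ua:
            raise ValueError(f"target {g!r} not in universe A")
    for g in targets_b:
        if g not in ub:
            raise ValueError(f"target {g!r} not in universe B")
    n1, n2 = len(targets_a), len(targets_b)
    if n1 > len(ua) or n2 > len(ub):
        raise ValueError("target list larger than its universe")
    na, nb = len(ua), len(ub)
    # homology as a boolean matrix A x B (universes are modest gene lists)
    H = np.zeros((na, nb), dtype=bool)
    for ga, gb in homology:
        if ga in ua and gb in ub:
            H[ua[ga], ub[gb]] = True

    b_set = np.zeros(nb, dtype=bool)
    b_set[[ub[g] for g in targets_b]] = True
    a_idx = np.array([ua[g] for g in targets_a], dtype=np.intp)
    observed = int((H[a_idx] @ b_set > 0).sum()) if n1 and n2 else 0

    one_to_one = (H.sum(axis=1) <= 1).all()
    partner = H.argmax(axis=1) if one_to_one else None
    has_partner = H.any(axis=1)

    rng = np.random.default_rng(seed)
    total_x = 0.0
    n_ge = 0
    done = 0
    while done < draws:
        m = min(batch, draws - done)
        a_sel = np.argpartition(rng.random((m, na)), n1 - 1, axis=1)[:, :n1] if n1 else None
        b_sel = np.argpartition(rng.random((m, nb)), n2 - 1, axis=1)[:, :n2] if n2 else None
        if n1 == 0 or n2 == 0:
            x = np.zeros(m)
        else:
            bmask = np.zeros((m, nb), dtype=bool)
            np.put_along_axis(bmask, b_sel, True, axis=1)
            if one_to_one:
                hit = has_partner[a_sel] & np.take_along_axis(
                    bmask, np.where(has_partner[a_sel], partner[a_sel], 0), axis=1
                )
                x = hit.sum(axis=1)
            else:
                amask = np.zeros((m, na), dtype=bool)
                np.put_along_axis(amask, a_sel, True, axis=1)
                cross = bmask @ H.T  # (m, na) counts of B-homologs drawn per A gene
                x = (amask & (cross > 0)).sum(axis=1)
        total_x += float(x.sum())
        n_ge += int((x >= observed).sum())
        done += m
    return OverlapTestResult(
        observed=observed,
        expected=total_x / draws,
        p_value=(n_ge + 1) / (draws + 1),
        draws=draws,
        seed=seed,
    )
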