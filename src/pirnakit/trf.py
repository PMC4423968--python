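"""tRNA-derived fragment (tRF) profiling.

Periodate-resistant small RNAs include abundant 5' tRNA halves. Reads
classified as tRNA are matched back to the tRNA reference set, assigned to
anticodon families, and profiled by 5' start position on the tRNA (a start
at the very 5' end marks a genuine 5' half, interior starts mark putative
degradation), length, 1U rate, and by TE co-annotation of their genomic
hits (tRNA-derived SINEs make this overlap informative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import CollapsedReadSet, ConfigError, RepeatAnnotation
from .mapping import HitTable

__all__ = ["TRFProfile", "trf_profile", "library_comparison"]

FIVE_PRIME_MAX_START = 3  # 1-based start positions <= this count as 5' fragments


@dataclass
class TRFProfile:
    """Per-tRNA-type composition of the tRNA-classified reads."""

    type_shares: pd.Series  # anticodon family -> weighted share (sums to 1)
    start_histogram: pd.Series  # 1-based tRNA position of read 5' end -> mass
    length_histogram: pd.Series
    rate_1U: float
    five_prime_share: float  # mass fraction starting at positions <= 3
    te_share_sense: float  # genomic-hit mass fraction inside TEs, by orientation
    te_share_antisense: float
    trna_names: tuple[str, ...] = ()

    @property
    def total_mass(self) -> float:
        return float(self.start_histogram.sum())


def trf_profile(
    trna_reads: CollapsedReadSet,
    trna_set: dict[str, str],
    genomic_hits: HitTable | None = None,
    repeats: RepeatAnnotation | None = None,
    weighting: str = "weighted",
) -> TRFProfile:
    """Profile tRNA-classified reads against the tRNA reference set.

    Reads matching several tRNA types contribute 1/n mass to each matching
    type; the start position is the leftmost 1-based match coordinate on the
    tRNA. ``weighting="weighted"`` uses count x genomic multimapper weight
    (weight 1 for sequences without genomic hits), ``"raw"`` uses counts.
    """
    if not trna_set:
        raise ConfigError("tRNA reference set is empty")
    # deduplicate identical tRNA sequences (keep first name)
    seen: dict[str, str] = {}
    for name, seq in trna_set.items():
        seen.setdefault(seq, name)
    refs = {name: seq for seq, name in seen.items()}

    if weighting == "weighted" and genomic_hits is not None:
        w = np.where(np.isfinite(genomic_hits.weights), genomic_hits.weights, 1.0)
        read_mass = trna_reads.counts * w
    elif weighting in ("weighted", "raw"):
        read_mass = trna_reads.counts.astype(float)
    else:
        raise ConfigError(f"unknown weighting {weighting!r}")

    type_mass: dict[str, float] = {}
    start_mass: dict[int, float] = {}
    length_mass: dict[int, float] = {}
    u1_mass = 0.0
    five_prime_mass = 0.0
    total = 0.0
    for i, seq in enumerate(trna_reads.sequences):
        matches: dict[str, int] = {}
        for name, ref in refs.items():
            pos = ref.find(seq)
            if pos >= 0:
                ttype = name  # names follow the AminoAcid-Anticodon convention
                if ttype not in matches or pos < matches[ttype]:
                    matches[ttype] = pos
        if not matches:
            continue
        m = float(read_mass[i])
        total += m
        split = m / len(matches)
        start = min(matches.values()) + 1  # leftmost across matched types, 1-based
        for ttype, pos in matches.items():
            type_mass[ttype] = type_mass.get(ttype, 0.0) + split
        start_mass[start] = start_mass.get(start, 0.0) + m
        length_mass[len(seq)] = length_mass.get(len(seq), 0.0) + m
        if seq[0] == "T":
            u1_mass += m
        if start <= FIVE_PRIME_MAX_START:
            five_prime_mass += m

    te_sense = te_anti = 0.0
    if genomic_hits is not None and repeats is not None and len(repeats):
        trees: dict[str, IntervalTree] = {}
        for row in repeats.records.itertuples(index=False):
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.strand)
        hm = genomic_hits.hit_mass
        fp = genomic_hits.five_prime
        g_total = 0.0
        for i in range(len(genomic_hits)):
            g_total += float(hm[i])
            tree = trees.get(genomic_hits.ref_names[genomic_hits.ref_index[i]])
            if tree is None:
                continue
            ivs = tree.at(int(fp[i]))
            if ivs:
                iv = min(ivs, key=lambda v: v.begin)
                if genomic_hits.strand[i] == iv.data:
                    te_sense += float(hm[i])
                else:
                    te_anti += float(hm[i])
        if g_total > 0:
            te_sense /= g_total
            te_anti /= g_total

    def _series(d: dict, name: str) -> pd.Series:
        return pd.Series(d, name=name).sort_index() if d else pd.Series(dtype=float, name=name)

    shares = _series(type_mass, "share")
    if total > 0:
        shares = shares / total
    return TRFProfile(
        type_shares=shares,
        start_histogram=_series(start_mass, "mass"),
        length_histogram=_series(length_mass, "mass"),
        rate_1U=(u1_mass / total) if total else float("nan"),
        five_prime_share=(five_prime_mass / total) if total else float("nan"),
        te_share_sense=te_sense,
        te_share_antisense=te_anti,
        trna_names=tuple(sorted(trna_set)),
    )


def library_comparison(
    treated: TRFProfile,
    untreated: TRFProfile,
    class_shares_treated: pd.Series | None = None,
    class_shares_untreated: pd.Series | None = None,
) -> pd.DataFrame:
    """Differences between two libraries' tRF profiles (e.g. oxidized vs not).

    Returns per-quantity deltas (treated minus untreated) for the tRNA type
    shares, the 5'-start share and the 1U rate; optional ncRNA class shares
    are compared the same way when both are supplied.
    """
    if treated.trna_names != untreated.trna_names:
        raise ConfigError("profiles were built against different tRNA sets")
    rows = []
    all_types = sorted(set(treated.type_shares.index) | set(untreated.type_shares.index))
    for t in all_types:
        a = float(treated.type_shares.get(t, 0.0))
        b = float(untreated.type_shares.get(t, 0.0))
        rows.append(dict(quantity=f"type_share:{t}", treated=a, untreated=b, delta=a - b))
    rows.append(
        dict(
            quantity="five_prime_share",
            treated=treated.five_prime_share,
            untreated=untreated.five_prime_share,
            delta=treated.five_prime_share - untreated.five_prime_share,
        )
    )
    rows.append(
        dict(
            quantity="rate_1U",
            treated=treated.rate_1U,
            untreated=untreated.rate_1U,
            delta=treated.rate_1U - untreated.rate_1U,
        )
    )
    if class_shares_treated is not None and class_shares_untreated is not None:
        for cls in sorted(set(class_shares_treated.index) | set(class_shares_untreated.index)):
            a = float(class_shares_treated.get(cls, 0.0))
            b = float(class_shares_untreated.get(cls, 0.0))
            rows.append(dict(quantity=f"class_share:{cls}", treated=a, untreated=b, delta=a - b))
    return pd.DataFrame(rows)
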