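"""Small-RNA sequence signatures.

Length distributions, positional nucleotide frequencies (anchored at either
end), 5'-overlap histograms between opposite-strand reads, and the two
ping-pong calls used throughout the pipeline: the z-score of the 10-nt
overlap bin against the other overlap bins, and the 2-fold peak rule.

The ping-pong signature is the population-level fingerprint of secondary
piRNA biogenesis: a piRNA-guided cleavage 10 nt from the guide's 5' end
produces responder piRNAs whose 5' ends overlap the guide's by exactly
10 nt on the opposite strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CollapsedReadSet, ConfigError
from .mapping import HitTable

__all__ = [
    "OverlapHistogram",
    "PingPongResult",
    "PositionalProfile",
    "length_distribution",
    "positional_nt_freq",
    "overlap_histogram",
    "pingpong_z",
    "twofold_rule",
    "pingpong_result",
]


@dataclass
class OverlapHistogram:
    """Weighted pair mass per 5'-overlap length ``o`` in 1..o_max."""

    scores: np.ndarray  # scores[o-1] = s(o)
    n_pairs: int  # number of contributing hit pairs (unweighted)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores < 0).any():
            raise ValueError("overlap scores must be non-negative")

    @property
    def o_max(self) -> int:
        return len(self.scores)

    def s(self, o: int) -> float:
        return float(self.scores[o - 1])

    @property
    def is_empty(self) -> bool:
        return not self.scores.any()


@dataclass
class PingPongResult:
    histogram: OverlapHistogram
    z: float  # NaN when the background has zero variance
    twofold: bool
    evident: bool


@dataclass
class PositionalProfile:
    """Per-position nucleotide frequencies from one end of the reads."""

    freqs: pd.DataFrame  # index position 1.., columns A/C/G/T(/N)
    anchor: str  # "five_prime" | "three_prime"
    rate_1U: float
    rate_10A: float
    rate_3pC: float


def length_distribution(
    reads: CollapsedReadSet,
    weights: str = "by_read_count",
    subset: np.ndarray | None = None,
) -> pd.Series:
    """Histogram of read lengths, by read count or by unique sequence."""
    rs = reads if subset is None else reads.subset(subset)
    lengths = rs.lengths
    if weights == "by_read_count":
        w = rs.counts
    elif weights == "by_unique_sequence":
        w = np.ones(len(rs), dtype=np.int64)
    else:
        raise ConfigError(f"unknown weighting {weights!r}")
    if len(lengths) == 0:
        return pd.Series(dtype=np.int64, name="reads")
    out = pd.Series(
        np.bincount(lengths, weights=w)[lengths.min() :],
        index=pd.RangeIndex(lengths.min(), lengths.max() + 1, name="length"),
        name="reads",
    )
    return out[out > 0].astype(np.int64)


def positional_nt_freq(
    reads: CollapsedReadSet,
    anchor: str = "five_prime",
    weighting: str = "unique",
    subset: np.ndarray | None = None,
) -> PositionalProfile:
    """Nucleotide frequencies per position from the 5' or 3' end.

    Positions beyond a read's length do not contribute to that position's
    denominator. Default weighting counts each unique sequence once (the
    convention for 1U/10A rates); ``weighting="count"`` weights by read count.
    """
    if anchor not in ("five_prime", "three_prime"):
        raise ConfigError(f"unknown anchor {anchor!r}")
    rs = reads if subset is None else reads.subset(subset)
    if weighting == "unique":
        w = np.ones(len(rs))
    elif weighting == "count":
        w = rs.counts.astype(float)
    else:
        raise ConfigError(f"unknown weighting {weighting!r}")
    max_len = int(rs.lengths.max()) if len(rs) else 0
    bases = "ACGTN"
    tallies = np.zeros((max_len, len(bases)))
    base_idx = {b: i for i, b in enumerate(bases)}
    for seq, wi in zip(rs.sequences, w):
        s = seq if anchor == "five_prime" else seq[::-1]
        for pos, b in enumerate(s):
            tallies[pos, base_idx[b]] += wi
    totals = tallies.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals > 0, tallies / totals, 0.0)
    df = pd.DataFrame(freqs, index=pd.RangeIndex(1, max_len + 1, name="position"), columns=list(bases))

    def _rate(a: str, pos: int, base: str) -> float:
        if anchor != a or max_len < pos:
            # recompute from the opposite anchor when needed
            t = np.zeros(len(bases))
            for seq, wi in zip(rs.sequences, w):
                s = seq if a == "five_prime" else seq[::-1]
                if len(s) >= pos:
                    t[base_idx[s[pos - 1]]] += wi
            return float(t[base_idx[base]] / t.sum()) if t.sum() else float("nan")
        return float(df.loc[pos, base])

    return PositionalProfile(
        freqs=df,
        anchor=anchor,
        rate_1U=_rate("five_prime", 1, "T"),
        rate_10A=_rate("five_prime", 10, "A"),
        rate_3pC=_rate("three_prime", 1, "C"),
    )


def overlap_histogram(hits: HitTable, o_max: int = 20) -> OverlapHistogram:
    """5'-overlap histogram between opposite-strand hits on each reference.

    For a plus-strand hit with 5' position p and a minus-strand hit with 5'
    position q on the same reference, the overlap is ``o = q - p + 1``; every
    pair with ``1 <= o <= o_max`` adds the product of the two hits' weighted
    masses (count x multimapper weight) to bin o. Distinct sequences sharing
    a 5' position each contribute (their masses sum per position).
    """
    scores = np.zeros(o_max)
    n_pairs = 0
    mass = hits.hit_mass
    fp = hits.five_prime
    for ref in np.unique(hits.ref_index):
        on_ref = hits.ref_index == ref
        plus = on_ref & (hits.strand == "+")
        minus = on_ref & (hits.strand == "-")
        if not plus.any() or not minus.any():
            continue
        p_pos, p_inv = np.unique(fp[plus], return_inverse=True)
        p_mass = np.bincount(p_inv, weights=mass[plus])
        p_n = np.bincount(p_inv)
        m_pos, m_inv = np.unique(fp[minus], return_inverse=True)
        m_mass = np.bincount(m_inv, weights=mass[minus])
        m_n = np.bincount(m_inv)
        for o in range(1, o_max + 1):
            target = p_pos + o - 1
            j = np.searchsorted(m_pos, target)
            ok = (j < len(m_pos)) & (m_pos[np.minimum(j, len(m_pos) - 1)] == target)
            if ok.any():
                scores[o - 1] += float(np.sum(p_mass[ok] * m_mass[j[ok]]))
                n_pairs += int(np.sum(p_n[ok] * m_n[j[ok]]))
    return OverlapHistogram(scores=scores, n_pairs=n_pairs)


def pingpong_z(hist: OverlapHistogram) -> float:
    """z-score of the 10-nt overlap bin against all other bins.

    The background is every bin except o=10; its dispersion is the sample
    (n-1) standard deviation. Returns NaN when the background has zero
    variance (the z-score is then not evaluable and callers fall back to the
    2-fold rule).
    """
    if hist.o_max < 11:
        raise ConfigError("overlap histogram must extend to at least o=11")
    background = np.delete(hist.scores, 9)
    sd = float(np.std(background, ddof=1))
    if sd == 0.0:
        # a perfectly flat histogram is scored 0; a spike over a constant
        # background has no finite z (callers fall back to the 2-fold rule)
        return 0.0 if hist.s(10) == background.mean() else float("nan")
    return (hist.s(10) - float(background.mean())) / sd


def twofold_rule(hist: OverlapHistogram) -> bool:
    """True iff s(10) is at least twice the next-highest bin (and positive)."""
    s10 = hist.s(10)
    if s10 <= 0:
        return False
    rest = np.delete(hist.scores, 9)
    return bool(s10 >= 2.0 * rest.max())


def pingpong_result(hist: OverlapHistogram, z_threshold: float | None = None) -> PingPongResult:
    """Combine the z-score and 2-fold rule into one signature call.

    ``evident`` is the 2-fold rule; when ``z_threshold`` is given, a finite
    z >= threshold is additionally required.
    """
    z = pingpong_z(hist)
    two = twofold_rule(hist)
    evident = two
    if z_threshold is not None and evident:
        evident = bool(np.isfinite(z) and z >= z_threshold) or not np.isfinite(z) and two
    return PingPongResult(histogram=hist, z=z, twofold=two, evident=evident)
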