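"""Exact-match short-read alignment with all-hit reporting.

Perfect-match mapping is the contract of the whole pipeline: a read either
occurs verbatim in the reference (on either strand) or it does not, and every
occurrence is reported. Multimapping sequences are down-weighted by the
reciprocal of their total hit count so that each sequenced read contributes
total mass 1 to downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CollapsedReadSet, ConfigError, reverse_complement

__all__ = ["ExactMatchIndex", "HitTable", "map_perfect", "assign_weights"]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class ExactMatchIndex:
    """k-mer seed index over a set of reference sequences.

    Every position of every reference is hashed over a window of ``k`` bases;
    a query is located by looking up its first k-mer and verifying the full
    sequence by direct comparison, so results are exact. Minus-strand hits are
    found by searching the reverse complement of the query.
    """

    def __init__(self, references: dict[str, str], k: int = 12):
        if k < 1 or k > 31:
            raise ConfigError("seed length k must be in [1, 31]")
        self.k = k
        self.ref_names: list[str] = []
        self.ref_seqs: list[str] = []
        offsets = [0]
        hash_parts = []
        pos_parts = []
        for name, seq in references.items():
            codes = _encode(seq)
            if (codes == 255).any() and set(seq) - set("ACGTN"):
                raise ValueError(f"reference {name!r} contains non-ACGTN symbols")
            self.ref_names.append(name)
            self.ref_seqs.append(seq)
            L = len(seq)
            if L >= k:
                n = L - k + 1
                h = np.zeros(n, dtype=np.int64)
                bad = np.zeros(n, dtype=bool)
                for j in range(k):
                    c = codes[j : j + n]
                    h = h * 4 + np.where(c == 255, 0, c)
                    bad |= c == 255
                valid = np.flatnonzero(~bad)
                hash_parts.append(h[valid])
                pos_parts.append(valid + offsets[-1])
            offsets.append(offsets[-1] + L)
        self.offsets = np.array(offsets, dtype=np.int64)
        if hash_parts:
            hashes = np.concatenate(hash_parts)
            positions = np.concatenate(pos_parts)
            order = np.argsort(hashes, kind="stable")
            self.sorted_hashes = hashes[order]
            self.sorted_positions = positions[order]
        else:
            self.sorted_hashes = np.empty(0, dtype=np.int64)
            self.sorted_positions = np.empty(0, dtype=np.int64)

    @property
    def ref_lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in zip(self.ref_names, self.ref_seqs)}

    def _hash_batch(self, seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """First-k-mer hash per query and a validity mask (False if N in seed)."""
        n = len(seqs)
        buf = "".join(s[: self.k] for s in seqs)
        codes = _CODE[np.frombuffer(buf.encode("ascii"), dtype=np.uint8)].reshape(n, self.k)
        valid = (codes != 255).all(axis=1)
        powers = 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        h = (np.where(codes == 255, 0, codes).astype(np.int64) * powers).sum(axis=1)
        return h, valid

    def _verify(self, gpos: int, query: str) -> tuple[int, int] | None:
        """Check a candidate seed position against the full query string."""
        ref_i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        local = int(gpos - self.offsets[ref_i])
        ref_seq = self.ref_seqs[ref_i]
        if local + len(query) <= len(ref_seq) and ref_seq[local : local + len(query)] == query:
            return ref_i, local
        return None

    def _kmer_hash(self, seq: str) -> int | None:
        codes = _encode(seq[: self.k])
        if (codes == 255).any():
            return None
        h = 0
        for c in codes:
            h = h * 4 + int(c)
        return h

    def _locate(self, query: str) -> list[tuple[int, int]]:
        """All (ref_index, local_start) where ``query`` occurs verbatim."""
        L = len(query)
        if L < self.k:
            raise ConfigError(f"query shorter than seed length k={self.k}")
        h = self._kmer_hash(query)
        if h is None:
            return []
        lo = np.searchsorted(self.sorted_hashes, h, side="left")
        hi = np.searchsorted(self.sorted_hashes, h, side="right")
        out = []
        for gpos in self.sorted_positions[lo:hi]:
            ref_i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
            local = int(gpos - self.offsets[ref_i])
            ref_seq = self.ref_seqs[ref_i]
            if local + L <= len(ref_seq) and ref_seq[local : local + L] == query:
                out.append((ref_i, local))
        return out

    def find(self, query: str, orientation: str = "both") -> list[tuple[int, str, int]]:
        """All exact occurrences of ``query`` as (ref_index, strand, start).

        ``start`` is 0-based on the reference plus strand; a minus-strand hit
        means the reverse complement of the query occurs at that position.
        """
        hits = [(r, "+", s) for r, s in self._locate(query)]
        if orientation == "both":
            rc = reverse_complement(query)
            minus = [(r, "-", s) for r, s in self._locate(rc)]
            if rc == query:  # palindromic query: both searches find the same loci
                hits.extend(m for m in minus if (m[0], "+", m[2]) not in set(hits))
            else:
                hits.extend(minus)
        elif orientation != "sense_only":
            raise ConfigError(f"unknown orientation {orientation!r}")
        return hits


@dataclass
class HitTable:
    """All perfect-match alignments of a collapsed read set.

    Columns are parallel numpy arrays; ``seq_index`` points into ``reads``.
    ``weights[i]`` is the multimapper weight of sequence i (1 / its total hit
    count; NaN until :func:`assign_weights` runs). The weighted mass of a hit
    is ``counts[seq_index] * weights[seq_index]``.
    """

    reads: CollapsedReadSet
    ref_names: list[str]
    seq_index: np.ndarray
    ref_index: np.ndarray
    strand: np.ndarray  # "+" / "-"
    start: np.ndarray
    end: np.ndarray
    hit_counts: np.ndarray = field(default=None)  # per sequence, 0 = unmapped
    weights: np.ndarray = field(default=None)  # per sequence

    def __post_init__(self) -> None:
        n = len(self.reads)
        if self.hit_counts is None:
            self.hit_counts = np.bincount(self.seq_index, minlength=n).astype(np.int64)
        if self.weights is None:
            self.weights = np.full(n, np.nan)

    def __len__(self) -> int:
        return len(self.seq_index)

    @property
    def five_prime(self) -> np.ndarray:
        """Position of the read 5' end on the reference plus strand."""
        return np.where(self.strand == "+", self.start, self.end - 1)

    @property
    def mapped_mask(self) -> np.ndarray:
        return self.hit_counts > 0

    @property
    def total_mapped_reads(self) -> int:
        """Number of sequenced reads whose sequence maps at least once."""
        return int(self.reads.counts[self.mapped_mask].sum())

    @property
    def hit_mass(self) -> np.ndarray:
        """Weighted read mass per hit: count x weight of the hit's sequence."""
        return self.reads.counts[self.seq_index] * self.weights[self.seq_index]

    @property
    def total_weighted_mass(self) -> float:
        return float(self.hit_mass.sum())

    def unmapped_sequences(self) -> list[str]:
        return [s for s, c in zip(self.reads.sequences, self.hit_counts) if c == 0]

    def subset(self, mask: np.ndarray) -> "HitTable":
        """Restrict to a subset of hits (weights and counts are kept as-is)."""
        mask = np.asarray(mask)
        return HitTable(
            reads=self.reads,
            ref_names=self.ref_names,
            seq_index=self.seq_index[mask],
            ref_index=self.ref_index[mask],
            strand=self.strand[mask],
            start=self.start[mask],
            end=self.end[mask],
            hit_counts=self.hit_counts,
            weights=self.weights,
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sequence": [self.reads.sequences[i] for i in self.seq_index],
                "ref": [self.ref_names[i] for i in self.ref_index],
                "strand": self.strand,
                "start": self.start,
                "end": self.end,
                "five_prime": self.five_prime,
                "count": self.reads.counts[self.seq_index],
                "weight": self.weights[self.seq_index],
            }
        )

    def to_bed(self, path) -> None:
        """BED6 export; score = multimapper weight x 1000, rounded."""
        with open(path, "w") as fh:
            for i in range(len(self)):
                si = self.seq_index[i]
                w = self.weights[si]
                score = int(round((0.0 if np.isnan(w) else w) * 1000))
                fh.write(
                    f"{self.ref_names[self.ref_index[i]]}\t{self.start[i]}\t{self.end[i]}\t"
                    f"seq{si}\t{score}\t{self.strand[i]}\n"
                )


def map_perfect(
    reads: CollapsedReadSet, index: ExactMatchIndex, orientation: str = "both"
) -> HitTable:
    """Report every exact occurrence of every read sequence in the index.

    ``orientation="sense_only"`` restricts to plus-strand occurrences, the
    mode used for ncRNA annotation where only sense matches count.
    """
    if orientation not in ("both", "sense_only"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    seqs = reads.sequences
    for s in seqs:
        if len(s) < index.k:
            raise ConfigError(f"query shorter than seed length k={index.k}")
    seq_idx: list[int] = []
    ref_idx: list[int] = []
    strands: list[str] = []
    starts: list[int] = []
    ends: list[int] = []

    def _candidates(hashes: np.ndarray, valid: np.ndarray):
        lo = np.searchsorted(index.sorted_hashes, hashes, side="left")
        hi = np.searchsorted(index.sorted_hashes, hashes, side="right")
        return np.where(valid, lo, 0), np.where(valid, hi, 0)

    f_lo, f_hi = _candidates(*index._hash_batch(seqs)) if seqs else (None, None)
    if orientation == "both" and seqs:
        rcs = [reverse_complement(s) for s in seqs]
        r_lo, r_hi = _candidates(*index._hash_batch(rcs))
    for i, seq in enumerate(seqs):
        L = len(seq)
        plus_hits = set()
        for gpos in index.sorted_positions[f_lo[i] : f_hi[i]]:
            v = index._verify(int(gpos), seq)
            if v is not None:
                plus_hits.add(v)
                seq_idx.append(i)
                ref_idx.append(v[0])
                strands.append("+")
                starts.append(v[1])
                ends.append(v[1] + L)
        if orientation == "both":
            palindrome = rcs[i] == seq
            for gpos in index.sorted_positions[r_lo[i] : r_hi[i]]:
                v = index._verify(int(gpos), rcs[i])
                if v is None or (palindrome and v in plus_hits):
                    continue
                seq_idx.append(i)
                ref_idx.append(v[0])
                strands.append("-")
                starts.append(v[1])
                ends.append(v[1] + L)
    return HitTable(
        reads=reads,
        ref_names=list(index.ref_names),
        seq_index=np.array(seq_idx, dtype=np.int64),
        ref_index=np.array(ref_idx, dtype=np.int64),
        strand=np.array(strands, dtype="U1"),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
    )


def assign_weights(table: HitTable) -> HitTable:
    """Set each sequence's weight to 1 / (its total number of hits).

    After weighting, the summed weighted mass over all hits equals the total
    number of mapped reads exactly (each read contributes mass 1 split across
    its hits).
    """
    counts = table.hit_counts
    if len(table) and (counts[np.unique(table.seq_index)] == 0).any():
        raise ValueError("hit table lists a sequence with zero recorded hits")
    with np.errstate(divide="ignore"):
        table.weights = np.where(counts > 0, 1.0 / np.maximum(counts, 1), np.nan)
    return table
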