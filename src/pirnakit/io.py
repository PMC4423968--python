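"""Readers, writers and read preprocessing.

External formats handled here: FASTA (reads, genome, ncRNA reference sets),
RepeatMasker ``.out`` tables, Ensembl-dialect GTF gene models, and TSV for
collapsed reads. All genomic intervals are converted to the internal 0-based
half-open convention on input and back to the native 1-based inclusive
convention on output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "RawRead",
    "CollapsedReadSet",
    "RepeatAnnotation",
    "GeneModel",
    "ParseError",
    "ConfigError",
    "read_fasta",
    "read_fasta_dict",
    "write_fasta",
    "clip_and_filter",
    "parse_repeatmasker",
    "write_repeatmasker",
    "parse_gtf",
    "write_gtf",
    "spliced_sequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


class ConfigError(ValueError):
    """Raised when parameters are inconsistent with their documented ranges."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class RawRead:
    """A single sequencing read (identifier + ACGTN sequence)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(f"read {self.id!r} contains invalid symbols {sorted(bad)}")


def read_fasta(path: str | Path) -> list[RawRead]:
    """Read small-RNA reads from FASTA.

    Multi-line records are concatenated, sequences are uppercased and U is
    converted to T. A non-empty file whose first record line does not start
    with ``>`` is rejected with the offending line number.
    """
    path = Path(path)
    reads: list[RawRead] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is not None:
            seq = _normalize("".join(chunks))
            reads.append(RawRead(header, seq))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else line[1:]
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: expected FASTA header line starting with '>'"
                    )
                chunks.append(line)
    flush()
    return reads


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Load reference sequences (genome, ncRNA sets) as ``{name: sequence}``."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = _normalize(str(rec.seq))
    return records


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Read preprocessing


@dataclass
class CollapsedReadSet:
    """Unique read sequences with occurrence counts.

    Collapsing many identical sequencing reads to one entry with a count is
    the standard first step of small-RNA analysis; all downstream statistics
    are computed per unique sequence and re-weighted by ``counts``.
    """

    sequences: list[str]
    counts: np.ndarray  # positive ints, aligned with sequences
    n_raw_input: int = 0  # raw reads seen before filtering

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.sequences) != len(self.counts):
            raise ValueError("sequences and counts length mismatch")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("sequences must be unique after collapsing")
        if len(self.counts) and (self.counts <= 0).any():
            raise ValueError("counts must be positive")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def lengths(self) -> np.ndarray:
        return np.fromiter((len(s) for s in self.sequences), dtype=np.int64, count=len(self.sequences))

    def index_of(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sequences)}

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], n_raw_input: int | None = None) -> "CollapsedReadSet":
        seqs = list(seqs)
        uniq: dict[str, int] = {}
        for s in seqs:
            uniq[s] = uniq.get(s, 0) + 1
        return cls(
            sequences=list(uniq),
            counts=np.array(list(uniq.values()), dtype=np.int64),
            n_raw_input=len(seqs) if n_raw_input is None else n_raw_input,
        )

    def subset(self, mask: np.ndarray) -> "CollapsedReadSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CollapsedReadSet(
            sequences=[self.sequences[i] for i in idx],
            counts=self.counts[idx],
            n_raw_input=self.n_raw_input,
        )

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"sequence": self.sequences, "count": self.counts}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CollapsedReadSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(sequences=df["sequence"].tolist(), counts=df["count"].to_numpy())


def clip_and_filter(
    reads: Sequence[RawRead],
    adapter3: str,
    min_len: int = 18,
    max_len: int = 34,
    adapter_seed: int = 8,
    prefix_strip: int = 0,
) -> CollapsedReadSet:
    """Clip the 3' adapter, size-filter and collapse reads.

    Each read is truncated at the leftmost exact occurrence of the first
    ``adapter_seed`` bases of ``adapter3``; reads without the adapter are kept
    unchanged (already-clipped input). ``prefix_strip`` bases are removed from
    the 5' end first (fixed-length 5'-adapter/tag removal). Reads containing N
    or falling outside ``[min_len, max_len]`` after clipping are discarded,
    and survivors are collapsed to unique sequences with counts.
    """
    adapter3 = _normalize(adapter3)
    if len(adapter3) < 8:
        raise ConfigError("3' adapter must be at least 8 nt")
    if adapter_seed > len(adapter3):
        raise ConfigError("adapter_seed longer than the adapter itself")
    seed = adapter3[:adapter_seed]

    kept: list[str] = []
    for read in reads:
        seq = read.sequence[prefix_strip:]
        pos = seq.find(seed)
        if pos >= 0:
            seq = seq[:pos]
        if not (min_len <= len(seq) <= max_len):
            continue
        if "N" in seq:
            continue  # perfect-match mapping cannot place N reads
        kept.append(seq)
    out = CollapsedReadSet.from_sequences(kept)
    out.n_raw_input = len(reads)
    return out


# ---------------------------------------------------------------------------
# RepeatMasker annotation


@dataclass
class RepeatAnnotation:
    """RepeatMasker TE copies as a table.

    Columns: chrom, start, end (0-based half-open), strand (+/-),
    family, te_class, divergence (percent substitutions from consensus).
    """

    records: pd.DataFrame

    COLUMNS = ["chrom", "start", "end", "strand", "family", "te_class", "divergence"]

    def __post_init__(self) -> None:
        df = self.records
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"RepeatAnnotation missing columns {sorted(missing)}")
        if len(df):
            if (df["start"] >= df["end"]).any():
                raise ValueError("RepeatMasker interval with start >= end")
            if ((df["divergence"] < 0) | (df["divergence"] > 100)).any():
                raise ValueError("divergence outside [0, 100]")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def empty(cls) -> "RepeatAnnotation":
        return cls(pd.DataFrame(columns=cls.COLUMNS))


def parse_repeatmasker(path: str | Path) -> RepeatAnnotation:
    """Parse a RepeatMasker ``.out`` file (3 header lines, whitespace columns).

    RepeatMasker reports 1-based inclusive coordinates and marks minus-strand
    matches with ``C``; both are converted here.
    """
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno <= 3 or not line.strip():
            continue
        parts = line.split()
        if len(parts) < 11:
            raise ParseError(f"{path}:{lineno}: expected >= 11 whitespace-delimited fields")
        try:
            div = float(parts[1])
            begin = int(parts[5])
            end = int(parts[6])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric coordinate field ({exc})") from exc
        strand = "-" if parts[8] == "C" else "+"
        rows.append(
            dict(
                chrom=parts[4],
                start=begin - 1,
                end=end,
                strand=strand,
                family=parts[9],
                te_class=parts[10],
                divergence=div,
            )
        )
    if not rows:
        return RepeatAnnotation.empty()
    return RepeatAnnotation(pd.DataFrame(rows))


_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def write_repeatmasker(ann: RepeatAnnotation, path: str | Path) -> None:
    """Write a RepeatAnnotation back to RepeatMasker ``.out`` layout."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, row in enumerate(ann.records.itertuples(index=False), start=1):
            strand = "C" if row.strand == "-" else "+"
            fh.write(
                f"  225 {row.divergence:5.1f}  0.0  0.0  {row.chrom} "
                f"{row.start + 1} {row.end} (0) {strand} {row.family} "
                f"{row.te_class} 1 {row.end - row.start} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (GTF)


@dataclass
class GeneModel:
    """One transcript of a gene: strand, ordered exons, biotype, optional CDS."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, disjoint
    biotype: str = "protein_coding"  # protein_coding | pseudogene | lncRNA | other
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        if self.cds is not None:
            cs, ce = self.cds
            covered = sum(max(0, min(e, ce) - max(s, cs)) for s, e in self.exons)
            if covered != ce - cs and not any(s <= cs and ce <= e for s, e in self.exons):
                # CDS must lie within the exon union (possibly spliced)
                in_union = sum(
                    max(0, min(e, ce) - max(s, cs)) for s, e in self.exons
                )
                if in_union == 0:
                    raise ValueError(
                        f"transcript {self.transcript_id}: CDS outside exon union"
                    )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1]


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Parse exon (and CDS) features of an Ensembl-dialect GTF into GeneModels."""
    exons: dict[str, GeneModel] = {}
    cds_parts: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-delimited GTF fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature not in ("exon", "CDS"):
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if not tid:
                raise ParseError(f"{path}:{lineno}: {feature} feature without transcript_id")
            gid = attr.get("gene_id", tid)
            biotype = attr.get("gene_biotype", attr.get("transcript_biotype", "other"))
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if feature == "exon":
                model = exons.get(tid)
                if model is None:
                    exons[tid] = GeneModel(gid, tid, chrom, strand, [(s, e)], biotype)
                else:
                    model.exons.append((s, e))
            else:
                cds_parts.setdefault(tid, []).append((s, e))
    models = []
    for tid, model in exons.items():
        # re-run invariant checks once all exons are collected
        model = GeneModel(
            model.gene_id, tid, model.chrom, model.strand, model.exons, model.biotype
        )
        if tid in cds_parts:
            cs = min(s for s, _ in cds_parts[tid])
            ce = max(e for _, e in cds_parts[tid])
            model.cds = (cs, ce)
        models.append(model)
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


def write_gtf(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_biotype "{m.biotype}";'
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tpirnakit\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds is not None:
                cs, ce = m.cds
                fh.write(
                    f"{m.chrom}\tpirnakit\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def spliced_sequence(model: GeneModel, genome: dict[str, str]) -> str:
    """Spliced transcript sequence; minus-strand models are reverse-complemented."""
    chrom_seq = genome[model.chrom]
    seq = "".join(chrom_seq[s:e] for s, e in model.exons)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq
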