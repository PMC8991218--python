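"""Raw FASTQ to clean reads and collapsed unique tags.

The cleaning contract mirrors standard small-RNA preprocessing: strip the 3'
adapter, drop adapter-only / low-quality / ambiguous reads, keep inserts of
18-30 nt, then collapse identical inserts into unique tags carrying their
redundancy count. All surviving sequences are U-normalized (T -> U) so every
downstream comparison happens in RNA space.

Descriptive statistics computed here — the per-length read/tag distribution
and the first-nucleotide composition per length — are the library-level
summaries a small-RNA study reports (majority of reads at 20-24 nt, 5'-U
bias at lengths 20 and 22).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import to_rna

log = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "U")

REJECT_REASONS = (
    "adapter_only",
    "no_adapter",
    "low_quality",
    "ambiguous_base",
    "too_short",
    "too_long",
)


class TrimResult(NamedTuple):
    insert: str | None  # None on rejection
    reason: str | None  # rejection reason code, None on success


class FastqParseError(ValueError):
    """Malformed FASTQ record; message names the record index."""


@dataclass(frozen=True)
class UniqueTag:
    """A distinct clean insert with its read count."""

    sequence: str  # RNA space
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("tag count must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def first_nt(self) -> str:
        return self.sequence[0]


@dataclass
class LibraryProfile:
    """One cleaned, collapsed sequencing library.

    ``total_clean_reads`` is the normalization denominator (the N1/N2 of the
    exact test). Invariant: sum of tag counts == total_clean_reads <=
    raw_read_count, and accepted + rejected == raw_read_count.
    """

    name: str
    tags: list[UniqueTag]
    total_clean_reads: int
    raw_read_count: int
    rejections: Counter = field(default_factory=Counter)

    def validate(self) -> None:
        if sum(t.count for t in self.tags) != self.total_clean_reads:
            raise ValueError("tag counts do not sum to total_clean_reads")
        if self.total_clean_reads + sum(self.rejections.values()) != self.raw_read_count:
            raise ValueError("accepted + rejected != raw reads")


def parse_fastq(source) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a FASTQ path/handle.

    Wraps Biopython's parser so a malformed record is reported with its
    index.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        handle = open(source)
        close = True
    else:
        handle = source
    try:
        it = FastqGeneralIterator(handle)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ record at index {i}: {exc}") from exc
            i += 1
            yield rec
    finally:
        if close:
            handle.close()


def trim_adapter(read_sequence: str, adapter: str, min_overlap: int = 6) -> TrimResult:
    """Cut at the leftmost adapter occurrence and return the preceding insert.

    A match is either the full adapter anywhere in the read, or a prefix of
    the adapter (>= ``min_overlap`` long) flush with the read's 3' end.
    Rejects adapter-only reads (empty insert) and, reads with no match at
    all ("no_adapter").
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not read_sequence:
        return TrimResult(None, "too_short")
    read = read_sequence.upper()
    ad = adapter.upper()
    best: int | None = None
    full = read.find(ad)
    if full != -1:
        best = full
    # adapter prefix running off the read's 3' end
    max_k = min(len(ad), len(read))
    for k in range(max_k, min_overlap - 1, -1):
        pos = len(read) - k
        if (best is None or pos < best) and read.endswith(ad[:k], pos):
            best = pos
    if best is None:
        return TrimResult(None, "no_adapter")
    if best == 0:
        return TrimResult(None, "adapter_only")
    return TrimResult(read[:best], None)


def mean_phred(quality: str, offset: int = 33) -> float:
    if not quality:
        return 0.0
    return float(np.mean([ord(c) - offset for c in quality]))


@dataclass
class CleanResult:
    clean: list[str]  # U-normalized inserts
    rejections: Counter
    raw_count: int


def clean_reads(
    records: Iterable[tuple[str, str, str]],
    adapter: str,
    quality_floor: float = 20.0,
    min_len: int = 18,
    max_len: int = 30,
    min_overlap: int = 6,
    require_adapter: bool = True,
) -> CleanResult:
    """Filter and trim a FASTQ stream; tally every rejection reason.

    ``records`` is a path or an iterable of (id, sequence, quality).
    Checks, in order: mean Phred >= ``quality_floor``; adapter trim
    (adapter-only and, if ``require_adapter``, adapterless reads rejected);
    no ambiguous base in the insert; ``min_len`` <= length <= ``max_len``
    (both inclusive). Accepted inserts are returned U-normalized.
    """
    if not (min_len <= max_len):
        raise ValueError("min_len must be <= max_len")
    if isinstance(records, (str, bytes)) or hasattr(records, "__fspath__"):
        records = parse_fastq(records)
    clean: list[str] = []
    rej: Counter = Counter()
    raw = 0
    for _rid, seq, qual in records:
        raw += 1
        if mean_phred(qual) < quality_floor:
            rej["low_quality"] += 1
            continue
        insert, reason = trim_adapter(seq, adapter, min_overlap)
        if insert is None:
            if reason == "no_adapter" and not require_adapter:
                insert = seq.upper()
            else:
                rej[reason] += 1
                continue
        if any(b not in "ACGT" for b in insert):
            rej["ambiguous_base"] += 1
            continue
        if len(insert) < min_len:
            rej["too_short"] += 1
            continue
        if len(insert) > max_len:
            rej["too_long"] += 1
            continue
        clean.append(to_rna(insert))
    return CleanResult(clean, rej, raw)


def collapse(clean: Iterable[str]) -> list[UniqueTag]:
    """One tag per distinct sequence, ordered by count desc then sequence."""
    counts = Counter(clean)
    return [
        UniqueTag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def build_profile(
    name: str,
    records: Iterable[tuple[str, str, str]],
    adapter: str,
    **clean_kwargs,
) -> LibraryProfile:
    """Convenience: clean + collapse a FASTQ stream into a LibraryProfile."""
    res = clean_reads(records, adapter, **clean_kwargs)
    profile = LibraryProfile(name, collapse(res.clean), len(res.clean), res.raw_count, res.rejections)
    profile.validate()
    return profile


def length_distribution(profile: LibraryProfile, lo: int = 18, hi: int = 30) -> pd.DataFrame:
    """Reads and unique tags per insert length (rows = lengths lo..hi)."""
    idx = range(lo, hi + 1)
    reads = {length: 0 for length in idx}
    tags = {length: 0 for length in idx}
    for t in profile.tags:
        reads[t.length] = reads.get(t.length, 0) + t.count
        tags[t.length] = tags.get(t.length, 0) + 1
    df = pd.DataFrame({"reads": pd.Series(reads), "tags": pd.Series(tags)}).sort_index()
    df.index.name = "length"
    return df


def first_nt_bias(
    profile: LibraryProfile,
    lengths: Iterable[int] = range(18, 24),
    by_reads: bool = True,
) -> pd.DataFrame:
    """Fraction of reads (or tags) starting with each nucleotide, per length.

    Rows sum to 1; a length with no reads yields an all-zero row.
    """
    lengths = list(lengths)
    mat = pd.DataFrame(0.0, index=lengths, columns=list(NUCLEOTIDES))
    for t in profile.tags:
        if t.length in mat.index:
            mat.loc[t.length, t.first_nt] += t.count if by_reads else 1
    totals = mat.sum(axis=1)
    nz = totals > 0
    mat.loc[nz] = mat.loc[nz].div(totals[nz], axis=0)
    mat.index.name = "length"
    return mat


def write_tags_fasta(profile: LibraryProfile, path) -> None:
    """Unique tags as FASTA with headers ``tag_<i>_x<count>`` (DNA letters kept as RNA)."""
    with open(path, "w") as fh:
        for i, t in enumerate(profile.tags, start=1):
            fh.write(f">tag_{i}_x{t.count}\n{t.sequence}\n")
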