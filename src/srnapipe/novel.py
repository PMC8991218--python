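"""Novel miRNA discovery from unannotated tags.

Pipeline: exact mapping of each unannotated tag to the genome (both
strands), extraction of two candidate precursor windows per locus (tag on
the 5' arm vs the 3' arm), secondary-structure prediction by base-pair
maximization (Nussinov recursion with Watson-Crick + GU pairs and a minimum
loop of 3), and a stem-loop screen: the tag must sit entirely on one arm of
the longest stem, with enough of its bases paired, a terminal loop of
plausible size, a long-enough stem, and no long bulge inside the tag.

Base-pair maximization stands in for thermodynamic (minimum free energy)
folding: it is self-contained, exactly checkable against brute-force
enumeration, and sufficient for a screen that only asks whether a clean
hairpin exists — not for its folding energy.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp_dna, to_dna, to_rna

log = logging.getLogger(__name__)

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class GenomeLocus:
    """1-based inclusive genomic interval on a named segment."""

    segment: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError("require 1 <= start <= end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    def to_string(self) -> str:
        return f"{self.segment}:{self.start}..{self.end}:{self.strand}"


_LOCUS_RE = re.compile(r"^(?P<seg>[^:]+):(?P<start>\d+)\.\.(?P<end>\d+):(?P<strand>[+-])$")


def parse_locus(text: str) -> GenomeLocus:
    m = _LOCUS_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse locus string {text!r}")
    return GenomeLocus(m.group("seg"), int(m.group("start")), int(m.group("end")), m.group("strand"))


def map_exact(tag_sequence: str, genome_segments: dict[str, str]) -> list[GenomeLocus]:
    """All exact occurrences of a (U-normalized) tag on both genome strands."""
    t = to_dna(tag_sequence)
    rc = revcomp_dna(t)
    loci: list[GenomeLocus] = []
    for seg_name in sorted(genome_segments):
        seg = genome_segments[seg_name].upper()
        for query, strand in ((t, "+"), (rc, "-")):
            pos = seg.find(query)
            while pos != -1:
                loci.append(GenomeLocus(seg_name, pos + 1, pos + len(query), strand))
                pos = seg.find(query, pos + 1)
    return loci


@dataclass(frozen=True)
class PrecursorWindow:
    """A candidate precursor sequence (RNA, transcript orientation) with the
    tag's 0-based [start, end) placement inside it."""

    locus: GenomeLocus  # genomic extent of the window
    sequence: str
    tag_start: int
    tag_end: int


def extract_precursor_windows(
    locus: GenomeLocus, genome_segments: dict[str, str], flank: int = 70
) -> list[PrecursorWindow]:
    """Two windows per tag locus: flank downstream (tag on 5' arm) and flank
    upstream (tag on 3' arm), in transcript orientation, clipped at segment
    bounds."""
    if flank < 20:
        raise ValueError("flank must be >= 20")
    seg = genome_segments[locus.segment]
    n = len(seg)
    windows = []
    # genomic intervals; transcript orientation handled after extraction
    if locus.strand == "+":
        intervals = [
            (locus.start, min(locus.end + flank, n)),  # tag at 5' arm
            (max(locus.start - flank, 1), locus.end),  # tag at 3' arm
        ]
    else:
        intervals = [
            (max(locus.start - flank, 1), locus.end),  # tag at 5' arm (downstream on -)
            (locus.start, min(locus.end + flank, n)),
        ]
    for gstart, gend in intervals:
        dna = seg[gstart - 1 : gend]
        if locus.strand == "-":
            dna = revcomp_dna(dna)
        rna = to_rna(dna)
        if locus.strand == "+":
            tstart = locus.start - gstart
        else:
            tstart = gend - locus.end
        windows.append(
            PrecursorWindow(
                GenomeLocus(locus.segment, gstart, gend, locus.strand),
                rna,
                tstart,
                tstart + (locus.end - locus.start + 1),
            )
        )
    return windows


@dataclass(frozen=True)
class FoldResult:
    structure: str  # dot-bracket
    pairs: tuple[tuple[int, int], ...]  # 0-based (i, j) with i < j
    n_pairs: int

    def pair_table(self) -> dict[int, int]:
        pt: dict[int, int] = {}
        for i, j in self.pairs:
            pt[i] = j
            pt[j] = i
        return pt


def _pairable(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def fold_rna(sequence: str, min_loop: int = 3) -> FoldResult:
    """Maximum base-pair non-crossing fold (Nussinov) with deterministic
    traceback: pair the outermost bases when optimal, otherwise split at the
    5'-most optimal point."""
    seq = to_rna(sequence)
    if len(seq) < 10:
        raise ValueError("sequence must be >= 10 nt")
    if any(b not in "ACGU" for b in seq):
        raise ValueError("sequence must contain only A/C/G/U (or T)")
    n = len(seq)
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1][j - 1] + 1 if _pairable(seq[i], seq[j]) else 0
            row_i = M[i]
            for k in range(i, j):
                v = M[i][k] + M[k + 1][j]
                if v > best:
                    best = v
            row_i[j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop or M[i][j] == 0:
            continue
        if _pairable(seq[i], seq[j]) and M[i][j] == M[i + 1][j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            if M[i][k] + M[k + 1][j] == M[i][j]:
                stack.append((k + 1, j))
                stack.append((i, k))
                break
    pairs.sort()
    struct = ["."] * n
    for i, j in pairs:
        struct[i] = "("
        struct[j] = ")"
    return FoldResult("".join(struct), tuple(pairs), len(pairs))


@dataclass(frozen=True)
class HairpinThresholds:
    """Screen thresholds approximating common novel-miRNA caller defaults."""

    min_stem_pairs: int = 18
    min_tag_paired: int = 14
    min_loop: int = 3
    max_loop: int = 20
    max_unpaired_run: int = 4


@dataclass
class HairpinCandidate:
    locus: GenomeLocus
    precursor: str
    structure: str
    mature_arm: str | None  # '5p' | '3p' | None when off-stem
    mature_sequence: str
    tag_start: int
    tag_end: int
    read_support: dict[str, int] = field(default_factory=dict)
    n_stem_pairs: int = 0
    paired_mature_bases: int = 0
    loop_length: int = 0
    verdict: bool = False
    reason: str | None = None


def _tag_stem(pt: dict[int, int], ts: int, te: int, max_gap: int) -> dict | None:
    """The helix the tag participates in, walked from the tag's own pairs.

    Returns None when the tag makes no pairs at all; a dict with
    ``reason="spans_loop"`` when the tag pairs with itself or into both
    directions (i.e. it crosses a terminal loop); otherwise the stem chain:
    nested pairs reachable from the tag's innermost pair with at most
    ``max_gap`` unpaired/bulged bases per step on each side, its loop bounds,
    pair count, arm and outer extent.
    """
    tag_pairs = [(q, pt[q]) for q in range(ts, te + 1) if q in pt]
    if not tag_pairs:
        return None
    if any(ts <= p <= te for _q, p in tag_pairs):
        return {"reason": "spans_loop"}
    up = all(p > te for _q, p in tag_pairs)
    down = all(p < ts for _q, p in tag_pairs)
    if not (up or down):
        return {"reason": "spans_loop"}
    arm = "5p" if up else "3p"
    norm = sorted((min(q, p), max(q, p)) for q, p in tag_pairs)
    i0, j0 = norm[-1]  # innermost tag pair (largest 5' index under nesting)

    def step_in(i: int, j: int) -> tuple[int, int] | None:
        for di in range(1, max_gap + 2):
            ii = i + di
            if ii >= j:
                return None
            jj = pt.get(ii)
            if jj is None:
                continue
            if ii < jj < j and (j - jj - 1) <= max_gap:
                return ii, jj
            return None
        return None

    def step_out(i: int, j: int) -> tuple[int, int] | None:
        for di in range(1, max_gap + 2):
            ii = i - di
            if ii < 0:
                return None
            jj = pt.get(ii)
            if jj is None:
                continue
            if jj > j and (jj - j - 1) <= max_gap:
                return ii, jj
            return None
        return None

    chain = {(i0, j0)}
    i, j = i0, j0
    while (nxt := step_in(i, j)) is not None:
        chain.add(nxt)
        i, j = nxt
    loop = (i, j)
    i, j = i0, j0
    while (nxt := step_out(i, j)) is not None:
        chain.add(nxt)
        i, j = nxt
    return {
        "arm": arm,
        "chain": chain,
        "loop": loop,
        "loop_length": loop[1] - loop[0] - 1,
        "n_pairs": len(chain),
        "outer": (i, j),
    }


def evaluate_hairpin(
    window: PrecursorWindow,
    fold: FoldResult | None = None,
    thresholds: HairpinThresholds = HairpinThresholds(),
    read_support: dict[str, int] | None = None,
) -> HairpinCandidate:
    """Screen one precursor window; verdict records the first failed criterion.

    Criteria, in evaluation order: the tag lies entirely on one arm of a
    stem (pairing only in one direction; pairing with itself or both ways
    means it crosses the terminal loop -> ``spans_loop``, no pairing at all
    -> ``off_stem``); the terminal loop enclosed by the tag's helix is
    within [min_loop, max_loop]; the helix has >= min_stem_pairs pairs;
    >= min_tag_paired of the tag's bases pair into it; and no run of more
    than max_unpaired_run tag bases is unpaired. On a pass the candidate is
    trimmed to the helix extent so the reported coordinates describe the
    hairpin, not the extraction window.
    """
    if fold is None:
        fold = fold_rna(window.sequence)
    pt = fold.pair_table()
    tag_seq = window.sequence[window.tag_start : window.tag_end]
    cand = HairpinCandidate(
        locus=window.locus,
        precursor=window.sequence,
        structure=fold.structure,
        mature_arm=None,
        mature_sequence=tag_seq,
        tag_start=window.tag_start,
        tag_end=window.tag_end,
        read_support=dict(read_support or {}),
    )

    def fail(reason: str) -> HairpinCandidate:
        cand.verdict = False
        cand.reason = reason
        return cand

    ts, te = window.tag_start, window.tag_end - 1  # inclusive tag span
    stem = _tag_stem(pt, ts, te, thresholds.max_unpaired_run)
    if stem is None:
        return fail("off_stem")
    if "reason" in stem:
        return fail(stem["reason"])
    cand.mature_arm = stem["arm"]
    cand.n_stem_pairs = stem["n_pairs"]
    cand.loop_length = stem["loop_length"]
    if not (thresholds.min_loop <= cand.loop_length <= thresholds.max_loop):
        return fail("loop_length")
    if cand.n_stem_pairs < thresholds.min_stem_pairs:
        return fail("stem_too_short")
    chain = stem["chain"]
    cand.paired_mature_bases = sum(
        1
        for q in range(ts, te + 1)
        if q in pt and (min(q, pt[q]), max(q, pt[q])) in chain
    )
    if cand.paired_mature_bases < thresholds.min_tag_paired:
        return fail("few_paired_bases")
    run = best_run = 0
    for q in range(ts, te + 1):
        in_chain = q in pt and (min(q, pt[q]), max(q, pt[q])) in chain
        run = 0 if in_chain else run + 1
        best_run = max(best_run, run)
    if best_run > thresholds.max_unpaired_run:
        return fail("bulge_too_long")
    cand.verdict = True
    a, b = stem["outer"]
    a, b = min(a, ts), max(b, te)  # keep unpaired tag edges inside the trim
    loc = window.locus
    if loc.strand == "+":
        glo, ghi = loc.start + a, loc.start + b
    else:
        glo, ghi = loc.end - b, loc.end - a
    cand.locus = GenomeLocus(loc.segment, glo, ghi, loc.strand)
    cand.precursor = window.sequence[a : b + 1]
    cand.structure = fold.structure[a : b + 1]
    cand.tag_start = ts - a
    cand.tag_end = te + 1 - a
    return cand


def call_novel(
    tag_counts: dict[str, dict[str, int]],
    genome_segments: dict[str, str],
    thresholds: HairpinThresholds = HairpinThresholds(),
    min_read_count: int = 10,
    max_loci: int = 5,
    flank: int = 70,
    libraries: list[str] | None = None,
) -> tuple[pd.DataFrame, list[HairpinCandidate]]:
    """Screen unannotated tags and emit a novel-candidate table.

    ``tag_counts`` maps tag sequence -> per-library read counts. Tags
    mapping to more than ``max_loci`` genomic sites are discarded as likely
    repeats; candidates whose total support is below ``min_read_count`` are
    dropped. Candidates are named ``novel-miR-<k>`` in descending
    total-support order (ties by locus string).
    """
    if libraries is None:
        libraries = sorted({lib for c in tag_counts.values() for lib in c})
    passing: dict[str, HairpinCandidate] = {}
    for seq in sorted(tag_counts):
        loci = map_exact(seq, genome_segments)
        if not loci or len(loci) > max_loci:
            continue
        support = {lib: tag_counts[seq].get(lib, 0) for lib in libraries}
        if sum(support.values()) == 0:
            continue
        for locus in loci:
            best: HairpinCandidate | None = None
            for window in extract_precursor_windows(locus, genome_segments, flank):
                cand = evaluate_hairpin(window, thresholds=thresholds, read_support=support)
                if cand.verdict and (best is None or cand.n_stem_pairs > best.n_stem_pairs):
                    best = cand
            if best is None:
                continue
            key = best.locus.to_string()
            if key in passing:
                for lib, c in support.items():
                    passing[key].read_support[lib] = passing[key].read_support.get(lib, 0) + c
            else:
                passing[key] = best
    kept = [
        c for c in passing.values() if sum(c.read_support.values()) >= min_read_count
    ]
    kept.sort(key=lambda c: (-sum(c.read_support.values()), c.locus.to_string()))
    rows = []
    for k, cand in enumerate(kept, start=1):
        row = {
            "name": f"novel-miR-{k}",
            "mature_sequence": cand.mature_sequence,
            "precursor": cand.locus.to_string(),
            "total_reads": sum(cand.read_support.values()),
        }
        for lib in libraries:
            row[lib] = cand.read_support.get(lib, 0)
        rows.append(row)
    columns = ["name", "mature_sequence", "precursor", "total_reads"] + list(libraries)
    table = pd.DataFrame(rows, columns=columns)
    return table, kept
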