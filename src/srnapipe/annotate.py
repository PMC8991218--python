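"""Hierarchical annotation of unique tags and conserved-miRNA identification.

Each tag gets exactly one category, decided by a configurable priority walk:
ncRNA categories (rRNA, tRNA, snRNA, snoRNA) and exon sense/antisense by
exact substring match against the reference set, then known miRNAs by a
mismatch-tolerant alignment (<= 2 substitutions, with <= 2 nt of overhang at
either terminus to absorb isomiR end-variation), else unannotated. Counts
for a mature miRNA are the sum of the counts of all tags assigned to it.

Matures with fewer than ``min_count`` reads in every library are flagged
``low_expression`` and excluded from differential expression by default,
mirroring the read-count floor applied in practice.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from ._seq import revcomp_rna, to_rna
from .reads import LibraryProfile, UniqueTag
from .simulate import ReferencePanel

log = logging.getLogger(__name__)

DEFAULT_PRIORITY = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "exon_sense",
    "exon_antisense",
    "known_miRNA",
)

CATEGORIES = DEFAULT_PRIORITY + ("unannotated",)

MAX_MISMATCHES = 2
MAX_OVERHANG = 2


@dataclass(frozen=True)
class CategoryAssignment:
    sequence: str
    category: str
    best_hit: str | None
    mismatches: int


@dataclass
class MiRNARecord:
    """A mature miRNA with per-library raw and normalized counts."""

    name: str
    family: str
    sequence: str
    raw_counts: dict[str, int]
    normalized: dict[str, float] = field(default_factory=dict)
    low_expression: bool = False


def _rna_reference_views(panel: ReferencePanel) -> dict[str, list[tuple[str, str]]]:
    """Per-category (name, RNA sequence) lists used by the substring checks."""
    views: dict[str, list[tuple[str, str]]] = {}
    for cat in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        views[cat] = [(n, to_rna(s)) for n, s in sorted(panel.ncrna_sets[cat].items())]
    exons = [(n, to_rna(s)) for n, s in sorted(panel.ncrna_sets["exon"].items())]
    views["exon_sense"] = exons
    views["exon_antisense"] = [(n, revcomp_rna(s)) for n, s in exons]
    return views


def match_mature(tag_seq: str, matures: dict[str, str]) -> tuple[str, int] | None:
    """Best mismatch-tolerant hit of a tag against a mature catalogue.

    The tag is slid over each mature at offsets -2..+2; at each placement
    both sequences may overhang the other by at most ``MAX_OVERHANG`` nt per
    end, and mismatches are counted on the overlap only. Hits with more than
    ``MAX_MISMATCHES`` substitutions are discarded. Ties on mismatch count
    resolve to the lexicographically first mature name (logged).
    """
    best: tuple[int, str] | None = None
    tied = False
    for name in sorted(matures):
        mat = matures[name]
        if abs(len(tag_seq) - len(mat)) > 2 * MAX_OVERHANG:
            continue
        local_best: int | None = None
        for d in range(-MAX_OVERHANG, MAX_OVERHANG + 1):
            # tag position i aligns with mature position i + d
            left_over_tag = max(0, -d)
            right_over_tag = max(0, d + len(tag_seq) - len(mat))
            left_over_mat = max(0, d)
            right_over_mat = max(0, len(mat) - d - len(tag_seq))
            if max(left_over_tag, right_over_tag, left_over_mat, right_over_mat) > MAX_OVERHANG:
                continue
            lo = max(0, -d)
            hi = min(len(tag_seq), len(mat) - d)
            if hi - lo < 10:  # overlap too small to call a hit
                continue
            mm = 0
            for i in range(lo, hi):
                if tag_seq[i] != mat[i + d]:
                    mm += 1
                    if mm > MAX_MISMATCHES:
                        break
            if mm <= MAX_MISMATCHES and (local_best is None or mm < local_best):
                local_best = mm
        if local_best is None:
            continue
        if best is None or local_best < best[0]:
            best = (local_best, name)
            tied = False
        elif local_best == best[0]:
            tied = True
    if best is None:
        return None
    if tied:
        log.info("tag %s ties multiple matures at %d mismatches; kept %s", tag_seq, best[0], best[1])
    return best[1], best[0]


def classify_tag(
    tag: UniqueTag | str,
    panel: ReferencePanel,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    _views: dict | None = None,
) -> CategoryAssignment:
    """Assign the first category in ``priority`` with a qualifying hit."""
    seq = tag.sequence if isinstance(tag, UniqueTag) else to_rna(tag)
    views = _views if _views is not None else _rna_reference_views(panel)
    for cat in priority:
        if cat == "known_miRNA":
            hit = match_mature(seq, panel.mature_mirnas)
            if hit is not None:
                return CategoryAssignment(seq, "known_miRNA", hit[0], hit[1])
        else:
            for name, ref in views[cat]:
                if seq in ref:
                    return CategoryAssignment(seq, cat, name, 0)
    return CategoryAssignment(seq, "unannotated", None, 0)


def classify_profile(
    profile: LibraryProfile,
    panel: ReferencePanel,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> dict[str, CategoryAssignment]:
    """Classify every tag of a library; keyed by tag sequence."""
    views = _rna_reference_views(panel)
    return {t.sequence: classify_tag(t, panel, priority, _views=views) for t in profile.tags}


def summarize_categories(
    profile: LibraryProfile, assignments: dict[str, CategoryAssignment]
) -> pd.DataFrame:
    """Per-category totals: reads, % reads, unique tags, % tags."""
    reads = {c: 0 for c in CATEGORIES}
    tags = {c: 0 for c in CATEGORIES}
    for t in profile.tags:
        if t.sequence not in assignments:
            raise ValueError(f"tag {t.sequence} has no assignment")
        cat = assignments[t.sequence].category
        reads[cat] += t.count
        tags[cat] += 1
    df = pd.DataFrame({"reads": pd.Series(reads), "tags": pd.Series(tags)})
    df = df[(df.reads > 0) | (df.tags > 0)]
    total_r, total_t = df.reads.sum(), df.tags.sum()
    df["reads_pct"] = 100.0 * df.reads / total_r if total_r else 0.0
    df["tags_pct"] = 100.0 * df.tags / total_t if total_t else 0.0
    df.index.name = "category"
    return df[["reads", "reads_pct", "tags", "tags_pct"]]


def identify_conserved(
    profiles: dict[str, LibraryProfile],
    assignments: dict[str, dict[str, CategoryAssignment]],
    panel: ReferencePanel,
    min_count: int = 10,
) -> list[MiRNARecord]:
    """Aggregate known-miRNA tag counts into per-mature records.

    A record whose maximum per-library raw count is below ``min_count`` is
    flagged ``low_expression`` (kept, but excluded from DE by default).
    Normalized counts are reads-per-million of clean reads with the 0.01
    pseudo-count for zeros.
    """
    from .diffexpr import normalize

    raw: dict[str, dict[str, int]] = {}
    for lib, profile in profiles.items():
        amap = assignments[lib]
        for t in profile.tags:
            a = amap[t.sequence]
            if a.category == "known_miRNA":
                raw.setdefault(a.best_hit, {}).setdefault(lib, 0)
                raw[a.best_hit][lib] += t.count
    records = []
    for name in sorted(raw):
        counts = {lib: raw[name].get(lib, 0) for lib in profiles}
        rec = MiRNARecord(
            name,
            family_of(name),
            panel.mature_mirnas.get(name, ""),
            counts,
            {
                lib: normalize(c, max(profiles[lib].total_clean_reads, 1))
                for lib, c in counts.items()
            },
            low_expression=max(counts.values()) < min_count,
        )
        records.append(rec)
    return records


_FAMILY_RE = re.compile(r"^(?P<sp>[A-Za-z]+)-(?P<kind>let|miR)-(?P<num>\d+)", re.IGNORECASE)


def family_of(mirna_name: str) -> str:
    """Family name: strip arm suffix, paralog letters and sub-numbering.

    ``hsa-let-7b-5p -> hsa-let-7``; names that do not parse (e.g. novel
    candidates) pass through unchanged with a logged warning.
    """
    m = _FAMILY_RE.match(mirna_name)
    if m is None or mirna_name.lower().startswith("novel"):
        if m is None:
            log.warning("unparseable miRNA name %r; using it as its own family", mirna_name)
        return mirna_name
    return f"{m.group('sp')}-{m.group('kind')}-{m.group('num')}"


def family_overlap(family_sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exact Venn region counts over per-library family sets.

    Returns ``{tuple(sorted(libs present)): count}`` for every membership
    pattern; the counts partition the union of all families.
    """
    if len(family_sets) < 2:
        raise ValueError("need at least two libraries")
    libs = sorted(family_sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(libs) + 1):
        for combo in combinations(libs, r):
            inside = set.intersection(*(family_sets[l] for l in combo))
            outside = set().union(*(family_sets[l] for l in libs if l not in combo))
            regions[combo] = len(inside - outside)
    return regions


def count_matrix(records: list[MiRNARecord], libraries: list[str], include_low: bool = False) -> pd.DataFrame:
    """Per-miRNA raw-count matrix (rows = miRNAs, columns = libraries)."""
    rows = {
        r.name: [r.raw_counts.get(lib, 0) for lib in libraries]
        for r in records
        if include_low or not r.low_expression
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=libraries).sort_index()
    df.index.name = "mirna"
    return df
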