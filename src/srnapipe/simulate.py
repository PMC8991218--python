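"""Synthetic small-RNA sequencing data with complete ground truth.

Every downstream stage of the pipeline (cleaning, annotation, novel hairpin
discovery, differential expression) is exercised against libraries generated
here, because the study design this emulates — three unreplicated Illumina
small-RNA libraries from mesenchymal stem cells driven toward a motor-neuron
fate (an untreated Control, a morphogen-treated Test 1, and a
morphogen-withdrawn Test 2) — has no public raw data. The generator plants:

* a panel of mature miRNAs grouped into families, each embedded in a
  hairpin-folding precursor that is itself embedded in a genome segment;
* ncRNA reference sets (rRNA, tRNA, snRNA, snoRNA, exon) that contribute
  contaminating fragments;
* novel hairpins whose mature arm is sequenced but absent from the mature
  catalogue, so the novel-miRNA caller must rediscover them;
* per-library miRNA abundances with known log2 fold changes between
  libraries; and
* reads destined for each rejection class of the cleaning stage
  (adapter-only, low-quality, too short, too long).

Emitted reads reproduce the two length/composition tendencies reported for
real libraries of this kind: a majority of inserts 20-24 nt long, and a
modal 5'-uridine at lengths 20 and 22.

References are stored as DNA; mature and precursor miRNAs as RNA. Reads are
emitted as DNA (as a sequencer would) and U-normalized by the cleaning
stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp_dna, revcomp_rna, to_dna, to_rna

log = logging.getLogger(__name__)

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter

NCRNA_CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA", "exon")
REJECT_REASONS = ("adapter_only", "low_quality", "too_short", "too_long")

#: read-mass fractions of each non-miRNA clean category (of total reads)
DEFAULT_CATEGORY_FRACTIONS = {
    "rRNA": 0.10,
    "tRNA": 0.06,
    "snRNA": 0.015,
    "snoRNA": 0.015,
    "exon_sense": 0.03,
    "exon_antisense": 0.01,
}
DEFAULT_MIRNA_FRACTION = 0.55
#: ~7% of raw reads fail cleaning, matching the attrition reported for the
#: real libraries (36.2M raw -> 33.7M clean)
DEFAULT_REJECT_FRACTIONS = {
    "adapter_only": 0.020,
    "low_quality": 0.020,
    "too_short": 0.020,
    "too_long": 0.009,
}

_DNA = np.array(list("ACGT"))


class ConsistencyError(ValueError):
    """Truth table and reference panel disagree."""


@dataclass(frozen=True)
class PlantedHairpin:
    """A novel-miRNA precursor written into the genome, with its ground truth."""

    name: str
    segment: str
    start: int  # 1-based inclusive genomic coordinates of the precursor
    end: int
    strand: str  # '+' or '-'
    precursor: str  # RNA, transcript orientation
    mature: str  # RNA, the sequenced arm
    arm: str  # '5p' or '3p'


@dataclass
class ReferencePanel:
    """Named reference sequences every stage annotates against."""

    genome_segments: dict[str, str]  # DNA
    mature_mirnas: dict[str, str]  # RNA
    mirna_families: dict[str, str]  # mature name -> family
    precursor_mirnas: dict[str, str]  # RNA
    ncrna_sets: dict[str, dict[str, str]]  # category -> name -> DNA
    adapter: str
    hairpins: list[PlantedHairpin] = field(default_factory=list)

    def validate(self) -> None:
        for name, mat in self.mature_mirnas.items():
            pre = self.precursor_mirnas[name + "-pre"]
            if mat not in pre:
                raise ConsistencyError(f"mature {name} not inside its precursor")
        genome = list(self.genome_segments.values())
        for pname, pre in self.precursor_mirnas.items():
            dna = to_dna(pre)
            if not any(dna in seg for seg in genome):
                raise ConsistencyError(f"precursor {pname} absent from genome")
        for hp in self.hairpins:
            seg = self.genome_segments[hp.segment]
            window = seg[hp.start - 1 : hp.end]
            expect = to_dna(hp.precursor) if hp.strand == "+" else revcomp_dna(to_dna(hp.precursor))
            if window != expect:
                raise ConsistencyError(f"hairpin {hp.name} genome coordinates wrong")
            if hp.mature not in hp.precursor:
                raise ConsistencyError(f"hairpin {hp.name} mature arm not in precursor")


@dataclass
class TruthTable:
    """Intended composition of each library, and realized counts after sampling.

    Component keys used in ``realized``: ``("miRNA", name)``,
    ``("ncRNA", category)`` (including ``unannotated``),
    ``("hairpin", name)``, ``("reject", reason)``.
    """

    library_totals: dict[str, int]
    mirna_counts: dict[str, dict[str, int]]
    category_counts: dict[str, dict[str, int]]
    hairpin_counts: dict[str, dict[str, int]]
    reject_counts: dict[str, dict[str, int]]
    intended_log2fc: dict[tuple[str, str, str], float]
    hairpin_loci: list[PlantedHairpin]
    intended_length_hist: dict[str, dict[int, float]]
    intended_first_nt: dict[str, dict[int, dict[str, float]]]
    realized: dict[str, dict[tuple, int]] = field(default_factory=dict)

    def intended_clean_total(self, lib: str) -> int:
        return self.library_totals[lib] - sum(self.reject_counts[lib].values())


def _rand_seq(rng: np.random.Generator, length: int, first: str | None = None) -> str:
    s = "".join(rng.choice(_DNA, size=length))
    if first is not None:
        s = first + s[1:]
    return s


def _pick_first_nt(rng: np.random.Generator, length: int) -> str:
    # 5'-U enrichment, strict at the lengths where real libraries show it
    p_u = 1.0 if length in (20, 22) else 0.5
    if rng.random() < p_u:
        return "T"
    return str(rng.choice(np.array(list("ACG"))))


def _make_mature(rng: np.random.Generator, length: int | None = None) -> str:
    if length is None:
        length = int(rng.choice([20, 21, 22, 23, 24], p=[0.15, 0.20, 0.40, 0.20, 0.05]))
    return to_rna(_rand_seq(rng, length, first=_pick_first_nt(rng, length)))


_NO_PAIR = {
    "A": "AG", "C": "AC", "G": "AG", "U": "CU",  # partner -> bases it cannot pair
}


def _hairpin_around(rng: np.random.Generator, mature: str, arm: str) -> str:
    """Near-perfect-stem hairpin (RNA) with `mature` fully on the requested arm.

    The opposite arm carries two non-pairing substitutions facing the middle
    of the mature, as real precursors do; this also keeps the mature's exact
    reverse complement out of the genome, so a sequenced arm maps uniquely.
    """
    ext = to_rna(_rand_seq(rng, int(rng.integers(4, 9))))
    carrier = mature + ext
    other = list(revcomp_rna(carrier))
    # positions in `other` pairing with the middle third of the mature
    lo = len(ext) + len(mature) // 3
    hi = len(ext) + 2 * len(mature) // 3
    for pos in rng.choice(np.arange(lo, hi), size=2, replace=False):
        partner = carrier[len(carrier) - 1 - pos]
        choices = [b for b in _NO_PAIR[partner] if b != other[pos]]
        other[pos] = str(rng.choice(np.array(choices)))
    loop = to_rna(_rand_seq(rng, int(rng.integers(6, 13))))
    if arm == "5p":
        return carrier + loop + "".join(other)
    return "".join(other) + loop + carrier


def _hairpin_discoverable(hp: PlantedHairpin, segment_seq: str) -> bool:
    """True when the planted mature arm, mapped back to this segment, passes
    the novel-miRNA stem-loop screen."""
    from .novel import GenomeLocus, evaluate_hairpin, extract_precursor_windows

    m_off = hp.precursor.index(hp.mature)
    length = len(hp.mature)
    if hp.strand == "+":
        locus = GenomeLocus(hp.segment, hp.start + m_off, hp.start + m_off + length - 1, "+")
    else:
        locus = GenomeLocus(
            hp.segment, hp.end - (m_off + length - 1), hp.end - m_off, "-"
        )
    segs = {hp.segment: segment_seq}
    return any(
        evaluate_hairpin(w).verdict for w in extract_precursor_windows(locus, segs)
    )


def build_reference_panel(
    seed: int,
    n_mirnas: int = 30,
    n_families: int = 10,
    n_hairpins: int = 4,
    n_segments: int = 5,
    segment_length: int = 1500,
    adapter: str = DEFAULT_ADAPTER,
) -> ReferencePanel:
    """Deterministically generate genome, miRNA, ncRNA and hairpin references.

    Planted novel hairpins have perfect stems of >= 18 bp (mature arm plus a
    4-8 nt extension), terminal loops of 6-12 nt, and the designated mature
    arm entirely on one side of the stem.
    """
    if n_mirnas < n_families or n_families < 1 or n_hairpins < 0 or n_segments < 1:
        raise ValueError("need n_mirnas >= n_families >= 1, n_hairpins >= 0, n_segments >= 1")
    rng = np.random.default_rng(seed)

    matures: dict[str, str] = {}
    families: dict[str, str] = {}
    per_family_index: dict[int, int] = {}
    # guarantee the panel carries 22- and 20-nt species (the lengths with the
    # strict 5'-U start) before sampling the remaining lengths freely
    forced_lengths = [22, 22, 20, 20][:n_mirnas]
    while len(matures) < n_mirnas:
        fam_no = len(matures) % n_families + 1
        length = forced_lengths[len(matures)] if len(matures) < len(forced_lengths) else None
        seq = _make_mature(rng, length)
        # keep matures well separated so <=2-mismatch annotation is unambiguous
        clash = any(
            len(seq) == len(m) and sum(a != b for a, b in zip(seq, m)) <= 4
            for m in matures.values()
        )
        if clash or seq in matures.values():
            continue
        letter = "abcdefghijklmnopqrstuvwxyz"[per_family_index.get(fam_no, 0)]
        per_family_index[fam_no] = per_family_index.get(fam_no, 0) + 1
        arm = "5p" if rng.random() < 0.7 else "3p"
        name = f"syn-miR-{fam_no}{letter}-{arm}"
        matures[name] = seq
        families[name] = f"syn-miR-{fam_no}"

    precursors: dict[str, str] = {}
    for name, mat in matures.items():
        arm = name.rsplit("-", 1)[1]
        flank5 = to_rna(_rand_seq(rng, int(rng.integers(5, 11))))
        flank3 = to_rna(_rand_seq(rng, int(rng.integers(5, 11))))
        precursors[name + "-pre"] = flank5 + _hairpin_around(rng, mat, arm) + flank3

    def draw_hairpin(k: int) -> tuple:
        # novel-arm matures run a little long so the tag-side stem stays
        # comfortably above the screen threshold even in clipped windows
        length = int(rng.choice([22, 23, 24]))
        mature = to_rna(_rand_seq(rng, length, first=_pick_first_nt(rng, length)))
        arm = "5p" if k % 2 == 0 else "3p"
        strand = "+" if k % 2 == 0 else "-"
        return (f"hp{k + 1}", _hairpin_around(rng, mature, arm), mature, arm, strand)

    hairpin_specs = [draw_hairpin(k) for k in range(n_hairpins)]

    # assemble genome segments: precursors (+ strand) and hairpins (either
    # strand) separated by random spacers, padded to segment_length
    seg_names = [f"seg{i + 1}" for i in range(n_segments)]
    pre_items: dict[str, list] = {s: [] for s in seg_names}
    hp_assignment: dict[str, list[int]] = {s: [] for s in seg_names}
    for i, (pname, pre) in enumerate(sorted(precursors.items())):
        pre_items[seg_names[i % n_segments]].append(("pre", pname, to_dna(pre), "+"))
    for i in range(len(hairpin_specs)):
        hp_assignment[seg_names[i % n_segments]].append(i)

    genome: dict[str, str] = {}
    hairpins: list[PlantedHairpin] = []
    for seg_name in seg_names:
        # rebuild the segment until every planted hairpin actually passes the
        # stem-loop screen in its genomic context: base-pair maximization on
        # window + flank occasionally prefers a different geometry, and the
        # generator's contract is that planted hairpins are discoverable
        for _attempt in range(50):
            items = list(pre_items[seg_name])
            for hp_i in hp_assignment[seg_name]:
                name, pre, mature, arm, strand = hairpin_specs[hp_i]
                dna = to_dna(pre) if strand == "+" else revcomp_dna(to_dna(pre))
                items.append(("hp", hp_i, dna, strand))
            parts: list[str] = []
            cursor = 0
            placed: list[PlantedHairpin] = []
            for kind, key, dna, strand in items:
                spacer = _rand_seq(rng, int(rng.integers(40, 121)))
                parts.append(spacer)
                cursor += len(spacer)
                start = cursor + 1
                parts.append(dna)
                cursor += len(dna)
                if kind == "hp":
                    name, pre, mature, arm, _ = hairpin_specs[key]
                    placed.append(
                        PlantedHairpin(name, seg_name, start, cursor, strand, pre, mature, arm)
                    )
            tail = max(segment_length - cursor, int(rng.integers(60, 201)))
            parts.append(_rand_seq(rng, tail))
            seq = "".join(parts)
            bad = [hp for hp in placed if not _hairpin_discoverable(hp, seq)]
            if not bad:
                genome[seg_name] = seq
                hairpins.extend(placed)
                break
            for hp in bad:  # redraw the failing hairpin(s) and reassemble
                idx = int(hp.name[2:]) - 1
                hairpin_specs[idx] = draw_hairpin(idx)
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not assemble a discoverable segment {seg_name}")

    ncrna_sizes = {"rRNA": (3, 1000), "tRNA": (8, 75), "snRNA": (4, 150), "snoRNA": (4, 120), "exon": (6, 400)}
    ncrna_sets = {
        cat: {f"{cat}_{i + 1}": _rand_seq(rng, length) for i in range(n)}
        for cat, (n, length) in ncrna_sizes.items()
    }

    panel = ReferencePanel(genome, matures, families, precursors, ncrna_sets, adapter, hairpins)
    panel.validate()
    return panel


def build_truth_table(
    panel: ReferencePanel,
    library_totals: dict[str, int],
    seed: int,
    mirna_fraction: float = DEFAULT_MIRNA_FRACTION,
    category_fractions: dict[str, float] | None = None,
    reject_fractions: dict[str, float] | None = None,
    de_plan: dict[str, dict[str, float]] | None = None,
    hairpin_read_range: tuple[int, int] = (12, 40),
) -> TruthTable:
    """Assign intended per-library read counts to every panel component.

    ``de_plan`` maps a mature miRNA name to per-library linear rate
    multipliers (unlisted libraries get 1.0). The default plants a 4x
    up-regulation of the first mature miRNA in the second library, giving a
    known +2 log2 fold change to recover downstream. Multiplied read mass is
    taken from / returned to the unannotated slice so planted rate ratios
    are exact.
    """
    cat_frac = dict(DEFAULT_CATEGORY_FRACTIONS if category_fractions is None else category_fractions)
    rej_frac = dict(DEFAULT_REJECT_FRACTIONS if reject_fractions is None else reject_fractions)
    libs = list(library_totals)
    mirnas = sorted(panel.mature_mirnas)
    if de_plan is None:
        de_plan = {mirnas[0]: {libs[1]: 4.0}} if len(libs) > 1 else {}
    unknown = set(de_plan) - set(mirnas)
    if unknown:
        raise ConsistencyError(f"de_plan names not in panel: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    base_w = np.exp(rng.uniform(np.log(1.0), np.log(50.0), size=len(mirnas)))
    # planted DE miRNAs get a fixed moderate share of the miRNA slice: large
    # enough that fold-change recovery is measured on well-covered counts,
    # small enough that a 4x multiplier leaves room for the other slices
    target_share = 0.06
    for m in de_plan:
        others = base_w.sum() - base_w[mirnas.index(m)]
        base_w[mirnas.index(m)] = target_share / (1 - target_share) * others
    base_share = base_w / base_w.sum()

    mirna_counts: dict[str, dict[str, int]] = {}
    category_counts: dict[str, dict[str, int]] = {}
    hairpin_counts: dict[str, dict[str, int]] = {}
    reject_counts: dict[str, dict[str, int]] = {}
    hp_base = {hp.name: int(rng.integers(*hairpin_read_range)) for hp in panel.hairpins}
    for lib in libs:
        total = library_totals[lib]
        if total < 1:
            raise ValueError("library totals must be >= 1")
        mult = np.array([de_plan.get(m, {}).get(lib, 1.0) for m in mirnas])
        rates = base_share * mult  # per-miRNA share of the miRNA slice, unnormalized
        mirna_counts[lib] = {
            m: int(round(r * mirna_fraction * total)) for m, r in zip(mirnas, rates)
        }
        hairpin_counts[lib] = dict(hp_base)
        reject_counts[lib] = {r: int(round(f * total)) for r, f in rej_frac.items()}
        cats = {c: int(round(f * total)) for c, f in cat_frac.items()}
        used = (
            sum(mirna_counts[lib].values())
            + sum(hairpin_counts[lib].values())
            + sum(reject_counts[lib].values())
            + sum(cats.values())
        )
        if used >= total:
            raise ValueError("intended fractions leave no room for unannotated reads")
        cats["unannotated"] = total - used
        category_counts[lib] = cats

    intended_log2fc: dict[tuple[str, str, str], float] = {}
    for m in de_plan:
        for i, la in enumerate(libs):
            for lb in libs[i + 1 :]:
                ra = mirna_counts[la][m] / (library_totals[la] - sum(reject_counts[la].values()))
                rb = mirna_counts[lb][m] / (library_totals[lb] - sum(reject_counts[lb].values()))
                if ra > 0 and rb > 0:
                    intended_log2fc[(m, la, lb)] = math.log2(rb / ra)

    length_hist: dict[str, dict[int, float]] = {}
    first_nt: dict[str, dict[int, dict[str, float]]] = {}
    for lib in libs:
        hist: dict[int, float] = {length: 0.0 for length in range(18, 31)}
        nt: dict[int, dict[str, float]] = {length: {b: 0.0 for b in "ACGU"} for length in range(18, 31)}
        for m, c in mirna_counts[lib].items():
            seq = panel.mature_mirnas[m]
            hist[len(seq)] += c
            nt[len(seq)][seq[0]] += c
        for hp in panel.hairpins:
            c = hairpin_counts[lib][hp.name]
            hist[len(hp.mature)] += c
            nt[len(hp.mature)][hp.mature[0]] += c
        unann = category_counts[lib]["unannotated"]
        frag_total = sum(category_counts[lib].values()) - unann
        for length in range(18, 31):
            hist[length] += (frag_total + unann) / 13.0
            for b in "ACGU":
                nt[length][b] += frag_total / 13.0 / 4.0
                # unannotated background leans 5'-U (0.4 vs 0.2)
                nt[length][b] += unann / 13.0 * (0.4 if b == "U" else 0.2)
        clean = sum(hist.values())
        length_hist[lib] = {k: v / clean for k, v in hist.items()}
        first_nt[lib] = {
            k: {b: (v[b] / sum(v.values()) if sum(v.values()) else 0.0) for b in "ACGU"}
            for k, v in nt.items()
        }

    return TruthTable(
        dict(library_totals),
        mirna_counts,
        category_counts,
        hairpin_counts,
        reject_counts,
        intended_log2fc,
        list(panel.hairpins),
        length_hist,
        first_nt,
    )


def _fragment(rng: np.random.Generator, ref: str) -> str:
    length = min(int(rng.integers(18, 31)), len(ref))
    start = int(rng.integers(0, len(ref) - length + 1))
    return ref[start : start + length]


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(k, len(chars)), replace=False):
        alt = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = str(rng.choice(np.array(alt)))
    return "".join(chars)


def simulate_library(
    panel: ReferencePanel,
    truth: TruthTable,
    library_name: str,
    total_reads: int,
    seed: int,
    read_length: int = 50,
    mutation_prob: float = 0.0,
    error_rate: float = 0.0,
) -> tuple[list[tuple[str, str, str]], dict[tuple, int]]:
    """Emit one library as (id, sequence, quality) FASTQ records.

    Reads are instrument-style: insert + 3' adapter + random padding,
    truncated to ``read_length``. Component counts are drawn multinomially
    from the truth table's intended counts (rescaled to ``total_reads``);
    the realized counts are recorded in ``truth.realized[library_name]``
    and also returned. ``mutation_prob`` is the chance a miRNA-derived
    insert carries 1-2 substitutions; ``error_rate`` is an independent
    per-base sequencing substitution rate applied to the final read.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if library_name not in truth.library_totals:
        raise ConsistencyError(f"library {library_name!r} not in truth table")
    missing = set(truth.mirna_counts[library_name]) - set(panel.mature_mirnas)
    if missing:
        raise ConsistencyError(f"truth names miRNAs absent from panel: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    components: list[tuple] = []
    intended: list[int] = []
    for m in sorted(truth.mirna_counts[library_name]):
        components.append(("miRNA", m))
        intended.append(truth.mirna_counts[library_name][m])
    for cat in sorted(truth.category_counts[library_name]):
        components.append(("ncRNA", cat))
        intended.append(truth.category_counts[library_name][cat])
    for hp in sorted(truth.hairpin_counts[library_name]):
        components.append(("hairpin", hp))
        intended.append(truth.hairpin_counts[library_name][hp])
    for reason in sorted(truth.reject_counts[library_name]):
        components.append(("reject", reason))
        intended.append(truth.reject_counts[library_name][reason])
    intended_arr = np.array(intended, dtype=float)
    if intended_arr.sum() <= 0:
        raise ConsistencyError("truth table has no read mass")
    counts = rng.multinomial(total_reads, intended_arr / intended_arr.sum())
    realized = {comp: int(c) for comp, c in zip(components, counts)}
    truth.realized[library_name] = realized

    hp_by_name = {hp.name: hp for hp in panel.hairpins}
    adapter = panel.adapter
    good_q = "I" * read_length
    bad_q = "#" * read_length

    inserts: list[tuple[str, str]] = []  # (insert DNA, quality class)
    for comp, c in zip(components, counts):
        kind, key = comp
        for _ in range(int(c)):
            if kind == "miRNA":
                ins = to_dna(panel.mature_mirnas[key])
                if mutation_prob > 0 and rng.random() < mutation_prob:
                    ins = _mutate(rng, ins, int(rng.integers(1, 3)))
                inserts.append((ins, "good"))
            elif kind == "hairpin":
                inserts.append((to_dna(hp_by_name[key].mature), "good"))
            elif kind == "ncRNA":
                if key == "unannotated":
                    # background sRNAs share the mild genome-wide 5'-U lean
                    first = "T" if rng.random() < 0.4 else None
                    inserts.append((_rand_seq(rng, int(rng.integers(18, 31)), first=first), "good"))
                elif key == "exon_antisense":
                    refs = sorted(panel.ncrna_sets["exon"])
                    ref = revcomp_dna(panel.ncrna_sets["exon"][refs[int(rng.integers(len(refs)))]])
                    inserts.append((_fragment(rng, ref), "good"))
                else:
                    cat = "exon" if key == "exon_sense" else key
                    refs = sorted(panel.ncrna_sets[cat])
                    ref = panel.ncrna_sets[cat][refs[int(rng.integers(len(refs)))]]
                    inserts.append((_fragment(rng, ref), "good"))
            else:  # reject classes
                if key == "adapter_only":
                    inserts.append(("", "good"))
                elif key == "low_quality":
                    inserts.append((_rand_seq(rng, int(rng.integers(18, 31))), "bad"))
                elif key == "too_short":
                    inserts.append((_rand_seq(rng, int(rng.integers(12, 18))), "good"))
                else:  # too_long
                    inserts.append((_rand_seq(rng, int(rng.integers(31, 41))), "good"))

    order = rng.permutation(len(inserts))
    records: list[tuple[str, str, str]] = []
    for out_i, idx in enumerate(order):
        ins, qclass = inserts[idx]
        read = ins + adapter
        if len(read) < read_length:
            read += _rand_seq(rng, read_length - len(read))
        read = read[:read_length]
        if error_rate > 0:
            n_err = rng.binomial(len(read), error_rate)
            if n_err:
                read = _mutate(rng, read, int(n_err))
        records.append((f"{library_name}:{out_i + 1}", read, bad_q if qclass == "bad" else good_q))
    return records, realized


def write_fastq(records: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")
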