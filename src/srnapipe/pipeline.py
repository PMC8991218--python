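"""End-to-end orchestration with a config file and a reproducible manifest.

Stage order follows the analysis: simulate (or ingest) -> clean -> annotate
-> novel -> diffexp -> cluster. All randomness flows from one seed; each
stage derives its own sub-seed by hashing its name, so disabling one stage
does not perturb another's random stream. Outputs are plain text (TSV /
FASTA / FASTQ / newick, LF endings, 6-significant-digit reals) and the run
manifest records a SHA-256 digest of every artifact, so identical config +
inputs yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import annotate as ann
from . import diffexpr as de
from . import novel as nv
from . import reads as rd
from . import simulate as sim

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "clean", "annotate", "novel", "diffexp", "cluster")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    libraries: dict[str, int] = field(
        default_factory=lambda: {"Control": 20000, "Test1": 20000, "Test2": 20000}
    )
    n_mirnas: int = 30
    n_families: int = 10
    n_hairpins: int = 4
    adapter: str = sim.DEFAULT_ADAPTER
    quality_floor: float = 20.0
    min_len: int = 18
    max_len: int = 30
    min_overlap: int = 6
    min_mirna_count: int = 10
    novel_min_read_count: int = 10
    hairpin_thresholds: dict = field(default_factory=dict)
    de_config: dict = field(default_factory=dict)
    count_matrix: str | None = None  # external DE input when annotate is off

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("require 1 <= min_len <= max_len")
        if self.min_overlap < 1 or self.quality_floor < 0:
            raise ValueError("min_overlap >= 1 and quality_floor >= 0 required")
        if self.n_mirnas < self.n_families or self.n_families < 1 or self.n_hairpins < 0:
            raise ValueError("bad panel sizes")
        for lib, total in self.libraries.items():
            if total < 1:
                raise ValueError(f"library {lib} total must be >= 1")
        de.DEConfig(**self.de_config)  # raises on bad values
        nv.HairpinThresholds(**self.hairpin_thresholds)
        if "diffexp" in self.stages and "annotate" not in self.stages:
            if not self.count_matrix or not Path(self.count_matrix).exists():
                raise ValueError("diffexp without annotate requires an existing count_matrix path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _sub_seed(seed: int, stage: str) -> int:
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    artifacts: dict[str, Path] = {}

    def record(stage: str, paths: dict[str, Path], rows: dict[str, int] | None = None) -> None:
        manifest["stages"][stage] = {
            "outputs": {name: _digest(p) for name, p in sorted(paths.items())},
            "rows": rows or {},
        }
        artifacts.update(paths)

    panel = truth = None
    profiles: dict[str, rd.LibraryProfile] = {}
    assignments: dict[str, dict] = {}
    matrix = totals = None
    thresholds = nv.HairpinThresholds(**config.hairpin_thresholds)
    de_config = de.DEConfig(**config.de_config)

    for stage in [s for s in ALL_STAGES if s in config.stages]:
        t0 = time.time()
        try:
            if stage == "simulate":
                panel = sim.build_reference_panel(
                    _sub_seed(config.seed, "panel"),
                    n_mirnas=config.n_mirnas,
                    n_families=config.n_families,
                    n_hairpins=config.n_hairpins,
                    adapter=config.adapter,
                )
                truth = sim.build_truth_table(
                    panel, config.libraries, _sub_seed(config.seed, "truth")
                )
                paths = {}
                sim.write_fasta(panel.genome_segments, out / "genome.fa")
                sim.write_fasta(panel.mature_mirnas, out / "mature.fa")
                sim.write_fasta(panel.precursor_mirnas, out / "precursor.fa")
                paths |= {p.name: p for p in (out / "genome.fa", out / "mature.fa", out / "precursor.fa")}
                for cat, seqs in panel.ncrna_sets.items():
                    p = out / f"ncrna_{cat}.fa"
                    sim.write_fasta(seqs, p)
                    paths[p.name] = p
                for lib, total in config.libraries.items():
                    recs, _ = sim.simulate_library(
                        panel, truth, lib, total, _sub_seed(config.seed, f"lib:{lib}")
                    )
                    p = out / f"{lib}.fastq"
                    sim.write_fastq(recs, p)
                    paths[p.name] = p
                tp = out / "truth.json"
                tp.write_text(
                    json.dumps(
                        {
                            "library_totals": truth.library_totals,
                            "mirna_counts": truth.mirna_counts,
                            "category_counts": truth.category_counts,
                            "hairpin_counts": truth.hairpin_counts,
                            "reject_counts": truth.reject_counts,
                            "intended_log2fc": {
                                "|".join(k): v for k, v in truth.intended_log2fc.items()
                            },
                            "hairpin_loci": [asdict(h) for h in truth.hairpin_loci],
                        },
                        indent=1,
                        sort_keys=True,
                    )
                    + "\n"
                )
                paths[tp.name] = tp
                record(stage, paths)
            elif stage == "clean":
                if panel is None:
                    raise PipelineError("clean requires the simulate stage in this configuration")
                paths, rows = {}, {}
                for lib in config.libraries:
                    profile = rd.build_profile(
                        lib,
                        out / f"{lib}.fastq",
                        config.adapter,
                        quality_floor=config.quality_floor,
                        min_len=config.min_len,
                        max_len=config.max_len,
                        min_overlap=config.min_overlap,
                    )
                    profiles[lib] = profile
                    p = out / f"{lib}.tags.fa"
                    rd.write_tags_fasta(profile, p)
                    paths[p.name] = p
                    ld = rd.length_distribution(profile, config.min_len, config.max_len)
                    p2 = out / f"{lib}.lengths.tsv"
                    ld.to_csv(p2, sep="\t")
                    paths[p2.name] = p2
                    p3 = out / f"{lib}.first_nt.tsv"
                    rd.first_nt_bias(profile).to_csv(p3, sep="\t", float_format="%.6g")
                    paths[p3.name] = p3
                    rows[lib] = len(profile.tags)
                record(stage, paths, rows)
            elif stage == "annotate":
                paths, rows = {}, {}
                for lib, profile in profiles.items():
                    assignments[lib] = ann.classify_profile(profile, panel)
                    summary = ann.summarize_categories(profile, assignments[lib])
                    p = out / f"{lib}.categories.tsv"
                    summary.to_csv(p, sep="\t", float_format="%.6g")
                    paths[p.name] = p
                records = ann.identify_conserved(
                    profiles, assignments, panel, min_count=config.min_mirna_count
                )
                libs = list(config.libraries)
                matrix = ann.count_matrix(records, libs)
                totals = {lib: profiles[lib].total_clean_reads for lib in libs}
                p = out / "mirna_counts.tsv"
                de.write_count_matrix(p, matrix, totals)
                paths[p.name] = p
                rows["conserved_mirnas"] = len(records)
                record(stage, paths, rows)
            elif stage == "novel":
                tag_counts: dict[str, dict[str, int]] = {}
                for lib, profile in profiles.items():
                    amap = assignments.get(lib) or ann.classify_profile(profile, panel)
                    assignments[lib] = amap
                    for t in profile.tags:
                        if amap[t.sequence].category == "unannotated":
                            tag_counts.setdefault(t.sequence, {})[lib] = t.count
                table, cands = nv.call_novel(
                    tag_counts,
                    panel.genome_segments,
                    thresholds=thresholds,
                    min_read_count=config.novel_min_read_count,
                    libraries=list(config.libraries),
                )
                p = out / "novel_mirnas.tsv"
                table.to_csv(p, sep="\t", index=False)
                p2 = out / "novel_structures.txt"
                with open(p2, "w") as fh:
                    for row, cand in zip(table.itertuples(), cands):
                        fh.write(f">{row.name} {cand.locus.to_string()}\n")
                        fh.write(cand.precursor + "\n" + cand.structure + "\n")
                record(stage, {p.name: p, p2.name: p2}, {"candidates": len(table)})
            elif stage == "diffexp":
                if matrix is None:
                    matrix, totals = de.read_count_matrix(config.count_matrix)
                paths, rows = {}, {}
                libs = list(matrix.columns)
                for i, la in enumerate(libs):
                    for lb in libs[i + 1 :]:
                        results = de.run_de(matrix, totals, la, lb, de_config)
                        p = out / f"de_{la}_vs_{lb}.tsv"
                        de.de_table(results, la, lb).to_csv(
                            p, sep="\t", index=False, float_format="%.6g"
                        )
                        paths[p.name] = p
                        rows[f"{la}_vs_{lb}"] = sum(r.tested for r in results)
                record(stage, paths, rows)
            elif stage == "cluster":
                if matrix is None:
                    matrix, totals = de.read_count_matrix(config.count_matrix)
                norm = matrix.apply(
                    lambda col: [
                        de.normalize(v, totals[col.name], de_config.pseudo_count) for v in col
                    ]
                )
                if len(norm) >= 2:
                    newick, _, _ = de.cluster_expression(norm, de_config.pseudo_count)
                    p = out / "expression_tree.nwk"
                    p.write_text(newick + "\n")
                    record(stage, {p.name: p}, {"leaves": len(norm)})
                else:
                    record(stage, {}, {"leaves": len(norm)})
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2fs", stage, time.time() - t0)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
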