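"""End-to-end screen pipeline: map -> annotate -> enrich -> compare.

Stage outputs are persisted as plain TSV/BED so every stage is
independently inspectable and resumable; a JSON manifest records the
configuration hash, seed, package version and a checksum of every output,
so a rerun with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation import GeneIndex, read_annotation
from .mapping import (
    collapse_nearby_sites,
    dedupe_sites,
    derive_insertion_sites,
    read_alignment_reports,
    read_bed,
    write_bed,
)
from .compare import build_comparison_matrix
from .stats import analyze_screen

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenSpec:
    screen_id: str
    sorted_path: str
    control_path: str


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    screens: list[ScreenSpec]
    annotation: str
    outdir: str
    hit_q: float = 0.01
    compare_q: float = 1e-4
    collapse_bp: int = 2
    collapse_across_strands: bool = False
    exon_mode: str = "any"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        screens = [
            ScreenSpec(s["screen_id"], s["sorted"], s["control"])
            for s in d["screens"]
        ]
        return cls(
            screens=screens,
            annotation=d["annotation"],
            outdir=d.get("outdir", "gtscreen_run"),
            hit_q=d.get("hit_q", 0.01),
            compare_q=d.get("compare_q", 1e-4),
            collapse_bp=d.get("collapse_bp", 2),
            collapse_across_strands=d.get("collapse_across_strands", False),
            exon_mode=d.get("exon_mode", "any"),
            seed=d.get("seed", 0),
        )

    def to_dict(self) -> dict:
        return {
            "screens": [
                {"screen_id": s.screen_id, "sorted": s.sorted_path, "control": s.control_path}
                for s in self.screens
            ],
            "annotation": self.annotation,
            "outdir": self.outdir,
            "hit_q": self.hit_q,
            "compare_q": self.compare_q,
            "collapse_bp": self.collapse_bp,
            "collapse_across_strands": self.collapse_across_strands,
            "exon_mode": self.exon_mode,
            "seed": self.seed,
        }


@dataclass
class ValidationReport:
    failures: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def sniff_format(path) -> str:
    """Guess an input file's dialect: 'bed', 'sam' or 'report_tsv'."""
    name = str(path).lower()
    if name.endswith((".sam", ".bam")):
        return "sam"
    if name.endswith(".bed"):
        return "bed"
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                return "sam"
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 6 and fields[5] in "+-" and fields[1].isdigit() and fields[2].isdigit():
                return "bed"
            if len(fields) == 5 and fields[3] in "+-":
                return "report_tsv"
            if len(fields) >= 11:
                return "sam"
            break
    raise ValueError(f"cannot determine format of {path}")


def load_sites(path, collapse_bp: int = 2, same_strand_only: bool = True):
    """Load a site dataset from BED, SAM/BAM or the alignment-report TSV.

    Alignment inputs pass through the full unique-read derivation; BED
    inputs are assumed pre-filtered but are still deduplicated and
    collapse-merged so downstream invariants hold for any input.
    """
    fmt = sniff_format(path)
    if fmt == "bed":
        return collapse_nearby_sites(
            dedupe_sites(read_bed(path)),
            max_gap=collapse_bp,
            same_strand_only=same_strand_only,
        )
    reports = read_alignment_reports(path)
    return derive_insertion_sites(
        reports, max_gap=collapse_bp, same_strand_only=same_strand_only
    )


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Check paths, formats, thresholds and chromosome consistency.

    Never mutates state; a non-empty failure list blocks ``run_pipeline``.
    """
    report = ValidationReport()
    ids = [s.screen_id for s in config.screens]
    if len(set(ids)) != len(ids):
        report.failures.append("duplicate screen_id in configuration")
    if not config.screens:
        report.failures.append("no screens configured")
    for name, value in (("hit_q", config.hit_q), ("compare_q", config.compare_q)):
        if not 0 < value <= 1:
            report.failures.append(f"{name}={value} outside (0, 1]")
    if config.collapse_bp < 0:
        report.failures.append(f"collapse_bp={config.collapse_bp} negative")
    if config.exon_mode not in ("any", "all"):
        report.failures.append(f"unknown exon_mode {config.exon_mode!r}")

    paths = [config.annotation] + [
        p for s in config.screens for p in (s.sorted_path, s.control_path)
    ]
    missing = [p for p in paths if not Path(p).exists()]
    for p in missing:
        report.failures.append(f"missing input file: {p}")
    if report.failures:
        return report

    genes = read_annotation(config.annotation, exon_mode=config.exon_mode)
    if not genes:
        report.failures.append(f"annotation {config.annotation} contains no genes")
        return report
    chroms = {g.chrom for g in genes}
    for spec in config.screens:
        for label, p in (("sorted", spec.sorted_path), ("control", spec.control_path)):
            try:
                fmt = sniff_format(p)
            except ValueError as exc:
                report.failures.append(str(exc))
                continue
            if fmt == "bed":
                sites = read_bed(p)
                orphans = sum(1 for s in sites if s.chrom not in chroms)
                if orphans:
                    report.warnings.append(
                        f"{spec.screen_id}/{label}: {orphans} site(s) on chromosomes "
                        "absent from the annotation"
                    )
    return report


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and persist) the run manifest.

    Writes, under ``config.outdir``: per-screen unique-site BEDs, per-screen
    enrichment and circle-plot TSVs, the cross-screen comparison matrix
    (signed and display-clipped) when >= 2 screens are configured, and
    ``manifest.json``.
    """
    report = validate_inputs(config)
    if not report.ok:
        raise ValueError("invalid configuration: " + "; ".join(report.failures))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = read_annotation(config.annotation, exon_mode=config.exon_mode)
    index = GeneIndex(genes)

    outputs: dict[str, str] = {}
    stages: list[dict] = []
    screen_results = []
    for spec in config.screens:
        datasets = {}
        for label, path in (("sorted", spec.sorted_path), ("control", spec.control_path)):
            try:
                sites = load_sites(
                    path,
                    collapse_bp=config.collapse_bp,
                    same_strand_only=not config.collapse_across_strands,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage map-insertions failed for {spec.screen_id}/{label}: {exc}"
                ) from exc
            datasets[label] = sites
            bed = outdir / f"{spec.screen_id}.{label}.sites.bed"
            write_bed(sites, bed)
            outputs[bed.name] = str(bed)
            stages.append(
                {
                    "stage": "map-insertions",
                    "screen": spec.screen_id,
                    "dataset": label,
                    "n_unique_sites": len(sites),
                }
            )
        try:
            result = analyze_screen(
                datasets["sorted"],
                datasets["control"],
                index,
                screen_id=spec.screen_id,
                hit_q=config.hit_q,
            )
        except Exception as exc:
            raise RuntimeError(f"stage enrich failed for {spec.screen_id}: {exc}") from exc
        screen_results.append(result)
        enr = outdir / f"{spec.screen_id}.enrichment.tsv"
        result.write_tsv(enr)
        outputs[enr.name] = str(enr)
        circ = outdir / f"{spec.screen_id}.circle.tsv"
        result.circle_plot_table().to_csv(circ, sep="\t", index=False, float_format="%.6g")
        outputs[circ.name] = str(circ)
        stages.append(
            {
                "stage": "enrich",
                "screen": spec.screen_id,
                "n_genes_tested": len(result),
                "n_hits": len(result.hits),
            }
        )

    if len(screen_results) >= 2:
        matrix = build_comparison_matrix(screen_results, threshold=config.compare_q)
        for name, display in (("comparison.tsv", False), ("comparison.display.tsv", True)):
            path = outdir / name
            matrix.write_tsv(path, display=display)
            outputs[path.name] = str(path)
        stages.append({"stage": "compare", "n_genes_included": matrix.n_genes})

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "stages": stages,
        "outputs": {
            name: {"path": path, "sha256": _sha256(path)}
            for name, path in sorted(outputs.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d screen(s), outputs in %s", len(config.screens), outdir)
    return manifest
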