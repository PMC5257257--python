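"""Derivation of unique gene-trap insertion sites from junction-read alignments.

A gene-trap screen recovers short genomic sequences flanking each proviral
LTR junction.  After alignment, every read comes with a set of candidate
placements at 0, 1 or 2 mismatches.  This module applies the two filtering
rules that turn those per-read reports into a dataset of unique insertion
sites:

1. a read is kept only if it aligns to exactly one place with zero
   mismatches and nowhere else even when 1 or 2 mismatches are allowed;
2. sites whose positions lie 1-2 bp apart (same chromosome and strand) are
   collapsed to a single retained site.

Coordinates are 0-based throughout; the insertion position is the leftmost
aligned genomic base of the junction read, and the provirus orientation is
the alignment strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class Placement(NamedTuple):
    """One candidate genomic placement of a junction read."""

    chrom: str
    position: int
    strand: str
    mismatches: int


@dataclass
class AlignmentReport:
    """All candidate placements (0-2 mismatches) for one junction read."""

    read_id: str
    placements: list[Placement] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.placements:
            if p.mismatches not in (0, 1, 2):
                raise ValueError(
                    f"read {self.read_id}: mismatch count {p.mismatches} outside 0-2"
                )
            if p.strand not in STRANDS:
                raise ValueError(f"read {self.read_id}: bad strand {p.strand!r}")


@dataclass(frozen=True)
class InsertionSite:
    """A unique, deduplicated gene-trap integration locus.

    ``position`` is the first genomic base flanking the LTR junction
    (0-based); ``strand`` is the provirus orientation; ``read_support`` the
    number of reads collapsed into this site.
    """

    chrom: str
    position: int
    strand: str
    read_support: int = 1

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")
        if self.read_support < 1:
            raise ValueError(f"read_support must be >= 1, got {self.read_support}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")


def filter_unique_reads(reports: Iterable[AlignmentReport]) -> list[AlignmentReport]:
    """Keep reads that align uniquely even when 1-2 mismatches are allowed.

    A read is retained iff it has exactly one zero-mismatch placement and no
    additional placement at <= 2 mismatches.  Retained reads keep only their
    zero-mismatch placement.  Dropped reads are logged, not raised.
    """
    kept: list[AlignmentReport] = []
    n_dropped = 0
    for report in reports:
        zero = [p for p in report.placements if p.mismatches == 0]
        if len(zero) == 1 and len(report.placements) == 1:
            kept.append(AlignmentReport(report.read_id, zero))
        else:
            n_dropped += 1
            if not zero:
                reason = "no zero-mismatch placement"
            elif len(zero) > 1:
                reason = "multiple zero-mismatch placements"
            else:
                reason = "additional placement at 1-2 mismatches"
            logger.debug("dropping read %s: %s", report.read_id, reason)
    logger.info("filter_unique_reads: kept %d, dropped %d", len(kept), n_dropped)
    return kept


def dedupe_sites(sites: Iterable[InsertionSite]) -> list[InsertionSite]:
    """Merge sites sharing (chrom, position, strand), summing read support."""
    support: dict[tuple[str, int, str], int] = {}
    for s in sites:
        key = (s.chrom, s.position, s.strand)
        support[key] = support.get(key, 0) + s.read_support
    return [
        InsertionSite(c, pos, st, n)
        for (c, pos, st), n in sorted(support.items())
    ]


def collapse_nearby_sites(
    sites: Sequence[InsertionSite],
    max_gap: int = 2,
    same_strand_only: bool = True,
) -> list[InsertionSite]:
    """Collapse sites whose positions lie within ``max_gap`` bp of each other.

    Pairs <= ``max_gap`` apart are merged transitively within each
    (chrom, strand) group (chrom only if ``same_strand_only`` is False).  The
    retained representative is the member with the greatest read support,
    ties broken by the smallest position; its support is the sum over the
    merged members.  Output is sorted by (chrom, position, strand).

    ``same_strand_only`` defaults to True: junction reads on opposite strands
    represent different provirus orientations and are kept apart.
    """
    def group_key(s: InsertionSite):
        return (s.chrom, s.strand) if same_strand_only else (s.chrom,)

    groups: dict[tuple, list[InsertionSite]] = {}
    for s in sites:
        groups.setdefault(group_key(s), []).append(s)

    out: list[InsertionSite] = []
    for members in groups.values():
        members.sort(key=lambda s: s.position)
        cluster: list[InsertionSite] = []
        for s in members:
            if cluster and s.position - cluster[-1].position <= max_gap:
                cluster.append(s)
            else:
                if cluster:
                    out.append(_merge_cluster(cluster))
                cluster = [s]
        if cluster:
            out.append(_merge_cluster(cluster))
    out.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return out


def _merge_cluster(cluster: list[InsertionSite]) -> InsertionSite:
    if len(cluster) == 1:
        return cluster[0]
    rep = max(cluster, key=lambda s: (s.read_support, -s.position))
    total = sum(s.read_support for s in cluster)
    return InsertionSite(rep.chrom, rep.position, rep.strand, total)


def derive_insertion_sites(
    reports: Iterable[AlignmentReport],
    max_gap: int = 2,
    same_strand_only: bool = True,
) -> list[InsertionSite]:
    """Full report-to-site derivation: unique filter, dedup, 1-2 bp collapse."""
    kept = filter_unique_reads(reports)
    sites = dedupe_sites(
        InsertionSite(p.chrom, p.position, p.strand)
        for r in kept
        for p in r.placements
    )
    return collapse_nearby_sites(sites, max_gap=max_gap, same_strand_only=same_strand_only)


# ---------------------------------------------------------------------------
# I/O: TSV alignment-report dialect, SAM, BED6
# ---------------------------------------------------------------------------

def read_alignment_tsv(path) -> list[AlignmentReport]:
    """Read the 5-column alignment-report dialect.

    Columns: read_id, chrom, position (0-based), strand, mismatches; one row
    per candidate placement.  Lines starting with '#' are ignored.
    """
    by_read: dict[str, list[Placement]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            read_id, chrom, pos, strand, mm = line.split("\t")
            if read_id not in by_read:
                by_read[read_id] = []
                order.append(read_id)
            by_read[read_id].append(Placement(chrom, int(pos), strand, int(mm)))
    return [AlignmentReport(r, by_read[r]) for r in order]


def write_alignment_tsv(reports: Iterable[AlignmentReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tchrom\tposition\tstrand\tmismatches\n")
        for r in reports:
            for p in r.placements:
                fh.write(f"{r.read_id}\t{p.chrom}\t{p.position}\t{p.strand}\t{p.mismatches}\n")


def read_alignment_sam(path) -> list[AlignmentReport]:
    """Reconstruct alignment reports from SAM/BAM.

    Every mapped record (primary and secondary) of a read contributes one
    placement; the mismatch count is taken from the NM tag (0 when absent).
    Placements listed in an XA tag (chrom,(+|-)pos,CIGAR,NM; 1-based) are
    also included.
    """
    import pysam

    by_read: dict[str, dict[tuple[str, int, str], int]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            name = rec.query_name
            if name not in by_read:
                by_read[name] = {}
                order.append(name)
            strand = "-" if rec.is_reverse else "+"
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            key = (rec.reference_name, rec.reference_start, strand)
            prev = by_read[name].get(key)
            by_read[name][key] = nm if prev is None else min(prev, nm)
            if rec.has_tag("XA"):
                for alt in str(rec.get_tag("XA")).rstrip(";").split(";"):
                    chrom, spos, _cigar, alt_nm = alt.split(",")
                    akey = (chrom, abs(int(spos)) - 1, spos[0] if spos[0] in "+-" else "+")
                    prev = by_read[name].get(akey)
                    nm_i = int(alt_nm)
                    by_read[name][akey] = nm_i if prev is None else min(prev, nm_i)
    return [
        AlignmentReport(
            name,
            [Placement(c, p, s, mm) for (c, p, s), mm in sorted(by_read[name].items())],
        )
        for name in order
    ]


def read_alignment_reports(path) -> list[AlignmentReport]:
    """Dispatch on extension: .sam/.bam via pysam, anything else as TSV."""
    suffix = str(path).lower()
    if suffix.endswith((".sam", ".bam")):
        return read_alignment_sam(path)
    return read_alignment_tsv(path)


def write_bed(sites: Iterable[InsertionSite], path) -> None:
    """Write sites as BED6: chrom, start, start+1, name=read_support, 0, strand."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.read_support}\t0\t{s.strand}\n")


def read_bed(path) -> list[InsertionSite]:
    sites: list[InsertionSite] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start = fields[0], int(fields[1])
            support = int(fields[3]) if len(fields) > 3 and fields[3].isdigit() else 1
            strand = fields[5] if len(fields) > 5 else "+"
            sites.append(InsertionSite(chrom, start, strand, max(support, 1)))
    return sites
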