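"""Gene models and orientation/region classification of insertion sites.

A gene trap carries a splice acceptor followed by a polyadenylation signal,
so an intronic insertion truncates the transcript only when the cassette is
in the sense orientation relative to the gene; exonic insertions disrupt in
either orientation.  An insertion is therefore called *inactivating* when it
is exonic (sense or antisense) or sense-intronic.

Gene models collapse all transcripts of a gene into a single span (the union
of transcript extents) and a single exon union; a position that is exonic in
any transcript is treated as exonic (configurable to require all
transcripts).  Coordinates are 0-based half-open internally; refFlat is
native 0-based, GTF is converted on read.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .mapping import InsertionSite

Orientation = Literal["sense", "antisense"]
Region = Literal["exon", "intron"]


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to strand, merged span and an exon-interval union.

    ``exons`` are disjoint, sorted, 0-based half-open intervals contained in
    [start, end); intronic space is the span minus the exon union.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: empty span")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.end:
                raise ValueError(f"{self.gene_id}: exons not disjoint/sorted within span")
            prev = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        prev = self.start
        for s, e in self.exons:
            if s > prev:
                out.append((prev, s))
            prev = e
        if prev < self.end:
            out.append((prev, self.end))
        return tuple(out)

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def is_exonic(self, position: int) -> bool:
        """True iff ``position`` falls inside the exon union."""
        starts = [s for s, _ in self.exons]
        i = bisect_right(starts, position) - 1
        return i >= 0 and position < self.exons[i][1]


@dataclass(frozen=True)
class ClassifiedInsertion:
    """One insertion site classified against one gene."""

    site: InsertionSite
    gene_id: str
    orientation: Orientation
    region: Region
    inactivating: bool


def classify_insertion(site: InsertionSite, gene: GeneModel) -> ClassifiedInsertion:
    """Classify a site by orientation and region relative to one gene.

    Orientation is sense iff the site strand equals the gene strand; region
    is exon iff the position falls in the gene's exon union.  The insertion
    is inactivating iff exonic (either orientation) or sense-intronic.
    Raises ValueError if the site lies outside the gene span.
    """
    if site.chrom != gene.chrom or not gene.contains(site.position):
        raise ValueError(
            f"site {site.chrom}:{site.position} outside gene {gene.gene_id} span"
        )
    orientation: Orientation = "sense" if site.strand == gene.strand else "antisense"
    region: Region = "exon" if gene.is_exonic(site.position) else "intron"
    inactivating = region == "exon" or orientation == "sense"
    return ClassifiedInsertion(site, gene.gene_id, orientation, region, inactivating)


class GeneIndex:
    """Interval index over gene spans for per-position lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_id in annotation")
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def overlapping(self, chrom: str, position: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(position)), key=lambda g: g.gene_id)

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)


@dataclass
class GeneTally:
    """Per-gene insertion tallies split by orientation and region."""

    gene_id: str
    sense_exonic: int = 0
    antisense_exonic: int = 0
    sense_intronic: int = 0
    antisense_intronic: int = 0

    @property
    def inactivating(self) -> int:
        return self.sense_exonic + self.antisense_exonic + self.sense_intronic

    @property
    def any_orientation(self) -> int:
        return (
            self.sense_exonic
            + self.antisense_exonic
            + self.sense_intronic
            + self.antisense_intronic
        )


def tally_gene_insertions(
    sites: Iterable[InsertionSite],
    genes: Sequence[GeneModel] | GeneIndex,
) -> dict[str, GeneTally]:
    """Tally every intragenic unique site per overlapping gene.

    A site overlapping several genes is counted once in each; regions shared
    by multiple transcripts of one gene were already merged into the gene
    model, so a site counts once per gene.  Every gene appears in the result,
    with zeros when it has no insertions.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    tallies = {g.gene_id: GeneTally(g.gene_id) for g in index.genes}
    for site in sites:
        for gene in index.overlapping(site.chrom, site.position):
            c = classify_insertion(site, gene)
            t = tallies[gene.gene_id]
            if c.region == "exon":
                if c.orientation == "sense":
                    t.sense_exonic += 1
                else:
                    t.antisense_exonic += 1
            else:
                if c.orientation == "sense":
                    t.sense_intronic += 1
                else:
                    t.antisense_intronic += 1
    return tallies


def count_gene_insertions(
    sites: Iterable[InsertionSite],
    genes: Sequence[GeneModel] | GeneIndex,
    mode: Literal["inactivating_only", "any_orientation"],
) -> tuple[dict[str, GeneTally], dict[str, int], int]:
    """Per-gene counts under the requested counting mode, plus the total.

    Returns ``(tallies, counts, total)`` where ``counts[gene_id]`` is the
    gene's count under ``mode`` (inactivating insertions only, or every
    intragenic insertion regardless of orientation) and ``total`` is the sum
    over all genes.
    """
    if mode not in ("inactivating_only", "any_orientation"):
        raise ValueError(f"unknown mode {mode!r}")
    tallies = tally_gene_insertions(sites, genes)
    if mode == "inactivating_only":
        counts = {g: t.inactivating for g, t in tallies.items()}
    else:
        counts = {g: t.any_orientation for g, t in tallies.items()}
    return tallies, counts, sum(counts.values())


def counts_table(
    sites: Iterable[InsertionSite],
    genes: Sequence[GeneModel] | GeneIndex,
) -> pd.DataFrame:
    """Per-gene classification table (one row per gene)."""
    tallies = tally_gene_insertions(sites, genes)
    rows = [
        {
            "gene_id": t.gene_id,
            "inactivating": t.inactivating,
            "any": t.any_orientation,
            "sense_intronic": t.sense_intronic,
            "antisense_intronic": t.antisense_intronic,
            "sense_exonic": t.sense_exonic,
            "antisense_exonic": t.antisense_exonic,
        }
        for t in tallies.values()
    ]
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


def gene_insertion_histogram(
    sites: Iterable[InsertionSite],
    gene: GeneModel,
    bin_size: int = 500,
) -> np.ndarray:
    """Per-bin (sense, antisense) counts in consecutive bins along the gene.

    Bins of ``bin_size`` bp tile the gene span starting from the gene's
    5' end (the rightmost coordinate for a minus-strand gene), so bin 0 is
    always promoter-proximal.  Returns an integer array of shape
    (n_bins, 2) with columns (sense, antisense).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = -(-gene.length // bin_size)
    hist = np.zeros((n_bins, 2), dtype=int)
    for site in sites:
        if site.chrom != gene.chrom or not gene.contains(site.position):
            continue
        if gene.strand == "+":
            offset = site.position - gene.start
        else:
            offset = gene.end - 1 - site.position
        col = 0 if site.strand == gene.strand else 1
        hist[offset // bin_size, col] += 1
    return hist


# ---------------------------------------------------------------------------
# Annotation I/O: refFlat (canonical) and GTF 2.2
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _subtract_intervals(
    base: tuple[tuple[int, int], ...], cut: tuple[tuple[int, int], ...]
) -> tuple[tuple[int, int], ...]:
    out: list[tuple[int, int]] = []
    ci = 0
    for s, e in base:
        pos = s
        while ci < len(cut) and cut[ci][1] <= pos:
            ci += 1
        j = ci
        while j < len(cut) and cut[j][0] < e:
            cs, ce = cut[j]
            if cs > pos:
                out.append((pos, cs))
            pos = max(pos, ce)
            j += 1
        if pos < e:
            out.append((pos, e))
    return tuple(out)


def _build_gene_models(
    transcripts: Mapping[str, list[tuple[str, str, int, int, list[tuple[int, int]]]]],
    exon_mode: Literal["any", "all"] = "any",
) -> list[GeneModel]:
    """Reduce per-gene transcript lists (chrom, strand, start, end, exons).

    ``exon_mode`` controls how isoform disagreement is resolved: under
    "any" a position is exonic when exonic in any transcript (exon union);
    under "all" a position exonic in one transcript but intronic in another
    is treated as intronic (exon union minus intron union).
    """
    genes: list[GeneModel] = []
    for gene_id, txs in transcripts.items():
        chroms = {t[0] for t in txs}
        strands = {t[1] for t in txs}
        if len(chroms) > 1 or len(strands) > 1:
            # paralogous copies on several chromosomes/strands cannot be
            # merged into one span; keep the most transcript-rich location
            from collections import Counter

            (chrom, strand), _ = Counter((t[0], t[1]) for t in txs).most_common(1)[0]
            txs = [t for t in txs if t[0] == chrom and t[1] == strand]
        chrom, strand = txs[0][0], txs[0][1]
        start = min(t[2] for t in txs)
        end = max(t[3] for t in txs)
        exons = _merge_intervals([iv for t in txs for iv in t[4]])
        if exon_mode == "all":
            introns: list[tuple[int, int]] = []
            for t in txs:
                prev = None
                for s, e in sorted(t[4]):
                    if prev is not None and s > prev:
                        introns.append((prev, s))
                    prev = max(prev, e) if prev is not None else e
            exons = _subtract_intervals(exons, _merge_intervals(introns))
        genes.append(GeneModel(gene_id, chrom, strand, start, end, exons))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def read_refflat(path, exon_mode: Literal["any", "all"] = "any") -> list[GeneModel]:
    """Read UCSC refFlat (one transcript per line, 0-based half-open).

    ``exon_mode`` picks how isoform disagreement over exon/intron status is
    resolved; see :func:`_build_gene_models`.
    """
    transcripts: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            gene_id, chrom, strand = f[0], f[2], f[3]
            tx_start, tx_end = int(f[4]), int(f[5])
            starts = [int(x) for x in f[9].rstrip(",").split(",")]
            ends = [int(x) for x in f[10].rstrip(",").split(",")]
            exons = list(zip(starts, ends))
            transcripts.setdefault(gene_id, []).append(
                (chrom, strand, tx_start, tx_end, exons)
            )
    return _build_gene_models(transcripts, exon_mode=exon_mode)


def write_refflat(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as refFlat, one (merged) transcript per gene."""
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                f"{g.gene_id}\t{g.gene_id}.t1\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}"
                f"\t{g.start}\t{g.end}\t{len(g.exons)}\t{starts}\t{ends}\n"
            )


def read_gtf(path) -> list[GeneModel]:
    """Read GTF 2.2 exon features, reduced to per-gene models.

    Only ``exon`` features are used; genes are keyed by the ``gene_id``
    attribute.  GTF 1-based closed coordinates are converted to 0-based
    half-open.
    """
    import re

    gene_re = re.compile(r'gene_id "([^"]+)"')
    transcripts: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            m = gene_re.search(f[8])
            if not m:
                raise ValueError(f"GTF exon without gene_id attribute: {line!r}")
            gene_id = m.group(1)
            chrom, strand = f[0], f[6]
            start, end = int(f[3]) - 1, int(f[4])
            transcripts.setdefault(gene_id, []).append(
                (chrom, strand, start, end, [(start, end)])
            )
    merged: dict[str, list] = {}
    for gene_id, rows in transcripts.items():
        chrom, strand = rows[0][0], rows[0][1]
        start = min(r[2] for r in rows)
        end = max(r[3] for r in rows)
        exons = [iv for r in rows for iv in r[4]]
        merged[gene_id] = [(chrom, strand, start, end, exons)]
    return _build_gene_models(merged)


def read_annotation(path, exon_mode: Literal["any", "all"] = "any") -> list[GeneModel]:
    """Dispatch on extension: .gtf via the GTF reader, otherwise refFlat.

    The GTF reader does not group exons into transcripts, so ``exon_mode``
    applies to refFlat input only.
    """
    if str(path).lower().endswith((".gtf", ".gtf.txt")):
        return read_gtf(path)
    return read_refflat(path, exon_mode=exon_mode)
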