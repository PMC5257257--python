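"""Synthetic gene-trap screen generator.

Emulates the statistical structure of a haploid gene-trap screen so every
downstream stage is testable without external sequencing data:

* each haploid cell carries exactly one retroviral insertion, with a random
  orientation and a position drawn from a mixture of a genome-uniform
  component and a TSS-proximal component (retroviral integration favors
  transcription start sites);
* FACS selection keeps a cell with base probability ``gate_fraction``,
  multiplied by the gene's ``effect_strength`` when the insertion qualifies
  under the gene's effect class:

  - ``lof_positive_regulator``: any inactivating insertion qualifies
    (exonic in either orientation, or sense-intronic);
  - ``three_prime_sense_dominant``: only sense insertions in the 3'-terminal
    intron qualify — the pattern of genes whose trap alleles act through a
    truncated dominant product rather than a simple null;
  - ``orientation_independent_intronic``: sense or antisense intronic
    insertions qualify — a rare class where either orientation disrupts;
  - ``null``: base probability only.

The generator can also re-emit its insertion sites as per-read alignment
reports with injected ambiguous alignments and near-duplicate positions, to
exercise the mapping filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .annotation import GeneModel, write_refflat
from .mapping import AlignmentReport, InsertionSite, Placement, write_bed

EffectClass = Literal[
    "null",
    "lof_positive_regulator",
    "three_prime_sense_dominant",
    "orientation_independent_intronic",
]

EFFECT_CLASSES = (
    "null",
    "lof_positive_regulator",
    "three_prime_sense_dominant",
    "orientation_independent_intronic",
)


@dataclass(frozen=True)
class SimGene:
    """A simulated gene: coordinates plus its phenotypic effect class.

    ``effect_strength`` multiplies the FACS gate probability when a cell
    carries a qualifying insertion in this gene; it is exactly 1 iff the
    effect class is ``null``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    effect_class: EffectClass = "null"
    effect_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown effect class {self.effect_class!r}")
        if self.effect_strength < 0:
            raise ValueError(f"{self.gene_id}: negative effect_strength")
        if (self.effect_class == "null") != (self.effect_strength == 1.0):
            raise ValueError(
                f"{self.gene_id}: effect_strength must be 1 exactly when effect_class is null"
            )
        self.to_gene_model()  # interval invariants checked by GeneModel

    def to_gene_model(self) -> GeneModel:
        return GeneModel(self.gene_id, self.chrom, self.strand, self.start, self.end, self.exons)

    @property
    def last_intron(self) -> tuple[int, int] | None:
        """The 3'-terminal intron (None for intronless genes)."""
        introns = self.to_gene_model().introns
        if not introns:
            return None
        return introns[-1] if self.strand == "+" else introns[0]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated screen.

    Defaults reflect a scaled-down version of a typical screen: ~1e5
    mutagenized cells per population and a 10% FACS gate, with a moderate
    TSS integration bias (30% of integrations drawn from a 2 kb window
    downstream of a random gene's transcription start).
    """

    genome_length: int
    genes: list[SimGene]
    chrom: str = "chr1"
    n_cells_control: int = 100_000
    n_cells_sorted_pool: int = 100_000
    gate_fraction: float = 0.1
    tss_bias_weight: float = 0.3
    tss_window: int = 2000
    intergenic_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 < self.gate_fraction <= 1:
            raise ValueError("gate_fraction must lie in (0, 1]")
        if not 0 <= self.tss_bias_weight < 1:
            raise ValueError("tss_bias_weight must lie in [0, 1)")
        if self.intergenic_rate is not None and not 0 <= self.intergenic_rate <= 1:
            raise ValueError("intergenic_rate must lie in [0, 1]")
        if self.gate_fraction * self.n_cells_sorted_pool < 1:
            raise ValueError("expected sorted-set size below one cell")
        prev_end = 0
        for g in sorted(self.genes, key=lambda g: g.start):
            if g.chrom != self.chrom:
                raise ValueError(f"{g.gene_id}: chrom {g.chrom} != genome chrom {self.chrom}")
            if g.end > self.genome_length:
                raise ValueError(f"{g.gene_id}: span exceeds genome_length")
            if g.start < prev_end:
                raise ValueError(f"{g.gene_id}: overlapping gene spans are not supported")
            prev_end = g.end

    def gene_models(self) -> list[GeneModel]:
        return [g.to_gene_model() for g in self.genes]


# ---------------------------------------------------------------------------
# integration and sorting
# ---------------------------------------------------------------------------

def _integration_arrays(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n integration (position, strand) pairs from the mixture model."""
    L = config.genome_length
    positions = np.empty(n, dtype=np.int64)
    genes = sorted(config.genes, key=lambda g: g.start)
    from_tss = (
        rng.random(n) < config.tss_bias_weight
        if genes and config.tss_bias_weight > 0
        else np.zeros(n, dtype=bool)
    )

    n_uni = int((~from_tss).sum())
    if n_uni:
        if config.intergenic_rate is None or not genes:
            positions[~from_tss] = rng.integers(0, L, n_uni)
        else:
            positions[~from_tss] = _uniform_split(genes, L, config.intergenic_rate, n_uni, rng)

    n_tss = int(from_tss.sum())
    if n_tss:
        idx = rng.integers(0, len(genes), n_tss)
        starts = np.empty(n_tss, dtype=np.int64)
        ends = np.empty(n_tss, dtype=np.int64)
        for j, gi in enumerate(idx):
            g = genes[gi]
            w = min(config.tss_window, g.end - g.start)
            if g.strand == "+":
                starts[j], ends[j] = g.start, g.start + w
            else:
                starts[j], ends[j] = g.end - w, g.end
        positions[from_tss] = starts + rng.integers(0, ends - starts)

    strands = np.where(rng.integers(0, 2, n) == 0, "+", "-")
    return positions, strands


def _uniform_split(
    genes: Sequence[SimGene], L: int, intergenic_rate: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform positions, reweighted between intergenic and genic space."""
    genic = [(g.start, g.end) for g in genes]
    inter: list[tuple[int, int]] = []
    prev = 0
    for s, e in genic:
        if s > prev:
            inter.append((prev, s))
        prev = e
    if prev < L:
        inter.append((prev, L))

    def sample_from(intervals: list[tuple[int, int]], m: int) -> np.ndarray:
        lens = np.array([e - s for s, e in intervals], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(lens)])
        offs = rng.integers(0, cum[-1], m)
        iv = np.searchsorted(cum, offs, side="right") - 1
        return np.array([intervals[i][0] for i in iv]) + (offs - cum[iv])

    pick_inter = rng.random(n) < intergenic_rate
    out = np.empty(n, dtype=np.int64)
    if pick_inter.any():
        out[pick_inter] = sample_from(inter, int(pick_inter.sum()))
    if (~pick_inter).any():
        out[~pick_inter] = sample_from(genic, int((~pick_inter).sum()))
    return out


def simulate_integration(
    config: SimulationConfig, n: int, rng: np.random.Generator | None = None
) -> list[InsertionSite]:
    """Simulate n independent single-cell integrations (one site per cell)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n == 0:
        return []
    positions, strands = _integration_arrays(config, n, rng)
    return [
        InsertionSite(config.chrom, int(p), str(s)) for p, s in zip(positions, strands)
    ]


def _qualifies(
    config: SimulationConfig, positions: np.ndarray, strands: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (qualifies, strength) under each gene's effect class."""
    genes = sorted(config.genes, key=lambda g: g.start)
    qual = np.zeros(len(positions), dtype=bool)
    strength = np.ones(len(positions), dtype=float)
    if not genes:
        return qual, strength
    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    gi = np.searchsorted(starts, positions, side="right") - 1
    inside = (gi >= 0) & (positions < ends[np.maximum(gi, 0)])
    for i in np.nonzero(inside)[0]:
        g = genes[gi[i]]
        if g.effect_class == "null":
            continue
        pos, strand = int(positions[i]), str(strands[i])
        model = g.to_gene_model()
        exonic = model.is_exonic(pos)
        sense = strand == g.strand
        if g.effect_class == "lof_positive_regulator":
            ok = exonic or sense
        elif g.effect_class == "three_prime_sense_dominant":
            li = g.last_intron
            ok = sense and li is not None and li[0] <= pos < li[1]
        else:  # orientation_independent_intronic
            ok = not exonic
        if ok:
            qual[i] = True
            strength[i] = g.effect_strength
    return qual, strength


def simulate_sorting(
    config: SimulationConfig,
) -> tuple[list[InsertionSite], list[InsertionSite]]:
    """Simulate the (control, sorted) insertion datasets of one screen.

    The control set is the unselected mutagenized population; the sorted set
    is an independent pool passed through the FACS gate, where each cell is
    kept with probability ``gate_fraction`` times its insertion's effect
    multiplier (capped at 1).
    """
    rng = np.random.default_rng(config.seed)
    control = simulate_integration(config, config.n_cells_control, rng)
    pool_pos, pool_strand = _integration_arrays(config, config.n_cells_sorted_pool, rng)
    qual, strength = _qualifies(config, pool_pos, pool_strand)
    p_keep = np.minimum(1.0, config.gate_fraction * np.where(qual, strength, 1.0))
    keep = rng.random(len(pool_pos)) < p_keep
    sorted_sites = [
        InsertionSite(config.chrom, int(p), str(s))
        for p, s in zip(pool_pos[keep], pool_strand[keep])
    ]
    return control, sorted_sites


# ---------------------------------------------------------------------------
# alignment-report emission (post-alignment fixture generator)
# ---------------------------------------------------------------------------

def emit_alignment_reports(
    sites: Iterable[InsertionSite],
    multimap_rate: float = 0.0,
    near_dup_rate: float = 0.0,
    seed: int = 0,
    genome_length: int | None = None,
) -> list[AlignmentReport]:
    """Emit per-read alignment reports for a site list, with injected noise.

    Each site yields ``read_support`` reads.  With probability
    ``multimap_rate`` a read receives a decoy second placement (at 0, 1 or 2
    mismatches, far from the source), which the uniqueness filter must
    exclude; with probability ``near_dup_rate`` a read's position is offset
    by 1-2 bp, which the collapse rule must merge back.  At both rates 0,
    reads map back to their source sites exactly.
    """
    if not 0 <= multimap_rate < 1 or not 0 <= near_dup_rate < 1:
        raise ValueError("rates must lie in [0, 1)")
    sites = list(sites)
    rng = np.random.default_rng(seed)
    if genome_length is None:
        genome_length = (max((s.position for s in sites), default=0) + 1) * 2 + 10_000
    reports: list[AlignmentReport] = []
    i = 0
    for site in sites:
        for _ in range(site.read_support):
            pos = site.position
            if near_dup_rate and rng.random() < near_dup_rate:
                pos = max(0, pos + int(rng.choice([-2, -1, 1, 2])))
            placements = [Placement(site.chrom, pos, site.strand, 0)]
            if multimap_rate and rng.random() < multimap_rate:
                decoy = int(rng.integers(0, genome_length))
                while abs(decoy - pos) <= 2:
                    decoy = int(rng.integers(0, genome_length))
                placements.append(
                    Placement(
                        site.chrom,
                        decoy,
                        str(rng.choice(["+", "-"])),
                        int(rng.integers(0, 3)),
                    )
                )
            reports.append(AlignmentReport(f"r{i:07d}", placements))
            i += 1
    return reports


# ---------------------------------------------------------------------------
# genome construction and study-scale configuration
# ---------------------------------------------------------------------------

def random_genome(
    n_genes: int = 200,
    seed: int = 0,
    effects: Mapping[int, tuple[EffectClass, float]] | None = None,
    gene_length_range: tuple[int, int] = (10_000, 40_000),
    intergenic_gap_range: tuple[int, int] = (20_000, 80_000),
    n_exons_range: tuple[int, int] = (4, 10),
    exon_length_range: tuple[int, int] = (100, 300),
) -> tuple[list[SimGene], int]:
    """Build a non-overlapping random gene layout on one chromosome.

    ``effects`` maps gene indexes to (effect_class, effect_strength); all
    other genes are phenotypically null.  Returns (genes, genome_length).
    Gene and exon dimensions default to compact-gene scales so that a
    simulated population reaches insertion densities of tens to a couple of
    hundred unique insertions per gene, as a saturating screen does.
    """
    rng = np.random.default_rng(seed)
    effects = dict(effects or {})
    genes: list[SimGene] = []
    cursor = 0
    for i in range(n_genes):
        cursor += int(rng.integers(*intergenic_gap_range))
        length = int(rng.integers(*gene_length_range))
        n_ex = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        ex_lens = rng.integers(*exon_length_range, size=n_ex)
        intron_total = length - int(ex_lens.sum())
        if intron_total < n_ex - 1:  # tiny gene: stretch to fit its exons
            length = int(ex_lens.sum()) + (n_ex - 1) * 200
            intron_total = length - int(ex_lens.sum())
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        eff_class, eff_strength = effects.get(i, ("null", 1.0))
        n_gaps = n_ex - 1
        if n_gaps:
            gaps = rng.multinomial(intron_total - n_gaps, [1.0 / n_gaps] * n_gaps) + 1
            if eff_class == "three_prime_sense_dominant":
                # genes of this class act through trap insertions in a large
                # 3'-terminal intron; reshape so it covers ~60% of the introns
                target = n_gaps - 1 if strand == "+" else 0
                want = int(0.6 * intron_total)
                surplus = want - int(gaps[target])
                if surplus > 0:
                    others = [j for j in range(n_gaps) if j != target]
                    take = np.minimum(
                        gaps[others] - 1,
                        np.ceil(surplus * gaps[others] / max(1, gaps[others].sum())).astype(int),
                    )
                    gaps[others] -= take
                    gaps[target] += int(take.sum())
        else:
            gaps = np.array([], dtype=int)
        exons = []
        pos = cursor
        for j in range(n_ex):
            exons.append((pos, pos + int(ex_lens[j])))
            pos += int(ex_lens[j])
            if j < n_gaps:
                pos += int(gaps[j])
        end = pos  # exon/intron alternation ends in the 3'-terminal exon
        genes.append(
            SimGene(
                gene_id=f"GENE{i:04d}",
                chrom="chr1",
                strand=strand,
                start=cursor,
                end=end,
                exons=tuple(exons),
                effect_class=eff_class,
                effect_strength=eff_strength,
            )
        )
        cursor = end
    genome_length = cursor + int(rng.integers(*intergenic_gap_range))
    return genes, genome_length


def make_screen_config(
    seed: int = 0,
    n_genes: int = 200,
    effects: Mapping[int, tuple[EffectClass, float]] | None = None,
    **overrides,
) -> SimulationConfig:
    """Study-scale screen configuration over a fresh random genome.

    The genome layout is seeded from ``seed`` and the screen draws use the
    same seed, so a configuration is fully reproducible from one integer.
    """
    genes, genome_length = random_genome(n_genes=n_genes, seed=seed, effects=effects)
    return SimulationConfig(
        genome_length=genome_length, genes=genes, seed=seed, **overrides
    )


# ---------------------------------------------------------------------------
# config and dataset I/O
# ---------------------------------------------------------------------------

def write_datasets(
    config: SimulationConfig, outdir, prefix: str = "screen"
) -> dict[str, str]:
    """Simulate one screen and write BED6 site files plus a refFlat annotation."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    control, sorted_ = simulate_sorting(config)
    paths = {
        "control": str(outdir / f"{prefix}.control.bed"),
        "sorted": str(outdir / f"{prefix}.sorted.bed"),
        "annotation": str(outdir / f"{prefix}.refflat.txt"),
    }
    from .mapping import dedupe_sites

    write_bed(dedupe_sites(control), paths["control"])
    write_bed(dedupe_sites(sorted_), paths["sorted"])
    write_refflat(config.gene_models(), paths["annotation"])
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "genome_length": config.genome_length,
        "chrom": config.chrom,
        "n_cells_control": config.n_cells_control,
        "n_cells_sorted_pool": config.n_cells_sorted_pool,
        "gate_fraction": config.gate_fraction,
        "tss_bias_weight": config.tss_bias_weight,
        "tss_window": config.tss_window,
        "intergenic_rate": config.intergenic_rate,
        "seed": config.seed,
        "genes": [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
                "exons": [list(e) for e in g.exons],
                "effect_class": g.effect_class,
                "effect_strength": g.effect_strength,
            }
            for g in config.genes
        ],
    }


def config_from_dict(d: dict) -> SimulationConfig:
    genes = [
        SimGene(
            gene_id=g["gene_id"],
            chrom=g.get("chrom", d.get("chrom", "chr1")),
            strand=g["strand"],
            start=g["start"],
            end=g["end"],
            exons=tuple(tuple(e) for e in g["exons"]),
            effect_class=g.get("effect_class", "null"),
            effect_strength=g.get("effect_strength", 1.0),
        )
        for g in d["genes"]
    ]
    return SimulationConfig(
        genome_length=d["genome_length"],
        genes=genes,
        chrom=d.get("chrom", "chr1"),
        n_cells_control=d.get("n_cells_control", 100_000),
        n_cells_sorted_pool=d.get("n_cells_sorted_pool", 100_000),
        gate_fraction=d.get("gate_fraction", 0.1),
        tss_bias_weight=d.get("tss_bias_weight", 0.3),
        tss_window=d.get("tss_window", 2000),
        intergenic_rate=d.get("intergenic_rate"),
        seed=d.get("seed", 0),
    )


def load_sim_config(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_sim_config(config: SimulationConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
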