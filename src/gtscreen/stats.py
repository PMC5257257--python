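"""Per-gene enrichment statistics for a sorted-vs-control screen.

For each gene the screen asks whether inactivating insertions are
over-represented among the sorted (phenotype-selected) cells relative to how
often the gene carries any insertion in the unselected control population.
The test is the one-sided Fisher exact test on the 2x2 table

    [[k, N - k],
     [m, M - m]]

with k = inactivating insertions in the gene (sorted dataset), N = total
inactivating insertions over all genes (sorted), m = any-orientation
insertions in the gene (control), M = total insertions over all genes
(control); the alternative is a greater gene frequency in the sorted set.
p-values are corrected across the tested genes by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import GeneIndex, GeneModel, tally_gene_insertions
from .mapping import InsertionSite


@dataclass(frozen=True)
class GeneCounts:
    """The 2x2 table margins plus intronic orientation counts for one gene."""

    gene_id: str
    k_sorted_inactivating: int
    N_sorted_total: int
    m_control_any: int
    M_control_total: int
    S_raw: int = 0  # sense-intronic insertions, sorted dataset
    A_raw: int = 0  # antisense-intronic insertions, sorted dataset

    def __post_init__(self) -> None:
        k, N = self.k_sorted_inactivating, self.N_sorted_total
        m, M = self.m_control_any, self.M_control_total
        if min(k, N, m, M, self.S_raw, self.A_raw) < 0:
            raise ValueError(f"{self.gene_id}: negative count")
        if k > N or m > M:
            raise ValueError(f"{self.gene_id}: gene count exceeds dataset total")


def fisher_enrichment(counts: GeneCounts) -> float:
    """One-sided Fisher exact p-value for enrichment in the sorted dataset.

    Exact hypergeometric upper tail P(X >= k) conditional on the table
    margins, with no continuity correction and no pseudocounts.
    """
    k = counts.k_sorted_inactivating
    N = counts.N_sorted_total
    m = counts.m_control_any
    M = counts.M_control_total
    if N < 1 or M < 1:
        raise ValueError("dataset totals must be >= 1")
    # drawing N items from a pool of N+M of which k+m belong to the gene
    return float(min(1.0, hypergeom.sf(k - 1, N + M, k + m, N)))


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentResult:
    gene_id: str
    p_value: float
    fdr_q: float
    counts: GeneCounts
    is_hit: bool


@dataclass
class ScreenResult:
    """Ranked per-gene enrichment results for one screen."""

    screen_id: str
    results: list[EnrichmentResult]
    hit_q: float = 0.01

    def __post_init__(self) -> None:
        self._by_gene = {r.gene_id: r for r in self.results}

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, gene_id: str) -> EnrichmentResult:
        return self._by_gene[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_gene

    @property
    def hits(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.is_hit]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": r.gene_id,
                "k_sorted_inactivating": r.counts.k_sorted_inactivating,
                "N_sorted_total": r.counts.N_sorted_total,
                "m_control_any": r.counts.m_control_any,
                "M_control_total": r.counts.M_control_total,
                "sense_intronic": r.counts.S_raw,
                "antisense_intronic": r.counts.A_raw,
                "p_value": r.p_value,
                "fdr_q": r.fdr_q,
                "hit": r.is_hit,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def circle_plot_table(self) -> pd.DataFrame:
        """Per-gene (-log10 q, unique inactivating count) display pairs.

        The significance axis of the screen summary plots is -log10 of the
        FDR-corrected p-value and the circle diameter is proportional to the
        number of unique inactivating insertions in the sorted cells.
        """
        with np.errstate(divide="ignore"):
            return pd.DataFrame(
                {
                    "gene_id": [r.gene_id for r in self.results],
                    "neglog10_q": [
                        float(-np.log10(r.fdr_q)) if r.fdr_q > 0 else np.inf
                        for r in self.results
                    ],
                    "n_inactivating": [
                        r.counts.k_sorted_inactivating for r in self.results
                    ],
                }
            )


def build_gene_counts(
    sorted_sites: Iterable[InsertionSite],
    control_sites: Iterable[InsertionSite],
    genes: Sequence[GeneModel] | GeneIndex,
) -> list[GeneCounts]:
    """Assemble per-gene 2x2 margins from the two deduplicated site lists.

    Only genes with at least one insertion in either dataset are returned:
    genes never hit in either population carry no information and would only
    inflate the multiple-testing family.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    sorted_tallies = tally_gene_insertions(sorted_sites, index)
    control_tallies = tally_gene_insertions(control_sites, index)
    N = sum(t.inactivating for t in sorted_tallies.values())
    M = sum(t.any_orientation for t in control_tallies.values())
    out: list[GeneCounts] = []
    for gene_id in sorted(sorted_tallies):
        st = sorted_tallies[gene_id]
        ct = control_tallies[gene_id]
        if st.any_orientation == 0 and ct.any_orientation == 0:
            continue
        out.append(
            GeneCounts(
                gene_id=gene_id,
                k_sorted_inactivating=st.inactivating,
                N_sorted_total=N,
                m_control_any=ct.any_orientation,
                M_control_total=M,
                S_raw=st.sense_intronic,
                A_raw=st.antisense_intronic,
            )
        )
    return out


def analyze_screen(
    sorted_sites: Iterable[InsertionSite],
    control_sites: Iterable[InsertionSite],
    genes: Sequence[GeneModel] | GeneIndex,
    screen_id: str = "screen",
    hit_q: float = 0.01,
) -> ScreenResult:
    """Full per-gene enrichment analysis of one screen.

    Tests every gene with >= 1 insertion in either dataset, corrects across
    exactly that set, flags hits at q < ``hit_q`` and returns results sorted
    by (q, p, gene_id).
    """
    counts = build_gene_counts(list(sorted_sites), list(control_sites), genes)
    if not counts:
        raise ValueError("no gene has any insertion in either dataset")
    if counts[0].N_sorted_total == 0:
        raise ValueError("sorted dataset contains no inactivating insertions")
    p = [fisher_enrichment(c) for c in counts]
    q = fdr_correct(p)
    results = [
        EnrichmentResult(c.gene_id, pv, qv, c, bool(qv < hit_q))
        for c, pv, qv in zip(counts, p, q)
    ]
    results.sort(key=lambda r: (r.fdr_q, r.p_value, r.gene_id))
    return ScreenResult(screen_id, results, hit_q=hit_q)
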