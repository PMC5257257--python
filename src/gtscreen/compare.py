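"""Cross-screen comparison via the intronic orientation-bias (IGTIOB) score.

FDR-corrected enrichment p-values depend on experimental variables of both
datasets of a screen and compare poorly across screens.  The IGTIOB score
depends only on the sorted dataset: because the gene-trap splice acceptor is
directional, a gene whose disruption drives the sorted phenotype should
accumulate intronic insertions predominantly in the sense orientation.  With
S = 1 + sense-intronic count and A = 1 + antisense-intronic count,

    IGTIOB = log2(S / A) * ln(S * A)

so the first factor captures the orientation bias and the second grows with
the overall weight of intronic evidence.  Genes enter the cross-screen
matrix when at least one screen calls them at a stringent q < 1e-4; gene
rows are ordered by agglomerative complete-linkage clustering under the
city-block (L1) distance without row normalization, and negative scores are
clipped to 0 for display only, after clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .stats import ScreenResult


def igtiob(s_raw: int, a_raw: int) -> float:
    """Intronic gene-trap insertion orientation-bias score.

    ``s_raw`` and ``a_raw`` are the numbers of unique sense and antisense
    intronic insertions of a gene in the sorted dataset; one is added to
    each before the log terms, so (0, 0) scores exactly 0.
    """
    if s_raw < 0 or a_raw < 0:
        raise ValueError("insertion counts must be non-negative")
    s = 1 + s_raw
    a = 1 + a_raw
    return math.log2(s / a) * math.log(s * a)


def median_sem(values: Sequence[float]) -> tuple[float, float]:
    """Sample median and its standard error, SEM = 1.253 * sigma / sqrt(n).

    The 1.253 factor is the large-sample ratio between the standard errors
    of the median and of the mean under normality (sqrt(pi/2)); sigma is the
    sample standard deviation (n-1 denominator).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("median_sem requires at least two values")
    return float(np.median(x)), float(1.253 * np.std(x, ddof=1) / math.sqrt(x.size))


def _complete_linkage_merges(
    rows: np.ndarray,
) -> tuple[list[int], list[tuple[float, frozenset[int], frozenset[int]]]]:
    """Agglomerative complete-linkage clustering under city-block distance.

    Returns the dendrogram leaf order and the merge trace, each merge
    recorded as (linkage distance, members of the first child, members of
    the second child).  Ties in merge distance are broken by the lowest
    original row index of the candidate pair, and at each merge the child
    cluster containing the lower original index comes first in the leaf
    order, so the result is fully deterministic.
    """
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if n <= 1:
        return list(range(n)), []
    dist = np.abs(rows[:, None, :] - rows[None, :, :]).sum(axis=2)

    # each active cluster: (min original index, leaf order list)
    clusters: dict[int, tuple[int, list[int]]] = {i: (i, [i]) for i in range(n)}
    cdist = {
        (i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[float, frozenset[int], frozenset[int]]] = []
    while len(clusters) > 1:
        best = min(
            cdist.items(),
            key=lambda kv: (kv[1], clusters[kv[0][0]][0], clusters[kv[0][1]][0]),
        )
        (i, j), d = best
        first, second = (i, j) if clusters[i][0] <= clusters[j][0] else (j, i)
        merges.append(
            (float(d), frozenset(clusters[first][1]), frozenset(clusters[second][1]))
        )
        merged = (clusters[first][0], clusters[first][1] + clusters[second][1])
        for k in list(clusters):
            if k in (i, j):
                continue
            a = cdist.pop((min(i, k), max(i, k)))
            b = cdist.pop((min(j, k), max(j, k)))
            cdist[(min(i, k), max(i, k))] = max(a, b)
        del cdist[(i, j)]
        del clusters[j]
        clusters[i] = merged
    return next(iter(clusters.values()))[1], merges


def complete_linkage_order(
    rows: np.ndarray, metric: Literal["cityblock"] = "cityblock"
) -> list[int]:
    """Leaf order from complete-linkage clustering of rows (L1 distance)."""
    return _complete_linkage_merges(rows)[0]


@dataclass
class ComparisonMatrix:
    """Gene x screen IGTIOB matrix with a clustering-derived gene order.

    ``scores`` holds signed scores in the original (unclustered) gene order;
    ``included_by`` records, per gene, a screen in which it passed the
    inclusion threshold; ``gene_order`` is the dendrogram leaf order.
    """

    gene_ids: list[str]
    screen_ids: list[str]
    scores: np.ndarray
    included_by: dict[str, str]
    gene_order: list[int]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gene_ids), len(self.screen_ids)):
            raise ValueError("score matrix shape inconsistent with id lists")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def ordered(self) -> pd.DataFrame:
        """Signed scores as a DataFrame in clustered gene order."""
        idx = [self.gene_ids[i] for i in self.gene_order]
        return pd.DataFrame(
            self.scores[self.gene_order], index=idx, columns=self.screen_ids
        ).rename_axis("gene_id")

    def write_tsv(self, path, display: bool = False) -> None:
        df = self.ordered()
        if display:
            df = df.clip(lower=0.0)
        df.to_csv(path, sep="\t", float_format="%.6g")


def build_comparison_matrix(
    screens: Sequence[ScreenResult],
    threshold: float = 1e-4,
    distance_on: Literal["signed", "absolute"] = "signed",
) -> ComparisonMatrix:
    """Assemble and cluster the cross-screen IGTIOB matrix.

    A gene is included iff its FDR-corrected q-value is below ``threshold``
    in at least one screen; its score is then reported for every screen.  A
    gene with no insertions in some screen has S_raw = A_raw = 0 there, and
    the score formula itself yields 0.  Clustering runs on signed scores by
    default (``distance_on="absolute"`` clusters |score| instead; display
    clipping never feeds the clustering either way).
    """
    if len(screens) < 2:
        raise ValueError("cross-screen comparison needs at least two screens")
    ids = [s.screen_id for s in screens]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate screen_id")

    included: list[str] = []
    included_by: dict[str, str] = {}
    seen: set[str] = set()
    for screen in screens:
        for r in screen.results:
            if r.fdr_q < threshold and r.gene_id not in seen:
                seen.add(r.gene_id)
                included.append(r.gene_id)
                included_by[r.gene_id] = screen.screen_id
    included.sort()

    scores = np.zeros((len(included), len(screens)))
    for j, screen in enumerate(screens):
        for i, gene_id in enumerate(included):
            if gene_id in screen:
                c = screen[gene_id].counts
                scores[i, j] = igtiob(c.S_raw, c.A_raw)
    if len(included) >= 2:
        basis = np.abs(scores) if distance_on == "absolute" else scores
        order = complete_linkage_order(basis)
    else:
        order = list(range(len(included)))
    return ComparisonMatrix(included, ids, scores, included_by, order)


def cluster_genes(matrix: ComparisonMatrix | np.ndarray,
                  distance_on: Literal["signed", "absolute"] = "signed") -> list[int]:
    """Recompute the complete-linkage leaf order for a matrix's gene rows."""
    rows = matrix.scores if isinstance(matrix, ComparisonMatrix) else np.asarray(matrix)
    basis = np.abs(rows) if distance_on == "absolute" else rows
    return complete_linkage_order(basis)


def clip_for_display(matrix: ComparisonMatrix | np.ndarray) -> np.ndarray:
    """Elementwise max(score, 0): negative scores are displayed as 0.

    Clipping is display-only; the clustering order is computed on unclipped
    scores and is unchanged by this operation.
    """
    scores = matrix.scores if isinstance(matrix, ComparisonMatrix) else np.asarray(matrix)
    return np.maximum(scores, 0.0)
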