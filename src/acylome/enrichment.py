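"""Hypergeometric over-representation analysis with BH FDR.

The query is a set of protein/gene identifiers (e.g. proteins carrying
dysregulated PTM sites); the background defaults to all proteins
quantified in the experiment. A gene set passes when its FDR and raw
p-value clear the reporting cutoffs (1% by default) and at least
``min_pathway_genes`` of its members overlap the query.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .records import Thresholds

__all__ = [
    "hypergeom_p",
    "bh_fdr",
    "EnrichmentResult",
    "OverRepresentationAnalyzer",
    "enrich",
    "results_to_frame",
    "dotplot_export",
]

logger = logging.getLogger(__name__)


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Exact hypergeometric upper tail P(X >= k).

    ``k`` = overlap, ``K`` = annotated set size, ``n`` = query size,
    ``N`` = background size.
    """
    if not (0 <= k and k <= K and k <= n and K <= N and n <= N):
        raise ValueError(
            f"inconsistent counts: need 0 <= k <= min(K, n) <= N, got "
            f"k={k}, K={K}, n={n}, N={N}"
        )
    # sf(k-1) = P(X >= k)
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    """Over-representation outcome for one gene set."""

    set_name: str
    k: int  # overlap with the query
    K: int  # set members present in the background
    n: int  # query size
    N: int  # background size
    p_value: float
    fdr: float
    passes: bool
    overlap_genes: tuple[str, ...] = ()


class OverRepresentationAnalyzer(BaseEstimator):
    """Hypergeometric ORA against a gene-set collection (sklearn style).

    Parameters
    ----------
    gene_sets : mapping set name -> set of gene identifiers.
    background : iterable of gene ids, or None
        The statistical universe. None means it must be supplied to
        :meth:`fit`. Set sizes (K) are counted within the background.
    fdr_threshold, p_threshold : float, default 0.01
        Reporting cutoffs.
    min_overlap : int, default 5
        Minimum number of query genes found in a set for it to pass.

    Attributes
    ----------
    results_ : list of EnrichmentResult, sorted by (fdr, p, name).
    dropped_ : sorted list of query ids absent from the background.
    """

    def __init__(
        self,
        gene_sets: Mapping[str, set] | None = None,
        background: Iterable[str] | None = None,
        fdr_threshold: float = 0.01,
        p_threshold: float = 0.01,
        min_overlap: int = 5,
    ):
        self.gene_sets = gene_sets
        self.background = background
        self.fdr_threshold = fdr_threshold
        self.p_threshold = p_threshold
        self.min_overlap = min_overlap

    def fit(
        self, X: Iterable[str], background: Iterable[str] | None = None
    ) -> "OverRepresentationAnalyzer":
        if not self.gene_sets:
            raise ValueError("gene_sets must be a non-empty mapping")
        bg_src = background if background is not None else self.background
        if bg_src is None:
            raise ValueError("a background universe is required")
        bg = set(bg_src)
        query = set(X)
        if not query or not bg:
            raise ValueError("query and background must be non-empty")
        dropped = query - bg
        if dropped:
            logger.warning(
                "%d query id(s) absent from the background were dropped: %s",
                len(dropped), sorted(dropped)[:10],
            )
        query &= bg
        if not query:
            raise ValueError("no query ids remain inside the background")

        N, n = len(bg), len(query)
        rows = []
        for name in sorted(self.gene_sets):
            members = set(self.gene_sets[name]) & bg
            if not members:
                continue
            overlap = sorted(query & members)
            rows.append((name, overlap, len(members)))
        ps = [hypergeom_p(len(ov), K, n, N) for _, ov, K in rows]
        qs = bh_fdr(ps)
        results = [
            EnrichmentResult(
                set_name=name,
                k=len(ov),
                K=K,
                n=n,
                N=N,
                p_value=p,
                fdr=float(q),
                passes=(
                    float(q) <= self.fdr_threshold
                    and p <= self.p_threshold
                    and len(ov) >= self.min_overlap
                ),
                overlap_genes=tuple(ov),
            )
            for (name, ov, K), p, q in zip(rows, ps, qs)
        ]
        results.sort(key=lambda r: (r.fdr, r.p_value, r.set_name))
        self.results_ = results
        self.dropped_ = sorted(dropped)
        return self


def enrich(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, set],
    background: Iterable[str],
    thresholds: Thresholds | None = None,
) -> list[EnrichmentResult]:
    """Over-representation of ``query_genes`` in each gene set."""
    thresholds = thresholds or Thresholds()
    analyzer = OverRepresentationAnalyzer(
        gene_sets=gene_sets,
        fdr_threshold=thresholds.enrich_fdr,
        p_threshold=thresholds.enrich_p,
        min_overlap=thresholds.min_pathway_genes,
    ).fit(query_genes, background=background)
    return analyzer.results_


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p_value,
                "fdr": r.fdr,
                "passes": r.passes,
                "overlap_genes": ";".join(r.overlap_genes),
            }
            for r in results
        ]
    )


def dotplot_export(
    results_by_comparison: Mapping[tuple[str, str, str], Sequence[EnrichmentResult]],
    figure_path: str | Path | None = None,
    passing_only: bool = True,
):
    """Long-format dot-plot table (and optional figure) of enrichments.

    ``results_by_comparison`` maps ``(comparison, ptm, direction)`` to
    that comparison's enrichment results. The table has one row per
    (comparison, pathway): overlap count ``k`` sizes the dot, FDR sets
    its color. Returns ``(table, figure_or_None)``.
    """
    rows = []
    for (comparison, ptm, direction), results in results_by_comparison.items():
        for r in results:
            if passing_only and not r.passes:
                continue
            rows.append(
                {
                    "comparison": comparison,
                    "ptm": ptm,
                    "direction": direction,
                    "pathway": r.set_name,
                    "k": r.k,
                    "fdr": r.fdr,
                }
            )
    table = pd.DataFrame(
        rows, columns=["comparison", "ptm", "direction", "pathway", "k", "fdr"]
    )
    if table.empty:
        warnings.warn("no enrichment results to plot")
        return table, None

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [
        f"{c}/{p}/{d}"
        for c, p, d in zip(table["comparison"], table["ptm"], table["direction"])
    ]
    xcats = sorted(set(labels))
    ycats = sorted(set(table["pathway"]))
    x = [xcats.index(l) for l in labels]
    y = [ycats.index(p) for p in table["pathway"]]
    fig, ax = plt.subplots(
        figsize=(2 + 0.9 * len(xcats), 1.5 + 0.35 * len(ycats))
    )
    sc = ax.scatter(x, y, s=25.0 * table["k"], c=table["fdr"], cmap="viridis_r")
    ax.set_xticks(range(len(xcats)), xcats, rotation=45, ha="right")
    ax.set_yticks(range(len(ycats)), ycats)
    ax.set_xlim(-0.5, len(xcats) - 0.5)
    fig.colorbar(sc, ax=ax, label="FDR")
    fig.tight_layout()
    if figure_path is not None:
        fig.savefig(figure_path)
        plt.close(fig)
    return table, fig
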