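"""Per-modified-peptide one-way ANOVA, dysregulation calls and summaries.

A modified peptide whose abundance differs between groups at ANOVA
p <= 0.05 is called differentially expressed; the raw p-value is
thresholded (no multiple-testing correction), mirroring how search-engine
ANOVA output is conventionally filtered, with BH q-values reported
alongside for reference. The test runs on log2(abundance + 1) by default.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .records import PeptideMeasurement, StudyDesign, Thresholds

__all__ = [
    "anova_oneway",
    "DifferentialResult",
    "OneWayAnovaTester",
    "call_differential",
    "classify_protein_direction",
    "FrequencySummary",
    "frequency_summary",
    "results_to_frame",
]

logger = logging.getLogger(__name__)


def anova_oneway(
    values_by_group: Mapping[str, Sequence[float]],
    on_log: bool = False,
) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Returns ``(F, p)`` with p from the F(k-1, n-k) survival function.
    With ``on_log`` the test runs on log2 of the values (all must be
    positive). Degenerate cases: zero within-group variance with unequal
    means gives ``(inf, 0.0)`` with a warning; identical constant groups
    give ``(0.0, 1.0)``.
    """
    if len(values_by_group) < 2:
        raise ValueError("ANOVA needs at least two groups")
    groups = []
    for g, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {g!r} has {arr.size} value(s); need >= 2")
        if on_log:
            if np.any(arr <= 0):
                raise ValueError(f"log scale requires positive values (group {g!r})")
            arr = np.log2(arr)
        groups.append(arr)

    n = sum(a.size for a in groups)
    k = len(groups)
    grand = sum(a.sum() for a in groups) / n
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in groups)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance with unequal means; p set to 0")
        return math.inf, 0.0
    F = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(scipy.stats.f.sf(F, k - 1, n - k))
    return float(F), p


@dataclass
class DifferentialResult:
    """ANOVA outcome for one modified peptide."""

    feature_id: int
    accession: str
    peptide_sequence: str
    ptms: tuple[str, ...]
    group_means: dict[str, float]  # linear-scale group means
    F: float
    p_value: float
    direction: str  # "up"/"down" vs. the reference group
    significant: bool
    q_value: float = math.nan


class OneWayAnovaTester(BaseEstimator):
    """Per-modified-peptide one-way ANOVA across design groups.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance cutoff on the raw ANOVA p-value.
    on_log : bool, default True
        Test log2(abundance + 1) instead of raw abundances.
    reference_group : str or None
        Group whose mean anchors the up/down direction; defaults to the
        vehicle1 role if declared, else the design's first group.
    groups : sequence of str or None
        Restrict the test to these groups (default: all design groups).

    Attributes
    ----------
    results_ : list of DifferentialResult (q-values BH-filled).
    n_skipped_ : int, features skipped (all-zero or under-replicated).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        on_log: bool = True,
        reference_group: str | None = None,
        groups: Sequence[str] | None = None,
    ):
        self.alpha = alpha
        self.on_log = on_log
        self.reference_group = reference_group
        self.groups = groups

    def fit(
        self, X: Sequence[PeptideMeasurement], design: StudyDesign
    ) -> "OneWayAnovaTester":
        group_ids = list(self.groups) if self.groups is not None else design.groups
        reference = self.reference_group
        if reference is None:
            reference = design.roles.get("vehicle1", group_ids[0])
        if reference not in group_ids:
            raise ValueError(f"reference group {reference!r} not among {group_ids}")
        by_group = design.samples_by_group

        results: list[DifferentialResult] = []
        n_skipped = 0
        for i, p in enumerate(X):
            if not p.is_acyl_modified:
                continue
            values = {g: [p.abundances.get(s, 0.0) for s in by_group[g]]
                      for g in group_ids}
            if all(v == 0.0 for vals in values.values() for v in vals):
                logger.warning("feature %d: all-zero abundances, skipped", i)
                n_skipped += 1
                continue
            if any(len(v) < 2 for v in values.values()):
                logger.warning("feature %d: group with < 2 samples, skipped", i)
                n_skipped += 1
                continue
            if self.on_log:
                test_values = {g: [v + 1.0 for v in vals] for g, vals in values.items()}
            else:
                test_values = values
            F, pval = anova_oneway(test_values, on_log=self.on_log)
            means = {g: float(np.mean(vals)) for g, vals in values.items()}
            non_ref = [m for g, m in means.items() if g != reference]
            direction = "up" if float(np.mean(non_ref)) >= means[reference] else "down"
            results.append(
                DifferentialResult(
                    feature_id=i,
                    accession=p.protein_accession,
                    peptide_sequence=p.peptide_sequence,
                    ptms=tuple(sorted({n for n, _ in p.acyl_modifications})),
                    group_means=means,
                    F=F,
                    p_value=pval,
                    direction=direction,
                    significant=pval <= self.alpha,
                )
            )
        if results:
            qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
            for r, q in zip(results, qs):
                r.q_value = float(q)
        self.results_ = results
        self.n_skipped_ = n_skipped
        self.reference_group_ = reference
        return self


def call_differential(
    peptides: Sequence[PeptideMeasurement],
    design: StudyDesign,
    thresholds: Thresholds | None = None,
    reference_group: str | None = None,
    on_log: bool = True,
    groups: Sequence[str] | None = None,
) -> list[DifferentialResult]:
    """One-way ANOVA per modified peptide; see :class:`OneWayAnovaTester`."""
    thresholds = thresholds or Thresholds()
    tester = OneWayAnovaTester(
        alpha=thresholds.anova_alpha,
        on_log=on_log,
        reference_group=reference_group,
        groups=groups,
    ).fit(peptides, design)
    return tester.results_


def classify_protein_direction(
    results: Iterable[DifferentialResult],
) -> dict[str, str]:
    """Per-protein direction over its *significant* modified peptides.

    "Up" if every significant site is up, "Down" if every one is down,
    "Both" if a protein has sites moving in both directions.
    """
    directions: dict[str, set[str]] = {}
    for r in results:
        if not r.significant:
            continue
        directions.setdefault(r.accession, set()).add(r.direction)
    out = {}
    for acc, dirs in directions.items():
        out[acc] = "Both" if len(dirs) > 1 else ("Up" if "up" in dirs else "Down")
    return out


@dataclass
class FrequencySummary:
    """Identification/dysregulation frequency statistics.

    Percentages are on the 0–100 scale; ``per_ptm`` holds the same
    counters restricted to each PTM type.
    """

    n_quantified_peptides: int
    n_modified_peptides: int
    n_dysregulated_modified: int
    pct_modified: float
    pct_dysregulated_of_modified: float
    protein_directions: dict[str, str] = field(default_factory=dict)
    per_ptm: dict[str, dict[str, float]] = field(default_factory=dict)


def _pct(num: int, den: int) -> float:
    if den == 0:
        warnings.warn("zero denominator in frequency summary; percentage set to 0")
        return 0.0
    return 100.0 * num / den


def frequency_summary(
    peptides: Sequence[PeptideMeasurement],
    results: Sequence[DifferentialResult],
) -> FrequencySummary:
    """Counts and percentages of modified / dysregulated peptides."""
    n_total = len(peptides)
    modified = [p for p in peptides if p.is_acyl_modified]
    sig = [r for r in results if r.significant]

    per_ptm: dict[str, dict[str, float]] = {}
    for ptm in ("succinyl", "malonyl"):
        n_mod = sum(1 for p in modified
                    if ptm in {n for n, _ in p.acyl_modifications})
        n_dys = sum(1 for r in sig if ptm in r.ptms)
        per_ptm[ptm] = {
            "n_modified": n_mod,
            "n_dysregulated": n_dys,
            "pct_modified": _pct(n_mod, n_total),
            "pct_dysregulated_of_modified": _pct(n_dys, n_mod),
        }

    return FrequencySummary(
        n_quantified_peptides=n_total,
        n_modified_peptides=len(modified),
        n_dysregulated_modified=len(sig),
        pct_modified=_pct(len(modified), n_total),
        pct_dysregulated_of_modified=_pct(len(sig), len(modified)),
        protein_directions=classify_protein_direction(results),
        per_ptm=per_ptm,
    )


def results_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Differential results as a flat table for TSV export."""
    rows = [
        {
            "feature_id": r.feature_id,
            "accession": r.accession,
            "peptide": r.peptide_sequence,
            "ptm": ";".join(r.ptms),
            "F": r.F,
            "p": r.p_value,
            "q": r.q_value,
            "direction": r.direction,
            "significant": r.significant,
            **{f"mean_{g}": m for g, m in r.group_means.items()},
        }
        for r in results
    ]
    return pd.DataFrame(rows)
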