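"""Per-sample normalization and Hi-N (top-N peptide) protein quantitation.

Hi-N estimates a protein's relative abundance per sample as the mean of
its N most intense peptides (N = 3 by default), with the peptide set
fixed across samples by ranking on the mean abundance over all samples.
Acyl-modified peptides are excluded from protein quantitation by default
because their intensity tracks site stoichiometry rather than protein
amount.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import PeptideMeasurement, StudyDesign

__all__ = [
    "peptides_to_frame",
    "peptide_matrix",
    "normalize_total",
    "TotalIntensityNormalizer",
    "hi_n_protein_quant",
    "HiNQuantifier",
]


def peptides_to_frame(
    peptides: Sequence[PeptideMeasurement],
    design: StudyDesign | None = None,
) -> pd.DataFrame:
    """Peptides as a DataFrame: metadata columns followed by sample columns.

    The index is the peptide row number; ``modified`` flags acyl-modified
    peptides.
    """
    sample_ids = (
        list(design.sample_ids)
        if design is not None
        else (list(peptides[0].abundances) if peptides else [])
    )
    rows = []
    for p in peptides:
        row = {
            "sequence": p.peptide_sequence,
            "accession": p.protein_accession,
            "score": p.id_score,
            "charge": p.charge,
            "mass_error_ppm": p.mass_error_ppm,
            "modified": p.is_acyl_modified,
            "ptms": ";".join(sorted({n for n, _ in p.acyl_modifications})),
        }
        for s in sample_ids:
            row[s] = p.abundances.get(s, 0.0)
        rows.append(row)
    df = pd.DataFrame(rows, columns=(
        ["sequence", "accession", "score", "charge", "mass_error_ppm",
         "modified", "ptms"] + sample_ids
    ))
    df.attrs["sample_ids"] = sample_ids
    return df


def peptide_matrix(
    peptides: Sequence[PeptideMeasurement], design: StudyDesign
) -> pd.DataFrame:
    """Abundance matrix (rows = peptide row index, columns = sample ids)."""
    data = {
        s: [p.abundances.get(s, 0.0) for p in peptides] for s in design.sample_ids
    }
    return pd.DataFrame(data, index=range(len(peptides)), dtype=float)


def normalize_total(matrix: pd.DataFrame, enabled: bool = True) -> pd.DataFrame:
    """Scale each sample column so column sums equal the grand mean sum.

    ``enabled=False`` is a no-op for tables that are already normalized
    upstream (search-engine exports usually are).
    """
    if not enabled:
        return matrix.copy()
    sums = matrix.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero) > 0:
        raise ValueError(f"all-zero abundance column(s): {list(zero.index)}")
    target = float(sums.mean())
    return matrix * (target / sums)


class TotalIntensityNormalizer(BaseEstimator, TransformerMixin):
    """Total-intensity column normalizer (sklearn transformer).

    ``fit`` records the grand-mean column sum of the fitted matrix as the
    target; ``transform`` rescales each column of the given matrix to
    that target sum.
    """

    def __init__(self, enabled: bool = True):
        self.enabled = enabled

    def fit(self, X: pd.DataFrame, y=None) -> "TotalIntensityNormalizer":
        sums = X.sum(axis=0)
        if self.enabled and (sums == 0).any():
            raise ValueError(
                f"all-zero abundance column(s): {list(sums.index[sums == 0])}"
            )
        self.target_sum_ = float(sums.mean())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not self.enabled:
            return X.copy()
        sums = X.sum(axis=0)
        zero = sums[sums == 0]
        if len(zero) > 0:
            raise ValueError(f"all-zero abundance column(s): {list(zero.index)}")
        return X * (self.target_sum_ / sums)


class HiNQuantifier(BaseEstimator):
    """Hi-N top-N protein-level quantifier.

    ``fit`` selects, per protein, the N peptides with the highest mean
    abundance across samples (ties broken by higher identification
    score, then lexicographic sequence); ``transform`` averages the
    selected peptide rows per sample.

    Parameters
    ----------
    n : int, default 3
        Number of top peptides per protein.
    include_modified : bool, default False
        Whether acyl-modified peptides may contribute to protein
        quantitation.

    Attributes
    ----------
    selected_ : dict accession -> list of row indices used for that protein.
    """

    def __init__(self, n: int = 3, include_modified: bool = False):
        self.n = n
        self.include_modified = include_modified

    def fit(self, X: pd.DataFrame, y=None) -> "HiNQuantifier":
        """X is a peptide frame from :func:`peptides_to_frame`."""
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        sample_ids = X.attrs.get("sample_ids")
        if sample_ids is None:
            meta = {"sequence", "accession", "score", "charge", "mass_error_ppm",
                    "modified", "ptms"}
            sample_ids = [c for c in X.columns if c not in meta]
        self.sample_ids_ = list(sample_ids)

        pool = X if self.include_modified else X[~X["modified"]]
        selected: dict[str, list] = {}
        if len(pool):
            mean_ab = pool[self.sample_ids_].mean(axis=1)
            order = pool.assign(_mean=mean_ab).sort_values(
                by=["_mean", "score", "sequence"],
                ascending=[False, False, True],
                kind="mergesort",
            )
            # keep selected rows in original table order so the per-sample
            # mean sums in a selection-independent order
            position = {label: i for i, label in enumerate(X.index)}
            for acc, grp in order.groupby("accession", sort=True):
                top = list(grp.index[: self.n])
                selected[acc] = sorted(top, key=position.__getitem__)
        self.selected_ = selected
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Protein-level matrix: rows = accessions, columns = sample ids."""
        rows = {
            acc: X.loc[idx, self.sample_ids_].mean(axis=0)
            for acc, idx in self.selected_.items()
        }
        out = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
        out = out.reindex(columns=self.sample_ids_).sort_index()
        out.index.name = "accession"
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def hi_n_protein_quant(
    peptide_matrix: pd.DataFrame,
    accessions: Mapping[int, str] | pd.Series | Sequence[str],
    n: int = 3,
    id_scores: Sequence[float] | None = None,
    sequences: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Hi-N protein quantitation on a bare peptide abundance matrix.

    ``accessions`` maps each matrix row to its protein; ``id_scores`` and
    ``sequences`` (aligned to rows) refine the deterministic tie-break.
    Proteins with zero peptides are absent from the output.
    """
    m = peptide_matrix
    acc = pd.Series(list(accessions) if not isinstance(accessions, pd.Series)
                    else accessions, index=m.index)
    frame = m.copy()
    frame.insert(0, "accession", acc)
    frame.insert(1, "score", list(id_scores) if id_scores is not None else 0.0)
    frame.insert(2, "sequence", list(sequences) if sequences is not None
                 else [str(i) for i in m.index])
    frame.insert(3, "modified", False)
    frame.insert(4, "charge", 0)
    frame.insert(5, "mass_error_ppm", 0.0)
    frame.insert(6, "ptms", "")
    frame.attrs["sample_ids"] = list(m.columns)
    return HiNQuantifier(n=n, include_modified=True).fit_transform(frame)
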