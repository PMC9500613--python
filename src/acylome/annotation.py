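"""PTM mass annotation, site mapping, and the tryptic-filter rules.

Implements the post-identification filters applied to search-engine
output: the absolute mass-error cutoff (default |ppm| < 20) and the
missed-cleavage limit under the convention that acyl-modified lysines do
not count as cleavage sites (succinylation/malonylation neutralizes the
lysine charge and blocks trypsin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _mass
from sklearn.base import BaseEstimator

from .records import ACYL_PTMS, ModificationSite, PeptideMeasurement, Thresholds

__all__ = [
    "ACYL_COMPOSITIONS",
    "ptm_mass_delta",
    "map_sites",
    "collect_sites",
    "count_missed_cleavages",
    "filter_peptides",
    "PeptideFilter",
    "MappingError",
    "AmbiguousMappingError",
    "Rejection",
]

#: Elemental composition of the added moiety for each supported acyl PTM.
ACYL_COMPOSITIONS: dict[str, str] = {
    "succinyl": "C4H4O3",
    "malonyl": "C3H2O3",
}


def ptm_mass_delta(ptm: str) -> float:
    """Monoisotopic mass delta (Da) added by an acyl PTM.

    succinyl = C4H4O3 (+100.01604 Da), malonyl = C3H2O3 (+86.00039 Da).
    """
    try:
        formula = ACYL_COMPOSITIONS[ptm.lower()]
    except KeyError:
        raise ValueError(
            f"unknown PTM {ptm!r}; supported: {sorted(ACYL_COMPOSITIONS)}"
        ) from None
    return _mass.calculate_mass(formula=formula)


class MappingError(ValueError):
    """A peptide does not occur in its reported protein sequence."""


class AmbiguousMappingError(MappingError):
    """A peptide occurs more than once in its protein sequence."""


def _find_occurrences(protein: str, peptide: str) -> list[int]:
    """0-based start offsets of every occurrence of peptide in protein."""
    starts, i = [], protein.find(peptide)
    while i != -1:
        starts.append(i)
        i = protein.find(peptide, i + 1)
    return starts


def map_sites(
    peptide: PeptideMeasurement,
    proteome: Mapping[str, str],
    peptide_index: int | None = None,
    first_match: bool = False,
) -> list[ModificationSite]:
    """Map a peptide's acyl modifications to protein coordinates.

    Protein position = match start (1-based) + peptide position - 1.
    Only succinyl/malonyl modifications are emitted. Raises
    :class:`MappingError` if the peptide is absent from its protein and
    :class:`AmbiguousMappingError` on multiple matches unless
    ``first_match`` selects the first.
    """
    acc = peptide.protein_accession
    if acc not in proteome:
        raise MappingError(f"accession {acc!r} not in proteome")
    protein = proteome[acc]
    starts = _find_occurrences(protein, peptide.peptide_sequence)
    if not starts:
        raise MappingError(
            f"peptide {peptide.peptide_sequence!r} not found in protein {acc!r}"
        )
    if len(starts) > 1 and not first_match:
        raise AmbiguousMappingError(
            f"peptide {peptide.peptide_sequence!r} occurs {len(starts)} times in {acc!r}"
        )
    offset = starts[0]  # 0-based
    sites: list[ModificationSite] = []
    sources = (peptide_index,) if peptide_index is not None else ()
    for name, pos in peptide.modifications:
        if name not in ACYL_PTMS:
            continue
        protein_pos = offset + pos  # = (offset+1) + pos - 1, 1-based
        if protein[protein_pos - 1] != "K":
            raise MappingError(
                f"acyl site maps to {protein[protein_pos - 1]!r} at {acc}:{protein_pos}, "
                "expected K"
            )
        sites.append(ModificationSite(acc, protein_pos, name, tuple(sources)))
    return sites


def collect_sites(
    peptides: Sequence[PeptideMeasurement],
    proteome: Mapping[str, str],
    first_match: bool = False,
) -> list[ModificationSite]:
    """Unique modification sites over a peptide list, with supporting rows.

    Site identity is the (accession, position, ptm) triple; the
    ``source_peptides`` of each emitted site lists every contributing
    peptide row index.
    """
    support: dict[tuple[str, int, str], list[int]] = {}
    for i, p in enumerate(peptides):
        if not p.is_acyl_modified:
            continue
        for site in map_sites(p, proteome, peptide_index=i, first_match=first_match):
            support.setdefault(site.key, []).append(i)
    return [
        ModificationSite(acc, pos, ptm, tuple(rows))
        for (acc, pos, ptm), rows in sorted(support.items())
    ]


def count_missed_cleavages(
    peptide_sequence: str,
    modified_k_positions: Iterable[int] = (),
    kp_rule: bool = True,
) -> int:
    """Count internal tryptic sites left uncleaved in a peptide.

    Counts internal (non-C-terminal) K/R residues, excluding K positions
    carrying an acyl modification and — when ``kp_rule`` is on — K/R
    immediately followed by proline.
    """
    modified = set(modified_k_positions)
    seq = peptide_sequence
    n = 0
    for pos in range(1, len(seq)):  # 1-based positions, C-terminus excluded
        residue = seq[pos - 1]
        if residue not in "KR":
            continue
        if residue == "K" and pos in modified:
            continue
        if kp_rule and seq[pos] == "P":
            continue
        n += 1
    return n


@dataclass(frozen=True)
class Rejection:
    """A filtered-out peptide with a machine-readable reason."""

    peptide: PeptideMeasurement
    reason: str  # "mass_error" or "missed_cleavages"
    detail: str = ""


class PeptideFilter(BaseEstimator):
    """Post-identification peptide filter (mass error + missed cleavages).

    Parameters
    ----------
    max_mass_error_ppm : float, default 20.0
        Keep peptides with ``|mass_error_ppm| < max_mass_error_ppm``.
    max_missed_cleavages : int, default 1
        Keep peptides with at most this many missed cleavages, counted
        with acyl-modified lysines excluded.
    kp_rule : bool, default True
        Do not count K/R followed by proline as cleavage sites.

    Attributes
    ----------
    rejections_ : list of Rejection
        Set by :meth:`fit`; one entry per removed peptide.
    n_kept_ : int
    """

    def __init__(
        self,
        max_mass_error_ppm: float = 20.0,
        max_missed_cleavages: int = 1,
        kp_rule: bool = True,
    ):
        self.max_mass_error_ppm = max_mass_error_ppm
        self.max_missed_cleavages = max_missed_cleavages
        self.kp_rule = kp_rule

    def fit(self, X: Sequence[PeptideMeasurement], y=None) -> "PeptideFilter":
        kept, rejections = [], []
        for p in X:
            if abs(p.mass_error_ppm) >= self.max_mass_error_ppm:
                rejections.append(
                    Rejection(p, "mass_error", f"|{p.mass_error_ppm}| >= {self.max_mass_error_ppm} ppm")
                )
                continue
            mc = count_missed_cleavages(
                p.peptide_sequence, p.acyl_positions, kp_rule=self.kp_rule
            )
            if mc > self.max_missed_cleavages:
                rejections.append(
                    Rejection(p, "missed_cleavages", f"{mc} > {self.max_missed_cleavages}")
                )
                continue
            kept.append(p)
        self.kept_ = kept
        self.rejections_ = rejections
        self.n_kept_ = len(kept)
        return self

    def transform(self, X: Sequence[PeptideMeasurement]) -> list[PeptideMeasurement]:
        self.fit(X)
        return self.kept_

    def fit_transform(self, X: Sequence[PeptideMeasurement], y=None) -> list[PeptideMeasurement]:
        return self.transform(X)


def filter_peptides(
    peptides: Sequence[PeptideMeasurement],
    thresholds: Thresholds | None = None,
    kp_rule: bool = True,
    max_missed_cleavages: int = 1,
) -> tuple[list[PeptideMeasurement], list[Rejection]]:
    """Apply the post-identification filters; returns (kept, rejections)."""
    thresholds = thresholds or Thresholds()
    f = PeptideFilter(
        max_mass_error_ppm=thresholds.max_mass_error_ppm,
        max_missed_cleavages=max_missed_cleavages,
        kp_rule=kp_rule,
    ).fit(peptides)
    return f.kept_, f.rejections_
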