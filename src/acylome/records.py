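"""Core record types for acyl-PTM label-free quantitation analysis.

The atomic record of the pipeline is a :class:`PeptideMeasurement` — one
identified peptide ion with its modification string, identification
metadata and per-sample normalized abundances. A :class:`StudyDesign`
maps samples to experimental groups and (optionally) assigns the four
roles used by the attenuation analysis: two vehicle controls, the
chemical-insult ("model") group and the drug co-treatment group.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "ACYL_PTMS",
    "PTM_SUCCINYL",
    "PTM_MALONYL",
    "PeptideMeasurement",
    "ModificationSite",
    "StudyDesign",
    "Thresholds",
    "parse_modifications",
    "format_modifications",
]

PTM_SUCCINYL = "succinyl"
PTM_MALONYL = "malonyl"

#: The variable acyl modifications considered by the pipeline; both occur
#: on lysine side chains only.
ACYL_PTMS = frozenset({PTM_SUCCINYL, PTM_MALONYL})

# "Succinyl(K3)" -> name="Succinyl", residue="K", position=3
_MOD_RE = re.compile(r"^\s*([A-Za-z0-9_-]+)\(([A-Z])(\d+)\)\s*$")


class FormatError(ValueError):
    """A file or field does not conform to the expected schema."""


def parse_modifications(text: str) -> list[tuple[str, int]]:
    """Parse a semicolon-separated modification string.

    The canonical syntax is ``PTMName(<residue><pos>)`` with a 1-based
    peptide position, e.g. ``"Succinyl(K3);Oxidation(M7)"``. PTM names are
    lower-cased on parse.

    Returns a list of ``(ptm_name, peptide_position)`` tuples.
    """
    text = (text or "").strip()
    if not text:
        return []
    mods: list[tuple[str, int]] = []
    for token in text.split(";"):
        m = _MOD_RE.match(token)
        if m is None:
            raise FormatError(f"unparseable modification token: {token!r}")
        name, _residue, pos = m.groups()
        mods.append((name.lower(), int(pos)))
    return mods


def format_modifications(mods: Sequence[tuple[str, int]], sequence: str) -> str:
    """Render modifications back to the canonical string syntax."""
    tokens = []
    for name, pos in mods:
        if not 1 <= pos <= len(sequence):
            raise ValueError(
                f"modification position {pos} outside peptide of length {len(sequence)}"
            )
        tokens.append(f"{name.capitalize()}({sequence[pos - 1]}{pos})")
    return ";".join(tokens)


@dataclass
class PeptideMeasurement:
    """One identified peptide ion with per-sample abundances.

    Parameters
    ----------
    peptide_sequence
        Upper-case amino-acid string.
    modifications
        ``(ptm_name, peptide_position)`` pairs, 1-based positions.
    charge
        Precursor charge state (positive integer).
    mass_error_ppm
        Signed relative mass error of the identification, in ppm.
    id_score
        Identification score (non-negative).
    protein_accession
        Lead protein accession reported by the search engine.
    abundances
        Mapping ``sample_id -> normalized abundance`` (non-negative).
    """

    peptide_sequence: str
    modifications: list[tuple[str, int]] = field(default_factory=list)
    charge: int = 2
    mass_error_ppm: float = 0.0
    id_score: float = 0.0
    protein_accession: str = ""
    abundances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, design: "StudyDesign | None" = None) -> None:
        seq = self.peptide_sequence
        if not seq or seq != seq.upper():
            raise ValueError(f"peptide sequence must be non-empty uppercase: {seq!r}")
        if self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")
        if self.id_score < 0:
            raise ValueError(f"id_score must be non-negative, got {self.id_score}")
        for name, pos in self.modifications:
            if not 1 <= pos <= len(seq):
                raise ValueError(
                    f"modification {name}({pos}) outside peptide {seq!r}"
                )
            if name in ACYL_PTMS and seq[pos - 1] != "K":
                raise ValueError(
                    f"acyl modification {name} at position {pos} of {seq!r} "
                    f"is on {seq[pos - 1]!r}, not K"
                )
        for sample, value in self.abundances.items():
            if value < 0:
                raise ValueError(f"negative abundance for sample {sample!r}: {value}")
        if design is not None:
            expected = set(design.sample_ids)
            got = set(self.abundances)
            if got != expected:
                raise ValueError(
                    f"abundance keys {sorted(got)} do not match design samples "
                    f"{sorted(expected)}"
                )

    @property
    def acyl_modifications(self) -> list[tuple[str, int]]:
        """Succinyl/malonyl modifications only."""
        return [(n, p) for n, p in self.modifications if n in ACYL_PTMS]

    @property
    def acyl_positions(self) -> frozenset[int]:
        return frozenset(p for _, p in self.acyl_modifications)

    @property
    def is_acyl_modified(self) -> bool:
        return bool(self.acyl_modifications)

    def with_abundances(self, abundances: Mapping[str, float]) -> "PeptideMeasurement":
        return replace(self, abundances=dict(abundances))


@dataclass(frozen=True)
class ModificationSite:
    """A (protein, residue, PTM) triple derived from one or more peptides."""

    protein_accession: str
    residue_position: int  # 1-based position in the protein
    ptm: str
    source_peptides: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.ptm not in ACYL_PTMS:
            raise ValueError(
                f"unknown acyl PTM {self.ptm!r}; expected one of {sorted(ACYL_PTMS)}"
            )
        if self.residue_position < 1:
            raise ValueError("residue_position is 1-based and must be >= 1")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.protein_accession, self.residue_position, self.ptm)


#: Role names recognized by the attenuation analysis.
ROLES = ("vehicle1", "vehicle2", "model", "treatment")


@dataclass
class StudyDesign:
    """Sample-to-group assignment plus optional group roles.

    ``roles`` assigns experimental roles to group ids: the two vehicle
    control groups (e.g. DMSO and acidified water), the disease-model
    group (MK-801 insult) and the antipsychotic co-treatment group.
    Roles are only required for the attenuation analysis.
    """

    samples: list[tuple[str, str]]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s for s, _ in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids in design: {dupes}")
        groups = set(g for _, g in self.samples)
        for role, group in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
            if group not in groups:
                raise ValueError(f"role {role!r} names unknown group {group!r}")
        if "vehicle1" in self.roles and "vehicle2" in self.roles:
            if self.roles["vehicle1"] == self.roles["vehicle2"]:
                raise ValueError("vehicle1 and vehicle2 must be distinct groups")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    @property
    def groups(self) -> list[str]:
        """Group ids in first-appearance order."""
        seen: dict[str, None] = {}
        for _, g in self.samples:
            seen.setdefault(g)
        return list(seen)

    @property
    def samples_by_group(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.samples:
            out.setdefault(g, []).append(s)
        return out

    def group_of(self, sample_id: str) -> str:
        for s, g in self.samples:
            if s == sample_id:
                return g
        raise KeyError(sample_id)

    def role_group(self, role: str) -> str:
        if role not in self.roles:
            raise KeyError(f"design does not declare the {role!r} role")
        return self.roles[role]

    def require_anova_groups(self, min_per_group: int = 2) -> None:
        """Every group entering ANOVA needs at least two replicates."""
        for g, members in self.samples_by_group.items():
            if len(members) < min_per_group:
                raise ValueError(
                    f"group {g!r} has {len(members)} sample(s); "
                    f"ANOVA needs >= {min_per_group}"
                )


@dataclass
class Thresholds:
    """All tunable cutoffs of the pipeline, with study defaults.

    Defaults: mass error < 20 ppm, ANOVA alpha 0.05, Hi-N with N = 3,
    10% vehicle concordance tolerance, dysregulation bands at 10/25/50%,
    enrichment reported at FDR <= 1% and p <= 0.01, pathways with fewer
    than 5 overlapping gene names excluded.
    """

    max_mass_error_ppm: float = 20.0
    anova_alpha: float = 0.05
    hi_n: int = 3
    vehicle_tolerance: float = 0.10
    bands: tuple[float, ...] = (0.10, 0.25, 0.50)
    enrich_fdr: float = 0.01
    enrich_p: float = 0.01
    min_pathway_genes: int = 5

    def __post_init__(self) -> None:
        self.bands = tuple(float(b) for b in self.bands)
        self.validate()

    def validate(self) -> None:
        if self.max_mass_error_ppm <= 0:
            raise ValueError("max_mass_error_ppm must be positive")
        if self.hi_n < 1:
            raise ValueError("hi_n must be >= 1")
        if self.min_pathway_genes < 0:
            raise ValueError("min_pathway_genes must be >= 0")
        for name in ("anova_alpha", "vehicle_tolerance", "enrich_fdr", "enrich_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not self.bands:
            raise ValueError("bands must be non-empty")
        if any(not 0 < b <= 1 for b in self.bands):
            raise ValueError(f"bands must lie in (0, 1], got {self.bands}")
        if any(b2 <= b1 for b1, b2 in zip(self.bands, self.bands[1:])):
            raise ValueError(f"bands must be strictly increasing, got {self.bands}")
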