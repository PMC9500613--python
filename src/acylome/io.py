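"""Readers and writers for the pipeline's external formats.

Peptide quantitation tables are CSV/TSV with one row per identified
peptide ion and columns ``[sequence, modifications, charge, score,
mass_error_ppm, accession, <sample_id>...]``. Sample columns are matched
to the study design by exact header, order-independently. Protein
sequences come from FASTA, gene sets from GMT, and the study design from
a 2–3 column CSV (``sample_id, group_id[, role]``).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import fasta as _fasta

from .records import (
    FormatError,
    PeptideMeasurement,
    StudyDesign,
    format_modifications,
    parse_modifications,
)

__all__ = [
    "FormatError",
    "RowError",
    "REQUIRED_COLUMNS",
    "read_peptide_table",
    "write_peptide_table",
    "read_fasta",
    "read_gmt",
    "read_design",
    "write_design",
    "write_site_table",
]

logger = logging.getLogger(__name__)

#: Metadata columns every peptide table must carry, in canonical order.
REQUIRED_COLUMNS = (
    "sequence",
    "modifications",
    "charge",
    "score",
    "mass_error_ppm",
    "accession",
)


@dataclass(frozen=True)
class RowError:
    """A parse failure for one data row (0-based index among data rows)."""

    row_index: int
    message: str


def _dialect_delimiter(dialect: str) -> str:
    if dialect == "comma":
        return ","
    if dialect == "tab":
        return "\t"
    raise ValueError(f"dialect must be 'comma' or 'tab', got {dialect!r}")


def _infer_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_peptide_table(
    path: str | Path,
    dialect: str | None = None,
    design: StudyDesign | None = None,
    sample_prefix: str | None = None,
    strict: bool = False,
    collect_errors: bool = False,
):
    """Read a peptide quantitation table.

    Abundance columns are the design's sample ids when a ``design`` is
    given, the columns starting with ``sample_prefix`` when that is
    given, and otherwise every column after the required metadata
    columns. Missing abundance cells are filled with 0.0 and logged
    (Progenesis-style exports use zeros for unmatched features) unless
    ``strict`` is set, in which case they are row errors.

    Returns the list of :class:`PeptideMeasurement` in file order; with
    ``collect_errors=True`` returns ``(records, row_errors)`` instead of
    raising on bad rows, so that ``len(records) + len(errors)`` equals
    the number of data rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _dialect_delimiter(dialect) if dialect else _infer_delimiter(path)

    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = [h.strip() for h in header]
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {missing}")

        if design is not None:
            sample_cols = list(design.sample_ids)
            absent = [s for s in sample_cols if s not in header]
            if absent:
                raise FormatError(f"{path}: design samples missing from header: {absent}")
        elif sample_prefix is not None:
            sample_cols = [h for h in header if h.startswith(sample_prefix)]
            if not sample_cols:
                raise FormatError(
                    f"{path}: no columns start with sample prefix {sample_prefix!r}"
                )
        else:
            meta = set(REQUIRED_COLUMNS)
            sample_cols = [h for h in header if h not in meta]

        idx = {name: header.index(name) for name in header}
        records: list[PeptideMeasurement] = []
        errors: list[RowError] = []
        for row_i, row in enumerate(reader):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                records.append(
                    _parse_row(row, idx, sample_cols, strict=strict, row_i=row_i)
                )
            except (ValueError, IndexError) as exc:
                err = RowError(row_i, str(exc))
                if collect_errors:
                    errors.append(err)
                else:
                    raise FormatError(f"{path} row {row_i}: {exc}") from exc

    if collect_errors:
        return records, errors
    return records


def _parse_row(
    row: Sequence[str],
    idx: dict[str, int],
    sample_cols: Sequence[str],
    strict: bool,
    row_i: int,
) -> PeptideMeasurement:
    def cell(name: str) -> str:
        return row[idx[name]].strip()

    abundances: dict[str, float] = {}
    for s in sample_cols:
        raw = row[idx[s]].strip() if idx[s] < len(row) else ""
        if raw == "":
            if strict:
                raise ValueError(f"missing abundance for sample {s!r}")
            logger.warning("row %d: missing abundance for sample %r set to 0.0", row_i, s)
            abundances[s] = 0.0
            continue
        try:
            abundances[s] = float(raw)
        except ValueError:
            raise ValueError(f"non-numeric abundance {raw!r} for sample {s!r}")

    return PeptideMeasurement(
        peptide_sequence=cell("sequence").upper(),
        modifications=parse_modifications(cell("modifications")),
        charge=int(cell("charge")),
        mass_error_ppm=float(cell("mass_error_ppm")),
        id_score=float(cell("score")),
        protein_accession=cell("accession"),
        abundances=abundances,
    )


def write_peptide_table(
    peptides: Iterable[PeptideMeasurement],
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    dialect: str | None = None,
) -> None:
    """Write peptides in the canonical table schema (round-trip safe)."""
    path = Path(path)
    peptides = list(peptides)
    if sample_ids is None:
        sample_ids = list(peptides[0].abundances) if peptides else []
    delim = _dialect_delimiter(dialect) if dialect else _infer_delimiter(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(list(REQUIRED_COLUMNS) + list(sample_ids))
        for p in peptides:
            writer.writerow(
                [
                    p.peptide_sequence,
                    format_modifications(p.modifications, p.peptide_sequence),
                    p.charge,
                    repr(p.id_score),
                    repr(p.mass_error_ppm),
                    p.protein_accession,
                ]
                + [repr(p.abundances.get(s, 0.0)) for s in sample_ids]
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by accession.

    The accession is the first whitespace-delimited header token; UniProt
    ``sp|ACC|NAME`` / ``tr|ACC|NAME`` headers yield ``ACC``. Sequences are
    upper-cased. Duplicate accessions are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    with path.open() as fh:
        for header, sequence in _fasta.FASTA(fh):
            token = header.split()[0]
            parts = token.split("|")
            acc = parts[1] if len(parts) >= 3 and parts[0] in {"sp", "tr"} else token
            if acc in out:
                raise FormatError(f"{path}: duplicate accession {acc!r}")
            out[acc] = sequence.upper()
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: ``name<TAB>description<TAB>member...``.

    Member lists are deduplicated; a line without members is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, set[str]] = {}
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise FormatError(f"{path} line {line_no}: gene set with no members")
            name = fields[0].strip()
            if name in sets:
                raise FormatError(f"{path} line {line_no}: duplicate set name {name!r}")
            sets[name] = {f.strip() for f in fields[2:] if f.strip()}
    return sets


def read_design(path: str | Path) -> StudyDesign:
    """Read a study design CSV with columns ``sample_id, group_id[, role]``.

    The optional third column assigns the row's *group* to a role
    (vehicle1/vehicle2/model/treatment); it needs to appear on only one
    row per group.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    samples: list[tuple[str, str]] = []
    roles: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty design file")
        header = [h.strip().lower() for h in header]
        if header[:2] != ["sample_id", "group_id"]:
            raise FormatError(
                f"{path}: design header must start with sample_id,group_id; got {header}"
            )
        has_role = len(header) >= 3 and header[2] == "role"
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            sample, group = row[0].strip(), row[1].strip()
            samples.append((sample, group))
            if has_role and len(row) >= 3 and row[2].strip():
                role = row[2].strip().lower()
                if role in roles and roles[role] != group:
                    raise FormatError(
                        f"{path}: role {role!r} assigned to both {roles[role]!r} and {group!r}"
                    )
                roles[role] = group
    return StudyDesign(samples=samples, roles=roles)


def write_design(design: StudyDesign, path: str | Path) -> None:
    path = Path(path)
    group_role = {g: r for r, g in design.roles.items()}
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "group_id", "role"])
        seen_groups: set[str] = set()
        for sample, group in design.samples:
            role = group_role.get(group, "") if group not in seen_groups else ""
            seen_groups.add(group)
            writer.writerow([sample, group, role])


def write_site_table(sites, path: str | Path) -> None:
    """Write modification sites as TSV [accession, position, ptm, n_supporting_peptides]."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "position", "ptm", "n_supporting_peptides"])
        for site in sites:
            writer.writerow(
                [site.protein_accession, site.residue_position, site.ptm,
                 len(site.source_peptides)]
            )
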