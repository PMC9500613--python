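"""End-to-end orchestration: filter → annotate → quantify → differential
→ attenuation → enrichment → report, with a JSON run manifest.

Every output table is written deterministically (fixed float format, no
timestamps), so reruns with the same inputs and seed are bitwise
identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import collect_sites, filter_peptides
from .attenuation import attenuation_table, calls_to_frame, render_attenuation_table
from .differential import call_differential, frequency_summary, results_to_frame
from .enrichment import dotplot_export, enrich, results_to_frame as enrich_frame
from .io import (
    read_design,
    read_fasta,
    read_gmt,
    read_peptide_table,
    write_site_table,
)
from .quantitation import HiNQuantifier, normalize_total, peptides_to_frame
from .records import Thresholds

__all__ = ["RunConfig", "ConfigError", "DataError", "PipelineError", "run_pipeline"]


class ConfigError(ValueError):
    """Bad or inconsistent run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Input data failed validation inside a stage (CLI exit code 3)."""


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, thresholds and mode flags for one pipeline run."""

    peptide_table: str
    design: str
    out_dir: str
    fasta: str | None = None
    gmt: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    normalize: bool = False  # tables are assumed pre-normalized
    anova_on_log: bool = True
    include_modified_in_hin: bool = False
    kp_rule: bool = True
    require_significant_for_attenuation: bool = False
    enrichment_directions: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        try:
            return cls(thresholds=thresholds, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        for name in ("peptide_table", "design"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ConfigError(f"{name} file not found: {p!r}")
        for name in ("fasta", "gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} file not found: {p!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=True, float_format="%.10g", lineterminator="\n")


def _guard(stage_name: str, fn):
    """Run one stage; any unexpected failure is tagged with the stage name."""
    try:
        return fn()
    except (ConfigError, DataError, PipelineError):
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage_name, exc) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "tool": "acylome",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "thresholds": asdict(thr),
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    # -- load ------------------------------------------------------------
    def load():
        design = read_design(config.design)
        peptides = read_peptide_table(config.peptide_table, design=design)
        proteome = read_fasta(config.fasta) if config.fasta else None
        gene_sets = read_gmt(config.gmt) if config.gmt else None
        return design, peptides, proteome, gene_sets

    design, peptides, proteome, gene_sets = _guard("load", load)
    manifest["stages"]["load"] = {
        "n_peptides": len(peptides),
        "n_samples": len(design.sample_ids),
        "n_groups": len(design.groups),
    }

    # -- filter ----------------------------------------------------------
    kept, rejections = _guard(
        "filter", lambda: filter_peptides(peptides, thr, kp_rule=config.kp_rule)
    )
    reasons: dict[str, int] = {}
    for r in rejections:
        reasons[r.reason] = reasons.get(r.reason, 0) + 1
    manifest["stages"]["filter"] = {
        "n_kept": len(kept),
        "n_rejected": len(rejections),
        "rejected_by_reason": dict(sorted(reasons.items())),
    }

    # -- annotate --------------------------------------------------------
    if proteome is not None:
        sites = _guard("annotate", lambda: collect_sites(kept, proteome))
        site_path = out / "sites.tsv"
        write_site_table(sites, site_path)
        written.append(site_path)
        manifest["stages"]["annotate"] = {"n_sites": len(sites)}

    # -- quantify --------------------------------------------------------
    def quantify():
        frame = peptides_to_frame(kept, design)
        sample_ids = frame.attrs["sample_ids"]
        matrix = normalize_total(frame[sample_ids], enabled=config.normalize)
        frame = frame.copy()
        frame[sample_ids] = matrix
        frame.attrs["sample_ids"] = sample_ids
        quantifier = HiNQuantifier(
            n=thr.hi_n, include_modified=config.include_modified_in_hin
        )
        return frame, quantifier.fit_transform(frame)

    pep_frame, protein_matrix = _guard("quantify", quantify)
    protein_path = out / "protein_quant.tsv"
    _write_tsv(protein_matrix, protein_path)
    written.append(protein_path)
    manifest["stages"]["quantify"] = {
        "n_proteins": len(protein_matrix),
        "hi_n": thr.hi_n,
    }

    # -- differential ----------------------------------------------------
    def differential():
        results = call_differential(kept, design, thr, on_log=config.anova_on_log)
        return results, frequency_summary(kept, results)

    diff_results, freq = _guard("differential", differential)
    diff_frame = results_to_frame(diff_results)
    if len(diff_frame):
        diff_frame = diff_frame.set_index("feature_id")
    diff_path = out / "differential.tsv"
    _write_tsv(diff_frame, diff_path)
    written.append(diff_path)
    freq_path = out / "frequency_summary.json"
    freq_path.write_text(json.dumps(asdict(freq), indent=1, sort_keys=True) + "\n")
    written.append(freq_path)
    manifest["stages"]["differential"] = {
        "n_tested": len(diff_results),
        "n_significant": sum(r.significant for r in diff_results),
        "pct_modified": freq.pct_modified,
    }

    # -- attenuation -----------------------------------------------------
    calls = []
    if all(r in design.roles for r in ("vehicle1", "vehicle2", "model", "treatment")):
        calls = _guard(
            "attenuation",
            lambda: attenuation_table(
                kept, design, thr,
                differential=diff_results,
                require_significant=config.require_significant_for_attenuation,
            ),
        )
        calls_frame = calls_to_frame(calls)
        if len(calls_frame):
            calls_frame = calls_frame.set_index("feature_id")
        calls_path = out / "attenuation.tsv"
        _write_tsv(calls_frame, calls_path)
        written.append(calls_path)
        table = render_attenuation_table(calls, treatment=design.roles["treatment"])
        table_path = out / "attenuation_table.tsv"
        _write_tsv(table, table_path)
        written.append(table_path)
        manifest["stages"]["attenuation"] = {
            "n_classified": len(calls),
            "n_attenuated": sum(c.attenuated for c in calls),
            "n_double_asterisk": sum(c.attenuated and c.asterisks == 2 for c in calls),
        }

    # -- enrichment ------------------------------------------------------
    if gene_sets is not None:
        def enrichment():
            background = sorted({p.protein_accession for p in kept})
            sig = [r for r in diff_results if r.significant]
            queries: dict[tuple[str, str, str], set[str]] = {}
            for r in sig:
                for ptm in r.ptms:
                    direction = r.direction if config.enrichment_directions else "all"
                    key = ("model_vs_control", ptm, direction)
                    queries.setdefault(key, set()).add(r.accession)
            return {
                key: enrich(accs, gene_sets, background, thr)
                for key, accs in sorted(queries.items())
            }

        results_by = _guard("enrichment", enrichment)
        all_rows = [
            dict(comparison=k[0], ptm=k[1], direction=k[2], **row)
            for k, res in results_by.items()
            for row in enrich_frame(res).to_dict("records")
        ]
        enr_path = out / "enrichment.tsv"
        _write_tsv(pd.DataFrame(all_rows), enr_path)
        written.append(enr_path)
        table, _figure = _guard(
            "enrichment",
            lambda: dotplot_export(results_by, figure_path=out / "dotplot.svg"),
        )
        dot_path = out / "dotplot_data.tsv"
        _write_tsv(table, dot_path)
        written.append(dot_path)
        manifest["stages"]["enrichment"] = {
            "n_comparisons": len(results_by),
            "n_passing": int(sum(r.passes for res in results_by.values() for r in res)),
        }

    # -- manifest --------------------------------------------------------
    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(written)}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
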