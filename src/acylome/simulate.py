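"""Synthetic label-free acyl-proteomics datasets with planted ground truth.

The generator emulates the data shape the analysis assumes: a cell-line
experiment with two vehicle control groups (DMSO-like and acidified
water), a chemical-insult group (MK-801) and an antipsychotic
co-treatment group. Proteins are random tryptic-friendly sequences built
by concatenating their own peptides; a configurable fraction of peptides
carries a succinyl or malonyl lysine. Dysregulation and attenuation
effects are planted as fractional deviations of the model/co-treatment
group means from a per-feature baseline, drawn uniformly inside the
severity/residual bands (kept away from band boundaries by a margin);
observed abundances are the planted means under multiplicative
log-normal noise, ``mean * 2**Normal(0, noise_sigma)``.

Ground-truth labels are produced by running the attenuation classifier
on the noiseless planted means, so they are consistent with the
pipeline's own band rules by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .attenuation import AttenuationCall, classify_attenuation
from .differential import DifferentialResult
from .records import PeptideMeasurement, StudyDesign

__all__ = [
    "GROUPS",
    "SimulationParams",
    "PeptideTruth",
    "GroundTruth",
    "SimulatedDataset",
    "generate",
    "write_dataset",
    "evaluate_recovery",
]

#: Group ids in role order: vehicle1, vehicle2, model, treatment.
GROUPS = ("vehicle_dmso", "vehicle_hcl", "mk801", "cotreat")

_AA_CORE = "ACDEFGHILMNQSTVWY"  # no K/R (cleavage sites) and no P (KP rule)


@dataclass
class SimulationParams:
    """Knobs of the synthetic experiment (defaults are the study conditions).

    ``effect_bands`` gives the mild/moderate/severe mix among
    dysregulated features; ``residual_band_mix`` the <10% / 10–25% /
    25–50% residual mix among attenuated ones (restricted per feature to
    the bands its severity allows, then renormalized).
    """

    n_proteins: int = 500
    peptides_per_protein: tuple[int, int] = (3, 8)
    frac_modified_peptides: float = 0.065
    ptm_mix: float = 0.5  # succinyl fraction; remainder malonyl
    n_replicates_per_group: int = 3
    noise_sigma: float = 0.1  # log2-scale sd of multiplicative noise
    frac_dysregulated: float = 0.4
    effect_bands: tuple[float, float, float] = (0.4, 0.35, 0.25)
    frac_attenuated_given_dysregulated: float = 0.5
    residual_band_mix: tuple[float, float, float] = (0.33, 0.22, 0.45)
    vehicle_discordance_rate: float = 0.1
    boundary_margin: float = 0.02
    bands: tuple[float, float, float] = (0.10, 0.25, 0.50)
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.peptides_per_protein
        if not 1 <= lo <= hi:
            raise ValueError("peptides_per_protein must be a (lo, hi) range, lo >= 1")
        if self.n_replicates_per_group < 2:
            raise ValueError("n_replicates_per_group must be >= 2")
        for name in (
            "frac_modified_peptides", "ptm_mix", "frac_dysregulated",
            "frac_attenuated_given_dysregulated", "vehicle_discordance_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("effect_bands", "residual_band_mix"):
            mix = getattr(self, name)
            if abs(sum(mix) - 1.0) > 1e-9 or any(m < 0 for m in mix):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PeptideTruth:
    """Planted labels for one modified peptide (feature id = table row)."""

    accession: str
    ptm: str
    concordant: bool  # vehicle pair obeys the 10% rule on noiseless means
    differential: bool  # any planted group-mean difference (ANOVA truth)
    dysregulated: bool  # model group planted away from baseline
    direction: str  # "up"/"down" when dysregulated, else ""
    severity: str
    residual_band: str
    asterisks: int
    attenuated: bool


@dataclass
class GroundTruth:
    peptides: dict[int, PeptideTruth]
    protein_directions: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "peptides": {str(i): asdict(t) for i, t in sorted(self.peptides.items())},
                "protein_directions": dict(sorted(self.protein_directions.items())),
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SimulatedDataset:
    peptides: list[PeptideMeasurement]
    proteome: dict[str, str]
    design: StudyDesign
    truth: GroundTruth
    params: SimulationParams


def _draw_in_band(rng, lower: float, upper: float, margin: float) -> float:
    lo, hi = lower + margin, upper - margin
    if hi <= lo:
        raise ValueError(f"band ({lower}, {upper}) too narrow for margin {margin}")
    return float(rng.uniform(lo, hi))


def _make_protein(rng, n_peptides: int, frac_modified: float, ptm_mix: float,
                  max_retries: int = 20):
    """Random peptides + concatenated protein; every peptide occurs once."""
    for _ in range(max_retries):
        peps: list[tuple[str, list[tuple[str, int]]]] = []
        for _ in range(n_peptides):
            core_len = int(rng.integers(7, 16))
            core = list(rng.choice(list(_AA_CORE), size=core_len))
            mods: list[tuple[str, int]] = []
            if rng.random() < frac_modified:
                pos = int(rng.integers(1, core_len + 1))
                core[pos - 1] = "K"
                ptm = "succinyl" if rng.random() < ptm_mix else "malonyl"
                mods = [(ptm, pos)]
            terminal = "K" if rng.random() < 0.5 else "R"
            peps.append(("".join(core) + terminal, mods))
        protein = "".join(seq for seq, _ in peps)
        if all(protein.count(seq) == 1 for seq, _ in peps):
            return protein, peps
    raise RuntimeError("could not build a protein with unique peptides")


def generate(params: SimulationParams | None = None) -> SimulatedDataset:
    """Generate a full synthetic dataset; deterministic given the seed."""
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    bands = params.bands
    margin = params.boundary_margin
    tol = 0.10  # vehicle concordance tolerance the plants are built around

    n_rep = params.n_replicates_per_group
    samples = [(f"{g}_r{r + 1}", g) for g in GROUPS for r in range(n_rep)]
    design = StudyDesign(
        samples=samples,
        roles={"vehicle1": GROUPS[0], "vehicle2": GROUPS[1],
               "model": GROUPS[2], "treatment": GROUPS[3]},
    )
    sample_group = dict(samples)

    peptides: list[PeptideMeasurement] = []
    proteome: dict[str, str] = {}
    truths: dict[int, PeptideTruth] = {}
    feature_id = 0

    for i in range(params.n_proteins):
        acc = f"SYN{i:05d}"
        lo, hi = params.peptides_per_protein
        n_pep = int(rng.integers(lo, hi + 1))
        protein, peps = _make_protein(
            rng, n_pep, params.frac_modified_peptides, params.ptm_mix
        )
        proteome[acc] = protein

        for seq, mods in peps:
            base = float(10.0 ** rng.uniform(4, 8))

            # Vehicle pair: identical for concordant features, split
            # symmetrically past the tolerance for discordant ones.
            discordant = bool(rng.random() < params.vehicle_discordance_rate)
            if discordant:
                d = _draw_in_band(rng, tol, 0.5, margin)
                flip = 1.0 if rng.random() < 0.5 else -1.0
                v1 = base * (1 + flip * d / 2)
                v2 = base * (1 - flip * d / 2)
            else:
                v1 = v2 = base

            model_mean = treated_mean = base
            dysregulated = False
            if mods and rng.random() < params.frac_dysregulated:
                dysregulated = True
                sev_idx = int(rng.choice(3, p=params.effect_bands))
                upper = bands[sev_idx + 1] if sev_idx < 2 else 1.0
                dev = _draw_in_band(rng, bands[sev_idx], upper, margin)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                model_mean = base * (1 + sign * dev)
                if rng.random() < params.frac_attenuated_given_dysregulated:
                    # Residual band limited to those under the severity's
                    # own threshold, i.e. indices 0..sev_idx.
                    weights = np.asarray(params.residual_band_mix[: sev_idx + 1])
                    weights = weights / weights.sum()
                    res_idx = int(rng.choice(sev_idx + 1, p=weights))
                    res_lower = 0.0 if res_idx == 0 else bands[res_idx - 1]
                    res = _draw_in_band(rng, res_lower, bands[res_idx], margin)
                    treated_mean = base * (1 + sign * res)
                else:
                    treated_mean = model_mean  # no return toward control

            group_means = {GROUPS[0]: v1, GROUPS[1]: v2,
                           GROUPS[2]: model_mean, GROUPS[3]: treated_mean}
            noise = rng.normal(0.0, 1.0, size=len(samples))
            abundances = {
                s: group_means[sample_group[s]] * float(2.0 ** (params.noise_sigma * z))
                for (s, _), z in zip(samples, noise)
            }

            peptides.append(
                PeptideMeasurement(
                    peptide_sequence=seq,
                    modifications=list(mods),
                    charge=int(rng.integers(2, 5)),
                    mass_error_ppm=float(rng.normal(0.0, 3.0)),
                    id_score=float(rng.uniform(5.0, 60.0)),
                    protein_accession=acc,
                    abundances=abundances,
                )
            )

            if mods:
                # Label with the classifier itself, on the noiseless means.
                call = classify_attenuation(base, model_mean, treated_mean, bands)
                truths[feature_id] = PeptideTruth(
                    accession=acc,
                    ptm=mods[0][0],
                    concordant=not discordant,
                    differential=bool(dysregulated or discordant),
                    dysregulated=dysregulated,
                    direction=("up" if model_mean > base else "down")
                    if dysregulated else "",
                    severity=call.severity,
                    residual_band=call.residual_band,
                    asterisks=call.asterisks,
                    attenuated=call.attenuated,
                )
            feature_id += 1

    directions: dict[str, set[str]] = {}
    for t in truths.values():
        if t.dysregulated:
            directions.setdefault(t.accession, set()).add(t.direction)
    protein_directions = {
        acc: "Both" if len(d) > 1 else ("Up" if "up" in d else "Down")
        for acc, d in directions.items()
    }

    return SimulatedDataset(
        peptides=peptides,
        proteome=proteome,
        design=design,
        truth=GroundTruth(truths, protein_directions),
        params=params,
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Emit the canonical peptide CSV, FASTA, design CSV and truth JSON."""
    from .io import write_design, write_peptide_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": out / "peptides.csv",
        "proteome": out / "proteome.fasta",
        "design": out / "design.csv",
        "truth": out / "truth.json",
    }
    write_peptide_table(dataset.peptides, paths["peptides"],
                        sample_ids=dataset.design.sample_ids)
    with paths["proteome"].open("w") as fh:
        for acc in sorted(dataset.proteome):
            fh.write(f">{acc} synthetic\n{dataset.proteome[acc]}\n")
    write_design(dataset.design, paths["design"])
    paths["truth"].write_text(dataset.truth.to_json() + "\n")
    return paths


def _prf(tp: int, fp: int, fn: int) -> dict[str, float]:
    if tp + fp + fn == 0:
        return {"precision": 1.0, "recall": 1.0, "f1": 1.0,
                "tp": 0, "fp": 0, "fn": 0}
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}


def evaluate_recovery(
    differential_results: Sequence[DifferentialResult],
    attenuation_calls: Sequence[AttenuationCall],
    truth: GroundTruth,
) -> dict:
    """Confusion metrics of pipeline outputs against planted truth.

    Tasks: differential detection, severity-band accuracy (over
    truth-concordant features that received a call, with the called
    fraction reported as coverage), attenuation detection, exact residual-band and asterisk accuracy
    (over features both planted and called attenuated), and
    precision/recall of the two-asterisk (severe-to-baseline) calls.
    """
    truth_ids = set(truth.peptides)
    for r in differential_results:
        if r.feature_id not in truth_ids:
            raise ValueError(f"differential feature id {r.feature_id} not in truth")
    calls = {}
    for c in attenuation_calls:
        if c.feature_id not in truth_ids:
            raise ValueError(f"attenuation feature id {c.feature_id} not in truth")
        calls[c.feature_id] = c

    pred_sig = {r.feature_id for r in differential_results if r.significant}
    true_sig = {i for i, t in truth.peptides.items() if t.differential}
    diff = _prf(
        len(pred_sig & true_sig),
        len(pred_sig - true_sig),
        len(true_sig - pred_sig),
    )

    concordant = {i for i, t in truth.peptides.items() if t.concordant}
    called = concordant & set(calls)
    sev_correct = sum(
        1 for i in called if calls[i].severity == truth.peptides[i].severity
    )
    severity = {
        "accuracy": sev_correct / len(called) if called else 1.0,
        "n": len(called),
        "coverage": len(called) / len(concordant) if concordant else 1.0,
    }

    pred_att = {i for i, c in calls.items() if c.attenuated}
    true_att = {i for i in concordant if truth.peptides[i].attenuated}
    attenuated = _prf(
        len(pred_att & true_att),
        len(pred_att - true_att),
        len(true_att - pred_att),
    )

    both = pred_att & true_att
    residual = {
        "exact_band_accuracy": (
            sum(1 for i in both
                if calls[i].residual_band == truth.peptides[i].residual_band) / len(both)
            if both else 1.0
        ),
        "n": len(both),
    }
    asterisk_acc = {
        "exact_accuracy": (
            sum(1 for i in both
                if calls[i].asterisks == truth.peptides[i].asterisks) / len(both)
            if both else 1.0
        ),
        "n": len(both),
    }

    pred2 = {i for i, c in calls.items() if c.attenuated and c.asterisks == 2}
    true2 = {i for i in concordant
             if truth.peptides[i].attenuated and truth.peptides[i].asterisks == 2}
    double = _prf(len(pred2 & true2), len(pred2 - true2), len(true2 - pred2))

    return {
        "differential": diff,
        "severity": severity,
        "attenuated": attenuated,
        "residual_band": residual,
        "asterisks": asterisk_acc,
        "double_asterisk": double,
    }
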