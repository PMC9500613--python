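"""Drug-attenuation classification of PTM sites with asterisk grading.

The procedure, per modified peptide:

1. *Vehicle concordance* — the two vehicle-group means must lie within
   10% of each other (symmetric relative difference), removing features
   that respond to the solvents themselves.
2. *Baseline* — the mean of the two vehicle means.
3. *Severity* of the model-group (MK-801) dysregulation from the signed
   fractional deviation from baseline: none (|dev| <= 10%), mild
   (10–25%], moderate (25–50%], severe (> 50%).
4. *Attenuation* — after co-treatment the deviation must fall strictly
   below the severity's own threshold, moving back toward control.
   The residual deviation is banded (< 10%, 10–25%, 25–50%) and the call
   earns one asterisk for every extra threshold crossed on the way back,
   so ``**`` is exactly a > ±50% disturbance returning to within ±10%
   of control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .differential import DifferentialResult
from .records import PeptideMeasurement, StudyDesign, Thresholds

__all__ = [
    "SEVERITIES",
    "RESIDUAL_BANDS",
    "AttenuationCall",
    "vehicle_concordance_filter",
    "classify_attenuation",
    "AttenuationClassifier",
    "attenuation_table",
    "render_attenuation_table",
    "calls_to_frame",
]

logger = logging.getLogger(__name__)

#: Severity labels indexed by band: index 0 = mild, 1 = moderate, 2 = severe.
SEVERITIES = ("mild", "moderate", "severe")
#: Residual-band labels, same indexing (lt10 = returned to within the
#: first band of control).
RESIDUAL_BANDS = ("lt10", "10to25", "25to50")


@dataclass
class AttenuationCall:
    """Classification of one feature's model-insult/co-treatment response."""

    baseline: float
    model_deviation: float  # signed fraction vs. baseline
    treated_deviation: float
    severity: str  # none | mild | moderate | severe
    residual_band: str  # lt10 | 10to25 | 25to50 | none
    asterisks: int
    attenuated: bool
    feature_id: int | None = None
    accession: str = ""
    peptide_sequence: str = ""
    ptm: str = ""


def vehicle_concordance_filter(
    mean_v1: float, mean_v2: float, tolerance: float = 0.10
) -> bool:
    """True iff the two vehicle means are within ``tolerance`` of each other.

    Concordance is measured as the symmetric relative difference
    ``|v1 - v2| / ((v1 + v2) / 2)``.
    """
    if mean_v1 <= 0 or mean_v2 <= 0:
        raise ValueError(
            f"vehicle means must be positive, got ({mean_v1}, {mean_v2})"
        )
    return abs(mean_v1 - mean_v2) / ((mean_v1 + mean_v2) / 2.0) <= tolerance


def _band_index(magnitude: float, bands: Sequence[float]) -> int:
    """Highest band index whose threshold is strictly exceeded, -1 if none.

    Exact-boundary values fall on the milder side (|dev| = bands[i] does
    not cross bands[i]).
    """
    idx = -1
    for i, b in enumerate(bands):
        if magnitude > b:
            idx = i
    return idx


def classify_attenuation(
    baseline: float,
    model_mean: float,
    treated_mean: float,
    bands: Sequence[float] = (0.10, 0.25, 0.50),
) -> AttenuationCall:
    """Classify one feature's dysregulation severity and attenuation.

    ``bands`` are the ordered dysregulation thresholds (fractions of the
    baseline). Severity comes from the model-group deviation magnitude;
    a feature is attenuated when the co-treatment deviation magnitude
    falls strictly below the severity's own threshold *and* strictly
    below the model deviation (movement toward control; overshoot past
    control counts by magnitude). Asterisks = severity band index minus
    residual band index.
    """
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    bands = tuple(bands)
    md = (model_mean - baseline) / baseline
    td = (treated_mean - baseline) / baseline

    sev_idx = _band_index(abs(md), bands)
    if sev_idx < 0:
        return AttenuationCall(baseline, md, td, "none", "none", 0, False)

    threshold = bands[sev_idx]
    attenuated = abs(td) < threshold and abs(td) < abs(md)
    if not attenuated:
        return AttenuationCall(baseline, md, td, SEVERITIES[sev_idx], "none", 0, False)

    # |td| < bands[sev_idx] <= bands[-1]: the residual always lands in a band
    # (half-open bands, [bands[i-1], bands[i]) at index i).
    res_idx = 0
    for i, b in enumerate(bands):
        if abs(td) >= b:
            res_idx = i + 1
    return AttenuationCall(
        baseline,
        md,
        td,
        SEVERITIES[sev_idx],
        RESIDUAL_BANDS[res_idx],
        sev_idx - res_idx,
        True,
    )


class AttenuationClassifier(BaseEstimator):
    """Vehicle-concordance filter + attenuation classifier (sklearn style).

    ``predict`` takes a DataFrame with columns ``vehicle1, vehicle2,
    model, treated`` (group means per feature) and returns one
    :class:`AttenuationCall` per concordant row.

    Attributes
    ----------
    concordant_ : pandas.Series of bool, vehicle-concordance per row.
    n_discordant_ : int
    """

    def __init__(
        self,
        bands: Sequence[float] = (0.10, 0.25, 0.50),
        vehicle_tolerance: float = 0.10,
    ):
        self.bands = bands
        self.vehicle_tolerance = vehicle_tolerance

    def fit(self, X: pd.DataFrame, y=None) -> "AttenuationClassifier":
        return self

    def predict(self, X: pd.DataFrame) -> dict:
        """Map row label -> AttenuationCall for concordant, positive rows."""
        concordant = {}
        calls = {}
        for label, row in X.iterrows():
            v1, v2 = float(row["vehicle1"]), float(row["vehicle2"])
            if v1 <= 0 or v2 <= 0:
                concordant[label] = False
                continue
            ok = vehicle_concordance_filter(v1, v2, self.vehicle_tolerance)
            concordant[label] = ok
            if not ok:
                continue
            baseline = (v1 + v2) / 2.0
            calls[label] = classify_attenuation(
                baseline, float(row["model"]), float(row["treated"]), self.bands
            )
        self.concordant_ = pd.Series(concordant)
        self.n_discordant_ = int((~self.concordant_).sum())
        return calls


def attenuation_table(
    peptides: Sequence[PeptideMeasurement],
    design: StudyDesign,
    thresholds: Thresholds | None = None,
    differential: Sequence[DifferentialResult] | None = None,
    require_significant: bool = False,
) -> list[AttenuationCall]:
    """Attenuation calls for every eligible modified peptide.

    The design must declare the vehicle1, vehicle2, model and treatment
    roles. Deviations are computed on linear-scale group means of the
    (normalized) peptide abundances. With ``require_significant`` the
    analysis is additionally restricted to peptides called
    differentially expressed by ANOVA (off by default: the band rules
    alone define eligibility).
    """
    thresholds = thresholds or Thresholds()
    for role in ("vehicle1", "vehicle2", "model", "treatment"):
        if role not in design.roles:
            raise ValueError(f"design does not declare the {role!r} role")
    by_group = design.samples_by_group
    role_samples = {role: by_group[design.roles[role]]
                    for role in ("vehicle1", "vehicle2", "model", "treatment")}

    sig_ids = None
    if require_significant:
        if differential is None:
            raise ValueError("require_significant needs differential results")
        sig_ids = {r.feature_id for r in differential if r.significant}

    rows = {}
    meta = {}
    for i, p in enumerate(peptides):
        if not p.is_acyl_modified:
            continue
        if sig_ids is not None and i not in sig_ids:
            continue
        means = {
            role: float(np.mean([p.abundances.get(s, 0.0) for s in samples]))
            for role, samples in role_samples.items()
        }
        if min(means.values()) <= 0:
            logger.warning("feature %d: non-positive group mean, excluded", i)
            continue
        rows[i] = {
            "vehicle1": means["vehicle1"],
            "vehicle2": means["vehicle2"],
            "model": means["model"],
            "treated": means["treatment"],
        }
        meta[i] = p

    frame = pd.DataFrame.from_dict(rows, orient="index")
    clf = AttenuationClassifier(
        bands=thresholds.bands, vehicle_tolerance=thresholds.vehicle_tolerance
    )
    calls = clf.predict(frame) if len(frame) else {}

    out: list[AttenuationCall] = []
    for i, call in calls.items():
        p = meta[i]
        call.feature_id = i
        call.accession = p.protein_accession
        call.peptide_sequence = p.peptide_sequence
        call.ptm = ";".join(sorted({n for n, _ in p.acyl_modifications}))
        out.append(call)
    return out


def calls_to_frame(calls: Sequence[AttenuationCall]) -> pd.DataFrame:
    """All attenuation calls as a flat table."""
    return pd.DataFrame(
        [
            {
                "feature_id": c.feature_id,
                "accession": c.accession,
                "peptide": c.peptide_sequence,
                "ptm": c.ptm,
                "baseline": c.baseline,
                "model_deviation": c.model_deviation,
                "treated_deviation": c.treated_deviation,
                "severity": c.severity,
                "residual_band": c.residual_band,
                "asterisks": c.asterisks,
                "attenuated": c.attenuated,
            }
            for c in calls
        ]
    )


def render_attenuation_table(
    calls: Sequence[AttenuationCall],
    treatment: str = "",
    gene_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Attenuated calls grouped into the published table layout.

    One row per attenuated peptide with columns ``[treatment, ptm, band,
    gene, asterisks, multi_peptide]``; ``multi_peptide`` marks proteins
    with more than one attenuated modified peptide (footnote-style).
    """
    attenuated = [c for c in calls if c.attenuated]
    n_per_acc: dict[tuple[str, str], int] = {}
    for c in attenuated:
        key = (c.accession, c.ptm)
        n_per_acc[key] = n_per_acc.get(key, 0) + 1
    band_order = {b: i for i, b in enumerate(RESIDUAL_BANDS)}
    attenuated.sort(key=lambda c: (c.ptm, band_order[c.residual_band],
                                   -c.asterisks, c.accession))
    rows = [
        {
            "treatment": treatment,
            "ptm": c.ptm,
            "band": c.residual_band,
            "gene": (gene_names or {}).get(c.accession, c.accession),
            "asterisks": "*" * c.asterisks,
            "multi_peptide": n_per_acc[(c.accession, c.ptm)] > 1,
        }
        for c in attenuated
    ]
    return pd.DataFrame(
        rows, columns=["treatment", "ptm", "band", "gene", "asterisks", "multi_peptide"]
    )
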