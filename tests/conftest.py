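import pytest
from hypothesis import HealthCheck, settings

from acylome import PeptideMeasurement, StudyDesign

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def design():
    """Two vehicles, model and treatment groups, 2 replicates each."""
    groups = ["veh1", "veh2", "mod", "trt"]
    return StudyDesign(
        samples=[(f"{g}_{r}", g) for g in groups for r in (1, 2)],
        roles={"vehicle1": "veh1", "vehicle2": "veh2",
               "model": "mod", "treatment": "trt"},
    )


@pytest.fixture
def make_peptide(design):
    """Factory for peptides with per-group abundances filled per sample."""

    def factory(sequence="AVLDETK", mods=(), group_means=None, **kwargs):
        group_means = group_means or {}
        abundances = {
            s: float(group_means.get(g, 100.0)) for s, g in design.samples
        }
        return PeptideMeasurement(
            peptide_sequence=sequence,
            modifications=list(mods),
            abundances=abundances,
            **kwargs,
        )

    return factory
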