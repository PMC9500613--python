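"""Vehicle concordance, severity/residual bands, asterisk grading."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from acylome.attenuation import (
    attenuation_table,
    classify_attenuation,
    render_attenuation_table,
    vehicle_concordance_filter,
)


class TestVehicleConcordance:
    def test_identical_means_pass(self):
        assert vehicle_concordance_filter(100, 100)

    def test_gap_just_over_tolerance_fails(self):
        # symmetric relative gap 11/105.5 ~ 0.1043 > 0.10
        assert not vehicle_concordance_filter(100, 111)

    def test_gap_under_tolerance_passes(self):
        # 10/105 ~ 0.0952 <= 0.10
        assert vehicle_concordance_filter(100, 110)

    def test_order_independent(self):
        assert vehicle_concordance_filter(110, 100) == vehicle_concordance_filter(100, 110)

    def test_non_positive_mean_is_error(self):
        with pytest.raises(ValueError):
            vehicle_concordance_filter(0.0, 100.0)


class TestClassifyAttenuation:
    @pytest.mark.parametrize(
        "model,treated,severity,band,asterisks,attenuated",
        [
            (100, 100, "none", "none", 0, False),
            (160, 105, "severe", "lt10", 2, True),  # the ** definition
            (70, 85, "moderate", "10to25", 0, True),
            (140, 138, "moderate", "none", 0, False),  # |treated| 0.38 >= 0.25
            (112, 104, "mild", "lt10", 0, True),
            (45, 92, "severe", "lt10", 2, True),  # downward severe, returned
            (180, 130, "severe", "25to50", 0, True),
            (126, 80, "moderate", "10to25", 0, True),  # overshoot by magnitude
        ],
    )
    def test_rule_table(self, model, treated, severity, band, asterisks, attenuated):
        call = classify_attenuation(100.0, model, treated)
        assert call.severity == severity
        assert call.residual_band == band
        assert call.asterisks == asterisks
        assert call.attenuated == attenuated

    def test_exact_boundary_falls_in_milder_class(self):
        assert classify_attenuation(100, 110, 100).severity == "none"
        assert classify_attenuation(100, 125, 100).severity == "mild"
        assert classify_attenuation(100, 150, 100).severity == "moderate"
        # residual exactly at 0.10 is not "returned to within 10%"
        call = classify_attenuation(100, 160, 110)
        assert call.residual_band == "10to25" and call.asterisks == 1

    def test_mild_requires_return_under_ten_percent(self):
        # mild severity's own threshold is 0.10: 0.12 residual not attenuated
        call = classify_attenuation(100, 120, 112)
        assert call.severity == "mild" and not call.attenuated

    def test_treated_must_move_toward_control(self):
        call = classify_attenuation(100, 112, 113)
        assert not call.attenuated

    def test_non_positive_baseline_is_error(self):
        with pytest.raises(ValueError, match="baseline"):
            classify_attenuation(0.0, 100, 100)

    @given(
        st.floats(-1, 1, allow_nan=False, width=32),
        st.floats(-1, 1, allow_nan=False, width=32),
    )
    def test_sign_flip_symmetry(self, md, td):
        """Direction-agnostic: flipping both deviations preserves the call."""
        a = classify_attenuation(100.0, 100.0 * (1 + md), 100.0 * (1 + td))
        b = classify_attenuation(100.0, 100.0 * (1 - md), 100.0 * (1 - td))
        assert (a.severity, a.residual_band, a.asterisks, a.attenuated) == (
            b.severity, b.residual_band, b.asterisks, b.attenuated)

    def test_monotone_in_shrinking_residual(self):
        """Shrinking |treated deviation| never loses attenuation/asterisks."""
        for md in np.linspace(-1, 1, 41):
            prev_ast, prev_att = None, None
            for t in np.linspace(0.8, 0.0, 81):
                call = classify_attenuation(
                    100.0, 100.0 * (1 + md), 100.0 * (1 + np.sign(md or 1) * t)
                )
                if prev_ast is not None:
                    assert call.asterisks >= prev_ast
                    assert call.attenuated >= prev_att
                if call.severity != "none":
                    prev_ast, prev_att = call.asterisks, call.attenuated

    def test_output_partition(self):
        """Each point is exactly one of: not-dysregulated, dysregulated-not-
        attenuated, or attenuated-with-one-residual-band."""
        rng = np.random.default_rng(5)
        for _ in range(500):
            md, td = rng.uniform(-1, 1, size=2)
            c = classify_attenuation(50.0, 50.0 * (1 + md), 50.0 * (1 + td))
            states = [
                c.severity == "none",
                c.severity != "none" and not c.attenuated,
                c.attenuated and c.residual_band in ("lt10", "10to25", "25to50"),
            ]
            assert sum(states) == 1
            assert (c.residual_band != "none") == c.attenuated


class TestAttenuationTable:
    def test_single_planted_severe_fully_attenuated(self, design, make_peptide):
        pep = make_peptide(
            "AVKLDTR", mods=[("succinyl", 3)],
            group_means={"veh1": 100, "veh2": 100, "mod": 160, "trt": 105},
        )
        calls = attenuation_table([pep], design)
        assert len(calls) == 1
        c = calls[0]
        assert c.attenuated and c.asterisks == 2 and c.residual_band == "lt10"
        table = render_attenuation_table(calls, treatment="trt")
        assert table["band"].tolist() == ["lt10"]
        assert table["asterisks"].tolist() == ["**"]

    def test_discordant_vehicles_yield_empty_table(self, design, make_peptide):
        pep = make_peptide(
            "AVKLDTR", mods=[("succinyl", 3)],
            group_means={"veh1": 100, "veh2": 150, "mod": 160, "trt": 105},
        )
        calls = attenuation_table([pep], design)
        assert calls == []

    def test_two_attenuated_peptides_one_protein_flagged(self, design, make_peptide):
        means = {"veh1": 100, "veh2": 100, "mod": 160, "trt": 105}
        peps = [
            make_peptide("AVKLDTR", mods=[("succinyl", 3)], group_means=means,
                         protein_accession="LRP"),
            make_peptide("GGKWETR", mods=[("succinyl", 3)], group_means=means,
                         protein_accession="LRP"),
        ]
        table = render_attenuation_table(attenuation_table(peps, design))
        assert len(table) == 2
        assert table["multi_peptide"].all()

    def test_missing_role_is_error(self, make_peptide):
        from acylome.records import StudyDesign

        design = StudyDesign(
            samples=[("a1", "g1"), ("a2", "g1"), ("b1", "g2"), ("b2", "g2")]
        )
        with pytest.raises(ValueError, match="role"):
            attenuation_table([], design)

    def test_unmodified_peptides_not_classified(self, design, make_peptide):
        assert attenuation_table([make_peptide("AVLDETK")], design) == []
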