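"""Synthetic-data generator: determinism, plants, recovery evaluation."""

import dataclasses

import numpy as np
import pytest

from acylome.attenuation import attenuation_table
from acylome.differential import call_differential
from acylome.simulate import (
    GroundTruth,
    SimulationParams,
    evaluate_recovery,
    generate,
    write_dataset,
)


def _small(**kw) -> SimulationParams:
    kw.setdefault("n_proteins", 40)
    kw.setdefault("seed", 11)
    return SimulationParams(**kw)


def _read_all(out_dir):
    return {p.name: p.read_bytes() for p in sorted(out_dir.iterdir())}


class TestGenerate:
    def test_same_seed_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_dataset(generate(_small()), a)
        write_dataset(generate(_small()), b)
        assert _read_all(a) == _read_all(b)

    def test_different_seed_differs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_dataset(generate(_small(seed=1)), a)
        write_dataset(generate(_small(seed=2)), b)
        assert _read_all(a) != _read_all(b)

    def test_no_modifications_when_fraction_zero(self):
        ds = generate(_small(frac_modified_peptides=0.0))
        assert all(not p.modifications for p in ds.peptides)
        assert ds.truth.peptides == {}

    def test_abundances_non_negative_and_acyl_on_k(self):
        ds = generate(_small())
        for p in ds.peptides:
            assert all(v >= 0 for v in p.abundances.values())
            for name, pos in p.acyl_modifications:
                assert p.peptide_sequence[pos - 1] == "K"

    def test_peptides_map_uniquely_into_proteins(self):
        ds = generate(_small())
        for p in ds.peptides:
            assert ds.proteome[p.protein_accession].count(p.peptide_sequence) == 1

    def test_planted_concordance_exact_on_noiseless_means(self):
        """The 10% vehicle rule is obeyed/violated exactly as planted."""
        from acylome.attenuation import vehicle_concordance_filter

        ds = generate(_small(noise_sigma=0.0, n_proteins=120,
                             vehicle_discordance_rate=0.3))
        v1 = ds.design.samples_by_group[ds.design.roles["vehicle1"]]
        v2 = ds.design.samples_by_group[ds.design.roles["vehicle2"]]
        for i, t in ds.truth.peptides.items():
            p = ds.peptides[i]
            m1 = float(np.mean([p.abundances[s] for s in v1]))
            m2 = float(np.mean([p.abundances[s] for s in v2]))
            assert vehicle_concordance_filter(m1, m2) == t.concordant

    def test_truth_consistent_with_classifier_on_noiseless_means(self):
        from acylome.attenuation import classify_attenuation

        ds = generate(_small(noise_sigma=0.0))
        groups = ds.design.samples_by_group
        roles = ds.design.roles
        for i, t in ds.truth.peptides.items():
            p = ds.peptides[i]
            mean = lambda role: float(
                np.mean([p.abundances[s] for s in groups[roles[role]]])
            )
            baseline = (mean("vehicle1") + mean("vehicle2")) / 2
            call = classify_attenuation(baseline, mean("model"), mean("treatment"))
            assert (call.severity, call.residual_band,
                    call.asterisks, call.attenuated) == (
                t.severity, t.residual_band, t.asterisks, t.attenuated)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(frac_modified_peptides=1.5).validate()
        with pytest.raises(ValueError):
            SimulationParams(n_replicates_per_group=1).validate()
        with pytest.raises(ValueError):
            SimulationParams(effect_bands=(0.5, 0.5, 0.5)).validate()


def _run_pipeline(ds):
    results = call_differential(ds.peptides, ds.design)
    calls = attenuation_table(ds.peptides, ds.design)
    return results, calls


class TestEvaluateRecovery:
    def test_zero_noise_recovery_is_exact(self):
        ds = generate(_small(noise_sigma=0.0, n_proteins=80))
        with pytest.warns(UserWarning):
            results, calls = _run_pipeline(ds)
        m = evaluate_recovery(results, calls, ds.truth)
        assert m["differential"]["f1"] == 1.0
        assert m["severity"]["accuracy"] == 1.0
        assert m["severity"]["coverage"] == 1.0
        assert m["attenuated"]["f1"] == 1.0
        assert m["residual_band"]["exact_band_accuracy"] == 1.0
        assert m["asterisks"]["exact_accuracy"] == 1.0
        assert m["double_asterisk"]["f1"] == 1.0

    def test_empty_predictions_zero_recall(self):
        ds = generate(_small())
        m = evaluate_recovery([], [], ds.truth)
        assert m["differential"]["recall"] == 0.0
        assert m["attenuated"]["recall"] == 0.0

    def test_unknown_feature_id_is_error(self):
        ds = generate(_small())
        from acylome.attenuation import AttenuationCall

        bogus = AttenuationCall(100.0, 0.0, 0.0, "none", "none", 0, False,
                                feature_id=10**9)
        with pytest.raises(ValueError, match="not in truth"):
            evaluate_recovery([], [bogus], ds.truth)

    def test_random_labels_near_chance(self):
        """Random attenuation guesses cannot beat the planted base rate."""
        ds = generate(_small(n_proteins=400, seed=3, noise_sigma=0.0))
        with pytest.warns(UserWarning):
            results, calls = _run_pipeline(ds)
        rng = np.random.default_rng(0)
        truth_ids = list(ds.truth.peptides)
        base_rate = float(np.mean(
            [t.attenuated and t.concordant for t in ds.truth.peptides.values()]
        ))
        ids = rng.choice(truth_ids, size=len(calls), replace=False)
        shuffled = [
            dataclasses.replace(c, feature_id=int(i)) for c, i in zip(calls, ids)
        ]
        m = evaluate_recovery(results, shuffled, ds.truth)
        # precision of random placement ~ base rate of attenuated truths
        assert m["attenuated"]["precision"] == pytest.approx(base_rate, abs=0.2)
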