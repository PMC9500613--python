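"""Hypergeometric ORA, BH FDR, dot-plot export."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from acylome.enrichment import (
    bh_fdr,
    dotplot_export,
    enrich,
    hypergeom_p,
    results_to_frame,
)
from acylome.records import Thresholds


def _enumeration_tail(k, K, n, N) -> Fraction:
    """Exact upper tail by direct enumeration of draw compositions."""
    total = comb(N, n)
    return sum(
        (Fraction(comb(K, j) * comb(N - K, n - j), total)
         for j in range(k, min(K, n) + 1)),
        Fraction(0),
    )


class TestHypergeom:
    def test_worked_example(self):
        # 66/252 by enumerating all C(10,5) draws
        assert hypergeom_p(3, 4, 5, 10) == pytest.approx(66 / 252, rel=1e-12)

    def test_zero_overlap_is_one(self):
        assert hypergeom_p(0, 4, 5, 10) == pytest.approx(1.0)

    def test_forced_full_overlap_is_one(self):
        assert hypergeom_p(5, 5, 5, 5) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_p(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_p(1, 4, 11, 10)

    @pytest.mark.parametrize("N", [1, 4, 9])
    def test_matches_enumeration_small_universe(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(max(0, K + n - N), min(K, n) + 1):
                    expected = float(_enumeration_tail(k, K, n, N))
                    assert hypergeom_p(k, K, n, N) == pytest.approx(
                        expected, rel=1e-10, abs=1e-14
                    )


class TestBhFdr:
    def test_hand_applied_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]).tolist() == [pytest.approx(0.3)]

    def test_ties_unchanged(self):
        assert bh_fdr([0.5] * 7).tolist() == pytest.approx([0.5] * 7)

    def test_order_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        assert bh_fdr(p[perm]).tolist() == pytest.approx(bh_fdr(p)[perm].tolist())

    def test_bounded_by_one(self):
        assert (bh_fdr([0.2, 0.9, 0.99, 1.0]) <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestEnrich:
    def _sets(self):
        target = {f"T{i}" for i in range(8)}
        decoys = {f"D{j}": {f"G{j}_{i}" for i in range(10)} for j in range(10)}
        return target, {"target_set": target, **decoys}

    def test_planted_set_has_minimal_p(self):
        target, sets = self._sets()
        background = set().union(*sets.values())
        results = enrich(target, sets, background, Thresholds())
        assert results[0].set_name == "target_set"
        assert results[0].p_value == min(r.p_value for r in results)
        assert results[0].passes

    def test_set_equal_to_background_has_p_one(self):
        bg = {"A", "B", "C"}
        (res,) = enrich({"A"}, {"S": set(bg)}, bg)
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_query_all_zero_overlap(self):
        results = enrich({"X"}, {"S": {"A", "B"}}, {"X", "A", "B"})
        assert all(r.k == 0 and not r.passes for r in results)

    def test_no_silent_filtering_with_permissive_thresholds(self):
        target, sets = self._sets()
        background = set().union(*sets.values())
        thr = Thresholds(enrich_fdr=1.0, enrich_p=1.0, min_pathway_genes=0)
        results = enrich(target, sets, background, thr)
        assert len(results) == len(sets)
        assert all(r.passes for r in results)

    def test_min_overlap_rule_blocks_small_pathways(self):
        target, sets = self._sets()
        background = set().union(*sets.values())
        query = set(list(target)[:4])  # overlap 4 < 5
        results = enrich(query, sets, background, Thresholds())
        by_name = {r.set_name: r for r in results}
        assert by_name["target_set"].k == 4
        assert not by_name["target_set"].passes

    def test_query_outside_background_dropped_with_log(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            enrich({"A", "ZZZ"}, {"S": {"A", "B"}}, {"A", "B"})
        assert "dropped" in caplog.text

    def test_empty_query_is_error(self):
        with pytest.raises(ValueError):
            enrich(set(), {"S": {"A"}}, {"A"})


class TestDotplot:
    def _results(self):
        target, sets = self._sets = TestEnrich()._sets()
        background = set().union(*sets.values())
        return enrich(target, sets, background, Thresholds())

    def test_empty_results_warn(self):
        with pytest.warns(UserWarning, match="no enrichment"):
            table, fig = dotplot_export({})
        assert table.empty and fig is None

    def test_single_passing_pathway_row(self, tmp_path):
        results = self._results()
        table, fig = dotplot_export(
            {("mk801", "succinyl", "up"): results},
            figure_path=tmp_path / "dot.svg",
        )
        assert len(table) == 1
        assert table.loc[0, "pathway"] == "target_set"
        assert (tmp_path / "dot.svg").exists()

    def test_shared_pathway_across_comparisons(self):
        results = self._results()
        table, _ = dotplot_export(
            {
                ("halo", "succinyl", "up"): results,
                ("chlor", "succinyl", "up"): results,
            }
        )
        assert len(table) == 2
        assert set(table["pathway"]) == {"target_set"}

    def test_frame_export_columns(self):
        frame = results_to_frame(self._results())
        assert {"set_name", "k", "K", "n", "N", "p", "fdr", "passes"} <= set(
            frame.columns
        )
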