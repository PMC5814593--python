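"""Fisher test, BH adjustment and the responsive-event compound rule."""

import numpy as np
import pandas as pd
import pytest

from juncsplice.annotation import ValidationError
from juncsplice.diffsplice import (
    bh_adjust,
    call_responsive,
    collect_dsgs,
    fisher_exact_2x2,
)

from oracles import bh_step_up, fisher_two_sided


class TestFisher:
    def test_identical_proportions(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_extreme_table_matches_enumeration(self):
        p = fisher_exact_2x2(10, 0, 0, 10)
        assert p == pytest.approx(fisher_two_sided(10, 0, 0, 10), abs=1e-12)
        assert p == pytest.approx(1.08e-5, rel=0.01)

    @pytest.mark.parametrize("table", [(0, 0, 3, 7), (3, 7, 0, 0), (0, 3, 0, 7)])
    def test_zero_margin_is_uninformative(self, table):
        assert fisher_exact_2x2(*table) == 1.0

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_agrees_with_enumeration_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_two_sided(int(a), int(b), int(c), int(d)), abs=1e-10
            )

    def test_agrees_with_scipy_reference(self):
        from scipy import stats

        rng = np.random.default_rng(17)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 80, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]])[1], abs=1e-10
            )

    def test_label_swap_preserves_p(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_exact_2x2(c, d, a, b), abs=1e-12
            )


class TestBH:
    def test_hand_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_test_unchanged(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert bh_adjust(p[perm]) == pytest.approx(bh_adjust(p)[perm])

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(bh_step_up(list(p)), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=30)
        assert (bh_adjust(p) >= p - 1e-15).all()


def _quants_from_tables(tables):
    """Build a quants frame: tables[event] = {sample: (n1, n2)}."""
    rows = []
    for ev, by_sample in tables.items():
        for s, (n1, n2) in by_sample.items():
            total = n1 + n2
            rows.append(
                {
                    "event_id": ev,
                    "sample_id": s,
                    "n1": n1,
                    "n2": n2,
                    "iep": n1 / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


SAMPLES = ["CK_1h_r1", "CK_1h_r2", "HS_1h_r1", "HS_1h_r2"]


class TestCallResponsive:
    def _call(self, tables, design, **kwargs):
        return call_responsive(_quants_from_tables(tables), design, **kwargs)

    def test_large_consistent_shift_called(self, two_condition_design):
        tables = {
            "e1": {
                "CK_1h_r1": (70, 30), "CK_1h_r2": (70, 30),
                "HS_1h_r1": (20, 80), "HS_1h_r2": (20, 80),
            }
        }
        _, summary = self._call(tables, two_condition_design)
        row = summary.iloc[0]
        assert row["responsive"]
        assert row["delta_rep1"] == pytest.approx(-0.50)
        assert row["delta_rep2"] == pytest.approx(-0.50)

    def test_opposite_signs_not_responsive(self, two_condition_design):
        tables = {
            "e1": {
                "CK_1h_r1": (50, 50), "CK_1h_r2": (50, 50),
                "HS_1h_r1": (85, 15), "HS_1h_r2": (15, 85),
            }
        }
        _, summary = self._call(tables, two_condition_design)
        assert not summary.iloc[0]["responsive"]

    def test_delta_below_30pct_not_responsive(self, two_condition_design):
        """|dIEP| = 0.29 in one replicate fails the >= 30% change rule."""
        tables = {
            "e1": {
                "CK_1h_r1": (500, 500), "CK_1h_r2": (500, 500),
                "HS_1h_r1": (790, 210), "HS_1h_r2": (900, 100),
            }
        }
        _, summary = self._call(tables, two_condition_design)
        row = summary.iloc[0]
        assert row["delta_rep1"] == pytest.approx(0.29)
        assert min(row["q_rep1"], row["q_rep2"]) < 1e-6
        assert not row["responsive"]

    def test_boundary_delta_exactly_30pct_passes_threshold(self, two_condition_design):
        tables = {
            "e1": {
                "CK_1h_r1": (500, 500), "CK_1h_r2": (500, 500),
                "HS_1h_r1": (800, 200), "HS_1h_r2": (800, 200),
            }
        }
        _, summary = self._call(tables, two_condition_design)
        assert summary.iloc[0]["responsive"]

    def test_requires_exactly_two_replicates(self):
        design = pd.DataFrame(
            [
                {"sample_id": "CK_1h_r1", "condition": "CK", "timepoint": "1h", "replicate": 1},
                {"sample_id": "HS_1h_r1", "condition": "HS", "timepoint": "1h", "replicate": 1},
            ]
        )
        tables = {"e1": {"CK_1h_r1": (50, 50), "HS_1h_r1": (10, 90)}}
        with pytest.raises(ValidationError, match="2 replicates"):
            call_responsive(_quants_from_tables(tables), design)

    def test_undefined_iep_sample_excludes_event(self, two_condition_design):
        tables = {
            "e1": {
                "CK_1h_r1": (0, 0), "CK_1h_r2": (70, 30),
                "HS_1h_r1": (20, 80), "HS_1h_r2": (20, 80),
            }
        }
        _, summary = self._call(tables, two_condition_design)
        assert summary.empty

    def test_label_swap_negates_delta_and_preserves_p(self, two_condition_design):
        tables = {
            "e1": {
                "CK_1h_r1": (70, 30), "CK_1h_r2": (60, 40),
                "HS_1h_r1": (20, 80), "HS_1h_r2": (30, 70),
            }
        }
        results, _ = self._call(tables, two_condition_design)
        swapped_tables = {
            "e1": {
                "CK_1h_r1": tables["e1"]["HS_1h_r1"],
                "CK_1h_r2": tables["e1"]["HS_1h_r2"],
                "HS_1h_r1": tables["e1"]["CK_1h_r1"],
                "HS_1h_r2": tables["e1"]["CK_1h_r2"],
            }
        }
        swapped, _ = self._call(swapped_tables, two_condition_design)
        assert swapped["delta_iep"].to_numpy() == pytest.approx(
            -results["delta_iep"].to_numpy()
        )
        assert swapped["p"].to_numpy() == pytest.approx(results["p"].to_numpy())

    def test_pooled_mode_single_test(self, two_condition_design):
        tables = {
            "e1": {
                "CK_1h_r1": (35, 15), "CK_1h_r2": (35, 15),
                "HS_1h_r1": (10, 40), "HS_1h_r2": (10, 40),
            }
        }
        _, summary = self._call(tables, two_condition_design, pool_replicates=True)
        assert summary.iloc[0]["responsive"]
        assert summary.iloc[0]["delta_rep1"] == summary.iloc[0]["delta_rep2"]


class TestDsgs:
    def test_gene_sets_per_condition_and_timepoint(self):
        summary = pd.DataFrame(
            [
                {"event_id": "e1", "condition": "HS", "timepoint": "1h", "responsive": True},
                {"event_id": "e2", "condition": "HD", "timepoint": "6h", "responsive": True},
                {"event_id": "e3", "condition": "HS", "timepoint": "6h", "responsive": False},
            ]
        )
        mapping = {"e1": "g1", "e2": "g1", "e3": "g2"}
        by_cond, by_tp = collect_dsgs(summary, mapping)
        assert by_cond == {"HS": {"g1"}, "HD": {"g1"}}
        assert by_tp == {("HS", "1h"): {"g1"}, ("HD", "6h"): {"g1"}}

    def test_no_responsive_events_no_sets(self):
        summary = pd.DataFrame(
            [{"event_id": "e1", "condition": "HS", "timepoint": "1h", "responsive": False}]
        )
        by_cond, _ = collect_dsgs(summary, {"e1": "g1"})
        assert by_cond == {}
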