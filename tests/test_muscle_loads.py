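import numpy as np
import pytest
from hypothesis import given, strategies as st

import jawfem as jf
from jawfem.errors import DistributionError, ParameterError
from jawfem.geometry import BALANCING_SIDE, WORKING_SIDE
from jawfem.muscle_loads import (MUSCLE_NUMBER_SCHEDULE, apply_proportions,
                                 build_load_case, default_scheme,
                                 distribute_traction, split_bilateral,
                                 subdivide_by_area)


class TestBilateralSplit:
    @pytest.mark.parametrize("r,expect", [
        (0.0, (1000.0, 0.0)),
        (1.0, (500.0, 500.0)),
        (0.6, (625.0, 375.0)),
    ])
    def test_worked_values(self, r, expect):
        assert split_bilateral(1000.0, r) == pytest.approx(expect)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_split_conserves_total_and_orders_sides(self, r):
        w, b = split_bilateral(1000.0, r)
        assert w + b == pytest.approx(1000.0, rel=1e-12)
        assert w >= b >= 0.0

    def test_out_of_range_ratio_rejected(self):
        with pytest.raises(ParameterError):
            split_bilateral(1000.0, 1.5)


class TestProportions:
    def test_base_ratio_budgets(self):
        b = apply_proportions(1000.0, (55, 26, 9, 10))
        assert b == pytest.approx({"temporalis": 550.0, "masseter": 260.0,
                                   "zygomaticomandibularis": 90.0,
                                   "pterygoid": 100.0})

    def test_temporalis_isolation(self):
        b = apply_proportions(1000.0, (100, 0, 0, 0))
        assert b["temporalis"] == 1000.0
        assert all(v == 0 for k, v in b.items() if k != "temporalis")

    def test_55_30_15_model(self):
        b = apply_proportions(1000.0, (55, 30, 0, 15))
        assert b == pytest.approx({"temporalis": 550.0, "masseter": 300.0,
                                   "zygomaticomandibularis": 0.0,
                                   "pterygoid": 150.0})

    def test_zygomatic_share_folds_into_masseter_when_absent(self):
        b = apply_proportions(100.0, (55, 26, 9, 10),
                              present=("temporalis", "masseter", "pterygoid"))
        assert b["masseter"] == pytest.approx(35.0)
        assert b["temporalis"] == pytest.approx(55.0)
        assert "zygomaticomandibularis" not in b

    def test_percentages_must_sum_to_100(self):
        with pytest.raises(ParameterError):
            apply_proportions(1000.0, (55, 26, 9, 5))


class TestAreaSubdivision:
    def test_proportional_split(self):
        assert subdivide_by_area(100.0, [1, 3]) == pytest.approx([25.0, 75.0])

    def test_single_patch_identity(self):
        assert subdivide_by_area(42.0, [7.7]) == pytest.approx([42.0])

    def test_equal_areas(self):
        assert subdivide_by_area(90.0, [2, 2, 2]) == pytest.approx([30.0] * 3)

    def test_zero_area_rejected(self):
        with pytest.raises(DistributionError):
            subdivide_by_area(10.0, [1.0, 0.0])


class TestTraction:
    def test_single_triangle_equal_split_toward_target(self):
        mesh = jf.build_beam_fixture(1, 1, 1, 1)
        tri = mesh.surface_tris[0]
        target = mesh.nodes[tri].mean(axis=0) + np.array([0.0, 0.0, 100.0])
        out = distribute_traction(mesh, tri, np.ones(3), 30.0, target)
        mags = np.linalg.norm(out[tri], axis=1)
        assert mags == pytest.approx([10.0, 10.0, 10.0])
        d = out[tri] / mags[:, None]
        expect = target - mesh.nodes[tri]
        expect /= np.linalg.norm(expect, axis=1)[:, None]
        assert np.allclose(d, expect)

    def test_far_target_resultant_approaches_budget(self, mandible_l1):
        key = "M.s:working"
        nodes = mandible_l1.patch_nodes[key]
        w = mandible_l1.node_surface_weights()[nodes]
        far = np.array([0.0, 0.0, 1e7])
        out = distribute_traction(mandible_l1, nodes, w, 100.0, far)
        assert np.linalg.norm(out.sum(axis=0)) == pytest.approx(100.0, rel=1e-5)

    def test_curved_patch_resultant_bounded_by_budget(self, mandible_l1):
        key = "T.s:working"
        nodes = mandible_l1.patch_nodes[key]
        w = mandible_l1.node_surface_weights()[nodes]
        target = mandible_l1.patch_targets[key]
        out = distribute_traction(mandible_l1, nodes, w, 100.0, target)
        assert np.linalg.norm(out.sum(axis=0)) <= 100.0 + 1e-9


class TestLoadCase:
    @pytest.mark.parametrize("n_groups", list(MUSCLE_NUMBER_SCHEDULE))
    def test_magnitude_conservation_every_model(self, mandible_l1, n_groups):
        lc = build_load_case(mandible_l1, n_groups=n_groups)
        total = np.linalg.norm(lc.nodal_forces, axis=1).sum()
        assert total == pytest.approx(1000.0, rel=1e-9)

    @pytest.mark.parametrize("r", [0.0, 0.3, 1.0])
    def test_magnitude_conservation_across_ratios(self, mandible_l1, r):
        lc = build_load_case(mandible_l1, r=r)
        total = np.linalg.norm(lc.nodal_forces, axis=1).sum()
        assert total == pytest.approx(1000.0, rel=1e-9)

    def test_no_balancing_side_forces_at_zero_ratio(self, mandible_l1):
        lc = build_load_case(mandible_l1, r=0.0)
        balancing = mandible_l1.nodes[:, 1] > 0
        assert np.abs(lc.nodal_forces[balancing]).max() == 0.0

    def test_single_muscle_model_loads_only_temporalis(self, mandible_l1):
        lc = build_load_case(mandible_l1, n_groups=1)
        loaded = set(np.nonzero(
            np.linalg.norm(lc.nodal_forces, axis=1) > 0)[0])
        temporalis = set()
        for side in (WORKING_SIDE, BALANCING_SIDE):
            for sp in ("T.s", "T.p", "T.z"):
                temporalis |= set(
                    mandible_l1.patch_nodes[f"{sp}:{side}"].tolist())
        assert loaded <= temporalis
        assert sum(lc.per_group_budget.values()) == pytest.approx(1000.0)

    def test_scheme_fraction_sums_validated(self, mandible_l1):
        s = default_scheme(mandible_l1)
        for side in (WORKING_SIDE, BALANCING_SIDE):
            frac = sum(g.fraction for g in s.groups if g.side == side)
            assert frac == pytest.approx(1.0, abs=1e-12)

    def test_side_budgets_mirror_on_side_swap(self, mandible_l1):
        lc = build_load_case(mandible_l1, r=0.6)
        w = sum(v for k, v in lc.per_group_budget.items()
                if k.endswith(WORKING_SIDE))
        b = sum(v for k, v in lc.per_group_budget.items()
                if k.endswith(BALANCING_SIDE))
        assert w == pytest.approx(625.0, rel=1e-12)
        assert b == pytest.approx(375.0, rel=1e-12)
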