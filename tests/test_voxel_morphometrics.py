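"""Voxel morphometrics: volumes, surface areas, sphericity, LAC stats,
composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sxtmorph import voxel_morphometrics as vm
from sxtmorph.phantoms import make_sphere_mask, make_lobed_shape
from sxtmorph.volume_io import LABEL_IDS, LACVolume, LabeledVolume


class TestLabelVolume:
    def test_cube_and_empty(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[1:11, 1:11, 1:11] = True
        assert vm.label_volume(mask, 0.1) == pytest.approx(1.0)
        assert vm.label_volume(np.zeros((3, 3, 3), bool), 0.1) == 0.0

    @pytest.mark.parametrize("radius", [0.5, 1.0, 2.0])
    def test_sphere_within_one_percent(self, radius):
        voxel = radius / 25
        mask, truth = make_sphere_mask(radius, voxel)
        assert vm.label_volume(mask, voxel) == \
            pytest.approx(truth.volume_um3, rel=0.01)

    def test_error_decreases_with_resolution(self):
        errors = []
        for ratio in (10, 20, 40):
            voxel = 1.0 / ratio
            mask, truth = make_sphere_mask(1.0, voxel)
            errors.append(abs(vm.label_volume(mask, voxel)
                              - truth.volume_um3) / truth.volume_um3)
        assert errors[2] < errors[0]

    def test_additive_over_disjoint_components(self):
        a = np.zeros((10, 10, 10), bool)
        a[1:3, 1:3, 1:3] = True
        b = np.zeros_like(a)
        b[6:9, 6:9, 6:9] = True
        assert vm.label_volume(a | b, 0.1) == \
            pytest.approx(vm.label_volume(a, 0.1) + vm.label_volume(b, 0.1))


class TestVoxelSurfaceArea:
    def test_single_voxel_and_cube(self):
        single = np.zeros((3, 3, 3), bool)
        single[1, 1, 1] = True
        assert vm.voxel_surface_area(single, 0.1) == pytest.approx(6 * 0.01)
        cube = np.zeros((12, 12, 12), bool)
        cube[1:11, 1:11, 1:11] = True
        assert vm.voxel_surface_area(cube, 0.1) == pytest.approx(600 * 0.01)

    def test_sphere_overestimates_analytic_by_half(self):
        # voxel faces overestimate smooth surface area by a factor ~1.5
        mask, truth = make_sphere_mask(1.0, 0.04)
        ratio = vm.voxel_surface_area(mask, 0.04) / truth.area_um2
        assert 1.4 < ratio < 1.6

    def test_rotation90_invariant(self):
        rng = np.random.default_rng(0)
        mask = rng.random((8, 8, 8)) > 0.6
        base = vm.voxel_surface_area(mask, 0.1)
        assert vm.voxel_surface_area(np.rot90(mask, axes=(0, 2)), 0.1) == base


class TestSphericity:
    def test_sphere_is_one(self):
        r = 0.73
        assert vm.sphericity(4 / 3 * np.pi * r ** 3, 4 * np.pi * r ** 2) \
            == pytest.approx(1.0)

    def test_cube_closed_form(self):
        s = 1.7
        assert vm.sphericity(s ** 3, 6 * s ** 2) == \
            pytest.approx(np.pi ** (1 / 3) * 6 ** (2 / 3) / 6, rel=1e-12)
        assert vm.sphericity(1.0, 6.0) == pytest.approx(0.80600, abs=5e-6)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            vm.sphericity(0.0, 1.0)
        with pytest.raises(ValueError):
            vm.sphericity(1.0, -1.0)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.01, 100.0))
    def test_scale_invariance(self, k):
        base = vm.sphericity(1.3, 7.1)
        scaled = vm.sphericity(k * 1.3, k ** (2 / 3) * 7.1)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_lobed_below_sphere(self):
        lobed, _ = make_lobed_shape(3, seed=7, voxel_um=0.05)
        sphere, _ = make_sphere_mask(0.8, 0.05)

        def sph(mask):
            return vm.sphericity(vm.label_volume(mask, 0.05),
                                 vm.voxel_surface_area(mask, 0.05))
        assert sph(lobed) < sph(sphere)


class TestLacStats:
    def test_constant_field(self):
        lac = LACVolume(np.full((4, 4, 4), 0.3, np.float32), 0.1)
        labels = LabeledVolume(np.ones((4, 4, 4), np.int32), 0.1)
        mean, sd = vm.lac_stats(lac, labels, 1)
        assert mean == pytest.approx(0.3)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_five_voxels(self):
        values = [0.1, 0.2, 0.3, 0.4, 0.5]
        data = np.zeros((5, 1, 1), np.float32)
        data[:, 0, 0] = values
        labels = np.ones((5, 1, 1), np.int32)
        mean, sd = vm.lac_stats(LACVolume(data, 0.1),
                                LabeledVolume(labels, 0.1), 1)
        assert mean == pytest.approx(0.3)
        # hand computation: Σ(x−x̄)² = 0.10, sample variance 0.10/4 = 0.025
        assert sd == pytest.approx(np.sqrt(0.025), rel=1e-6)

    def test_phantom_vacuole_mean(self, small_scene):
        lac, labels, _ = small_scene
        mean, sd = vm.lac_stats(lac, labels, "vacuole")
        n = int(labels.mask("vacuole").sum())
        se = 0.039 / np.sqrt(n)
        assert abs(mean - 0.182) < 3 * se + 1e-3

    def test_empty_label_raises(self):
        lac = LACVolume(np.zeros((3, 3, 3), np.float32), 0.1)
        labels = LabeledVolume(np.zeros((3, 3, 3), np.int32), 0.1)
        with pytest.raises(ValueError):
            vm.lac_stats(lac, labels, 4)


class TestComposition:
    def test_no_organelles(self):
        fractions = vm.composition(10.0, {"nucleus": 0.0, "vacuole": 0.0})
        assert fractions["remaining_cytoplasm"] == 1.0

    def test_fractions_sum_to_one(self):
        fractions = vm.composition(10.0, {"nucleus": 1.0, "vacuole": 2.5,
                                          "lipid_droplet": 0.01})
        assert sum(fractions.values()) == pytest.approx(1.0)
        assert fractions["vacuole"] == pytest.approx(0.25)

    def test_overfull_cell_rejected(self):
        with pytest.raises(ValueError):
            vm.composition(1.0, {"vacuole": 1.5})

    def test_constructed_quarter_vacuole(self):
        # vacuole occupies 25% of the cell voxels by construction
        data = np.zeros((10, 10, 10), np.int32)
        data[1:9, 1:9, 1:9] = LABEL_IDS["cell"]
        cell_voxels = int((data > 0).sum())
        target = cell_voxels // 4
        filled = 0
        it = np.ndindex(data.shape)
        for idx in it:
            if filled >= target:
                break
            if data[idx] == LABEL_IDS["cell"]:
                data[idx] = LABEL_IDS["vacuole"]
                filled += 1
        labels = LabeledVolume(data, 0.1)
        records = vm.measure_cell(None, labels, per_component=False)
        vac = [r for r in records if r.structure == "vacuole"
               and r.component == 0][0]
        assert vac.volume_fraction == pytest.approx(0.25, abs=1e-9)


class TestMeasureScene:
    def test_per_cell_records(self, small_scene):
        lac, labels, instances = small_scene
        records = vm.measure_scene(lac, labels, instances, strain="wt")
        cell_ids = {r.cell_id for r in records}
        assert cell_ids == {1, 2}
        for cid in cell_ids:
            rows = [r for r in records if r.cell_id == cid]
            aggregates = {r.structure: r for r in rows if r.component == 0}
            assert "cell" in aggregates
            # organelle fractions plus remaining cytoplasm sum to 1
            fracs = sum(r.volume_fraction for r in rows
                        if r.component == 0 and r.structure != "cell"
                        and r.volume_fraction is not None)
            assert fracs == pytest.approx(1.0, abs=1e-9)
            organelle_vol = sum(r.volume_um3 for r in rows
                                if r.component == 0
                                and r.structure in vm.ORGANELLES)
            assert organelle_vol <= aggregates["cell"].volume_um3 + 1e-9
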