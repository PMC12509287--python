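"""Shared fixtures: phantom volumes and meshes reused across test modules.

Everything is generated programmatically at test time; expensive artifacts
(refined meshes, multi-cell scenes) are session-scoped.
"""

from dataclasses import replace

import numpy as np
import pytest

from sxtmorph import mesh_pipeline as mp
from sxtmorph import phantoms
from sxtmorph.volume_io import LabeledVolume


@pytest.fixture(scope="session")
def sphere_mask_005():
    """R = 1 µm ball voxelized at 0.05 µm with its analytic truth."""
    return phantoms.make_sphere_mask(1.0, 0.05)


@pytest.fixture(scope="session")
def sphere_mesh_raw(sphere_mask_005):
    mask, _truth = sphere_mask_005
    return mp.extract_surface(mask, 0.05)


@pytest.fixture(scope="session")
def sphere_mesh_refined(sphere_mesh_raw):
    return mp.refine_mesh(sphere_mesh_raw)


@pytest.fixture(scope="session")
def small_scene():
    """Two-cell scene at a coarse voxel size, with instance ground truth."""
    params = phantoms.scaled_params(0.5, voxel_um=0.08)
    lac, labels, instances = phantoms.make_cell_scene(
        2, params, seed=42, field_um=6.0, return_instances=True)
    return lac, labels, instances


@pytest.fixture(scope="session")
def training_cell():
    """One representative phantom cell crop for segmenter tests.

    Full-size cell at a 0.08 µm voxel with a couple of medium-large
    vacuoles, cropped to its bounding box plus margin.
    """
    from sxtmorph import presegment

    params = replace(phantoms.StrainParams(), voxel_um=0.08,
                     vacuole_count=(2, 3), vacuole_volume_um3=(1.5, 3.0),
                     ld_count=(0, 0))
    lac, labels, instances = phantoms.make_cell_scene(
        1, params, seed=5, field_um=7.0, return_instances=True)
    crop = presegment.crop_instances(lac, instances, margin_voxels=3)[0]
    crop_labels = LabeledVolume(labels.data[crop.bbox], labels.voxel_um)
    return crop.lac, crop_labels


@pytest.fixture(scope="session")
def flat_contact_meshes():
    """Plane-clipped sphere pair meshed raw (facets exactly planar)."""
    mask_a, mask_b = phantoms.make_flat_contact_pair()
    return (mp.extract_surface(mask_a, 0.04),
            mp.extract_surface(mask_b, 0.04))
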