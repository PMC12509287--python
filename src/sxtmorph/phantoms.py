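"""Synthetic SXT phantoms with analytically known ground truth.

Every downstream stage (presegmentation, segmentation, voxel morphometrics,
meshing, curvature, interface detection, cohort statistics) is testable on
these phantoms without any external data.  The generator emulates soft
X-ray tomograms of budding yeast: multi-cell scenes inside a capillary at
isotropic voxel sizes of 30–36 nm, where each labeled compartment draws its
linear absorption coefficient (LAC, µm⁻¹) from the organelle-specific
Gaussian measured on real tomograms — vacuole 0.182 (±0.039), nucleus
0.310 (±0.020), lipid droplet 0.570 (±0.111), cytosol 0.346 (±0.027),
mitochondria 0.382 (±0.018).

Conventions
-----------
Voxelization is by voxel-center inclusion: a voxel belongs to a shape when
its center does.  Indices are 0-based ``(z, y, x)`` and the physical
position of a voxel center is ``index * voxel_um``.  Per-voxel LAC noise is
i.i.d. Gaussian truncated at zero (negative draws are set to 0); this is a
declared stand-in, not a claim about instrument physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, ndimage

from .volume_io import LABEL_IDS, LACVolume, LabeledVolume, SEMANTIC_LABELS

#: Printed per-compartment LAC mean and SD in µm⁻¹ (mitochondria are not a
#: segmentation label here but the measured value is kept for reference).
LAC_DEFAULTS: dict[str, tuple[float, float]] = {
    "background": (0.0, 0.005),
    "cell": (0.346, 0.027),        # cytosol
    "nucleus": (0.310, 0.020),
    "vacuole": (0.182, 0.039),
    "lipid_droplet": (0.570, 0.111),
    "mitochondria": (0.382, 0.018),
}

#: Default isotropic voxel size (µm), midpoint of the 30–36 nm range.
DEFAULT_VOXEL_UM = 0.033


class PlacementError(RuntimeError):
    """Raised when a scene is too crowded to place the requested objects."""


@dataclass(frozen=True)
class ShapeTruth:
    """Analytic ground truth for one phantom shape."""

    volume_um3: float
    area_um2: float
    mean_H_per_um: float | None = None   # 1/R for a sphere
    mean_K_per_um2: float | None = None  # 1/R² for a sphere
    genus: int = 0

    def __post_init__(self) -> None:
        if not (self.volume_um3 > 0 and self.area_um2 > 0):
            raise ValueError("truth volume and area must be positive")
        if self.genus < 0:
            raise ValueError("genus must be non-negative")


@dataclass(frozen=True)
class StrainParams:
    """Generator parameters for one phantom strain.

    Size ranges are in µm³ per organelle instance; counts are inclusive
    ranges.  Yeast-scale defaults: cell radius 1.8–2.6 µm, one nucleus of
    2–5 µm³, 1–10 vacuoles of 0.3–3 µm³, 0–5 lipid droplets of
    0.02–0.08 µm³.
    """

    lac: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(LAC_DEFAULTS))
    voxel_um: float = DEFAULT_VOXEL_UM
    cell_radius_um: tuple[float, float] = (1.8, 2.6)
    nucleus_volume_um3: tuple[float, float] = (2.0, 5.0)
    vacuole_count: tuple[int, int] = (1, 10)
    vacuole_volume_um3: tuple[float, float] = (0.3, 3.0)
    ld_count: tuple[int, int] = (0, 5)
    ld_volume_um3: tuple[float, float] = (0.02, 0.08)

    def __post_init__(self) -> None:
        for name, (mean, _sd) in self.lac.items():
            if name != "background" and mean <= 0:
                raise ValueError(f"LAC mean for {name!r} must be positive")
        if not self.voxel_um > 0:
            raise ValueError("voxel size must be positive")


# ---------------------------------------------------------------------------
# analytic shapes

def _grid_coords(grid_shape: tuple[int, int, int], voxel_um: float):
    axes = [np.arange(n) * voxel_um for n in grid_shape]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _auto_grid(extent_um: np.ndarray, voxel_um: float,
               margin_voxels: int = 2) -> tuple[int, ...]:
    return tuple(int(np.ceil(e / voxel_um)) + 2 * margin_voxels + 1
                 for e in extent_um)


def make_sphere_mask(radius_um: float, voxel_um: float,
                     center: tuple[float, float, float] | None = None,
                     grid_shape: tuple[int, int, int] | None = None,
                     ) -> tuple[np.ndarray, ShapeTruth]:
    """Voxelize a ball; truth carries V = 4πR³/3, A = 4πR², H = 1/R, K = 1/R².

    The sphere must lie fully inside the grid (clipping raises).
    """
    if radius_um < 3 * voxel_um:
        raise ValueError("radius must be at least 3 voxels for a faithful mask")
    if grid_shape is None:
        grid_shape = _auto_grid(np.full(3, 2 * radius_um), voxel_um)
    if center is None:
        center = tuple((n - 1) * voxel_um / 2 for n in grid_shape)
    lo = np.asarray(center) - radius_um
    hi = np.asarray(center) + radius_um
    extents = (np.asarray(grid_shape) - 1) * voxel_um
    if (lo < 0).any() or (hi > extents).any():
        raise ValueError("sphere clipped by grid boundary")
    zz, yy, xx = _grid_coords(grid_shape, voxel_um)
    mask = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius_um ** 2
    truth = ShapeTruth(volume_um3=4 / 3 * np.pi * radius_um ** 3,
                       area_um2=4 * np.pi * radius_um ** 2,
                       mean_H_per_um=1 / radius_um,
                       mean_K_per_um2=1 / radius_um ** 2)
    return mask, truth


def ellipsoid_area(a: float, b: float, c: float) -> float:
    """Ellipsoid surface area by numerical quadrature of the area integral."""
    def integrand(theta, phi):
        st, ct = np.sin(theta), np.cos(theta)
        sp, cp = np.sin(phi), np.cos(phi)
        # |∂r/∂θ × ∂r/∂φ| for r = (a st cp, b st sp, c ct)
        return st * np.sqrt((b * c * st * cp) ** 2
                            + (a * c * st * sp) ** 2
                            + (a * b * ct) ** 2)
    area, _err = integrate.dblquad(integrand, 0, 2 * np.pi, 0, np.pi,
                                   epsabs=1e-10, epsrel=1e-10)
    return area


def make_ellipsoid_mask(a: float, b: float, c: float, voxel_um: float,
                        center: tuple[float, float, float] | None = None,
                        grid_shape: tuple[int, int, int] | None = None,
                        ) -> tuple[np.ndarray, ShapeTruth]:
    """Voxelize an axis-aligned ellipsoid with semi-axes (a, b, c) along (z, y, x)."""
    semi = np.array([a, b, c], float)
    if (semi < 3 * voxel_um).any():
        raise ValueError("semi-axes must be at least 3 voxels")
    if grid_shape is None:
        grid_shape = _auto_grid(2 * semi, voxel_um)
    if center is None:
        center = tuple((n - 1) * voxel_um / 2 for n in grid_shape)
    extents = (np.asarray(grid_shape) - 1) * voxel_um
    if ((np.asarray(center) - semi) < 0).any() or \
            ((np.asarray(center) + semi) > extents).any():
        raise ValueError("ellipsoid clipped by grid boundary")
    zz, yy, xx = _grid_coords(grid_shape, voxel_um)
    mask = (((zz - center[0]) / a) ** 2 + ((yy - center[1]) / b) ** 2
            + ((xx - center[2]) / c) ** 2) <= 1.0
    sphere_like = np.isclose(a, b) and np.isclose(b, c)
    truth = ShapeTruth(
        volume_um3=4 / 3 * np.pi * a * b * c,
        area_um2=ellipsoid_area(a, b, c),
        mean_H_per_um=1 / a if sphere_like else None,
        mean_K_per_um2=1 / a ** 2 if sphere_like else None)
    return mask, truth


def make_lobed_shape(n_lobes: int,
                     lobe_radii: tuple[float, float] = (0.5, 0.9),
                     overlap_frac: float = 0.4,
                     seed: int = 0,
                     voxel_um: float = DEFAULT_VOXEL_UM,
                     ) -> tuple[np.ndarray, ShapeTruth]:
    """Union of overlapping balls emulating a multi-lobed vacuole.

    Each lobe after the first is attached to a previously placed lobe at a
    center distance of ``(r_prev + r_new) * (1 - overlap_frac)``, which
    guarantees pairwise overlap and a single connected, genus-0 component.
    Truth volume/area come from the voxel-counting and exposed-face oracles
    (no closed form exists for the union), so only ``volume_um3`` should be
    used as exact ground truth.
    """
    if n_lobes < 1:
        raise ValueError("need at least one lobe")
    if not 0 < overlap_frac < 1:
        raise ValueError("overlap_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    radii = rng.uniform(*lobe_radii, size=n_lobes)
    centers = [np.zeros(3)]
    for i in range(1, n_lobes):
        j = int(rng.integers(0, i))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = (radii[j] + radii[i]) * (1 - overlap_frac)
        centers.append(centers[j] + direction * dist)
    centers = np.asarray(centers)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    margin = 2 * voxel_um
    grid_shape = _auto_grid(hi - lo + 2 * margin, voxel_um)
    offset = -lo + margin
    zz, yy, xx = _grid_coords(grid_shape, voxel_um)
    mask = np.zeros(grid_shape, dtype=bool)
    for (cz, cy, cx), r in zip(centers + offset, radii):
        mask |= ((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) <= r ** 2
    _, n_components = ndimage.label(mask)
    if n_components != 1:
        raise PlacementError("lobed union is not a single connected component")
    n_vox = int(mask.sum())
    exposed = _exposed_faces(mask)
    truth = ShapeTruth(volume_um3=n_vox * voxel_um ** 3,
                       area_um2=exposed * voxel_um ** 2, genus=0)
    return mask, truth


def _exposed_faces(mask: np.ndarray) -> int:
    padded = np.pad(mask, 1)
    faces = 0
    for axis in range(3):
        faces += int(np.count_nonzero(np.diff(padded, axis=axis)))
    return faces


# ---------------------------------------------------------------------------
# cell scenes

def _radius_from_volume(v: float) -> float:
    return (3 * v / (4 * np.pi)) ** (1 / 3)


def _sphere_mask_at(grid_shape, voxel_um, center, radius):
    zz, yy, xx = _grid_coords(grid_shape, voxel_um)
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius ** 2


def _fill_cell(labels: np.ndarray, instance: np.ndarray,
               center: np.ndarray, r_cell: float, cell_id: int,
               params: StrainParams, rng: np.random.Generator,
               voxel_um: float) -> None:
    """Paint one cell (cytosol + organelles) into the semantic/instance maps."""
    grid_shape = labels.shape
    cell_mask = _sphere_mask_at(grid_shape, voxel_um, center, r_cell)
    labels[cell_mask] = LABEL_IDS["cell"]
    instance[cell_mask] = cell_id

    def place_inside(radius, avoid=(), tries=200):
        for _ in range(tries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            max_off = r_cell - radius - voxel_um
            if max_off <= 0:
                continue
            off = direction * (max_off * rng.uniform() ** (1 / 3))
            c = center + off
            if all(np.linalg.norm(c - ac) > radius + ar for ac, ar in avoid):
                return c
        return None

    placed: list[tuple[np.ndarray, float]] = []
    r_nuc = _radius_from_volume(rng.uniform(*params.nucleus_volume_um3))
    r_nuc = min(r_nuc, 0.6 * r_cell)
    c_nuc = place_inside(r_nuc)
    if c_nuc is not None:
        nm = _sphere_mask_at(grid_shape, voxel_um, c_nuc, r_nuc)
        labels[nm & cell_mask] = LABEL_IDS["nucleus"]
        placed.append((c_nuc, r_nuc))
    n_vac = int(rng.integers(params.vacuole_count[0],
                             params.vacuole_count[1] + 1))
    for _ in range(n_vac):
        r = _radius_from_volume(rng.uniform(*params.vacuole_volume_um3))
        r = min(r, 0.5 * r_cell)
        c = place_inside(r, avoid=placed)
        if c is None:
            continue
        vm = _sphere_mask_at(grid_shape, voxel_um, c, r)
        labels[vm & cell_mask & (labels != LABEL_IDS["nucleus"])] = \
            LABEL_IDS["vacuole"]
        placed.append((c, r))
    n_ld = int(rng.integers(params.ld_count[0], params.ld_count[1] + 1))
    for _ in range(n_ld):
        r = max(_radius_from_volume(rng.uniform(*params.ld_volume_um3)),
                2 * voxel_um)
        c = place_inside(r, avoid=placed)
        if c is None:
            continue
        lm = _sphere_mask_at(grid_shape, voxel_um, c, r)
        labels[lm & cell_mask & (labels == LABEL_IDS["cell"])] = \
            LABEL_IDS["lipid_droplet"]
        placed.append((c, r))


def _render_lac(labels: np.ndarray, params: StrainParams,
                rng: np.random.Generator) -> np.ndarray:
    lac = np.zeros(labels.shape, dtype=np.float32)
    for label_id, name in SEMANTIC_LABELS.items():
        voxels = labels == label_id
        n = int(voxels.sum())
        if n == 0:
            continue
        mean, sd = params.lac[name]
        lac[voxels] = np.maximum(rng.normal(mean, sd, size=n), 0.0)
    return lac


def make_cell_scene(n_cells: int,
                    params: StrainParams | None = None,
                    seed: int = 0,
                    field_um: float = 12.0,
                    return_instances: bool = False,
                    max_tries: int = 500,
                    ):
    """Multi-cell field with organelle-specific LAC.

    Cells are non-overlapping balls, each containing one nucleus, 1–10
    vacuoles and 0–5 lipid droplets strictly inside the cell.  Returns
    ``(LACVolume, LabeledVolume)``; with ``return_instances=True`` a third
    instance-id LabeledVolume is appended.
    """
    params = params or StrainParams()
    rng = np.random.default_rng(seed)
    voxel_um = params.voxel_um
    n_grid = int(round(field_um / voxel_um))
    grid_shape = (n_grid,) * 3
    labels = np.zeros(grid_shape, dtype=np.int32)
    instance = np.zeros(grid_shape, dtype=np.int32)
    centers: list[tuple[np.ndarray, float]] = []
    for cell_id in range(1, n_cells + 1):
        r_cell = rng.uniform(*params.cell_radius_um)
        for attempt in range(max_tries):
            center = rng.uniform(r_cell + voxel_um,
                                 field_um - r_cell - voxel_um, size=3)
            if all(np.linalg.norm(center - c) > r_cell + r + voxel_um
                   for c, r in centers):
                break
        else:
            raise PlacementError(
                f"could not place cell {cell_id} of {n_cells} in "
                f"{field_um} µm field")
        centers.append((center, r_cell))
        _fill_cell(labels, instance, center, r_cell, cell_id, params, rng,
                   voxel_um)
    lac = _render_lac(labels, params, rng)
    out = (LACVolume(lac, voxel_um), LabeledVolume(labels, voxel_um))
    if return_instances:
        inst_dict = {0: "background",
                     **{i: f"cell_{i}" for i in range(1, n_cells + 1)}}
        return (*out, LabeledVolume(instance, voxel_um,
                                    label_dictionary=inst_dict))
    return out


def make_capillary_scene(n_cells: int, seed: int = 0,
                         params: StrainParams | None = None,
                         field_um: float = 12.0,
                         capillary_radius_um: float | None = None,
                         touching_pairs: int = 1,
                         max_tries: int = 2000,
                         ) -> tuple[LACVolume, LabeledVolume]:
    """Cells inside a cylindrical capillary, some pairs touching.

    The returned LabeledVolume carries the per-cell *instance* ground truth
    (ids 1..n); touching cells keep distinct ids by construction.  The
    semantic organelle content is rendered into the LAC exactly as in
    :func:`make_cell_scene`.
    """
    params = params or StrainParams()
    rng = np.random.default_rng(seed)
    voxel_um = params.voxel_um
    if capillary_radius_um is None:
        capillary_radius_um = field_um / 2 - voxel_um
    n_grid = int(round(field_um / voxel_um))
    grid_shape = (n_grid,) * 3
    axis_center = field_um / 2

    def inside_capillary(center, r):
        radial = np.hypot(center[1] - axis_center, center[2] - axis_center)
        return (radial + r < capillary_radius_um
                and r + voxel_um < center[0] < field_um - r - voxel_um)

    centers: list[tuple[np.ndarray, float]] = []
    pairs_made = 0
    for cell_id in range(1, n_cells + 1):
        r_cell = rng.uniform(*params.cell_radius_um)
        placed = False
        for attempt in range(max_tries):
            if centers and pairs_made < touching_pairs:
                # attach flush to an existing cell so the pair touches
                base_c, base_r = centers[int(rng.integers(len(centers)))]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                center = base_c + direction * (base_r + r_cell - voxel_um / 2)
                min_gap = -voxel_um  # allowed to touch the partner
            else:
                center = np.array([
                    rng.uniform(r_cell, field_um - r_cell),
                    *rng.uniform(axis_center - capillary_radius_um,
                                 axis_center + capillary_radius_um, size=2)])
                min_gap = voxel_um
            if not inside_capillary(center, r_cell):
                continue
            gaps = [np.linalg.norm(center - c) - (r_cell + r)
                    for c, r in centers]
            if centers and pairs_made < touching_pairs:
                others_ok = all(g > voxel_um for g in sorted(gaps)[1:]) \
                    if len(gaps) > 1 else True
                if min(gaps) >= min_gap and others_ok:
                    pairs_made += 1
                    placed = True
                    break
            elif all(g > min_gap for g in gaps):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {cell_id} of {n_cells} in capillary")
        centers.append((center, r_cell))

    labels = np.zeros(grid_shape, dtype=np.int32)
    instance = np.zeros(grid_shape, dtype=np.int32)
    for cell_id, (center, r_cell) in enumerate(centers, start=1):
        _fill_cell(labels, instance, center, r_cell, cell_id, params, rng,
                   voxel_um)
    lac = _render_lac(labels, params, rng)
    inst_dict = {0: "background",
                 **{i: f"cell_{i}" for i in range(1, n_cells + 1)}}
    return (LACVolume(lac, voxel_um),
            LabeledVolume(instance, voxel_um, label_dictionary=inst_dict))


def make_flat_contact_pair(radius_um: float = 0.8,
                           gap_um: float = 0.02,
                           flatten_frac: float = 0.4,
                           voxel_um: float = 0.04,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Two plane-clipped balls facing each other across a small gap.

    Emulates two organelles flattened against each other at a membrane
    contact site: each ball is truncated by the plane at
    ``flatten_frac × radius`` from its center, and the two flat facets face
    each other separated by ``gap_um``.  Returns the two voxel masks on a
    common grid (same shape and voxel size), suitable for meshing and
    interface-region analysis.
    """
    if gap_um < 0:
        raise ValueError("gap must be non-negative")
    cut = flatten_frac * radius_um
    # extent along x: ball A occupies [-R, cut], ball B mirrors across the gap
    margin = 2 * voxel_um
    length = (radius_um + cut) * 2 + gap_um + 2 * margin
    width = 2 * radius_um + 2 * margin
    grid_shape = _auto_grid(np.array([width, width, length]), voxel_um)
    center_a = np.array([width / 2 + margin, width / 2 + margin,
                         margin + radius_um])
    plane_a = center_a[2] + cut
    center_b = center_a + np.array([0, 0, 2 * cut + gap_um + voxel_um])
    zz, yy, xx = _grid_coords(grid_shape, voxel_um)
    ball_a = ((zz - center_a[0]) ** 2 + (yy - center_a[1]) ** 2
              + (xx - center_a[2]) ** 2) <= radius_um ** 2
    mask_a = ball_a & (xx <= plane_a)
    ball_b = ((zz - center_b[0]) ** 2 + (yy - center_b[1]) ** 2
              + (xx - center_b[2]) ** 2) <= radius_um ** 2
    # the 0.5-level surface sits half a voxel beyond the last included
    # voxel center on each side, so offset the facet planes by one voxel
    # to realize a surface-to-surface gap of ~gap_um
    mask_b = ball_b & (xx >= plane_a + gap_um + voxel_um)
    return mask_a, mask_b


def scaled_params(scale: float, voxel_um: float | None = None,
                  **overrides) -> StrainParams:
    """StrainParams with all linear sizes scaled by ``scale`` (volumes by scale³).

    Convenience for running the full pipeline on small grids; LAC
    distributions are untouched.
    """
    base = StrainParams()
    kw = dict(
        cell_radius_um=tuple(np.array(base.cell_radius_um) * scale),
        nucleus_volume_um3=tuple(np.array(base.nucleus_volume_um3) * scale ** 3),
        vacuole_volume_um3=tuple(np.array(base.vacuole_volume_um3) * scale ** 3),
        ld_volume_um3=tuple(np.array(base.ld_volume_um3) * scale ** 3),
    )
    if voxel_um is not None:
        kw["voxel_um"] = voxel_um
    kw.update(overrides)
    return replace(base, **kw)
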