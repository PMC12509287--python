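"""Triangle-mesh extraction, refinement, and curvature / Willmore analysis.

The mesh route is the high-resolution counterpart to voxel morphometrics:
a labeled organelle mask is surface-reconstructed by marching cubes in
physical µm, the voxel terracing is removed by alternating smoothing and
selective decimation, and per-vertex discrete curvatures yield global
shape descriptors.

Shape descriptors
-----------------
For a closed surface with mean curvature ``H`` (µm⁻¹, positive convex
under outward normals) and Gaussian curvature ``K`` (µm⁻²), the Willmore
energy is ``WE = ∫(H² − K) dA`` — zero for a sphere, growing with shape
complexity — and the Willmore energy density is ``WED = WE / A``.
Approximating surface integrals by unweighted vertex averages (valid for
near-uniform triangle areas) gives

    WED = ⟨H⟩² + SD(H)² − ⟨K⟩,       WE = WED · A,

a pure function of the vertex statistics that is also usable on published
summary tables.  The discrete Gauss–Bonnet identity (total angle-deficit
Gaussian curvature = 2πχ, i.e. 4π for a closed genus-0 surface) serves as
a mesh-integrity check.

Estimators: cotangent-Laplacian mean-curvature normal and angle-deficit
Gaussian curvature, both over mixed Voronoi vertex areas (Meyer et al.);
smoothing is volume-preserving Taubin λ|µ; decimation is quadric
edge-collapse restricted to short edges, which naturally keeps more
triangles in curved regions.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage, sparse
from skimage.measure import marching_cubes

from .volume_io import LabeledVolume

__all__ = [
    "extract_surface", "refine_mesh", "DEFAULT_SCHEDULE",
    "mesh_volume", "mesh_area", "vertex_curvatures", "mixed_vertex_areas",
    "curvature_summary", "wed_from_stats", "gauss_bonnet_residual",
    "taubin_smooth", "decimate_quadric", "CurvatureSummary",
    "RefinementError",
]


class RefinementError(RuntimeError):
    """Raised when a refinement stage breaks mesh manifoldness."""


@dataclass(frozen=True)
class CurvatureSummary:
    """Surface-aggregated curvature statistics for one closed object."""

    mean_H: float          # µm⁻¹, unweighted vertex average
    sd_H: float            # µm⁻¹
    mean_K: float          # µm⁻²
    sd_K: float            # µm⁻²
    area_um2: float
    volume_um3: float
    wed: float             # µm⁻², ⟨H⟩² + SD(H)² − ⟨K⟩
    we: float              # dimensionless, WED · A
    gauss_bonnet_total: float  # Σ K·A_vertex, ≈ 2πχ for closed meshes
    n_vertices: int


# ---------------------------------------------------------------------------
# extraction

def extract_surface(mask: np.ndarray | LabeledVolume,
                    voxel_um: float | None = None,
                    label: int | str | None = None) -> trimesh.Trimesh:
    """Marching-cubes surface of a binary mask at the 0.5 iso-level.

    Vertices are in physical µm (voxel index × voxel size); the largest
    26-connected component is meshed; faces are wound so normals point
    outward.  The mesh bounding box matches the mask bounding box within
    one voxel per axis.
    """
    if isinstance(mask, LabeledVolume):
        if voxel_um is None:
            voxel_um = mask.voxel_um
        mask = mask.mask(label) if label is not None else mask.data > 0
    if voxel_um is None:
        raise ValueError("voxel_um is required for a bare array mask")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot extract a surface from an empty mask")
    comp, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                   index=np.arange(1, n + 1))
        mask = comp == (1 + int(np.argmax(sizes)))
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _normals, _values = marching_cubes(
        padded, level=0.5, spacing=(voxel_um,) * 3)
    verts -= voxel_um  # undo the one-voxel pad
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# basic measures

def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume (µm³) by the divergence theorem over signed tetrahedra.

    Requires a closed mesh; an inverted orientation is measured as its
    absolute volume.
    """
    if not mesh.is_watertight:
        raise ValueError("volume of an open mesh is undefined")
    return float(abs(mesh.volume))


def mesh_area(mesh: trimesh.Trimesh) -> float:
    """Total triangle area (µm²)."""
    return float(mesh.area)


# ---------------------------------------------------------------------------
# discrete curvature

def _face_angles_cots(verts: np.ndarray, faces: np.ndarray):
    """Per-face corner angles and cotangents (shape (n_faces, 3))."""
    p = verts[faces]
    e = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]],
                 axis=1)  # edge opposite each corner
    angles = np.empty(faces.shape, float)
    cots = np.empty(faces.shape, float)
    for c in range(3):
        u = -e[:, (c + 2) % 3]   # edges emanating from corner c
        v = e[:, (c + 1) % 3]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        dot = np.einsum("ij,ij->i", u, v)
        angles[:, c] = np.arctan2(cross, dot)
        cots[:, c] = dot / np.maximum(cross, 1e-300)
    return angles, cots


def mixed_vertex_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    """Mixed Voronoi vertex areas (Meyer et al.); sums to the mesh area."""
    verts = mesh.vertices.view(np.ndarray)
    faces = mesh.faces.view(np.ndarray)
    angles, cots = _face_angles_cots(verts, faces)
    p = verts[faces]
    edge_sq = np.stack([
        np.sum((p[:, 2] - p[:, 1]) ** 2, axis=1),  # opposite corner 0
        np.sum((p[:, 0] - p[:, 2]) ** 2, axis=1),
        np.sum((p[:, 1] - p[:, 0]) ** 2, axis=1)], axis=1)
    face_area = mesh.area_faces
    obtuse = angles > np.pi / 2
    any_obtuse = obtuse.any(axis=1)
    areas = np.zeros(len(verts))
    contrib = np.empty(faces.shape, float)
    for c in range(3):
        # Voronoi: (|e_b|² cot θ_b + |e_a|² cot θ_a)/8 with a,b the other corners
        a, b = (c + 1) % 3, (c + 2) % 3
        contrib[:, c] = (edge_sq[:, b] * cots[:, b]
                         + edge_sq[:, a] * cots[:, a]) / 8.0
    # obtuse triangles: T/2 at the obtuse corner, T/4 at the others
    for c in range(3):
        sel = any_obtuse
        contrib[sel, c] = np.where(obtuse[sel, c],
                                   face_area[sel] / 2, face_area[sel] / 4)
    for c in range(3):
        np.add.at(areas, faces[:, c], contrib[:, c])
    return areas


def _boundary_vertices(mesh: trimesh.Trimesh) -> np.ndarray:
    edges = mesh.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = np.zeros(len(mesh.vertices), bool)
    if (counts == 1).any():
        boundary[np.unique(uniq[counts == 1])] = True
    return boundary


def vertex_curvatures(mesh: trimesh.Trimesh
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex mean curvature H (µm⁻¹) and Gaussian curvature K (µm⁻²).

    H is the magnitude of the cotangent-Laplacian mean-curvature normal,
    signed positive for convex vertices (outward normals); K is the angle
    deficit over the mixed Voronoi area.  Boundary vertices are NaN.
    """
    verts = mesh.vertices.view(np.ndarray)
    faces = mesh.faces.view(np.ndarray)
    angles, cots = _face_angles_cots(verts, faces)
    areas = mixed_vertex_areas(mesh)

    lap = np.zeros_like(verts)
    for c in range(3):
        i, j = faces[:, (c + 1) % 3], faces[:, (c + 2) % 3]
        w = cots[:, c][:, None]
        np.add.at(lap, i, w * (verts[i] - verts[j]))
        np.add.at(lap, j, w * (verts[j] - verts[i]))

    H = np.linalg.norm(lap, axis=1) / np.maximum(4 * areas, 1e-300)
    sign = np.sign(np.einsum("ij,ij->i", lap,
                             mesh.vertex_normals.view(np.ndarray)))
    H = H * np.where(sign == 0, 1.0, sign)

    deficit = np.full(len(verts), 2 * np.pi)
    for c in range(3):
        np.subtract.at(deficit, faces[:, c], angles[:, c])
    K = deficit / np.maximum(areas, 1e-300)

    boundary = _boundary_vertices(mesh)
    if boundary.any():
        H[boundary] = np.nan
        K[boundary] = np.nan
    mesh.vertex_attributes["H"] = H
    mesh.vertex_attributes["K"] = K
    return H, K


def wed_from_stats(mean_H: float, sd_H: float, mean_K: float,
                   area: float) -> tuple[float, float]:
    """Willmore energy density and energy from vertex-averaged statistics.

    ``WED = mean_H² + sd_H² − mean_K`` (µm⁻²) and ``WE = WED × area``; a
    pure function, usable directly on printed summary statistics.
    """
    wed = mean_H ** 2 + sd_H ** 2 - mean_K
    return float(wed), float(wed * area)


def curvature_summary(mesh: trimesh.Trimesh,
                      area_weighted: bool = False) -> CurvatureSummary:
    """Vertex-aggregated curvature statistics, WED/WE and Gauss–Bonnet total.

    The default aggregation is the unweighted vertex average (the
    convention of the summary-table route, exact when triangle areas are
    uniform); ``area_weighted=True`` weights vertices by their mixed
    Voronoi areas, which is more faithful on convoluted surfaces.
    """
    H, K = vertex_curvatures(mesh)
    areas = mixed_vertex_areas(mesh)
    valid = np.isfinite(H)
    open_mesh = not bool(valid.all())
    Hv, Kv, av = H[valid], K[valid], areas[valid]
    if area_weighted:
        w = av / av.sum()
        mean_H = float(w @ Hv)
        sd_H = float(np.sqrt(w @ (Hv - mean_H) ** 2))
        mean_K = float(w @ Kv)
        sd_K = float(np.sqrt(w @ (Kv - mean_K) ** 2))
    else:
        mean_H, sd_H = float(Hv.mean()), float(Hv.std())
        mean_K, sd_K = float(Kv.mean()), float(Kv.std())
    area = mesh_area(mesh)
    wed, we = wed_from_stats(mean_H, sd_H, mean_K, area)
    total_K = float((Kv * av).sum())
    return CurvatureSummary(
        mean_H=mean_H, sd_H=sd_H, mean_K=mean_K, sd_K=sd_K,
        area_um2=area,
        volume_um3=mesh_volume(mesh) if not open_mesh else float("nan"),
        wed=wed, we=we, gauss_bonnet_total=total_K, n_vertices=int(valid.sum()))


def gauss_bonnet_residual(mesh: trimesh.Trimesh) -> tuple[float, dict]:
    """Σ K·A_vertex − 2πχ and a diagnostics dict.

    For a closed mesh the angle-deficit identity makes the residual zero to
    machine precision; holes (boundary edges) make it large, so a non-tiny
    residual is a mesh-integrity warning.  The genus is estimated from the
    Euler characteristic χ = V − E + F assuming a closed surface.
    """
    verts = mesh.vertices.view(np.ndarray)
    faces = mesh.faces.view(np.ndarray)
    angles, _ = _face_angles_cots(verts, faces)
    deficit = np.full(len(verts), 2 * np.pi)
    for c in range(3):
        np.subtract.at(deficit, faces[:, c], angles[:, c])
    total = float(deficit.sum())
    chi = len(verts) - len(mesh.edges_unique) + len(faces)
    genus = max(0, int(round((2 - chi) / 2)))
    boundary_edges = int((np.unique(mesh.edges_sorted, axis=0,
                                    return_counts=True)[1] == 1).sum())
    expected = 4 * np.pi * (1 - genus)
    info = {"chi": chi, "genus": genus, "boundary_edges": boundary_edges,
            "has_holes": boundary_edges > 0, "expected_total": expected}
    return total - expected, info


# ---------------------------------------------------------------------------
# smoothing

def _uniform_laplacian(mesh: trimesh.Trimesh) -> sparse.csr_matrix:
    edges = mesh.edges_unique
    n = len(mesh.vertices)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv_deg = sparse.diags(1.0 / np.maximum(deg, 1))
    return inv_deg @ adj - sparse.identity(n)


def taubin_smooth(mesh: trimesh.Trimesh, iterations: int = 10,
                  lam: float = 0.5, mu: float = -0.53,
                  preserve_volume: bool = True) -> trimesh.Trimesh:
    """Volume-preserving Taubin λ|µ smoothing.

    Each iteration applies a positive (λ) then a negative (µ) uniform
    Laplacian step; the alternating signs cancel most of the systematic
    shrinkage of plain Laplacian smoothing.  The residual volume drift
    (shrinkage or inflation, depending on mesh density) is removed exactly
    by a final uniform rescaling about the volume centroid back to the
    input volume (``preserve_volume``, skipped for open meshes).
    """
    L = _uniform_laplacian(mesh)
    verts = mesh.vertices.view(np.ndarray).copy()
    for _ in range(iterations):
        verts = verts + lam * (L @ verts)
        verts = verts + mu * (L @ verts)
    out = trimesh.Trimesh(vertices=verts, faces=mesh.faces.copy(),
                          process=False)
    if preserve_volume and mesh.is_watertight and out.is_watertight:
        v_in, v_out = abs(mesh.volume), abs(out.volume)
        if v_in > 0 and v_out > 0:
            scale = (v_in / v_out) ** (1 / 3)
            center = out.center_mass
            out = trimesh.Trimesh(
                vertices=center + (out.vertices - center) * scale,
                faces=out.faces, process=False)
    return out


# ---------------------------------------------------------------------------
# quadric edge-collapse decimation

def _vertex_quadrics(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    normals = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                       verts[faces[:, 2]] - verts[faces[:, 0]])
    norm = np.linalg.norm(normals, axis=1)
    keep = norm > 1e-300
    normals[keep] /= norm[keep][:, None]
    d = -np.einsum("ij,ij->i", normals, verts[faces[:, 0]])
    planes = np.concatenate([normals, d[:, None]], axis=1)
    Kp = planes[:, :, None] * planes[:, None, :]
    Q = np.zeros((len(verts), 4, 4))
    for c in range(3):
        np.add.at(Q, faces[:, c], Kp)
    return Q


def _optimal_point(Q: np.ndarray, p0: np.ndarray, p1: np.ndarray):
    """Quadric-optimal collapse position, falling back to the best of
    endpoints/midpoint when the system is ill-conditioned."""
    A = Q[:3, :3]
    b = -Q[:3, 3]
    try:
        x = np.linalg.solve(A + 1e-12 * np.eye(3), b)
        h = np.append(x, 1.0)
        err = float(h @ Q @ h)
        # reject wild solutions far outside the edge neighborhood
        if np.linalg.norm(x - (p0 + p1) / 2) < 2 * np.linalg.norm(p1 - p0) + 1e-12:
            return x, max(err, 0.0)
    except np.linalg.LinAlgError:
        pass
    best, best_err = None, np.inf
    for cand in (p0, p1, (p0 + p1) / 2):
        h = np.append(cand, 1.0)
        err = float(h @ Q @ h)
        if err < best_err:
            best, best_err = cand, err
    return best, max(best_err, 0.0)


def decimate_quadric(mesh: trimesh.Trimesh, iterations: int = 10,
                     threshold: float = 1.5,
                     max_error_frac: float = 0.025) -> trimesh.Trimesh:
    """Selective quadric edge-collapse decimation.

    ``threshold`` maps to a relative target edge length: edges shorter than
    ``threshold × (mean edge length at entry)`` are collapse candidates,
    processed in increasing quadric-error order over ``iterations`` passes.
    A collapse is refused when its quadric error exceeds
    ``(max_error_frac × target length)²`` — the quadric error is near zero
    on flat regions and grows with curvature, so flat regions coarsen while
    curvature-dense regions keep proportionally more triangles.  Collapses
    that would break the link condition or flip a face normal are skipped.
    """
    verts = mesh.vertices.view(np.ndarray).astype(float).copy()
    faces = mesh.faces.view(np.ndarray).copy()
    edge_lens = np.linalg.norm(
        verts[mesh.edges_unique[:, 0]] - verts[mesh.edges_unique[:, 1]],
        axis=1)
    target_len = threshold * float(edge_lens.mean())
    max_error = (max_error_frac * target_len) ** 2

    n_v = len(verts)
    alive_v = np.ones(n_v, bool)
    alive_f = np.ones(len(faces), bool)
    vertex_faces: list[set[int]] = [set() for _ in range(n_v)]
    for fi, face in enumerate(faces):
        for v in face:
            vertex_faces[v].add(fi)
    Q = _vertex_quadrics(verts, faces)
    version = np.zeros(n_v, np.int64)

    def neighbors(v: int) -> set[int]:
        out: set[int] = set()
        for fi in vertex_faces[v]:
            out.update(faces[fi])
        out.discard(v)
        return out

    def push_edges(heap, vs, len_limit, err_limit):
        for u in vs:
            if not alive_v[u]:
                continue
            for w in neighbors(u):
                if w <= u or not alive_v[w]:
                    continue
                if np.linalg.norm(verts[u] - verts[w]) >= len_limit:
                    continue
                x, err = _optimal_point(Q[u] + Q[w], verts[u], verts[w])
                if err > err_limit:
                    continue
                heapq.heappush(heap, (err, u, w, int(version[u]),
                                      int(version[w]), tuple(x)))

    # the extra pass collapses residual sliver edges (degenerate clusters
    # that concentrate spurious curvature) with the error cap lifted
    passes = [(target_len, max_error)] * iterations \
        + [(0.35 * target_len, np.inf)]
    for len_limit, err_limit in passes:
        heap: list = []
        push_edges(heap, np.flatnonzero(alive_v), len_limit, err_limit)
        collapsed_any = False
        while heap:
            err, u, w, vu, vw, x = heapq.heappop(heap)
            if not (alive_v[u] and alive_v[w]):
                continue
            if version[u] != vu or version[w] != vw:
                continue
            if np.linalg.norm(verts[u] - verts[w]) >= len_limit:
                continue
            shared = vertex_faces[u] & vertex_faces[w]
            # link condition: common neighbors must all lie on shared faces
            common = neighbors(u) & neighbors(w)
            opposite = set()
            for fi in shared:
                opposite.update(int(v) for v in faces[fi]
                                if v != u and v != w)
            if common != opposite or len(shared) != 2:
                continue
            x = np.asarray(x)
            # normal-flip check on surviving faces around both endpoints
            flip = False
            survivors = (vertex_faces[u] | vertex_faces[w]) - shared
            for fi in survivors:
                tri = faces[fi]
                p = verts[tri]
                n_old = np.cross(p[1] - p[0], p[2] - p[0])
                q = np.array([x if v in (u, w) else verts[v] for v in tri])
                n_new = np.cross(q[1] - q[0], q[2] - q[0])
                if np.dot(n_old, n_new) <= 0:
                    flip = True
                    break
            if flip:
                continue
            # perform collapse: w merges into u at position x
            verts[u] = x
            Q[u] = Q[u] + Q[w]
            alive_v[w] = False
            for fi in shared:
                alive_f[fi] = False
                for v in faces[fi]:
                    vertex_faces[v].discard(fi)
            for fi in list(vertex_faces[w]):
                faces[fi][faces[fi] == w] = u
                vertex_faces[u].add(fi)
            vertex_faces[w].clear()
            version[u] += 1
            version[w] += 1
            collapsed_any = True
            push_edges(heap, [u], len_limit, err_limit)
        if not collapsed_any and err_limit is not np.inf:
            continue

    new_index = -np.ones(n_v, np.int64)
    new_index[alive_v] = np.arange(int(alive_v.sum()))
    out_faces = new_index[faces[alive_f]]
    out = trimesh.Trimesh(vertices=verts[alive_v], faces=out_faces,
                          process=False)
    if out.volume < 0:
        out.invert()
    return out


# ---------------------------------------------------------------------------
# refinement schedule

#: Default refinement schedule: smoothing and selective decimation passes
#: followed by a final volume-preserving Taubin step.
DEFAULT_SCHEDULE: tuple = (
    ("smooth", {"iterations": 15}),
    ("decimate", {"iterations": 10, "threshold": 1.5}),
    ("smooth", {"iterations": 15}),
    ("decimate", {"iterations": 10, "threshold": 1.0}),
    ("smooth", {"iterations": 10}),
    ("taubin", {"iterations": 10}),
)


def refine_mesh(mesh: trimesh.Trimesh,
                schedule=DEFAULT_SCHEDULE) -> trimesh.Trimesh:
    """Run a smoothing/decimation schedule on a closed mesh.

    The default schedule removes marching-cubes terracing while preserving
    enclosed volume (typically <1% change) and reducing surface area by a
    few percent; decimation is selective, retaining triangle density in
    curved regions.  If any stage breaks manifoldness a
    :class:`RefinementError` names the stage.
    """
    if not mesh.is_watertight:
        raise ValueError("refine_mesh expects a closed input mesh")
    v_start = abs(mesh.volume)
    current = mesh
    for stage_index, (op, params) in enumerate(schedule):
        if op in ("smooth", "taubin"):
            current = taubin_smooth(current, **params)
        elif op == "decimate":
            current = decimate_quadric(current, **params)
        else:
            raise ValueError(f"unknown refinement op {op!r}")
        if not current.is_watertight:
            raise RefinementError(
                f"stage {stage_index} ({op}) broke mesh manifoldness")
        # rescale about the centroid to the input volume: every stage is
        # volume-preserving by construction, so refinement only reshapes
        v_now = abs(current.volume)
        if v_start > 0 and v_now > 0 and not np.isclose(v_now, v_start):
            scale = (v_start / v_now) ** (1 / 3)
            center = current.center_mass
            current = trimesh.Trimesh(
                vertices=center + (current.vertices - center) * scale,
                faces=current.faces, process=False)
    return current
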