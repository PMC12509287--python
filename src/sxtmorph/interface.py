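"""Geometric detection of organelle–organelle membrane interfaces.

Given two closed organelle meshes (e.g. nucleus and vacuole), the signed
distance of each vertex of one mesh to the other surface localizes the
contact interface.  Two delineation modes are provided:

* ``"overlap"`` — vertices with negative signed distance, i.e. inside the
  other mesh.  This detects interpenetrating segmentations, the situation
  the face-quality ``fq < 0`` selection targets.
* ``"imd"`` — vertices within a configurable inter-membrane distance
  (default 30 nm, the characteristic contact-site gap).  The threshold is
  a parameter rather than a constant because segmentation error makes
  precise absolute IMD measurement impossible.

Distances are vertex-sampled; the minimum IMD of two separated surfaces is
accurate to about one vertex-spacing of the meshes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from scipy.spatial import cKDTree

from .mesh_pipeline import vertex_curvatures


def _point_triangle_closest(points: np.ndarray, tri: np.ndarray
                            ) -> np.ndarray:
    """Closest point on each triangle ``tri[i]`` to ``points[i]``.

    Vectorized version of the standard barycentric clamping algorithm
    (Ericson, Real-Time Collision Detection).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(points)
    done = np.zeros(len(points), bool)

    def assign(mask, value):
        mask = mask & ~done
        result[mask] = value[mask] if value.ndim == 2 else value
        done[mask] = True

    assign((d1 <= 0) & (d2 <= 0), a)                       # vertex a
    assign((d3 >= 0) & (d4 <= d3), b)                      # vertex b
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
    assign((d6 >= 0) & (d5 <= d6), c)                      # vertex c
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w_bc[:, None] * (c - b))
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    assign(np.ones(len(points), bool), a + v[:, None] * ab + w[:, None] * ac)
    return result


class _SignedDistanceQuery:
    """Signed distance to a closed mesh via KD-tree candidate triangles.

    The sign comes from the angle-weighted pseudonormal of the nearest
    feature (Bærentzen & Aanæs), which is robust at edges and vertices of
    watertight meshes.
    """

    def __init__(self, mesh: trimesh.Trimesh, n_candidates: int = 24):
        self.mesh = mesh
        self.tri = mesh.triangles.view(np.ndarray)
        self.tree = cKDTree(self.tri.mean(axis=1))
        self.n_candidates = min(n_candidates, len(self.tri))
        # per-face corner-angle-weighted vertex normals
        self._face_normals = mesh.face_normals.view(np.ndarray)

    def query(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, float)
        _d, cand = self.tree.query(points, k=self.n_candidates)
        if self.n_candidates == 1:
            cand = cand[:, None]
        n_pts, k = cand.shape
        pts_rep = np.repeat(points, k, axis=0)
        tris = self.tri[cand.ravel()]
        closest = _point_triangle_closest(pts_rep, tris)
        dist2 = np.sum((pts_rep - closest) ** 2, axis=1).reshape(n_pts, k)
        best = np.argmin(dist2, axis=1)
        rows = np.arange(n_pts)
        best_face = cand[rows, best]
        best_point = closest.reshape(n_pts, k, 3)[rows, best]
        delta = points - best_point
        distance = np.sqrt(dist2[rows, best])
        # pseudonormal sign: average normals of all candidate faces whose
        # closest point coincides with the global closest point (handles
        # edge/vertex features); fall back to the face normal
        normal = self._face_normals[best_face].copy()
        coincident = np.isclose(dist2, dist2[rows, best][:, None],
                                rtol=0, atol=1e-18)
        multi = coincident.sum(axis=1) > 1
        if multi.any():
            for i in np.flatnonzero(multi):
                normal[i] = self._face_normals[cand[i][coincident[i]]] \
                    .mean(axis=0)
        sign = np.sign(np.einsum("ij,ij->i", delta, normal))
        sign[sign == 0] = 1.0
        return distance * sign


@dataclass
class InterfaceRegion:
    """Vertex/face subset of one mesh selected as an interface."""

    mesh: trimesh.Trimesh
    vertex_indices: np.ndarray   # indices into mesh.vertices
    face_indices: np.ndarray     # faces with all three vertices selected
    distances: np.ndarray        # signed distance (µm) for every mesh vertex
    threshold_um: float | None
    mode: str

    @property
    def is_empty(self) -> bool:
        return self.vertex_indices.size == 0

    @property
    def area_um2(self) -> float:
        if self.face_indices.size == 0:
            return 0.0
        return float(self.mesh.area_faces[self.face_indices].sum())


def signed_distance_map(query: trimesh.Trimesh,
                        reference: trimesh.Trimesh) -> np.ndarray:
    """Signed distance (µm) from each query vertex to the reference surface.

    Positive outside the reference mesh, negative inside.  The reference
    must be closed for the sign to be defined.
    """
    if not reference.is_watertight:
        raise ValueError("reference mesh is open; signed distance undefined")
    return _SignedDistanceQuery(reference).query(
        query.vertices.view(np.ndarray))


def select_interface(mesh: trimesh.Trimesh, distances: np.ndarray,
                     mode: str = "imd",
                     threshold_um: float = 0.030,
                     erode: int = 0) -> InterfaceRegion:
    """Select the interface region of ``mesh`` from its signed distances.

    ``mode="overlap"`` selects vertices with distance < 0; ``mode="imd"``
    selects vertices with distance ≤ ``threshold_um``.  Faces are included
    when all three vertices are selected.  ``erode`` removes that many
    rings of selection-boundary vertices, useful for isolating the flat
    interior of a contact facet from its curved rim.  An empty selection
    returns an empty (flagged) region, not an error.
    """
    distances = np.asarray(distances, float)
    if distances.shape[0] != len(mesh.vertices):
        raise ValueError("distances do not match mesh vertices")
    if mode == "overlap":
        selected = distances < 0
        threshold = None
    elif mode == "imd":
        selected = distances <= threshold_um
        threshold = threshold_um
    else:
        raise ValueError(f"unknown interface mode {mode!r}")
    edges = mesh.edges_unique
    for _ in range(erode):
        drop = np.zeros(len(selected), bool)
        boundary = selected[edges[:, 0]] != selected[edges[:, 1]]
        drop[edges[boundary].ravel()] = True
        selected = selected & ~drop
    vertex_indices = np.flatnonzero(selected)
    faces = mesh.faces.view(np.ndarray)
    face_indices = np.flatnonzero(selected[faces].all(axis=1))
    return InterfaceRegion(mesh=mesh, vertex_indices=vertex_indices,
                           face_indices=face_indices, distances=distances,
                           threshold_um=threshold, mode=mode)


def min_imd(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh) -> float:
    """Minimum inter-membrane distance (µm); negative when surfaces overlap.

    Vertex-sampled in both directions (the smaller minimum is reported), so
    symmetric to within one vertex-spacing.
    """
    d_ab = signed_distance_map(mesh_a, mesh_b)
    d_ba = signed_distance_map(mesh_b, mesh_a)
    return float(min(d_ab.min(), d_ba.min()))


def interface_curvature_stats(region: InterfaceRegion) -> dict[str, float]:
    """Mean/SD of H and K restricted to the interface region's vertices."""
    if region.is_empty:
        raise ValueError("interface region is empty")
    mesh = region.mesh
    if "H" in mesh.vertex_attributes and "K" in mesh.vertex_attributes:
        H = np.asarray(mesh.vertex_attributes["H"])
        K = np.asarray(mesh.vertex_attributes["K"])
    else:
        H, K = vertex_curvatures(mesh)
    Hr = H[region.vertex_indices]
    Kr = K[region.vertex_indices]
    Hr, Kr = Hr[np.isfinite(Hr)], Kr[np.isfinite(Kr)]
    return {
        "mean_H": float(Hr.mean()), "sd_H": float(Hr.std()),
        "mean_K": float(Kr.mean()), "sd_K": float(Kr.std()),
        "area_um2": region.area_um2, "n_vertices": int(Hr.size),
    }


def curvature_histograms(region: InterfaceRegion, bins: int = 50
                         ) -> pd.DataFrame:
    """Histogram table of H and K over the region, for plotting/export."""
    mesh = region.mesh
    H = np.asarray(mesh.vertex_attributes["H"])[region.vertex_indices]
    K = np.asarray(mesh.vertex_attributes["K"])[region.vertex_indices]
    rows = []
    for name, values in (("H", H), ("K", K)):
        counts, edges = np.histogram(values[np.isfinite(values)], bins=bins)
        centers = (edges[:-1] + edges[1:]) / 2
        rows.append(pd.DataFrame({"quantity": name, "bin_center": centers,
                                  "count": counts}))
    return pd.concat(rows, ignore_index=True)
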