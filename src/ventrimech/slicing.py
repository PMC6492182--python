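"""Short-axis slicing of endo/epicardial surface meshes.

Mirrors the automated clinical workflow for extracting the Laplace inputs
``r`` (mean inner radius) and ``h`` (mean wall width) from triangulated
surfaces: the long axis of the ventricle is found by principal component
analysis of the endocardial vertex cloud, the ventricle is decomposed into
short-axis slices of ~8 mm width anchored to the axial centroid, and in
each slice ``N = 360/dphi`` rays are cast radially outward from the axis
point.  First intersections with the endocardial and epicardial surfaces
give per-ray radii ``r_ij``, ``R_ij`` and wall widths ``h_ij = R_ij -
r_ij``; per-slice and multi-slice means are plain arithmetic averages.

Slices in which any ray misses either surface (near the apex or base the
rays graze the surfaces) are dropped and reported, so a full ventricle
typically retains 10-14 usable slices.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import trimesh

__all__ = ["SurfacePair", "SliceSet", "long_axis", "slice_and_sample", "slice_means", "load_surface"]

log = logging.getLogger(__name__)


class GeometryError(ValueError):
    """Degenerate geometry (no usable slices, degenerate vertex cloud...)."""


def load_surface(path) -> trimesh.Trimesh:
    """Load a triangulated surface (PLY/STL/OFF/OBJ) as a Trimesh."""
    mesh = trimesh.load_mesh(str(path))
    if not isinstance(mesh, trimesh.Trimesh):  # pragma: no cover - defensive
        raise GeometryError(f"{path} did not contain a single triangle mesh")
    return mesh


@dataclass
class SurfacePair:
    """Endocardial and epicardial surfaces for one time frame (mm)."""

    endo: trimesh.Trimesh
    epi: trimesh.Trimesh
    label: float = 0.0  # time stamp, ms


@dataclass
class SliceSet:
    """Per-slice radii sampled on short-axis planes.

    ``r`` and ``R`` have shape (M slices, N rays); ``z`` holds the slice
    centers along the long axis (axis coordinates relative to the
    centroid).  ``dropped`` lists slice centers discarded because a ray
    missed a surface.
    """

    axis: np.ndarray
    centroid: np.ndarray
    z: np.ndarray
    r: np.ndarray
    R: np.ndarray
    dropped: List[float] = field(default_factory=list)

    @property
    def h(self) -> np.ndarray:
        return self.R - self.r

    @property
    def r_slice(self) -> np.ndarray:
        """Per-slice mean inner radius (arithmetic mean over rays)."""
        return self.r.mean(axis=1)

    @property
    def h_slice(self) -> np.ndarray:
        return self.h.mean(axis=1)

    def to_json(self, path) -> None:
        payload = {
            "axis": self.axis.tolist(),
            "centroid": self.centroid.tolist(),
            "z": self.z.tolist(),
            "r": self.r.tolist(),
            "R": self.R.tolist(),
            "dropped": list(self.dropped),
        }
        Path(path).write_text(json.dumps(payload))


def long_axis(pair: SurfacePair) -> Tuple[np.ndarray, np.ndarray]:
    """Long axis (unit vector) and centroid of the endocardial cloud.

    The dominant principal direction of the vertex covariance.  For a
    perfect sphere the spectrum is degenerate and an arbitrary (but
    deterministic) eigenvector is returned.  The sign is fixed so that the
    wider cross-section (the base) lies at the +z end.
    """
    pts = np.asarray(pair.endo.vertices, float)
    if pts.shape[0] < 4:
        raise GeometryError("need at least 4 vertices for axis estimation")
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    if np.linalg.matrix_rank(cov, tol=1e-12) < 2:
        raise GeometryError("degenerate (collinear) vertex cloud")
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]  # largest eigenvalue
    # orient: compare mean transverse spread of the two axial halves
    z = (pts - c) @ axis
    trans = np.linalg.norm((pts - c) - np.outer(z, axis), axis=1)
    upper = trans[z > 0].mean() if np.any(z > 0) else 0.0
    lower = trans[z < 0].mean() if np.any(z < 0) else 0.0
    if lower > upper:
        axis = -axis
    return axis, c


def _first_hit_distances(
    mesh: trimesh.Trimesh, origins: np.ndarray, directions: np.ndarray
) -> np.ndarray:
    """Distance to the first intersection per ray; NaN where a ray misses.

    Vectorized Moller-Trumbore over all (ray, triangle) pairs; adequate for
    the modest surface meshes this module deals with and dependency-free.
    """
    tri = np.asarray(mesh.triangles, float)  # (m, 3, 3)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    O = np.asarray(origins, float)[:, None, :]  # (n, 1, 3)
    D = np.asarray(directions, float)[:, None, :]
    eps = 1e-9
    pvec = np.cross(D, e2[None, :, :])  # (n, m, 3)
    det = np.einsum("nmk,mk->nm", pvec, e1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = np.where(np.abs(det) > eps, 1.0 / det, np.nan)
        tvec = O - v0[None, :, :]
        u = np.einsum("nmk,nmk->nm", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("nmk,nmk->nm", qvec, D) * inv_det
        t = np.einsum("nmk,mk->nm", qvec, e2) * inv_det
    hit = (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t > eps)
    t = np.where(hit, t, np.inf)
    best = t.min(axis=1)
    return np.where(np.isfinite(best), best, np.nan)


def slice_and_sample(
    pair: SurfacePair,
    slice_width: float = 8.0,
    dphi: float = 9.0,
    axis: Optional[np.ndarray] = None,
    centroid: Optional[np.ndarray] = None,
    centers: Optional[np.ndarray] = None,
) -> SliceSet:
    """Decompose the ventricle into short-axis slices and sample radii.

    Slice centers are spaced ``slice_width`` apart, anchored at the axial
    centroid so that re-slicing a deforming ventricle keeps the offsets
    relative to the moving center fixed; passing ``centers`` (axial
    offsets from the centroid) reuses a previously determined slice layout
    for a new time frame.  ``dphi`` is the polar angular sampling in
    degrees (N = 360/dphi rays per slice).
    """
    if axis is None or centroid is None:
        axis, centroid = long_axis(pair)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    centroid = np.asarray(centroid, float)

    n_rays = int(round(360.0 / dphi))
    # polar-angle origin from the endocardial PCA frame (second principal
    # direction projected into the slice plane): rigid-motion equivariant
    # whenever the transverse spectrum is nondegenerate; for axisymmetric
    # shapes the anchor is arbitrary but deterministic
    pts = np.asarray(pair.endo.vertices, float) - centroid
    _, evecs = np.linalg.eigh(np.cov(pts.T))
    u = evecs[:, 1] - (evecs[:, 1] @ axis) * axis
    if np.linalg.norm(u) < 1e-6:  # second axis parallel to the slicing axis
        u = evecs[:, 0] - (evecs[:, 0] @ axis) * axis
    u = u / np.linalg.norm(u)
    v = np.cross(axis, u)
    phis = np.deg2rad(dphi) * np.arange(n_rays)
    dirs = np.outer(np.cos(phis), u) + np.outer(np.sin(phis), v)

    if centers is None:
        z_endo = pts @ axis
        zmin, zmax = z_endo.min(), z_endo.max()
        # keep one slice width clear of apex and base, where short-axis
        # cross-sections are dominated by surface curvature rather than by
        # the chamber radius (the analog of excluding apical MRI slices);
        # tiny tolerance so the count is stable under rigid motion
        eps = 1e-9 * max(abs(zmin), abs(zmax), 1.0)
        n_neg = int(np.floor((-zmin - slice_width) / slice_width + eps))
        n_pos = int(np.floor((zmax - slice_width) / slice_width + eps))
        centers = slice_width * np.arange(-n_neg, n_pos + 1)
        if len(centers) == 0:
            centers = np.array([0.0])
    else:
        centers = np.asarray(centers, float)

    kept_z, kept_r, kept_R, dropped = [], [], [], []
    for z_i in centers:
        origin = centroid + z_i * axis
        origins = np.tile(origin, (n_rays, 1))
        r_ij = _first_hit_distances(pair.endo, origins, dirs)
        R_ij = _first_hit_distances(pair.epi, origins, dirs)
        bad = np.isnan(r_ij) | np.isnan(R_ij) | (R_ij <= r_ij)
        if bad.any():
            dropped.append(float(z_i))
            continue
        kept_z.append(z_i)
        kept_r.append(r_ij)
        kept_R.append(R_ij)
    if dropped:
        log.info("dropped %d slice(s) with missed rays at z=%s", len(dropped), dropped)
    if not kept_z:
        raise GeometryError("no usable slices: all rays missed a surface")
    return SliceSet(
        axis=axis,
        centroid=centroid,
        z=np.asarray(kept_z),
        r=np.vstack(kept_r),
        R=np.vstack(kept_R),
        dropped=dropped,
    )


def slice_means(sliceset: SliceSet) -> Tuple[float, float]:
    """Multi-slice mean radius and wall width (arithmetic means)."""
    if sliceset.r.size == 0:
        raise GeometryError("empty slice set")
    return float(sliceset.r_slice.mean()), float(sliceset.h_slice.mean())
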