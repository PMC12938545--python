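"""Spatial machinery: signed distance fields, airway caliber, cross-sections.

The signed distance field (SDF) gives each voxel its minimum distance to the
boundary of a compartment (airway lumen or vessel), negative inside and
positive outside. Depth into the airway and depth into a vessel are the
matched quantities used for intensity transfer. Distances are computed with
the exact Euclidean distance transform on both the mask and its complement,
which makes the sign symmetry exact and places the zero level set at the
interface between inside and outside voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .errors import DataError
from .grid import VolumeGrid
from .phantom import AnatomyModel, Branch, CenterlineTree

__all__ = [
    "SDFVolume",
    "CrossSection",
    "LumenMap",
    "signed_distance_field",
    "local_airway_diameter",
    "cross_section",
    "plug_length",
    "per_section_occlusion",
]


@dataclass
class SDFVolume:
    """Per-voxel signed distance (mm) to a mask boundary; negative inside."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    mask_role: str = "airway"

    def at(self, voxels: np.ndarray) -> np.ndarray:
        """Sample at integer voxel indices of shape (N, 3)."""
        v = np.asarray(voxels)
        return self.values[v[:, 0], v[:, 1], v[:, 2]]


def signed_distance_field(mask: VolumeGrid | np.ndarray,
                          spacing_mm: tuple[float, float, float] | None = None,
                          mask_role: str = "airway") -> SDFVolume:
    """Exact Euclidean signed distance field of a binary mask.

    ``sdf = edt(~mask) - edt(mask)``: strictly negative inside, strictly
    positive outside, antisymmetric under mask complement. Magnitudes are
    distances to the nearest voxel center of the opposite class, so the zero
    crossing lies on the face boundary between inside and outside voxels.
    """
    if isinstance(mask, VolumeGrid):
        spacing_mm = mask.spacing_mm
        mask = mask.data
    if spacing_mm is None:
        raise DataError("spacing_mm required when mask is a bare array")
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise DataError("cannot compute SDF of an empty mask (no boundary)")
    if m.all():
        raise DataError("cannot compute SDF of an all-true mask (no boundary)")
    dist_out = ndi.distance_transform_edt(~m, sampling=spacing_mm)
    dist_in = ndi.distance_transform_edt(m, sampling=spacing_mm)
    return SDFVolume((dist_out - dist_in).astype(np.float64), tuple(spacing_mm), mask_role)


# ---------------------------------------------------------------------------
# Centerline queries


def _nearest_on_branch(branch: Branch, point: np.ndarray) -> tuple[float, float, float]:
    """(distance, arc_position_mm, interpolated_radius) of the nearest point
    on a branch polyline, with linear interpolation along segments."""
    pts = branch.points
    arc = branch.arc_lengths
    if len(pts) == 1:
        return float(np.linalg.norm(point - pts[0])), 0.0, float(branch.radii[0])
    seg = pts[1:] - pts[:-1]
    len2 = np.einsum("ij,ij->i", seg, seg)
    t = np.clip(np.einsum("ij,ij->i", point - pts[:-1], seg) / np.maximum(len2, 1e-12), 0.0, 1.0)
    proj = pts[:-1] + t[:, None] * seg
    d = np.linalg.norm(point - proj, axis=1)
    i = int(np.argmin(d))
    s = arc[i] + t[i] * (arc[i + 1] - arc[i])
    r = branch.radii[i] + t[i] * (branch.radii[i + 1] - branch.radii[i])
    return float(d[i]), float(s), float(r)


def local_airway_diameter(tree: CenterlineTree, point_mm: np.ndarray,
                          max_distance_mm: float = 5.0) -> float:
    """Airway diameter (2 x interpolated lumen radius) at the centerline
    location nearest to ``point_mm``.

    Raises DataError when the query point is farther than ``max_distance_mm``
    from every branch.
    """
    point = np.asarray(point_mm, dtype=float)
    best = (np.inf, 0.0, 0.0)
    for b in tree.branches:
        cand = _nearest_on_branch(b, point)
        if cand[0] < best[0]:
            best = cand
    if best[0] > max_distance_mm:
        raise DataError(
            f"point {tuple(np.round(point, 2))} is {best[0]:.2f} mm from the nearest "
            f"centerline (max {max_distance_mm} mm)"
        )
    return 2.0 * best[2]


# ---------------------------------------------------------------------------
# Lumen parametrization (voxel -> branch / arc position / radial offset)


class LumenMap:
    """Per-voxel parametrization of the airway lumen along the centerline tree.

    Every lumen voxel is assigned to its nearest branch and given an
    arc-length coordinate ``s`` (mm along that branch), a radial offset
    vector in the plane normal to the branch axis, and a section bin index
    ``floor(s / bin_width)``. This is the substrate for constrained plug
    growth and for per-section occlusion measurement; section bins are
    one-voxel-thick slabs along the centerline.
    """

    def __init__(self, anatomy: AnatomyModel, centerline_step_mm: float | None = None):
        grid = anatomy.airway_lumen_mask
        self.grid = grid
        self.bin_width = float(min(grid.spacing_mm))
        lumen = grid.data.astype(bool)
        vox = np.argwhere(lumen)
        if len(vox) == 0:
            raise DataError("anatomy has an empty airway lumen mask")
        self.voxels = vox
        coords = grid.index_to_world(vox)

        pts, bids, arcs, radii, tangents = [], [], [], [], []
        for b in anatomy.centerlines.branches:
            pts.append(b.points)
            bids.append(np.full(len(b.points), b.id))
            arcs.append(b.arc_lengths)
            radii.append(b.radii)
            d = b.direction
            tangents.append(np.tile(d, (len(b.points), 1)))
        cl_pts = np.concatenate(pts)
        cl_bid = np.concatenate(bids)
        cl_arc = np.concatenate(arcs)
        cl_rad = np.concatenate(radii)
        cl_tan = np.concatenate(tangents)

        tree = cKDTree(cl_pts)
        _, nearest = tree.query(coords, workers=-1)
        self.branch_id = cl_bid[nearest]
        tan = cl_tan[nearest]
        delta = coords - cl_pts[nearest]
        along = np.einsum("ij,ij->i", delta, tan)
        self.s = cl_arc[nearest] + along
        self.radial = delta - along[:, None] * tan
        self.radius = cl_rad[nearest]
        self.bin = np.floor(self.s / self.bin_width).astype(int)

        # flat voxel index -> row lookup
        self._flat = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), grid.shape)
        self._row_of = {f: i for i, f in enumerate(self._flat)}

        # per-branch bin ranges and per-(branch, bin) row groups
        self.branch_bins: dict[int, tuple[int, int]] = {}
        self.groups: dict[tuple[int, int], np.ndarray] = {}
        order = np.lexsort((self.bin, self.branch_id))
        b_sorted = self.branch_id[order]
        k_sorted = self.bin[order]
        boundaries = np.nonzero(np.diff(b_sorted) | (np.diff(k_sorted) != 0))[0] + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(order)]])
        for s0, e0 in zip(starts, ends):
            b, k = int(b_sorted[s0]), int(k_sorted[s0])
            self.groups[(b, k)] = order[s0:e0]
            lo, hi = self.branch_bins.get(b, (k, k))
            self.branch_bins[b] = (min(lo, k), max(hi, k))

    def row_of_voxel(self, voxel: tuple[int, int, int]) -> int:
        f = int(np.ravel_multi_index(tuple(voxel), self.grid.shape))
        if f not in self._row_of:
            raise DataError(f"voxel {tuple(voxel)} is not inside the airway lumen")
        return self._row_of[f]

    def rows_in_bin(self, branch_id: int, k: int) -> np.ndarray:
        return self.groups.get((branch_id, k), np.empty(0, dtype=int))


# ---------------------------------------------------------------------------
# Cross-sections


@dataclass
class CrossSection:
    """A one-voxel-thick lumen slab normal to the local airway axis."""

    point_mm: np.ndarray
    tangent: np.ndarray
    lumen_voxels: np.ndarray      # (N, 3) indices
    plugged_voxels: np.ndarray    # (M, 3) indices, subset of lumen_voxels
    lumen_area_mm2: float
    plugged_area_mm2: float

    @property
    def occlusion_ratio(self) -> float:
        if self.lumen_area_mm2 == 0:
            return 0.0
        return self.plugged_area_mm2 / self.lumen_area_mm2


def cross_section(lumen_mask: VolumeGrid, plug_mask: np.ndarray | None,
                  point_mm: np.ndarray, tangent: np.ndarray) -> CrossSection:
    """Lumen and plugged voxel sets in the slab through ``point_mm`` normal to
    ``tangent``, restricted to the connected lumen component containing the point.

    Slab thickness is one voxel (extent of a voxel along the tangent); areas
    are voxel counts times the in-plane voxel area.
    """
    t = np.asarray(tangent, dtype=float)
    norm = np.linalg.norm(t)
    if norm == 0:
        raise DataError("tangent must be nonzero")
    t = t / norm
    point = np.asarray(point_mm, dtype=float)

    lumen = lumen_mask.data.astype(bool)
    idx = np.rint(lumen_mask.world_to_index(point)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(lumen.shape)) or not lumen[tuple(idx)]:
        raise DataError(f"point {tuple(np.round(point, 2))} is outside the airway lumen")

    from skimage import measure

    labels = measure.label(lumen, connectivity=3)
    comp = labels == labels[tuple(idx)]

    vox = np.argwhere(comp)
    coords = lumen_mask.index_to_world(vox)
    spacing = np.asarray(lumen_mask.spacing_mm)
    slab_thickness = float(np.sum(np.abs(t) * spacing))
    dist_along = (coords - point) @ t
    in_slab = np.abs(dist_along) <= slab_thickness / 2.0
    lumen_vox = vox[in_slab]

    voxel_volume = float(np.prod(spacing))
    in_plane_area = voxel_volume / slab_thickness

    if plug_mask is None:
        plug = np.zeros_like(lumen)
    else:
        plug = np.asarray(plug_mask).astype(bool)
    plugged_flags = plug[lumen_vox[:, 0], lumen_vox[:, 1], lumen_vox[:, 2]]
    plugged_vox = lumen_vox[plugged_flags]

    return CrossSection(
        point_mm=point,
        tangent=t,
        lumen_voxels=lumen_vox,
        plugged_voxels=plugged_vox,
        lumen_area_mm2=len(lumen_vox) * in_plane_area,
        plugged_area_mm2=len(plugged_vox) * in_plane_area,
    )


# ---------------------------------------------------------------------------
# Plug measurements


def plug_length(plug_voxels: np.ndarray, tree: CenterlineTree,
                spacing_mm: tuple[float, float, float],
                origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> float:
    """Longitudinal extent (mm) of a plug along its host branch centerline.

    The extent is the arc-length span between the extreme projections of the
    plug voxels onto the branch, plus one voxel spacing so that a single-voxel
    plug reports one voxel of extent (keeps length-bin assignment total).
    Raises DataError when the voxels project onto more than one branch.
    """
    vox = np.asarray(plug_voxels)
    if vox.ndim != 2 or vox.shape[1] != 3 or len(vox) == 0:
        raise DataError("plug_voxels must be a nonempty (N, 3) index array")
    coords = vox * np.asarray(spacing_mm) + np.asarray(origin_mm)

    hosts, s_vals = [], []
    for c in coords:
        best = (np.inf, 0.0, None)
        for b in tree.branches:
            d, s, _ = _nearest_on_branch(b, c)
            if d < best[0]:
                best = (d, s, b.id)
        hosts.append(best[2])
        s_vals.append(best[1])
    if len(set(hosts)) > 1:
        raise DataError(f"plug spans multiple branches {sorted(set(hosts))}: invalid plug")
    h = float(min(spacing_mm))
    return float(max(s_vals) - min(s_vals)) + h


def per_section_occlusion(plug_voxels: np.ndarray, lumen_map: LumenMap) -> dict[int, float]:
    """Occlusion ratio (plugged / lumen voxel count) per covered section bin.

    A section bin is covered when it holds at least one plug voxel. This is
    the measurement used to audit the per-cross-section occlusion floor.
    """
    vox = np.asarray(plug_voxels)
    rows = np.array([lumen_map.row_of_voxel(tuple(v)) for v in vox])
    branches = np.unique(lumen_map.branch_id[rows])
    out: dict[int, float] = {}
    for b in branches:
        sel = rows[lumen_map.branch_id[rows] == b]
        for k in np.unique(lumen_map.bin[sel]):
            total = len(lumen_map.rows_in_bin(int(b), int(k)))
            plugged = int(np.sum(lumen_map.bin[sel] == k))
            out[int(k)] = plugged / total if total else 0.0
    return out
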