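"""Procedural CT phantoms: bifurcating airway trees with companion vessels.

The phantom stands in for a segmented thin-slice chest CT: it provides a
CT-like HU volume together with exact lung / airway-lumen / vessel masks and
the airway centerline tree with per-point lumen radius. Airways are straight
tubes arranged in a dichotomously branching tree; each branch carries one
companion vessel tube of comparable caliber running parallel at a fixed
center-to-center offset, mimicking the bronchoarterial pairing seen in real
lungs.

Default dimensions were chosen so that a single phantom comfortably hosts the
standard augmentation density of 50 disjoint plugs per scan: the depth-5 tree
has ~730 mm of total centerline, against an expected corridor demand of
50 plugs x ~11 mm mean target length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError, PhantomGeometryError
from .grid import VolumeGrid

__all__ = [
    "PhantomSpec",
    "Branch",
    "CenterlineTree",
    "AnatomyModel",
    "build_airway_tree",
    "rasterize_phantom",
    "generate_phantom",
    "save_case",
    "load_case",
]

_CENTERLINE_STEP_FRACTION = 0.5  # centerline sampling step, in voxels


@dataclass
class PhantomSpec:
    """Parameters of one procedural phantom.

    All lengths in mm, attenuations in HU. ``radius_taper`` scales lumen
    radius per bifurcation generation; ``length_taper`` does the same for
    segment length. ``vessel_offset_mm`` is the center-to-center distance
    between each airway branch and its companion vessel, which must exceed
    the sum of airway outer radius and vessel radius at the trunk.
    """

    volume_shape: tuple[int, int, int] = (112, 112, 112)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tree_depth: int = 5
    root_radius_mm: float = 4.0
    radius_taper: float = 0.8
    branch_length_mm: float = 22.0
    length_taper: float = 0.85
    branch_angle_deg: float = 32.0
    wall_thickness_mm: float = 1.0
    vessel_offset_mm: float = 10.0
    vessel_radius_ratio: float = 0.7
    hu_lumen: float = -1000.0
    hu_wall: float = -200.0
    hu_vessel: float = 40.0
    hu_parenchyma: float = -850.0
    noise_sigma_hu: float = 15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(n) for n in self.volume_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(n < 8 for n in self.volume_shape):
            raise ConfigError(f"volume_shape too small: {self.volume_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigError(f"spacing_mm must be positive: {self.spacing_mm}")
        if self.tree_depth < 0:
            raise ConfigError("tree_depth must be >= 0")
        if self.root_radius_mm <= 0:
            raise ConfigError("root_radius_mm must be > 0")
        if not (0.0 < self.radius_taper < 1.0):
            raise ConfigError("radius_taper must lie in (0, 1)")
        if not (0.0 < self.length_taper <= 1.0):
            raise ConfigError("length_taper must lie in (0, 1]")
        if self.branch_length_mm <= 0 or self.wall_thickness_mm < 0:
            raise ConfigError("branch_length_mm > 0 and wall_thickness_mm >= 0 required")
        if self.vessel_radius_ratio <= 0:
            raise ConfigError("vessel_radius_ratio must be > 0")
        root_outer = self.root_radius_mm + self.wall_thickness_mm
        root_vessel = self.vessel_radius_ratio * root_outer
        if self.vessel_offset_mm <= root_outer + root_vessel:
            raise ConfigError(
                f"vessel_offset_mm={self.vessel_offset_mm} must exceed airway outer radius "
                f"+ vessel radius at the trunk ({root_outer + root_vessel:.2f} mm)"
            )

    def radius_at(self, generation: int) -> float:
        return self.root_radius_mm * self.radius_taper**generation

    def length_at(self, generation: int) -> float:
        return self.branch_length_mm * self.length_taper**generation

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.volume_shape) * np.asarray(self.spacing_mm)


@dataclass
class Branch:
    """One straight airway segment with its companion vessel tube."""

    id: int
    parent: int | None
    generation: int
    points: np.ndarray          # (N, 3) world mm, ordered proximal -> distal
    radii: np.ndarray           # (N,) lumen radius in mm
    vessel_points: np.ndarray   # (N, 3) companion vessel centerline
    vessel_radius: float
    vessel_id: int = -1         # set equal to branch id by the builder

    @property
    def p0(self) -> np.ndarray:
        return self.points[0]

    @property
    def p1(self) -> np.ndarray:
        return self.points[-1]

    @property
    def direction(self) -> np.ndarray:
        d = self.p1 - self.p0
        return d / np.linalg.norm(d)

    @property
    def length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length (mm) at each centerline point."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class CenterlineTree:
    """Airway centerlines grouped into branches with parent/child topology."""

    branches: list[Branch]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = {b.id for b in self.branches}
        if len(ids) != len(self.branches):
            raise DataError("duplicate branch ids")
        roots = [b for b in self.branches if b.parent is None]
        if len(roots) != 1:
            raise DataError(f"tree must have exactly one root, found {len(roots)}")
        for b in self.branches:
            if np.any(b.radii <= 0):
                raise DataError(f"branch {b.id} has non-positive radius")
            if b.parent is not None:
                if b.parent not in ids:
                    raise DataError(f"branch {b.id} references missing parent {b.parent}")
                parent = self.branch(b.parent)
                if b.radii.max() > parent.radii.min() + 1e-9:
                    raise DataError(f"branch {b.id} radius exceeds parent radius")
        # connectivity/acyclicity: every branch must reach the root via parents
        for b in self.branches:
            seen, cur = set(), b
            while cur.parent is not None:
                if cur.id in seen:
                    raise DataError("cycle in branch topology")
                seen.add(cur.id)
                cur = self.branch(cur.parent)

    def branch(self, bid: int) -> Branch:
        for b in self.branches:
            if b.id == bid:
                return b
        raise KeyError(bid)

    def children(self, bid: int) -> list[Branch]:
        return [b for b in self.branches if b.parent == bid]

    @property
    def total_length_mm(self) -> float:
        return sum(b.length_mm for b in self.branches)

    # ------------------------------------------------------------------ I/O

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "id": b.id,
                "parent": b.parent,
                "generation": b.generation,
                "points": b.points.tolist(),
                "radii": b.radii.tolist(),
                "vessel_points": b.vessel_points.tolist(),
                "vessel_radius": b.vessel_radius,
                "vessel_id": b.vessel_id,
            }
            for b in self.branches
        ]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CenterlineTree":
        payload = json.loads(Path(path).read_text())
        branches = [
            Branch(
                id=d["id"],
                parent=d["parent"],
                generation=d["generation"],
                points=np.asarray(d["points"], dtype=float),
                radii=np.asarray(d["radii"], dtype=float),
                vessel_points=np.asarray(d["vessel_points"], dtype=float),
                vessel_radius=float(d["vessel_radius"]),
                vessel_id=d["vessel_id"],
            )
            for d in payload
        ]
        return cls(branches)


@dataclass
class AnatomyModel:
    """Bundle of CT + masks + centerlines for one case."""

    ct: VolumeGrid
    lung_mask: VolumeGrid
    airway_lumen_mask: VolumeGrid
    vessel_mask: VolumeGrid
    centerlines: CenterlineTree

    def validate(self) -> None:
        lumen = self.airway_lumen_mask.data.astype(bool)
        lung = self.lung_mask.data.astype(bool)
        vessel = self.vessel_mask.data.astype(bool)
        if lumen.shape != lung.shape or vessel.shape != lung.shape or self.ct.shape != lung.shape:
            raise DataError("anatomy grids have inconsistent shapes")
        if np.any(lumen & ~lung):
            raise DataError("airway lumen extends outside the lung mask")
        if np.any(vessel & lumen):
            raise DataError("vessel mask intersects the airway lumen")
        grid = self.airway_lumen_mask
        for b in self.centerlines.branches:
            idx = np.rint(grid.world_to_index(b.points)).astype(int)
            idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
            if not lumen[idx[:, 0], idx[:, 1], idx[:, 2]].all():
                raise DataError(f"centerline of branch {b.id} leaves the lumen mask")


# ---------------------------------------------------------------------------
# Tree construction


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    axis = _unit(axis)
    return (
        v * np.cos(angle_rad)
        + np.cross(axis, v) * np.sin(angle_rad)
        + axis * np.dot(axis, v) * (1.0 - np.cos(angle_rad))
    )


def build_airway_tree(spec: PhantomSpec, rng: np.random.Generator | None = None) -> CenterlineTree:
    """Grow a dichotomous airway tree that fits inside the phantom volume.

    Branch directions are rotated +-branch_angle_deg from the parent within a
    bifurcation plane that turns ~90 degrees each generation (with small
    random azimuthal jitter), plus a gentle bias along +z so the tree keeps
    descending like a real bronchial tree. Raises PhantomGeometryError when a
    branch (or its companion vessel) cannot fit inside the volume with a
    margin of its outer radius.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    extent = spec.extent_mm
    step = _CENTERLINE_STEP_FRACTION * min(spec.spacing_mm)
    zhat = np.array([1.0, 0.0, 0.0])  # axis order (z, y, x)

    root_outer = spec.root_radius_mm + spec.wall_thickness_mm
    start = np.array([root_outer + 2.0 * spec.spacing_mm[0], 0.5 * extent[1], 0.5 * extent[2]])

    branches: list[Branch] = []
    next_id = 0

    def margin_ok(points: np.ndarray, radius: float) -> bool:
        margin = radius + 1.5 * max(spec.spacing_mm)
        return bool(np.all(points >= margin) and np.all(points <= extent - margin))

    def sample_line(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
        n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / step)) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        return p0 + t * (p1 - p0)

    def add_branch(p0: np.ndarray, direction: np.ndarray, normal: np.ndarray,
                   generation: int, parent: int | None) -> None:
        nonlocal next_id
        r = spec.radius_at(generation)
        length = spec.length_at(generation)
        outer = r + spec.wall_thickness_mm
        r_vessel = spec.vessel_radius_ratio * outer

        # retry the stochastic jitter a few times if geometry exits the volume
        for attempt in range(8):
            jitter = np.deg2rad(rng.uniform(-12.0, 12.0))
            u = _rotate_about(normal, direction, jitter)
            u = _unit(u - np.dot(u, direction) * direction)
            d = direction
            if parent is not None:
                sign = 1.0 if (next_id % 2 == 0) else -1.0
                theta = np.deg2rad(spec.branch_angle_deg)
                d = _unit(np.cos(theta) * direction + sign * np.sin(theta) * u)
                d = _unit(d + 0.25 * zhat)  # descend bias
            p1 = p0 + d * length
            pts = sample_line(p0, p1)
            if margin_ok(pts, outer):
                break
        else:
            raise PhantomGeometryError(
                f"branch at generation {generation} (parent {parent}) does not fit inside "
                f"volume extent {tuple(np.round(extent, 1))} mm; shrink the tree or enlarge "
                f"the volume"
            )

        bid = next_id
        next_id += 1
        branches.append(
            Branch(
                id=bid,
                parent=parent,
                generation=generation,
                points=pts,
                radii=np.full(len(pts), r),
                vessel_points=pts.copy(),  # placeholder; _place_vessels fills in
                vessel_radius=r_vessel,
                vessel_id=bid,
            )
        )
        if generation < spec.tree_depth:
            # children bifurcate in the plane spanned by (d, u rotated 90deg)
            child_normal = _unit(np.cross(d, u))
            add_branch(p1, d, child_normal, generation + 1, bid)
            add_branch(p1, d, child_normal, generation + 1, bid)

    if not margin_ok(start[None, :], root_outer):
        raise PhantomGeometryError("root does not fit inside the volume")
    add_branch(start, zhat.copy(), np.array([0.0, 1.0, 0.0]), 0, None)
    _place_vessels(branches, spec, rng, extent)
    return CenterlineTree(branches)


def _segment_distance(p0: np.ndarray, p1: np.ndarray, q0: np.ndarray, q1: np.ndarray) -> float:
    """Minimum distance between two 3-D segments (sampled; ample for clearance checks)."""
    t = np.linspace(0.0, 1.0, 24)
    a = p0 + t[:, None] * (p1 - p0)
    d = q1 - q0
    len2 = float(np.dot(d, d))
    if len2 == 0:
        return float(np.min(np.linalg.norm(a - q0, axis=1)))
    s = np.clip((a - q0) @ d / len2, 0.0, 1.0)
    b = q0 + s[:, None] * d
    return float(np.min(np.linalg.norm(a - b, axis=1)))


def _place_vessels(branches: list[Branch], spec: PhantomSpec,
                   rng: np.random.Generator, extent: np.ndarray) -> None:
    """Assign each branch a parallel companion vessel at the configured offset.

    The offset direction is searched over azimuths around the branch axis so
    that the vessel tube stays inside the volume and clear of every airway
    lumen and previously placed vessel. Raises PhantomGeometryError naming
    the branch when no clear azimuth exists.
    """
    clearance = 0.75 * max(spec.spacing_mm)
    placed: list[tuple[np.ndarray, np.ndarray, float]] = []
    for b in branches:
        d = b.direction
        ref = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(ref, d)) > 0.9:
            ref = np.array([0.0, 0.0, 1.0])
        base = _unit(ref - np.dot(ref, d) * d)
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        margin = b.vessel_radius + 1.5 * max(spec.spacing_mm)
        best = None
        for k in range(16):
            phi = phi0 + k * (2.0 * np.pi / 16.0)
            w = _rotate_about(base, d, phi)
            vpts = b.points + w * spec.vessel_offset_mm
            if not (np.all(vpts >= margin) and np.all(vpts <= extent - margin)):
                continue
            v0, v1 = vpts[0], vpts[-1]
            ok_lumen = all(
                _segment_distance(v0, v1, o.p0, o.p1) > b.vessel_radius + float(o.radii[0]) + clearance
                for o in branches
            )
            if not ok_lumen:
                continue
            ok_vessel = all(
                _segment_distance(v0, v1, q0, q1) > b.vessel_radius + rv + clearance
                for q0, q1, rv in placed
            )
            if ok_vessel:
                best = vpts
                break
            if best is None:
                best = vpts  # lumen-clear but vessel-touching: acceptable fallback
        if best is None:
            raise PhantomGeometryError(
                f"no collision-free companion-vessel placement for branch {b.id}; "
                f"increase the volume or vessel_offset_mm"
            )
        b.vessel_points = best
        placed.append((best[0], best[-1], b.vessel_radius))


# ---------------------------------------------------------------------------
# Rasterization


def _paint_tube(grid: VolumeGrid, p0: np.ndarray,
                p1: np.ndarray, radius: float) -> np.ndarray:
    """Return a boolean mask (full volume) of voxels within radius of segment p0-p1."""
    spacing = np.asarray(grid.spacing_mm)
    origin = np.asarray(grid.origin_mm)
    shape = np.asarray(grid.shape)

    lo = np.maximum(np.floor((np.minimum(p0, p1) - radius - origin) / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + radius - origin) / spacing).astype(int) + 2, shape)
    if np.any(hi <= lo):
        return np.zeros(grid.shape, dtype=bool)

    zz = origin[0] + np.arange(lo[0], hi[0]) * spacing[0]
    yy = origin[1] + np.arange(lo[1], hi[1]) * spacing[1]
    xx = origin[2] + np.arange(lo[2], hi[2]) * spacing[2]
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    P = np.stack([Z, Y, X], axis=-1)

    d = p1 - p0
    seg_len2 = float(np.dot(d, d))
    if seg_len2 == 0:
        dist = np.linalg.norm(P - p0, axis=-1)
    else:
        t = np.clip(np.einsum("...k,k->...", P - p0, d) / seg_len2, 0.0, 1.0)
        closest = p0 + t[..., None] * d
        dist = np.linalg.norm(P - closest, axis=-1)

    mask = np.zeros(grid.shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = dist <= radius
    return mask


def rasterize_phantom(tree: CenterlineTree, spec: PhantomSpec,
                      rng: np.random.Generator | None = None) -> AnatomyModel:
    """Voxelize the tree into CT + masks.

    Lumen voxels get hu_lumen, the wall shell hu_wall, companion vessels
    hu_vessel and everything else hu_parenchyma; Gaussian noise perturbs the
    HU volume only, never the masks. Raises PhantomGeometryError if any
    vessel tube intersects the airway lumen.
    """
    rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1) if rng is None else rng
    proto = VolumeGrid(np.zeros(spec.volume_shape, dtype=np.uint8), spec.spacing_mm)

    lumen = np.zeros(spec.volume_shape, dtype=bool)
    outer = np.zeros(spec.volume_shape, dtype=bool)
    for b in tree.branches:
        r = float(b.radii[0])
        lumen |= _paint_tube(proto, b.p0, b.p1, r)
        outer |= _paint_tube(proto, b.p0, b.p1, r + spec.wall_thickness_mm)

    vessel = np.zeros(spec.volume_shape, dtype=bool)
    for b in tree.branches:
        tube = _paint_tube(proto, b.vessel_points[0], b.vessel_points[-1], b.vessel_radius)
        if np.any(tube & lumen):
            raise PhantomGeometryError(
                f"companion vessel of branch {b.id} intersects an airway lumen; "
                f"increase vessel_offset_mm or reduce radii"
            )
        vessel |= tube
    wall = outer & ~lumen

    lung = np.zeros(spec.volume_shape, dtype=bool)
    lung[1:-1, 1:-1, 1:-1] = True

    ct = np.full(spec.volume_shape, spec.hu_parenchyma, dtype=np.float32)
    ct[wall] = spec.hu_wall
    ct[vessel] = spec.hu_vessel
    ct[lumen] = spec.hu_lumen
    if spec.noise_sigma_hu > 0:
        ct = ct + rng.normal(0.0, spec.noise_sigma_hu, spec.volume_shape).astype(np.float32)

    model = AnatomyModel(
        ct=proto.with_data(ct),
        lung_mask=proto.with_data(lung),
        airway_lumen_mask=proto.with_data(lumen),
        vessel_mask=proto.with_data(vessel),
        centerlines=tree,
    )
    model.validate()
    return model


def generate_phantom(spec: PhantomSpec) -> AnatomyModel:
    """Build + rasterize in one reproducible step (seeded from ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    tree = build_airway_tree(spec, rng)
    return rasterize_phantom(tree, spec, rng)


# ---------------------------------------------------------------------------
# Case I/O


def save_case(model: AnatomyModel, out_dir: str | Path, case_id: str) -> list[Path]:
    """Write ``case_XXXX_{ct,lung,airway,vessel}.nii.gz`` + centerline JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for suffix, grid in [
        ("ct", model.ct),
        ("lung", model.lung_mask),
        ("airway", model.airway_lumen_mask),
        ("vessel", model.vessel_mask),
    ]:
        p = out / f"{case_id}_{suffix}.nii.gz"
        grid.save(p)
        written.append(p)
    tree_path = out / f"{case_id}_centerlines.json"
    model.centerlines.to_json(tree_path)
    written.append(tree_path)
    return written


def load_case(in_dir: str | Path, case_id: str) -> AnatomyModel:
    d = Path(in_dir)
    model = AnatomyModel(
        ct=VolumeGrid.load(d / f"{case_id}_ct.nii.gz"),
        lung_mask=VolumeGrid.load(d / f"{case_id}_lung.nii.gz"),
        airway_lumen_mask=VolumeGrid.load(d / f"{case_id}_airway.nii.gz"),
        vessel_mask=VolumeGrid.load(d / f"{case_id}_vessel.nii.gz"),
        centerlines=CenterlineTree.from_json(d / f"{case_id}_centerlines.json"),
    )
    model.validate()
    return model
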