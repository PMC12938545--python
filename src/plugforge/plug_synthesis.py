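"""Constrained region growing of synthetic mucus plugs.

A plug phenotype samples three anatomical parameters — target length along
the airway centerline (2-20 mm), target occlusion ratio (0.35-1.0), and the
eligible airway caliber range (1-20 mm diameter) — and a plug is grown from a
random seed voxel inside the airway lumen until the targets are met. Growth
is confined to the lumen, never crosses a bifurcation (a plug lives on one
branch), and proceeds deterministically given (anatomy, seed, phenotype):
the longitudinal window expands one section at a time around the seed, and
within each one-voxel-thick section the plugged region accretes lumen voxels
in order of in-plane distance from an anchor until the section's occlusion
ratio reaches the target. The anchor is the seed's own radial offset
(mural-adherent growth, the default: mucus tends to line the airway wall) or
the centerline (centered growth).

Plugs may be truncated when the host branch, or the free interval between
previously placed plugs, is shorter than the target length; the truncation
is flagged on the plug. This keeps a fixed per-scan density achievable on
compact anatomies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import ConfigError, DataError, NoEligibleSite
from .geometry import LumenMap
from .grid import VolumeGrid
from .phantom import AnatomyModel

__all__ = [
    "PlugPhenotype",
    "SyntheticPlug",
    "PlugSamplingConfig",
    "sample_phenotype",
    "select_seed",
    "grow_plug",
    "populate_scan",
    "plugs_to_dataframe",
]


@dataclass
class PlugSamplingConfig:
    """Sampling ranges and growth options; defaults follow the study protocol."""

    length_range_mm: tuple[float, float] = (2.0, 20.0)
    occlusion_range: tuple[float, float] = (0.35, 1.0)
    eligible_diameter_mm: tuple[float, float] = (1.0, 20.0)
    mural_adherent: bool = True
    allow_truncation: bool = True
    max_seed_attempts: int = 200
    max_phenotype_resamples: int = 50

    def __post_init__(self) -> None:
        for name, (lo, hi) in [
            ("length_range_mm", self.length_range_mm),
            ("occlusion_range", self.occlusion_range),
            ("eligible_diameter_mm", self.eligible_diameter_mm),
        ]:
            if lo > hi:
                raise ConfigError(f"{name} is empty: ({lo}, {hi})")
        if not (0.0 < self.occlusion_range[0] <= self.occlusion_range[1] <= 1.0):
            raise ConfigError(f"occlusion_range must lie within (0, 1]: {self.occlusion_range}")
        if self.length_range_mm[0] <= 0:
            raise ConfigError("length_range_mm must be positive")


@dataclass
class PlugPhenotype:
    """Sampled target parameters for one synthetic plug."""

    target_length_mm: float
    target_occlusion_ratio: float
    eligible_diameter_mm: tuple[float, float]
    distribution: str = "uniform"


@dataclass
class SyntheticPlug:
    """A realized plug: voxel set plus achieved measurements."""

    label_id: int
    seed_voxel: tuple[int, int, int]
    voxels: np.ndarray                       # (N, 3) indices, 26-connected
    host_branch: int
    achieved_length_mm: float
    achieved_occlusion_ratio: float          # mean over covered sections
    volume_mm3: float
    phenotype: PlugPhenotype
    truncated: bool = False
    section_bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    section_occlusion: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def sample_phenotype(config: PlugSamplingConfig, rng: np.random.Generator) -> PlugPhenotype:
    """Independent uniform draws of length and occlusion ratio; the eligible
    caliber range passes through unchanged."""
    lo, hi = config.length_range_mm
    length = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    lo, hi = config.occlusion_range
    occl = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return PlugPhenotype(length, occl, tuple(config.eligible_diameter_mm))


def _free_run(lumen_map: LumenMap, occupied: set[tuple[int, int]], branch: int,
              k_seed: int) -> tuple[int, int]:
    """Maximal contiguous free bin interval around k_seed within the branch."""
    kmin, kmax = lumen_map.branch_bins[branch]
    lo = k_seed
    while lo - 1 >= kmin and (branch, lo - 1) not in occupied:
        lo -= 1
    hi = k_seed
    while hi + 1 <= kmax and (branch, hi + 1) not in occupied:
        hi += 1
    return lo, hi


def select_seed(anatomy: AnatomyModel, phenotype: PlugPhenotype,
                existing_occupied: set[tuple[int, int]] | None,
                rng: np.random.Generator,
                lumen_map: LumenMap | None = None,
                config: PlugSamplingConfig | None = None) -> tuple[int, int, int]:
    """Uniformly sample an eligible lumen voxel to seed a plug.

    Eligibility: the local airway diameter lies in the phenotype's eligible
    range and the seed's section is not owned by an existing plug. When
    truncation is disabled, the full target-length corridor around the seed
    must additionally be free and inside the branch. Raises NoEligibleSite
    after ``config.max_seed_attempts`` failed draws (or when the pool is empty).
    """
    config = config or PlugSamplingConfig()
    lm = lumen_map if lumen_map is not None else LumenMap(anatomy)
    occupied = existing_occupied or set()

    d_lo, d_hi = phenotype.eligible_diameter_mm
    diam = 2.0 * lm.radius
    eligible = (diam >= d_lo) & (diam <= d_hi)
    pool = np.nonzero(eligible)[0]
    if len(pool) == 0:
        raise NoEligibleSite(
            f"no lumen voxel with airway diameter in [{d_lo}, {d_hi}] mm"
        )
    h = lm.bin_width
    n_bins = max(1, int(np.floor(phenotype.target_length_mm / h)))
    for _ in range(config.max_seed_attempts):
        row = int(pool[rng.integers(len(pool))])
        b = int(lm.branch_id[row])
        k = int(lm.bin[row])
        if (b, k) in occupied:
            continue
        if not config.allow_truncation:
            lo, hi = _free_run(lm, occupied, b, k)
            if hi - lo + 1 < n_bins:
                continue
        return tuple(int(v) for v in lm.voxels[row])
    raise NoEligibleSite(
        f"no eligible seed found in {config.max_seed_attempts} attempts "
        f"(diameter range [{d_lo}, {d_hi}] mm, length {phenotype.target_length_mm:.1f} mm)"
    )


def _connected_component(rows: np.ndarray, lumen_map: LumenMap, seed_row: int) -> np.ndarray:
    """Rows of the 26-connected component containing the seed row."""
    vox = lumen_map.voxels[rows]
    lo = vox.min(axis=0)
    sub = np.zeros(vox.max(axis=0) - lo + 1, dtype=bool)
    sub[tuple((vox - lo).T)] = True
    labels = measure.label(sub, connectivity=3)
    seed_sub = tuple(lumen_map.voxels[seed_row] - lo)
    keep = labels[tuple((vox - lo).T)] == labels[seed_sub]
    return rows[keep]


def grow_plug(anatomy: AnatomyModel, seed: tuple[int, int, int],
              phenotype: PlugPhenotype,
              lumen_map: LumenMap | None = None,
              occupied: set[tuple[int, int]] | None = None,
              config: PlugSamplingConfig | None = None,
              label_id: int = 1) -> SyntheticPlug:
    """Grow one plug from a seed voxel, deterministically.

    The longitudinal window covers ``floor(target_length / voxel)`` sections
    centered on the seed, clipped to the host branch (and to the free
    interval between existing plugs when ``occupied`` is given); clipping
    sets the ``truncated`` flag. Within each section, ``ceil(q * n)`` of the
    ``n`` lumen voxels are plugged, accreted in order of in-plane distance
    from the growth anchor, which guarantees an occlusion ratio of at least
    ``q`` at every covered section. The final voxel set is the 26-connected
    component containing the seed.
    """
    config = config or PlugSamplingConfig()
    lm = lumen_map if lumen_map is not None else LumenMap(anatomy)
    occupied = occupied or set()

    seed_row = lm.row_of_voxel(seed)
    b = int(lm.branch_id[seed_row])
    k_seed = int(lm.bin[seed_row])
    if (b, k_seed) in occupied:
        raise NoEligibleSite(f"seed section ({b}, {k_seed}) already occupied")

    h = lm.bin_width
    q = phenotype.target_occlusion_ratio
    n_bins = max(1, int(np.floor(phenotype.target_length_mm / h)))
    run_lo, run_hi = _free_run(lm, occupied, b, k_seed)

    # expand the window alternately left/right from the seed within the free run
    lo = hi = k_seed
    while hi - lo + 1 < n_bins and (lo > run_lo or hi < run_hi):
        if (k_seed - lo <= hi - k_seed and lo > run_lo) or hi >= run_hi:
            lo -= 1
        else:
            hi += 1
    truncated = (hi - lo + 1) < n_bins

    anchor = lm.radial[seed_row] if config.mural_adherent else np.zeros(3)

    selected: list[np.ndarray] = []
    for k in range(lo, hi + 1):
        rows = lm.rows_in_bin(b, k)
        n = len(rows)
        if n == 0:
            continue
        m = int(np.ceil(q * n - 1e-9))
        m = max(1, min(m, n))
        dist = np.linalg.norm(lm.radial[rows] - anchor, axis=1)
        order = np.argsort(dist, kind="stable")
        selected.append(rows[order[:m]])
    rows_sel = np.concatenate(selected)
    if seed_row not in rows_sel:
        rows_sel = np.concatenate([rows_sel, [seed_row]])

    # connectivity: keep the component containing the seed; if that drops any
    # section below the occlusion floor, trim the offending sections and repeat
    for _ in range(8):
        rows_sel = _connected_component(rows_sel, lm, seed_row)
        bins_sel = lm.bin[rows_sel]
        bad = []
        for k in np.unique(bins_sel):
            n = len(lm.rows_in_bin(b, int(k)))
            if n and np.sum(bins_sel == k) / n < q - 1e-9:
                bad.append(k)
        if not bad:
            break
        if k_seed in bad:
            raise NoEligibleSite("plug degenerated at the seed section during growth")
        rows_sel = rows_sel[~np.isin(bins_sel, bad)]
        truncated = True

    bins_sel = lm.bin[rows_sel]
    uniq = np.unique(bins_sel)
    ratios = np.array([
        np.sum(bins_sel == k) / len(lm.rows_in_bin(b, int(k))) for k in uniq
    ])
    s_vals = lm.s[rows_sel]
    vox = lm.voxels[rows_sel]
    return SyntheticPlug(
        label_id=label_id,
        seed_voxel=tuple(int(v) for v in seed),
        voxels=vox,
        host_branch=b,
        achieved_length_mm=float(s_vals.max() - s_vals.min()) + h,
        achieved_occlusion_ratio=float(ratios.mean()),
        volume_mm3=len(vox) * lm.grid.voxel_volume_mm3,
        phenotype=phenotype,
        truncated=truncated,
        section_bins=uniq,
        section_occlusion=ratios,
    )


def populate_scan(anatomy: AnatomyModel, n_plugs: int,
                  config: PlugSamplingConfig | None = None,
                  rng: np.random.Generator | None = None,
                  lumen_map: LumenMap | None = None,
                  ) -> tuple[list[SyntheticPlug], VolumeGrid]:
    """Insert ``n_plugs`` pairwise-disjoint plugs into one anatomy.

    Returns the plug list and an instance-label volume (background 0, plug k
    labelled k). Phenotypes are resampled when no eligible site exists; if
    the anatomy saturates before reaching ``n_plugs`` a warning is emitted
    and fewer plugs are returned.
    """
    if n_plugs < 0:
        raise ConfigError("n_plugs must be >= 0")
    if not anatomy.airway_lumen_mask.data.any():
        raise DataError("anatomy has no airway mask")
    config = config or PlugSamplingConfig()
    rng = rng if rng is not None else np.random.default_rng()
    lm = lumen_map if lumen_map is not None else LumenMap(anatomy)

    plugs: list[SyntheticPlug] = []
    occupied: set[tuple[int, int]] = set()
    labels = np.zeros(anatomy.airway_lumen_mask.shape, dtype=np.int32)

    for i in range(1, n_plugs + 1):
        plug = None
        for _ in range(config.max_phenotype_resamples):
            phenotype = sample_phenotype(config, rng)
            try:
                seed = select_seed(anatomy, phenotype, occupied, rng, lm, config)
                plug = grow_plug(anatomy, seed, phenotype, lm, occupied, config, label_id=i)
                break
            except NoEligibleSite:
                continue
        if plug is None:
            warnings.warn(
                f"anatomy saturated after {len(plugs)} of {n_plugs} plugs",
                stacklevel=2,
            )
            break
        plugs.append(plug)
        for k in range(int(plug.section_bins.min()), int(plug.section_bins.max()) + 1):
            occupied.add((plug.host_branch, k))
        labels[plug.voxels[:, 0], plug.voxels[:, 1], plug.voxels[:, 2]] = plug.label_id

    return plugs, anatomy.airway_lumen_mask.with_data(labels)


def plugs_to_dataframe(plugs: list[SyntheticPlug]):
    """Per-plug summary table (one row per plug) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label_id": [p.label_id for p in plugs],
            "seed_z": [p.seed_voxel[0] for p in plugs],
            "seed_y": [p.seed_voxel[1] for p in plugs],
            "seed_x": [p.seed_voxel[2] for p in plugs],
            "branch": [p.host_branch for p in plugs],
            "length_mm": [p.achieved_length_mm for p in plugs],
            "occlusion": [p.achieved_occlusion_ratio for p in plugs],
            "volume_mm3": [p.volume_mm3 for p in plugs],
            "n_voxels": [p.n_voxels for p in plugs],
            "truncated": [p.truncated for p in plugs],
            "target_length_mm": [p.phenotype.target_length_mm for p in plugs],
            "target_occlusion": [p.phenotype.target_occlusion_ratio for p in plugs],
        }
    )
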