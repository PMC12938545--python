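"""Augmentation-density sweep harness.

Reproduces the shape of the plugs-per-scan optimization experiment on
phantoms: for each density (10..100 plugs per scan by default), phantoms are
populated, textured, scored by a pluggable detector callback, and summarized
as sensitivity, FP/scan, and Dice. With the built-in oracle detectors the
whole loop runs on a CPU in seconds per density; absolute values on real
CT require a trained network and are out of scope here — only the curve
machinery is reproduced.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from skimage import measure

from .config import RunConfig
from .errors import ConfigError
from .evaluation import dice, match_lesions, stratify_and_summarize
from .geometry import LumenMap
from .grid import VolumeGrid
from .intensity_transfer import transfer_scan
from .phantom import PhantomSpec, generate_phantom
from .plug_synthesis import populate_scan

__all__ = [
    "DEFAULT_SWEEP_COUNTS",
    "run_density_sweep",
    "perfect_oracle",
    "make_noisy_oracle",
]

DEFAULT_SWEEP_COUNTS = tuple(range(10, 101, 10))

# detector signature: (ct, instance_labels, rng) -> binary prediction array
Detector = Callable[[VolumeGrid, VolumeGrid, np.random.Generator], np.ndarray]


def perfect_oracle(ct: VolumeGrid, labels: VolumeGrid, rng: np.random.Generator) -> np.ndarray:
    """Returns the ground truth: sensitivity 1.0, FP/scan 0 by construction."""
    return labels.data > 0


def make_noisy_oracle(min_voxels: int = 2, fp_rate_per_scan: float = 0.0) -> Detector:
    """Oracle degraded like a small-lesion-blind detector.

    Drops every lesion smaller than ``min_voxels`` voxels and, optionally,
    hallucinates ``fp_rate_per_scan`` random one-voxel false positives in the
    parenchyma per scan.
    """

    def detector(ct: VolumeGrid, labels: VolumeGrid, rng: np.random.Generator) -> np.ndarray:
        pred = labels.data > 0
        inst = measure.label(pred, connectivity=3)
        for lid in range(1, inst.max() + 1):
            region = inst == lid
            if region.sum() < min_voxels:
                pred = pred & ~region
        n_fp = int(rng.poisson(fp_rate_per_scan)) if fp_rate_per_scan > 0 else 0
        for _ in range(n_fp):
            z, y, x = (rng.integers(2, s - 2) for s in pred.shape)
            if not pred[z, y, x]:
                pred[z, y, x] = True
        return pred

    return detector


def run_density_sweep(config: RunConfig,
                      detector: Detector,
                      counts: tuple[int, ...] = DEFAULT_SWEEP_COUNTS,
                      n_phantoms: int = 3,
                      rng: np.random.Generator | None = None,
                      with_transfer: bool = True) -> pd.DataFrame:
    """Sensitivity / FP-per-scan / Dice as a function of plugs per scan.

    Returns one row per density. The same phantom anatomies are reused across
    densities so the curve reflects the density alone.
    """
    if detector is None:
        raise ConfigError("run_density_sweep requires a detector callback")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_phantoms)
    anatomies = []
    for s in seeds:
        spec = PhantomSpec(**{**_spec_dict(config.phantom), "seed": int(s)})
        anatomy = generate_phantom(spec)
        anatomies.append((anatomy, LumenMap(anatomy)))

    rows = []
    for count in counts:
        matches, gt_lengths, pred_lengths, dices = [], [], [], []
        for anatomy, lm in anatomies:
            plugs, labels = populate_scan(
                anatomy, count, config.plugs, np.random.default_rng(rng.integers(2**31 - 1)), lm
            )
            ct = anatomy.ct
            if with_transfer:
                ct, _ = transfer_scan(anatomy, plugs, np.random.default_rng(rng.integers(2**31 - 1)),
                                      config.transfer)
            pred = detector(ct, labels, np.random.default_rng(rng.integers(2**31 - 1)))
            m = match_lesions(pred, labels.data)
            matches.append(m)
            gt_lengths.append({p.label_id: p.achieved_length_mm for p in plugs})
            dices.append(dice(pred, labels.data > 0))
        report = stratify_and_summarize(matches, gt_lengths, dice_scores=dices)
        rows.append(
            {
                "plugs_per_scan": count,
                "sensitivity": report.overall["sensitivity"],
                "fp_per_scan": report.overall["fp_per_scan"],
                "dice": report.dice_mean,
                "gt_lesions": report.overall["gt"],
                "tp": report.overall["tp"],
                "fp": report.overall["fp"],
            }
        )
    return pd.DataFrame(rows)


def _spec_dict(spec: PhantomSpec) -> dict:
    from dataclasses import asdict

    return asdict(spec)
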