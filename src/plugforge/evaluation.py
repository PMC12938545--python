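"""Pixel- and lesion-level scoring of plug segmentations.

Pixel level: the Dice similarity coefficient D(A,B) = 2|A∩B| / (|A|+|B|).
Lesion (object) level: a ground-truth lesion counts as a true positive when
at least one predicted voxel overlaps it; a predicted lesion overlapping no
ground-truth lesion is a false positive; a ground-truth lesion with no
overlapping prediction is a false negative. Sensitivity = TP / (TP + FN)
with a binomial 95 % CI (Wilson score by default), and the false-positive
burden is reported per scan. Results are stratified by lesion length into
the bins (0,3), [3,6), [6,15), [15,inf) mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import measure
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError

__all__ = [
    "LesionMatchResult",
    "DetectionReport",
    "PairedTestResult",
    "dice",
    "match_lesions",
    "stratify_and_summarize",
    "paired_compare",
    "DEFAULT_LENGTH_BINS",
]

DEFAULT_LENGTH_BINS = (0.0, 3.0, 6.0, 15.0)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks.

    Defined as 1.0 when both masks are empty (perfect agreement on absence);
    this 0/0 convention is the only degenerate case.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise DataError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / (na + nb)


@dataclass
class LesionMatchResult:
    """Lesion-level matching for one scan."""

    gt_ids: np.ndarray
    pred_ids: np.ndarray
    gt_matched: dict[int, bool]
    gt_to_preds: dict[int, list[int]]
    pred_matched: dict[int, bool]

    @property
    def tp(self) -> int:
        return sum(self.gt_matched.values())

    @property
    def fn(self) -> int:
        return len(self.gt_ids) - self.tp

    @property
    def fp(self) -> int:
        return sum(not m for m in self.pred_matched.values())

    @property
    def fp_ids(self) -> list[int]:
        return [i for i, m in self.pred_matched.items() if not m]


def _as_labels(volume: np.ndarray) -> np.ndarray:
    """Binary volumes are instance-labelled with 26-connectivity; labelled
    volumes pass through."""
    v = np.asarray(volume)
    if v.dtype == bool or set(np.unique(v)) <= {0, 1}:
        return measure.label(v.astype(bool), connectivity=3)
    return v.astype(int)


def match_lesions(pred: np.ndarray, gt: np.ndarray) -> LesionMatchResult:
    """One-voxel-overlap lesion matching.

    A predicted lesion overlapping k ground-truth lesions marks all k as
    detected and counts as matched once; an unmatched predicted lesion is a
    false positive. Inputs may be binary (connected components are computed,
    26-connectivity) or already instance-labelled.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise DataError(f"grid mismatch: {pred.shape} vs {gt.shape}")
    pred_l = _as_labels(pred)
    gt_l = _as_labels(gt)

    gt_ids = np.unique(gt_l[gt_l > 0])
    pred_ids = np.unique(pred_l[pred_l > 0])

    both = (pred_l > 0) & (gt_l > 0)
    pairs = np.unique(np.stack([gt_l[both], pred_l[both]], axis=1), axis=0) if both.any() else np.empty((0, 2), int)

    gt_matched = {int(g): False for g in gt_ids}
    gt_to_preds: dict[int, list[int]] = {int(g): [] for g in gt_ids}
    pred_matched = {int(p): False for p in pred_ids}
    for g, p in pairs:
        gt_matched[int(g)] = True
        gt_to_preds[int(g)].append(int(p))
        pred_matched[int(p)] = True

    return LesionMatchResult(gt_ids, pred_ids, gt_matched, gt_to_preds, pred_matched)


# ---------------------------------------------------------------------------
# Stratified summary


def _bin_label(length: float, edges: tuple[float, ...]) -> str:
    labels = _bin_labels(edges)
    for i in range(len(edges) - 1, 0, -1):
        if length >= edges[i]:
            return labels[i]
    return labels[0]


def _bin_labels(edges: tuple[float, ...]) -> list[str]:
    out = [f"({edges[0]:g},{edges[1]:g})"]
    for i in range(1, len(edges) - 1):
        out.append(f"[{edges[i]:g},{edges[i + 1]:g})")
    out.append(f"[{edges[-1]:g},inf)")
    return out


@dataclass
class BinSummary:
    gt: int = 0
    tp: int = 0
    fp: int = 0

    @property
    def fn(self) -> int:
        return self.gt - self.tp


@dataclass
class DetectionReport:
    """Pooled lesion-level detection summary over a set of scans."""

    n_scans: int
    bin_edges: tuple[float, ...]
    per_bin: dict[str, dict]
    overall: dict
    dice_mean: float | None = None
    dice_sd: float | None = None
    sensitivity_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "n_scans": self.n_scans,
            "bin_edges": list(self.bin_edges),
            "per_bin": self.per_bin,
            "overall": self.overall,
            "dice_mean": self.dice_mean,
            "dice_sd": self.dice_sd,
            "sensitivity_defined": self.sensitivity_defined,
        }

    def to_dataframe(self):
        import pandas as pd

        rows = [dict(bin=k, **v) for k, v in self.per_bin.items()]
        rows.append(dict(bin="all", **self.overall))
        return pd.DataFrame(rows)


def _rate_with_ci(tp: int, n: int, ci_method: str) -> tuple[float | None, float | None, float | None]:
    if n == 0:
        return None, None, None
    method = {"wilson": "wilson", "clopper-pearson": "beta"}[ci_method]
    lo, hi = proportion_confint(tp, n, alpha=0.05, method=method)
    return tp / n, float(lo), float(hi)


def stratify_and_summarize(matches: list[LesionMatchResult],
                           gt_lengths: list[dict[int, float]],
                           pred_lengths: list[dict[int, float]] | None = None,
                           bins: tuple[float, ...] = DEFAULT_LENGTH_BINS,
                           dice_scores: list[float] | None = None,
                           ci_method: str = "wilson") -> DetectionReport:
    """Pool per-scan matches into a size-stratified detection report.

    ``gt_lengths[i]`` maps ground-truth lesion id to its length (mm) for scan
    i; false positives are binned by the predicted lesion's own length from
    ``pred_lengths`` (pooled un-binned when absent). A scan set with no
    ground-truth lesions yields a report flagged ``sensitivity_defined=False``
    rather than a silent zero.
    """
    if len(matches) != len(gt_lengths):
        raise DataError("matches and gt_lengths must align per scan")
    n_scans = len(matches)
    labels = _bin_labels(bins)
    per_bin = {lab: BinSummary() for lab in labels}
    overall = BinSummary()

    for i, m in enumerate(matches):
        lengths = gt_lengths[i]
        for g in m.gt_ids:
            g = int(g)
            if g not in lengths:
                raise DataError(f"scan {i}: ground-truth lesion {g} has no length")
            lab = _bin_label(lengths[g], bins)
            per_bin[lab].gt += 1
            overall.gt += 1
            if m.gt_matched[g]:
                per_bin[lab].tp += 1
                overall.tp += 1
        for p in m.fp_ids:
            overall.fp += 1
            if pred_lengths is not None:
                plen = pred_lengths[i].get(int(p))
                if plen is not None:
                    per_bin[_bin_label(plen, bins)].fp += 1

    def summary(b: BinSummary) -> dict:
        sens, lo, hi = _rate_with_ci(b.tp, b.gt, ci_method)
        return {
            "gt": b.gt,
            "tp": b.tp,
            "fn": b.fn,
            "fp": b.fp,
            "sensitivity": sens,
            "ci95": [lo, hi] if sens is not None else None,
            "fp_per_scan": b.fp / n_scans if n_scans else None,
        }

    dice_mean = dice_sd = None
    if dice_scores:
        dice_mean = float(np.mean(dice_scores))
        dice_sd = float(np.std(dice_scores, ddof=1)) if len(dice_scores) > 1 else 0.0

    return DetectionReport(
        n_scans=n_scans,
        bin_edges=tuple(bins),
        per_bin={lab: summary(b) for lab, b in per_bin.items()},
        overall=summary(overall),
        dice_mean=dice_mean,
        dice_sd=dice_sd,
        sensitivity_defined=overall.gt > 0,
    )


# ---------------------------------------------------------------------------
# Paired comparison


@dataclass
class PairedTestResult:
    """Classical paired two-sided Student's t-test result.

    ``degenerate`` explains non-standard cases: "zero-variance" when the
    paired differences have no spread (p is 1.0 for identical vectors and
    0.0 for a constant nonzero shift), "insufficient-n" for n < 2.
    """

    t: float
    p: float
    dof: int
    mean_difference: float
    degenerate: str | None = None

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def paired_compare(metric_a: np.ndarray, metric_b: np.ndarray) -> PairedTestResult:
    """Paired two-sided Student's t-test of per-scan metrics."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("paired vectors must have equal length")
    n = len(a)
    d = a - b
    if n < 2:
        return PairedTestResult(np.nan, np.nan, max(n - 1, 0),
                                float(d.mean()) if n else np.nan, "insufficient-n")
    if np.allclose(d.std(ddof=1), 0.0):
        mean = float(d.mean())
        if np.isclose(mean, 0.0):
            return PairedTestResult(0.0, 1.0, n - 1, 0.0, "zero-variance")
        return PairedTestResult(np.sign(mean) * np.inf, 0.0, n - 1, mean, "zero-variance")
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(float(t), float(p), n - 1, float(d.mean()))
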