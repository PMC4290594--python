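"""Evaluation metrics: MSE vs ground truth, angular error, fiber-count
rates, SNR estimation and paired significance testing.

Angular error between a ground-truth fiber axis ``p_gt`` and an estimated
peak ``p`` is ``(180 / pi) * arccos(|p_gt . p|)`` — the absolute value
implements antipodal fiber symmetry, so errors live in [0, 90] degrees.
Estimated peaks are matched to ground-truth fibers greedily one-to-one by
smallest angle; a voxel's error is the mean over its matched fibers.

Fiber-count rates compare the estimated and true per-voxel fiber numbers
over fiber-containing voxels: success (equal), over-estimation (too
many), under-estimation (too few, including voxels with no estimated
peak); the three always sum to 100%.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .core import DWIVolume
from .recon import PeakSet

__all__ = [
    "MSEReport",
    "AngularErrorReport",
    "CountRates",
    "SNRReport",
    "PairedTTestResult",
    "mse_map",
    "angular_error",
    "fiber_count_rates",
    "background_foreground_masks",
    "estimate_snr",
    "paired_ttest",
]


@dataclasses.dataclass
class MSEReport:
    per_voxel: np.ndarray  # (X, Y, Z) MSE over directions; NaN off-mask
    mean: float
    sd: float
    n_voxels: int


@dataclasses.dataclass
class AngularErrorReport:
    per_voxel: np.ndarray  # (X, Y, Z) degrees; NaN where not evaluated
    mean: float
    sd: float
    n_voxels: int
    n_unmatched: int  # ground-truth voxels with no estimated peak at all


@dataclasses.dataclass
class CountRates:
    success: float  # percentages of evaluated voxels
    over_estimation: float
    under_estimation: float
    n_voxels: int


@dataclasses.dataclass
class SNRReport:
    per_direction: np.ndarray
    mean: float
    sd: float


@dataclasses.dataclass
class PairedTTestResult:
    t: float
    p: float
    zero_variance: bool = False


def mse_map(test: DWIVolume, truth: DWIVolume,
            mask: np.ndarray | None = None) -> MSEReport:
    """Per-voxel mean squared error of the weighted signal vs ground truth."""
    if test.data.shape != truth.data.shape:
        raise ValueError("test and truth volumes have different shapes")
    if mask is None:
        mask = np.ones(test.data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    diff = test.weighted - truth.weighted
    per_voxel = np.mean(diff ** 2, axis=-1)
    vals = per_voxel[mask]
    out = np.full(per_voxel.shape, np.nan)
    out[mask] = vals
    return MSEReport(per_voxel=out, mean=float(vals.mean()),
                     sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                     n_voxels=int(vals.size))


def _axis_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(abs(float(np.dot(a, b))), 0.0, 1.0))))


def _greedy_match_errors(gt: np.ndarray, est: np.ndarray) -> list[float]:
    """Greedy one-to-one matching by smallest axis angle; returns the
    per-matched-fiber errors (unmatched ground-truth fibers are skipped —
    they are accounted for by the under-estimation rate instead)."""
    angles = np.array([[_axis_angle_deg(g, e) for e in est] for g in gt])
    errors: list[float] = []
    g_free = set(range(gt.shape[0]))
    e_free = set(range(est.shape[0]))
    while g_free and e_free:
        best = min(((angles[g, e], g, e) for g in g_free for e in e_free))
        errors.append(best[0])
        g_free.remove(best[1])
        e_free.remove(best[2])
    return errors


def angular_error(gt_directions: np.ndarray, gt_counts: np.ndarray,
                  est: PeakSet,
                  mask: np.ndarray | None = None) -> AngularErrorReport:
    """Mean angular error per voxel between true fibers and nearest peaks.

    ``gt_directions`` is (X, Y, Z, F, 3) with ``gt_counts`` valid fibers
    per voxel.  Voxels with ground-truth fibers but zero estimated peaks
    are excluded from the mean and counted in ``n_unmatched``.
    """
    shape = gt_counts.shape
    if mask is None:
        mask = gt_counts >= 1
    mask = np.asarray(mask, dtype=bool) & (gt_counts >= 1)
    per_voxel = np.full(shape, np.nan)
    n_unmatched = 0
    gt_dirs = gt_directions.reshape(-1, *gt_directions.shape[-2:])
    est_dirs = est.directions.reshape(-1, *est.directions.shape[-2:])
    est_counts = est.counts.reshape(-1)
    flat_mask = mask.reshape(-1)
    flat_out = per_voxel.reshape(-1)
    gt_counts_flat = gt_counts.reshape(-1)
    for i in np.where(flat_mask)[0]:
        k_est = int(est_counts[i])
        if k_est == 0:
            n_unmatched += 1
            continue
        errs = _greedy_match_errors(gt_dirs[i, : int(gt_counts_flat[i])],
                                    est_dirs[i, :k_est])
        if errs:
            flat_out[i] = float(np.mean(errs))
    vals = per_voxel[np.isfinite(per_voxel)]
    return AngularErrorReport(
        per_voxel=per_voxel,
        mean=float(vals.mean()) if vals.size else np.nan,
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n_voxels=int(vals.size), n_unmatched=n_unmatched)


def fiber_count_rates(est_counts: np.ndarray, gt_counts: np.ndarray,
                      mask: np.ndarray | None = None) -> CountRates:
    """Success / over- / under-estimation percentages of fiber number."""
    est_counts = np.asarray(est_counts)
    gt_counts = np.asarray(gt_counts)
    if mask is None:
        mask = gt_counts >= 1
    mask = np.asarray(mask, dtype=bool)
    e = est_counts[mask]
    g = gt_counts[mask]
    n = e.size
    if n == 0:
        raise ValueError("no voxels to evaluate")
    return CountRates(
        success=100.0 * float(np.mean(e == g)),
        over_estimation=100.0 * float(np.mean(e > g)),
        under_estimation=100.0 * float(np.mean(e < g)),
        n_voxels=int(n))


def background_foreground_masks(vol: DWIVolume) -> tuple[np.ndarray, np.ndarray]:
    """Median-Otsu style split: (foreground, background) boolean masks.

    The voxel-wise median across volumes is thresholded with Otsu's
    method; the background is the complement eroded by one voxel.
    """
    med = np.median(vol.data, axis=-1)
    if np.ptp(med) <= 0:
        raise ValueError("degenerate (constant) image; cannot segment")
    th = threshold_otsu(med)
    fg = med > th
    bg = ndimage.binary_erosion(~fg, iterations=1)
    return fg, bg


def estimate_snr(vol: DWIVolume, roi: np.ndarray,
                 background: np.ndarray) -> SNRReport:
    """Per-direction SNR: mean signal in ROI / SD of the background."""
    roi = np.asarray(roi, dtype=bool)
    background = np.asarray(background, dtype=bool)
    if not roi.any() or not background.any():
        raise ValueError("ROI and background masks must be nonempty")
    flat = vol.data.reshape(-1, vol.data.shape[-1])
    means = flat[roi.reshape(-1)].mean(axis=0)
    sds = flat[background.reshape(-1)].std(axis=0, ddof=1)
    snr = means / sds
    return SNRReport(per_direction=snr, mean=float(snr.mean()),
                     sd=float(snr.std(ddof=1)) if snr.size > 1 else 0.0)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> PairedTTestResult:
    """Two-sided paired t-test on ``a - b``.

    Zero-variance differences are flagged: identical samples give
    (t=0, p=1); a constant nonzero shift has an undefined p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length samples of at least 3 items")
    diff = a - b
    if np.ptp(diff) == 0.0:
        if diff[0] == 0.0:
            return PairedTTestResult(t=0.0, p=1.0, zero_variance=False)
        return PairedTTestResult(t=np.inf if diff[0] > 0 else -np.inf,
                                 p=np.nan, zero_variance=True)
    res = stats.ttest_rel(a, b)
    return PairedTTestResult(t=float(res.statistic), p=float(res.pvalue))
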