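"""Fourier low-pass denoising in the gradient direction domain (lop-DWI).

When gradient directions are acquired along a continuous spherical spiral,
the per-voxel diffusion-weighted samples, arranged by acquisition order,
form a smooth pseudo-periodic 1D signal whose fiber information
concentrates in the low-frequency Fourier bins while thermal noise is
spread across all bins.  The filter therefore:

1. detrends the direction-ordered signal by subtracting its least-squares
   line (the pole-to-equator sweep introduces a drift the DFT would smear
   across bins),
2. zeroes all Fourier bins with frequency index >= ``cutoff`` (the cutoff
   counts nonnegative-frequency bins including DC, so ``cutoff = 11`` on
   an 82-sample signal retains 21 of 82 complex bins, about 25%),
3. adds the trend back and optionally clips negative samples to zero
   (magnitude MR signals are nonnegative).

Filtering is purely per voxel; there is no spatial coupling.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core import DWIVolume
from .sampling import SPIRAL_KINDS

__all__ = ["FilterConfig", "detrend", "fourier_lowpass", "lop_denoise",
           "denoise_volume"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    """Low-pass filter settings.

    ``cutoff`` is the number of retained nonnegative-frequency bins
    including DC; the default 11 passes approximately 25% of the spectrum
    of an 82-direction scheme.
    """

    cutoff: int = 11
    detrend: bool = True
    clip_negative: bool = True


def _validate_cutoff(cutoff: int, n: int) -> None:
    if not (1 <= cutoff <= n // 2 + 1):
        raise ValueError(
            f"cutoff must be in [1, {n // 2 + 1}] for {n} samples, got {cutoff}")


def detrend(values: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Subtract the ordinary-least-squares line in the sample index.

    Works on the last axis.  Returns ``(residual, (slope, intercept))``;
    the residual is orthogonal to both the constant and the linear
    regressor.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples to detrend")
    x = np.arange(n, dtype=float)
    xm = x.mean()
    denom = np.sum((x - xm) ** 2)
    slope = ((values - values.mean(axis=-1, keepdims=True)) @ (x - xm)) / denom
    intercept = values.mean(axis=-1) - slope * xm
    resid = values - (slope[..., None] * x + intercept[..., None])
    return resid, (slope, intercept)


def fourier_lowpass(values: np.ndarray, cutoff: int) -> np.ndarray:
    """Zero all DFT bins with frequency index >= ``cutoff`` (last axis).

    Retains bins ``|k| <= cutoff - 1`` with conjugate-symmetric zeroing,
    so the output is real.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    _validate_cutoff(cutoff, n)
    spec = np.fft.rfft(values, axis=-1)
    spec[..., cutoff:] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


_PROJ_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _trend_lowpass_projector(n: int, cutoff: int) -> np.ndarray:
    """Orthogonal projector onto span{1, index, low-frequency Fourier modes}.

    One pass of detrend -> low-pass -> retrend leaves a small residual
    trend in the passband; projecting onto the joint subspace is that
    operation iterated to convergence, and is exactly idempotent.
    """
    key = (n, cutoff)
    if key not in _PROJ_CACHE:
        m = np.arange(n, dtype=float)
        cols = [np.ones(n), m]
        for k in range(1, cutoff):
            cols.append(np.cos(2 * np.pi * k * m / n))
            if 2 * k != n:
                cols.append(np.sin(2 * np.pi * k * m / n))
        q, _ = np.linalg.qr(np.stack(cols, axis=1))
        _PROJ_CACHE[key] = q @ q.T
    return _PROJ_CACHE[key]


def lop_denoise(values: np.ndarray, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Low-pass one (or a batch of) direction-ordered 1D signal(s).

    ``values`` must already be arranged in spiral acquisition order along
    the last axis.  With ``cfg.detrend`` the signal is projected onto the
    linear trend plus the retained Fourier modes (detrend, low-pass,
    retrend, iterated to convergence); without it, plain low-pass.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if n < 4:
        raise ValueError("signal too short to filter (need N >= 4)")
    _validate_cutoff(cfg.cutoff, n)
    if cfg.detrend:
        out = values @ _trend_lowpass_projector(n, cfg.cutoff)
    else:
        out = fourier_lowpass(values, cfg.cutoff)
    if cfg.clip_negative:
        out = np.maximum(out, 0.0)
    return out


def denoise_volume(vol: DWIVolume, cfg: FilterConfig = FilterConfig(),
                   mask: np.ndarray | None = None) -> DWIVolume:
    """Apply the lop filter independently to every voxel of a volume.

    The weighted volumes are rearranged into spiral acquisition order,
    filtered, and written back; b0 volumes pass through unchanged.  Only
    scheme kinds acquired along a spiral are accepted: applying the filter
    to an unordered (e.g. electrostatic) scheme would require inventing a
    re-ordering, which this tool deliberately refuses to do.
    """
    scheme = vol.scheme
    if scheme.kind not in SPIRAL_KINDS:
        raise ValueError(
            f"gradient-direction-domain filtering requires a spiral-ordered "
            f"scheme; got kind={scheme.kind!r}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.data.shape[:3]:
            raise ValueError("mask shape does not match volume grid")

    order = scheme.acquisition_order()          # storage idx in acq order
    inverse = np.argsort(order)
    weighted = vol.weighted.reshape(-1, scheme.n)
    if mask is None:
        sel = slice(None)
    else:
        sel = mask.reshape(-1)
    signals = weighted[sel][:, order]
    filtered = lop_denoise(signals, dataclasses.replace(cfg, clip_negative=False))
    if cfg.clip_negative:
        clipped_frac = float(np.mean(filtered < 0.0)) if filtered.size else 0.0
        if clipped_frac:
            logger.info("lop filter clipped %.3f%% of samples to zero",
                        100.0 * clipped_frac)
        filtered = np.maximum(filtered, 0.0)
    out_weighted = weighted.copy()
    out_weighted[sel] = filtered[:, inverse]
    data = vol.data.copy()
    data[..., scheme.n_b0:] = out_weighted.reshape(vol.weighted.shape)
    return DWIVolume(data=data, scheme=scheme, affine=vol.affine.copy())
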