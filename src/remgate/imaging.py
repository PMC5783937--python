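"""Miniscope calcium-movie preprocessing.

Stages: rigid integer-pixel motion correction (cross-correlation of a
high-contrast reference region on high-pass-filtered frames), polygon
ROI trace extraction, neuropil subtraction from a bordering concentric
ring (F_corrected = F_raw - cf * F_neuropil, with cf estimated from
blood-vessel / near-vessel / off-lens regions or defaulting to 0.55),
and ΔF/F against a linear baseline fitted to the low-activity frames
(the 20th percentile of the session).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

DEFAULT_CF = 0.55
HIGHPASS_SIGMA_PX = 10.0


# ---------------------------------------------------------------------------
# motion correction
# ---------------------------------------------------------------------------

def _highpass(frame: np.ndarray, sigma: float) -> np.ndarray:
    return frame - ndimage.gaussian_filter(frame, sigma, mode="wrap")


def _reference_block(mean_hp: np.ndarray, block: int) -> tuple[slice, slice]:
    """Highest-variance block of the mean high-pass projection."""
    H, W = mean_hp.shape
    block = min(block, H, W)
    local_sq = ndimage.uniform_filter(mean_hp ** 2, block, mode="constant")
    local_m = ndimage.uniform_filter(mean_hp, block, mode="constant")
    var = local_sq - local_m ** 2
    h = block // 2
    interior = np.full_like(var, -np.inf)
    interior[h:H - h or None, h:W - h or None] = var[h:H - h or None,
                                                     h:W - h or None]
    cy, cx = np.unravel_index(np.argmax(interior), var.shape)
    y0 = int(np.clip(cy - h, 0, H - block))
    x0 = int(np.clip(cx - h, 0, W - block))
    return slice(y0, y0 + block), slice(x0, x0 + block)


def _register_pass(hp: np.ndarray, template: np.ndarray, ref_sl,
                   max_shift: int) -> tuple[np.ndarray, np.ndarray]:
    template = template - template.mean()
    shifts = np.zeros((hp.shape[0], 2), dtype=int)
    flagged = np.zeros(hp.shape[0], dtype=bool)
    rng_d = range(-max_shift, max_shift + 1)
    for i, frame in enumerate(hp):
        best, best_val = (0, 0), -np.inf
        for dy in rng_d:
            for dx in rng_d:
                region = np.roll(frame, (-dy, -dx), axis=(0, 1))[ref_sl]
                val = float(np.sum(template * (region - region.mean())))
                if val > best_val:
                    best_val, best = val, (dy, dx)
        if abs(best[0]) == max_shift or abs(best[1]) == max_shift:
            flagged[i] = True
        shifts[i] = best
    return shifts, flagged


def motion_correct(movie: np.ndarray, max_shift: int = 8,
                   sigma: float = HIGHPASS_SIGMA_PX,
                   block: int = 32, n_passes: int = 8
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid integer-pixel motion correction.

    Each frame is high-pass filtered (frame minus a Gaussian low-pass,
    sigma in pixels); the integer shift maximising the correlation
    between a high-contrast reference region of the mean high-pass
    projection and each frame is found over +/- ``max_shift`` pixels and
    undone on the raw frame (cyclic shift).  The template is then
    rebuilt from the corrected frames and registration repeated until
    the shifts stop changing (the first-pass template is motion-blurred;
    a few passes reach a fixed point).  Frames whose best shift hits the
    search boundary are flagged and the shift clipped.

    Returns (shifts (n, 2) as (dy, dx), corrected movie, flagged bool
    per frame).
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be a (n_frames >= 2, H, W) stack")
    hp = np.array([_highpass(f, sigma) for f in movie])
    ref_sl = _reference_block(hp.mean(axis=0), block)
    shifts = np.zeros((movie.shape[0], 2), dtype=int)
    flagged = np.zeros(movie.shape[0], dtype=bool)
    for _ in range(max(1, n_passes)):
        aligned = np.array([np.roll(f, (-dy, -dx), axis=(0, 1))
                            for f, (dy, dx) in zip(hp, shifts)])
        template = aligned.mean(axis=0)[ref_sl]
        new_shifts, flagged = _register_pass(hp, template, ref_sl,
                                             max_shift)
        converged = np.array_equal(new_shifts, shifts)
        shifts = new_shifts
        if converged:
            break
    corrected = np.array([np.roll(f, (-dy, -dx), axis=(0, 1))
                          for f, (dy, dx) in zip(movie, shifts)])
    return shifts, corrected, flagged


# ---------------------------------------------------------------------------
# ROI geometry and traces
# ---------------------------------------------------------------------------

def rasterize_polygon(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels inside a polygon given as (x, y) vertices."""
    from skimage.draw import polygon as _sk_polygon

    poly = np.asarray(poly, dtype=float)
    rr, cc = _sk_polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def roi_trace(movie: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Per-frame mean intensity over the rasterised polygon."""
    mask = rasterize_polygon(poly, movie.shape[1:])
    if not mask.any():
        raise ValueError("polygon rasterises to zero pixels")
    return movie[:, mask].mean(axis=1)


def neuropil_ring(poly: np.ndarray, shape: tuple[int, int],
                  distance_px: float, width_px: float = 4.0,
                  exclude: list | None = None) -> np.ndarray:
    """Bordering concentric ring at ``distance_px`` from the ROI
    perimeter, ``width_px`` wide, with all ROI polygons excluded."""
    mask = rasterize_polygon(poly, shape)
    inner = ndimage.binary_dilation(mask, iterations=int(round(distance_px)))
    outer = ndimage.binary_dilation(
        inner, iterations=int(round(width_px)))
    ring = outer & ~inner
    for other in (exclude or []):
        ring &= ~rasterize_polygon(other, shape)
    ring &= ~mask
    if not ring.any():
        raise ValueError("neuropil ring is empty")
    return ring


def neuropil_trace(movie: np.ndarray, poly: np.ndarray,
                   distance_px: float, width_px: float = 4.0,
                   exclude: list | None = None) -> np.ndarray:
    ring = neuropil_ring(poly, movie.shape[1:], distance_px, width_px,
                         exclude)
    return movie[:, ring].mean(axis=1)


# ---------------------------------------------------------------------------
# neuropil correction and ΔF/F
# ---------------------------------------------------------------------------

def estimate_cf(f_bv: float | np.ndarray | None,
                f_near: float | np.ndarray | None,
                f_off: float | np.ndarray | None) -> tuple[float, str]:
    """Neuropil contamination factor.

    cf = (F_bv - F_off) / (F_near - F_off), with each F the mean pixel
    intensity of the blood-vessel, near-vessel (no ROI) and off-lens
    regions.  When the vessel region is unavailable the population
    default 0.55 is returned.  The provenance string reports which.
    """
    if f_bv is None:
        return DEFAULT_CF, "default"
    bv = float(np.mean(f_bv))
    near = float(np.mean(f_near))
    off = float(np.mean(f_off))
    if near <= off:
        raise ValueError("F_near must exceed F_off")
    cf = (bv - off) / (near - off)
    return cf, "estimated"


def neuropil_subtract(f_raw: np.ndarray, f_neuropil: np.ndarray,
                      cf: float) -> np.ndarray:
    """F_corrected = F_raw - cf * F_neuropil (elementwise)."""
    f_raw = np.asarray(f_raw, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_raw.shape != f_neuropil.shape:
        raise ValueError("traces must have equal length")
    return f_raw - cf * f_neuropil


@dataclass
class FluorTrace:
    """One ROI's fluorescence at each processing stage."""

    f_raw: np.ndarray
    f_neuropil: np.ndarray
    cf: float
    f_corrected: np.ndarray
    f0: np.ndarray
    dff: np.ndarray
    baseline_slope: float
    baseline_intercept: float


def dff(f_corrected: np.ndarray, frame_hz: float = 10.0,
        percentile: float = 20.0) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Linear low-activity baseline and ΔF/F.

    Frames at or below the session's 20th percentile are taken as
    low-activity; the best straight line through their (t, F) points is
    the baseline F0(t), and ΔF/F = (F - F0) / F0.  A non-positive fitted
    baseline anywhere raises (the ratio would be meaningless there).

    Returns (dff, f0, slope_per_s, intercept).
    """
    f = np.asarray(f_corrected, dtype=float)
    if f.size < 100:
        raise ValueError("need at least 100 frames")
    t = np.arange(f.size) / frame_hz
    cut = np.percentile(f, percentile)
    sel = f <= cut
    if sel.sum() < 2:
        sel = np.argsort(f)[: max(2, f.size // 5)]
    slope, intercept = np.polyfit(t[sel], f[sel], 1)
    f0 = slope * t + intercept
    if np.any(f0 <= 0):
        bad = int(np.argmax(f0 <= 0))
        raise ValueError(f"fitted baseline non-positive at frame {bad}")
    return (f - f0) / f0, f0, float(slope), float(intercept)


def process_roi(movie: np.ndarray, poly: np.ndarray, frame_hz: float,
                cf: float | None = None,
                neuropil_distance_px: float = 5.0,
                neuropil_width_px: float = 4.0,
                exclude: list | None = None) -> FluorTrace:
    """Full single-ROI pipeline: trace, ring, subtraction, ΔF/F."""
    f_raw = roi_trace(movie, poly)
    f_np = neuropil_trace(movie, poly, neuropil_distance_px,
                          neuropil_width_px, exclude)
    if cf is None:
        cf, _ = estimate_cf(None, None, None)
    f_corr = neuropil_subtract(f_raw, f_np, cf)
    d, f0, slope, icpt = dff(f_corr, frame_hz)
    return FluorTrace(f_raw=f_raw, f_neuropil=f_np, cf=cf,
                      f_corrected=f_corr, f0=f0, dff=d,
                      baseline_slope=slope, baseline_intercept=icpt)


def microns_to_px(distance_um: float, um_per_px: float) -> float:
    """Convert the 20 μm ring offset to (downsampled) pixels."""
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    return distance_um / um_per_px
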