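"""Technical image-quality estimators: noise SD, CNR, radial NPS, MTF.

Noise is the HU standard deviation in a homogeneous ROI.  CNR contrasts the
heart against the soft-tissue background (Otsu-segmented), normalized by the
background SD.  The noise power spectrum is estimated from the subtraction
of neighboring slices of the homogeneous epoxy rod: overlapping square ROIs
on a ring inside the rod are mean-detrended, their 2D periodograms averaged
(scaled by dx dy / (Nx Ny), halved because subtraction doubles noise power)
and radially binned.  The MTF comes from the oversampled line-spread
function of the slightly tilted air gap: pixels near the gap are binned by
their perpendicular distance to the gap line at sub-pixel resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from cacstudy.phantom_forge import GapSpec


def noise_sd(image: np.ndarray, roi_mask: np.ndarray) -> float:
    """Sample SD (ddof=1) of HU values inside the ROI (>= 100 voxels)."""
    vals = np.asarray(image)[np.asarray(roi_mask, dtype=bool)]
    if vals.size < 100:
        raise ValueError(f"ROI too small for a stable SD estimate ({vals.size} voxels)")
    return float(np.std(vals, ddof=1))


def otsu_rois(
    image: np.ndarray,
    rod_mask: np.ndarray,
    erode_voxels: int = 2,
    min_separation_hu: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Otsu-split the in-rod histogram into heart (bright) and background.

    Both masks are eroded to avoid boundary mixing.  Raises if the split is
    degenerate (classes closer than ``min_separation_hu`` -- effectively a
    unimodal histogram).
    """
    rod_mask = np.asarray(rod_mask, dtype=bool)
    vals = np.asarray(image)[rod_mask]
    thr = threshold_otsu(vals)
    heart = rod_mask & (image > thr)
    background = rod_mask & (image <= thr)
    if abs(float(image[heart].mean()) - float(image[background].mean())) < min_separation_hu:
        raise ValueError("degenerate Otsu split: in-rod histogram looks unimodal")
    heart = ndimage.binary_erosion(heart, iterations=erode_voxels)
    background = ndimage.binary_erosion(background, iterations=erode_voxels)
    if not heart.any() or not background.any():
        raise ValueError("Otsu segmentation produced an empty class after erosion")
    return heart, background


def cnr(image: np.ndarray, roi_a: np.ndarray, roi_b: np.ndarray) -> float:
    """|mean_a - mean_b| / SD_b, with the background SD in the denominator."""
    a = np.asarray(image)[np.asarray(roi_a, dtype=bool)]
    b = np.asarray(image)[np.asarray(roi_b, dtype=bool)]
    sd_b = np.std(b, ddof=1)
    if sd_b == 0:
        raise ValueError("background SD is zero; CNR undefined")
    return float(abs(a.mean() - b.mean()) / sd_b)


@dataclass
class NpsCurve:
    frequency: np.ndarray  # cycles/mm, radial bin centers from 0
    power: np.ndarray  # HU^2 mm^2
    nps2d: np.ndarray  # the averaged 2D NPS (for Parseval checks)
    roi_size: int
    n_rois: int
    pixel_spacing: tuple[float, float]

    def integral_2d(self) -> float:
        """2D integral of the NPS over frequency; approximates the variance."""
        dfy = 1.0 / (self.nps2d.shape[0] * self.pixel_spacing[0])
        dfx = 1.0 / (self.nps2d.shape[1] * self.pixel_spacing[1])
        return float(self.nps2d.sum() * dfy * dfx)

    def normalized(self) -> np.ndarray:
        peak = self.power.max()
        return self.power / peak if peak > 0 else self.power


def _ring_roi_origins(center, ring_radius, roi_size, n_rois):
    """Top-left corners of n ROIs spaced around a ring."""
    cy, cx = center
    origins = []
    for k in range(n_rois):
        ang = 2 * math.pi * k / n_rois
        oy = int(round(cy + ring_radius * math.sin(ang) - roi_size / 2))
        ox = int(round(cx + ring_radius * math.cos(ang) - roi_size / 2))
        origins.append((oy, ox))
    return origins


def radial_nps(
    slices: list[np.ndarray],
    pixel_spacing: tuple[float, float],
    roi_size: int = 64,
    n_rois: int = 8,
    ring_radius: float | None = None,
    interior_mask: np.ndarray | None = None,
) -> NpsCurve:
    """Radially averaged NPS from neighboring-slice subtraction.

    ``slices`` are >= 2 reconstructions of the homogeneous phantom at
    identical settings; ROIs falling outside ``interior_mask`` (if given)
    are skipped.
    """
    if len(slices) < 2:
        raise ValueError("need at least two slices for neighbor subtraction")
    dy, dx = pixel_spacing
    ny, nx = slices[0].shape
    center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    if ring_radius is None:
        ring_radius = min(ny, nx) / 5.0

    psd_sum = np.zeros((roi_size, roi_size))
    used = 0
    for a, b in zip(slices[:-1], slices[1:]):
        diff = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
        for oy, ox in _ring_roi_origins(center, ring_radius, roi_size, n_rois):
            if oy < 0 or ox < 0 or oy + roi_size > ny or ox + roi_size > nx:
                continue
            if interior_mask is not None and not interior_mask[oy : oy + roi_size, ox : ox + roi_size].all():
                continue
            roi = diff[oy : oy + roi_size, ox : ox + roi_size]
            roi = roi - roi.mean()
            psd = np.abs(np.fft.fft2(roi)) ** 2 * (dx * dy) / (roi_size * roi_size)
            psd_sum += psd
            used += 1
    if used == 0:
        raise ValueError("no ROI fit inside the phantom interior")
    nps2d = psd_sum / used / 2.0  # subtraction doubles the noise power

    fy = np.fft.fftfreq(roi_size, d=dy)
    fx = np.fft.fftfreq(roi_size, d=dx)
    fr = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    df = 1.0 / (roi_size * max(dx, dy))
    n_bins = roi_size // 2
    bins = np.clip((fr / df).astype(int), 0, n_bins - 1)
    power = np.bincount(bins.ravel(), weights=nps2d.ravel(), minlength=n_bins)
    counts = np.bincount(bins.ravel(), minlength=n_bins)
    power = power / np.maximum(counts, 1)
    freq = (np.arange(n_bins) + 0.5) * df
    return NpsCurve(
        frequency=freq,
        power=power,
        nps2d=nps2d,
        roi_size=roi_size,
        n_rois=used,
        pixel_spacing=(dy, dx),
    )


@dataclass
class MtfCurve:
    frequency: np.ndarray  # cycles/mm
    modulation: np.ndarray  # normalized to 1 at zero frequency

    def _crossing(self, level: float) -> float:
        m, f = self.modulation, self.frequency
        below = np.nonzero(m < level)[0]
        if below.size == 0:
            return float(f[-1])
        i = below[0]
        if i == 0:
            return float(f[0])
        # linear interpolation between the bracketing samples
        f0, f1, m0, m1 = f[i - 1], f[i], m[i - 1], m[i]
        return float(f0 + (m0 - level) * (f1 - f0) / (m0 - m1))

    @property
    def f50(self) -> float:
        return self._crossing(0.5)

    @property
    def f10(self) -> float:
        return self._crossing(0.1)


def mtf_from_gap(
    image: np.ndarray,
    gap: GapSpec,
    pixel_spacing: tuple[float, float],
    oversample: int = 4,
    profile_halfwidth_mm: float = 6.0,
) -> MtfCurve:
    """MTF from the line-spread function of the tilted air gap.

    The gap tilt makes pixel centers sample the profile at many sub-pixel
    offsets; binning signed perpendicular distances at 1/oversample pixel
    width yields an oversampled LSF.  The LSF is baseline-subtracted,
    Hann-tapered and Fourier transformed; the magnitude is normalized to 1
    at zero frequency.
    """
    dy, dx = pixel_spacing
    ny, nx = image.shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xx, yy = np.meshgrid(x, y)
    c, s = math.cos(math.radians(gap.angle_deg)), math.sin(math.radians(gap.angle_deg))
    u = (xx - gap.center[0]) * c + (yy - gap.center[1]) * s  # along the gap
    v = -(xx - gap.center[0]) * s + (yy - gap.center[1]) * c  # across the gap

    band = (np.abs(u) <= gap.length / 2.0 - 2 * dx) & (np.abs(v) <= profile_halfwidth_mm)
    if band.sum() < 8 * oversample:
        raise ValueError("air gap not found in the image (band too small)")
    bin_width = dx / oversample
    dist = v[band]
    vals = np.asarray(image, dtype=np.float64)[band]
    n_half = int(np.ceil(profile_halfwidth_mm / bin_width))
    idx = np.clip(np.round(dist / bin_width).astype(int) + n_half, 0, 2 * n_half)
    sums = np.bincount(idx, weights=vals, minlength=2 * n_half + 1)
    counts = np.bincount(idx, minlength=2 * n_half + 1)
    profile = np.full(2 * n_half + 1, np.nan)
    filled = counts > 0
    profile[filled] = sums[filled] / counts[filled]
    # fill sparse empty bins by linear interpolation
    if not filled.all():
        coords = np.arange(profile.size)
        profile = np.interp(coords, coords[filled], profile[filled])

    # the gap is a dip on a flat baseline; LSF = baseline - profile
    n_tail = max(2, profile.size // 8)
    baseline = 0.5 * (profile[:n_tail].mean() + profile[-n_tail:].mean())
    lsf = baseline - profile
    if np.abs(lsf).max() <= 0:
        raise ValueError("degenerate line-spread function (all zero)")
    lsf = lsf * np.hanning(lsf.size)

    spectrum = np.abs(np.fft.rfft(lsf))
    if spectrum[0] == 0:
        raise ValueError("degenerate MTF: zero area under the LSF")
    freq = np.fft.rfftfreq(lsf.size, d=bin_width)
    return MtfCurve(frequency=freq, modulation=spectrum / spectrum[0])


def mtf_distance(curve_a: MtfCurve, curve_b: MtfCurve, f_max: float) -> float:
    """Least-squares distance between two MTF curves up to f_max (cycles/mm)."""
    f = curve_a.frequency
    sel = f <= f_max
    mb = np.interp(f[sel], curve_b.frequency, curve_b.modulation)
    return float(np.sum((curve_a.modulation[sel] - mb) ** 2))
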