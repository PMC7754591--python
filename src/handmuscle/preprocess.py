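"""T1 pre-processing: bias-field correction and peak-based normalization.

The normalization maps the cortical-bone histogram peak to 0 and the muscle
peak to 100 intensity units:

    V_norm = (V − V_cort) / (V_muscle − V_cort) · 100

so features become comparable across scans. The two peaks are found by a
watershed-like thresholding of the in-hand grey-value histogram: a count
threshold is raised, merging histogram basins, until exactly two regional
maxima survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, ScalarVolume

__all__ = [
    "HistogramPeaks",
    "correct_bias_field",
    "find_histogram_peaks",
    "normalize_intensities",
]


@dataclass(frozen=True)
class HistogramPeaks:
    """Grey values of the cortical-bone and muscle histogram peak maxima."""

    v_cort: float
    v_muscle: float

    def __post_init__(self) -> None:
        if not self.v_cort < self.v_muscle:
            raise ValueError(
                f"cortical-bone peak ({self.v_cort}) must lie below the "
                f"muscle peak ({self.v_muscle})"
            )


def correct_bias_field(
    volume: ScalarVolume,
    method: str = "polyfit",
    order: int = 2,
    n4_shrink: int = 2,
) -> ScalarVolume:
    """Remove low-frequency multiplicative intensity inhomogeneity.

    Two interchangeable implementations stand behind one interface:

    ``"polyfit"``
        Self-contained: fits a low-order 3D polynomial to the log
        intensities of bright (tissue) voxels, normalizes the fitted field
        to unit mean over those voxels, and divides it out. Deterministic
        and dependency-free.
    ``"n4"``
        SimpleITK's N4 bias-field correction.
    ``"none"``
        Identity (for already-uniform input).
    """
    data = volume.data.astype(np.float64)
    if not np.any(data):
        raise ValueError("cannot bias-correct an all-zero volume")
    if method == "none":
        return volume.with_data(data)
    if method == "n4":
        import SimpleITK as sitk

        from .io import from_sitk, to_sitk

        img = sitk.Cast(to_sitk(volume), sitk.sitkFloat32)
        mask = sitk.OtsuThreshold(img, 0, 1)
        shrunk = sitk.Shrink(img, [n4_shrink] * 3)
        shrunk_mask = sitk.Shrink(mask, [n4_shrink] * 3)
        corrector = sitk.N4BiasFieldCorrectionImageFilter()
        corrector.Execute(shrunk, shrunk_mask)
        logfield = corrector.GetLogBiasFieldAsImage(img)
        corrected = img / sitk.Exp(logfield)
        out = from_sitk(corrected)
        return volume.with_data(np.maximum(out.data, 0.0))
    if method != "polyfit":
        raise ValueError(f"unknown bias correction method {method!r}")

    positive = data[data > 0]
    if np.ptp(positive) == 0:
        # constant volume: nothing to fit, return unchanged up to scale
        return volume.with_data(data)
    # tissue voxels: above the midpoint between background and tissue modes
    thr = _otsu(data)
    tissue = data > thr
    if tissue.sum() < 50:
        tissue = data > np.percentile(data, 75)
    nz, ny, nx = data.shape
    zc = np.linspace(-1, 1, nz)[:, None, None] * np.ones_like(data)
    yc = np.linspace(-1, 1, ny)[None, :, None] * np.ones_like(data)
    xc = np.linspace(-1, 1, nx)[None, None, :] * np.ones_like(data)
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((xc**i) * (yc**j) * (zc**k))
    A = np.stack([c[tissue] for c in cols], axis=1)
    b = np.log(np.maximum(data[tissue], 1e-6))
    # Fit the field on the dominant tissue intensity class only, so darker
    # classes (muscle, bone) do not drag the polynomial into anatomy.
    # Start from an upper quantile (safely inside the dominant class,
    # which holds the majority of the mass), then refine center and scale
    # iteratively; the scale comes from the upper, uncontaminated side.
    # When bias smears the histogram the window widens and the fit falls
    # back to all tissue voxels.
    mode = float(np.quantile(b, 0.70))
    s = 0.0
    for _ in range(3):
        upper = b[b >= mode] - mode
        if upper.size == 0:
            break
        s = 1.4826 * float(np.median(upper))
        window = b[(b >= mode - 2.0 * s) & (b <= mode + 4.0 * s)]
        if window.size == 0:
            break
        mode = float(np.median(window))
    keep = np.abs(b - mode) <= 2.5 * s if s > 0 else np.ones_like(b, dtype=bool)
    if keep.sum() < max(50, A.shape[1] * 5):
        keep = np.ones_like(b, dtype=bool)
    coef = None
    for _ in range(2):  # one refit after trimming gross residual outliers
        coef, *_ = np.linalg.lstsq(A[keep], b[keep], rcond=None)
        r = b - A @ coef
        scale = 1.4826 * np.median(np.abs(r[keep] - np.median(r[keep]))) + 1e-12
        keep = keep & (np.abs(r - np.median(r[keep])) <= 3.0 * scale)
    logfield = sum(c * cw for c, cw in zip(cols, coef))
    field = np.exp(logfield - np.mean((A @ coef)[keep]))
    return volume.with_data(np.maximum(data / field, 0.0))


def _otsu(data: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(data))


def find_histogram_peaks(
    volume: ScalarVolume,
    hand: BinaryMask,
    bins: int = 256,
    smooth_sigma: float = 2.0,
    min_peak_fraction: float = 0.01,
) -> HistogramPeaks:
    """Locate the cortical-bone and muscle grey-value peaks inside the hand.

    The histogram (``bins`` over the observed in-hand range, lightly
    smoothed) is thresholded at increasing count levels; bins above the
    level form basins that merge as the level rises. The first level at
    which exactly two basins remain defines the two surviving maxima; the
    lower bin center is returned as ``v_cort``, the higher as ``v_muscle``.
    Basins whose maximum is below ``min_peak_fraction`` of the global
    maximum are noise-floor clutter and never count as surviving peaks.

    Raises ``ValueError`` on effectively unimodal histograms, in which
    case the caller may supply peaks manually.
    """
    if not volume.same_geometry(hand):
        raise ValueError("hand mask geometry does not match the volume")
    values = volume.data[hand.data]
    if values.size == 0:
        raise ValueError("hand mask is empty")
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = ndimage.gaussian_filter1d(counts.astype(float), smooth_sigma)
    floor = min_peak_fraction * hist.max()
    # bottom-up: basins split as the level rises past valleys and die as it
    # passes their maxima; stop at the first level leaving exactly two
    for level in np.unique(hist):
        above = hist > level
        labels, ncomp = ndimage.label(above)
        tops = [
            np.flatnonzero(labels == c)[np.argmax(hist[labels == c])]
            for c in range(1, ncomp + 1)
        ]
        tops = [t for t in tops if hist[t] >= floor]
        # a genuine two-peak split has its separating valley (≈ level) well
        # below both surviving maxima; near-top noise splits (ratio → 1) do not
        if len(tops) == 2 and min(hist[t] for t in tops) >= 1.5 * level:
            lo, hi = sorted(float(centers[t]) for t in tops)
            return HistogramPeaks(v_cort=lo, v_muscle=hi)
    raise ValueError(
        "histogram thresholding could not isolate two peaks (unimodal "
        "in-hand histogram?); supply v_cort/v_muscle manually"
    )


def normalize_intensities(volume: ScalarVolume, peaks: HistogramPeaks) -> ScalarVolume:
    """Affine grey-value normalization: v_cort → 0, v_muscle → 100."""
    denom = peaks.v_muscle - peaks.v_cort
    if denom == 0:
        raise ValueError("cannot normalize with coincident histogram peaks")
    return volume.with_data((volume.data - peaks.v_cort) / denom * 100.0)
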