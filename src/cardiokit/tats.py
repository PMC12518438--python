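"""Quantification of the transverse–axial tubular system (TATS) in 3-D.

From a membrane-dye confocal stack: cell segmentation, interior tubule
segmentation, and four per-cell metrics — volume density and skeleton density
(% of cell volume), mean voxel-to-tubule Euclidean distance (µm, anisotropic
voxel spacing), and a spectral regularity score (power in the sarcomeric
period band of the longitudinal occupancy profile, normalised by total non-DC
power).
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .errors import AnalysisError, SpecError
from .io import VolumeImage

__all__ = [
    "LabeledVolume",
    "TatsMetrics",
    "segment_cell",
    "segment_tats",
    "volume_density",
    "distance_map",
    "skeleton_density",
    "spectral_density",
    "quantify",
]


@dataclass
class LabeledVolume:
    cell_mask: np.ndarray
    tats_mask: np.ndarray
    skeleton_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cell_mask.shape != self.tats_mask.shape:
            raise SpecError("cell and TATS masks must share a shape")
        if np.any(self.tats_mask & ~self.cell_mask):
            raise SpecError("tats_mask must be a subset of cell_mask")


@dataclass
class TatsMetrics:
    volume_density_pct: float
    skeleton_density_pct: float
    mean_distance_um: float
    spectral_density: float
    extras: dict = field(default_factory=dict)


def segment_cell(
    image: VolumeImage,
    smooth_sigma_um: float = 0.3,
    mode: str = "interior",
    edge_erode_um: float | None = None,
) -> np.ndarray:
    """Largest connected supra-threshold component after Gaussian smoothing.

    ``mode='interior'`` thresholds with Otsu's method between extracellular
    background and cytosolic signal — appropriate for volume dyes and
    autofluorescence.  ``mode='membrane'`` is for surface-stain images whose
    interior is dim: thresholding at half the sarcolemmal peak level (99.9th
    percentile) traces the *outer half-maximum* of the blurred membrane
    ridge, which overshoots the true surface by the ridge's half-width at
    half maximum, ≈ sqrt(2 ln 2)·σ_total; the filled mask is therefore
    eroded back by ``edge_erode_um`` (default: computed from
    ``smooth_sigma_um`` plus a typical confocal PSF of ~0.12 µm) so the
    boundary lands on the ridge centre, i.e. the sarcolemma.  Holes are
    filled per z-slice in both modes.
    """
    img = image.voxels
    if img.max() <= img.min():
        raise AnalysisError("image has no contrast: cannot segment a cell")
    if mode == "membrane" and smooth_sigma_um == 0.3:
        smooth_sigma_um = 0.15  # membrane shells need less smoothing
    sigma = tuple(smooth_sigma_um / v for v in image.voxel_size_um)
    smooth = ndi.gaussian_filter(img, sigma=sigma)
    if mode == "membrane":
        thr = 0.5 * float(np.percentile(smooth, 99.9))
    elif mode == "interior":
        thr = threshold_otsu(smooth)
    else:
        raise AnalysisError(f"unknown segmentation mode {mode!r}")
    mask = smooth > thr
    for z in range(mask.shape[0]):
        mask[z] = ndi.binary_fill_holes(mask[z])
    labels, n = ndi.label(mask)
    if n == 0:
        raise AnalysisError("no supra-threshold component found")
    sizes = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    if mode == "membrane":
        if edge_erode_um is None:
            sigma_total = math.hypot(smooth_sigma_um, 0.12)
            edge_erode_um = math.sqrt(2.0 * math.log(2.0)) * sigma_total
        if edge_erode_um > 0:
            mask = ndi.distance_transform_edt(mask, sampling=image.voxel_size_um) > edge_erode_um
    return mask


def segment_tats(
    image: VolumeImage,
    cell_mask: np.ndarray,
    rim_um: float = 0.5,
    background_sigma_um: float = 2.0,
    threshold_scale: float = 1.0,
    peak_percentile: float = 99.5,
    min_contrast_sd: float = 4.0,
) -> np.ndarray:
    """Interior membrane signal above an adaptive half-maximum threshold.

    A configurable surface-membrane rim (default 0.5 µm, applied as a
    Euclidean erosion in physical units) is excluded so the sarcolemma does
    not count as tubules.  The image is background-corrected by subtracting a
    heavily smoothed copy; the threshold sits halfway between the interior
    background (median) and the tubule peak level (``peak_percentile`` of the
    interior voxels) — the full-width-half-maximum rule, which places the
    mask edge at the true structure boundary under a symmetric PSF.
    ``threshold_scale`` rescales the half-height (>1 is stricter, so larger
    scales give subset masks).  If the peak level does not clear the
    background by ``min_contrast_sd`` robust standard deviations the cell is
    considered tubule-free and an empty mask is returned.
    """
    if not cell_mask.any():
        raise AnalysisError("empty cell mask")
    interior_dist = ndi.distance_transform_edt(cell_mask, sampling=image.voxel_size_um)
    interior = interior_dist > rim_um
    if not interior.any():
        raise AnalysisError(f"surface rim of {rim_um} um leaves no cell interior")
    sigma = tuple(background_sigma_um / v for v in image.voxel_size_um)
    corrected = image.voxels - ndi.gaussian_filter(image.voxels, sigma=sigma)
    vals = corrected[interior]
    if vals.max() <= vals.min():
        return np.zeros_like(cell_mask)
    bg = float(np.median(vals))
    robust_sd = 1.4826 * float(np.median(np.abs(vals - bg)))
    peak = float(np.percentile(vals, peak_percentile))
    if robust_sd > 0 and (peak - bg) < min_contrast_sd * robust_sd:
        return np.zeros_like(cell_mask)
    thr = bg + 0.5 * threshold_scale * (peak - bg)
    return (corrected > thr) & interior


def volume_density(masks: LabeledVolume) -> float:
    """TATS volume as % of cell volume."""
    n_cell = int(masks.cell_mask.sum())
    if n_cell == 0:
        raise AnalysisError("empty cell mask")
    return 100.0 * float(masks.tats_mask.sum()) / n_cell


def distance_map(
    masks: LabeledVolume, voxel_size_um: tuple[float, float, float]
) -> tuple[float, np.ndarray]:
    """Mean distance of each intracellular voxel to its closest tubule (µm).

    Euclidean distance transform with anisotropic voxel spacing; the mean is
    taken over all cell-mask voxels (tubule voxels contribute zero).
    """
    if not masks.tats_mask.any():
        raise AnalysisError("empty TATS mask: voxel-to-tubule distance undefined")
    dmap = ndi.distance_transform_edt(~masks.tats_mask, sampling=voxel_size_um)
    return float(dmap[masks.cell_mask].mean()), dmap


def skeleton_density(masks: LabeledVolume) -> tuple[float, np.ndarray]:
    """3-D morphological skeleton of the TATS, as % of cell volume."""
    n_cell = int(masks.cell_mask.sum())
    if n_cell == 0:
        raise AnalysisError("empty cell mask")
    if not masks.tats_mask.any():
        return 0.0, np.zeros_like(masks.tats_mask)
    skel = skeletonize(masks.tats_mask) & masks.tats_mask
    return 100.0 * float(skel.sum()) / n_cell, skel


def spectral_density(
    masks: LabeledVolume,
    voxel_size_um: tuple[float, float, float],
    axis: int = 2,
    band_period_um: tuple[float, float] = (1.5, 2.5),
) -> tuple[float, np.ndarray, np.ndarray]:
    """Regularity score of the TATS along the cell's longitudinal axis.

    The TATS occupancy is projected into a 1-D profile (per-slice mean within
    the cell mask along ``axis``), Fourier-transformed, and the power inside
    the sarcomeric period band is normalised by the total non-DC power.
    Returns (score, spatial frequencies 1/µm, power spectrum).
    """
    d = voxel_size_um[axis]
    n_axis = masks.cell_mask.shape[axis]
    if n_axis * d < 2 * band_period_um[1]:
        raise AnalysisError("profile shorter than two sarcomeric periods")
    other = tuple(i for i in range(3) if i != axis)
    cell_counts = masks.cell_mask.sum(axis=other).astype(float)
    tats_counts = (masks.tats_mask & masks.cell_mask).sum(axis=other).astype(float)
    keep = cell_counts > 0
    if keep.sum() < 4:
        raise AnalysisError("cell mask spans too few slices along the chosen axis")
    profile = tats_counts[keep] / cell_counts[keep]
    if profile.max() == 0:
        return 0.0, np.empty(0), np.empty(0)
    power = np.abs(np.fft.rfft(profile - profile.mean())) ** 2
    freqs = np.fft.rfftfreq(profile.size, d=d)
    total = float(power[1:].sum())
    if total == 0:
        return 0.0, freqs, power
    in_band = (freqs >= 1.0 / band_period_um[1]) & (freqs <= 1.0 / band_period_um[0])
    return float(power[in_band].sum()) / total, freqs, power


def quantify(
    image: VolumeImage,
    rim_um: float = 0.5,
    axis: int = 2,
    band_period_um: tuple[float, float] = (1.5, 2.5),
) -> TatsMetrics:
    """Full per-cell TATS quantification from a membrane-dye stack."""
    cell = segment_cell(image, mode="membrane")
    tats = segment_tats(image, cell, rim_um=rim_um)
    masks = LabeledVolume(cell_mask=cell, tats_mask=tats)
    vd = volume_density(masks)
    if tats.any():
        md, _ = distance_map(masks, image.voxel_size_um)
        sd, skel = skeleton_density(masks)
        score, _, _ = spectral_density(masks, image.voxel_size_um, axis, band_period_um)
    else:
        md, sd, score = float("nan"), 0.0, 0.0
    return TatsMetrics(
        volume_density_pct=vd,
        skeleton_density_pct=sd,
        mean_distance_um=md,
        spectral_density=score,
    )
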