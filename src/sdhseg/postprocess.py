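"""3D post-processing of the initial superpixel-level mask.

The classifier labels superpixels independently, so its initial mask
ignores neighborhood context. The repair chain follows the anatomy of a
subdural collection: per-slice removal of small sparse components,
morphological filling of holes and of gaps against the inner skull,
removal of 3D components that do not persist across slices, and a final
physically-scaled 3D Gaussian smoothing that rounds jagged contours.
All magnitudes are configurable; smoothing sigma is in mm so the 5 mm
slice axis is weighted correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationResult",
    "threshold_initial",
    "clean_2d",
    "fill_against_skull",
    "enforce_3d_continuity",
    "smooth_3d",
    "postprocess_mask",
]

DEFAULT_MIN_AREA_PX = 128
DEFAULT_FILL_RADIUS_PX = 2
DEFAULT_MAX_HOLE_PX = 200
DEFAULT_MIN_SLICES = 2
DEFAULT_SIGMA_MM = (1.0, 1.0, 1.0)
#: None = volume-preserving binarization (see smooth_3d); a float in (0, 1)
#: re-binarizes at that fixed level instead
DEFAULT_TAU_S = None

_SQUARE3 = np.ones((3, 3), dtype=bool)
_CUBE3 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass
class SegmentationResult:
    """Probability map, initial and post-processed masks, and the parameter
    snapshot that produced them."""

    probability: np.ndarray
    initial_mask: np.ndarray
    final_mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def threshold_initial(probability: np.ndarray, tau: float, roi_band: np.ndarray) -> np.ndarray:
    """Initial mask = {probability >= tau} within the ROI band."""
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie strictly in (0, 1)")
    return (probability >= tau) & roi_band


def clean_2d(mask: np.ndarray, min_area_px: int = DEFAULT_MIN_AREA_PX) -> np.ndarray:
    """Remove, per axial slice, 8-connected components with area below
    *min_area_px* (components of exactly min_area_px are kept)."""
    out = np.zeros_like(mask)
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl, structure=_SQUARE3)
        areas = np.bincount(labels.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = areas[1:] >= min_area_px
        out[:, :, k] = keep[labels]
    return out


def fill_against_skull(
    mask: np.ndarray,
    skull: np.ndarray,
    fill_radius_px: int = DEFAULT_FILL_RADIUS_PX,
    max_hole_px: int = DEFAULT_MAX_HOLE_PX,
) -> np.ndarray:
    """Close sub-radius gaps along the inner skull and small interior holes.

    Per slice: morphological closing of mask ∪ skull bridges gaps narrower
    than the structuring radius, holes enclosed by the closed set are
    filled, and skull voxels are removed again so the result never invades
    bone. Only holes up to *max_hole_px* are filled: two detections plus the
    skull ring can enclose a large pocket of healthy brain, which must stay
    open. Regions far from the skull are only hole-filled.
    """
    if mask.shape != skull.shape:
        raise ValueError("mask and skull must share geometry")
    selem = ndimage.generate_binary_structure(2, 2)
    selem = ndimage.iterate_structure(selem, fill_radius_px).astype(bool)
    out = np.zeros_like(mask)
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        sk = skull[:, :, k]
        # closing the union bridges gaps narrower than the radius between
        # mask and skull; the skull is then removed so bone is never claimed
        closed = ndimage.binary_closing(sl | sk, structure=selem)
        cand = closed & ~sk
        holes = ndimage.binary_fill_holes(cand) & ~cand
        if holes.any():
            hlabels, hn = ndimage.label(holes, structure=_SQUARE3)
            areas = np.bincount(hlabels.ravel())
            small = np.zeros(hn + 1, dtype=bool)
            small[1:] = areas[1:] <= max_hole_px
            cand = cand | small[hlabels]
        # keep only repairs attached to the original mask: closing also pads
        # skull concavities far from any detection, which must not survive
        labels, _ = ndimage.label(cand, structure=_SQUARE3)
        touching = np.unique(labels[sl])
        touching = touching[touching > 0]
        out[:, :, k] = np.isin(labels, touching)
    return out


def enforce_3d_continuity(
    mask: np.ndarray,
    min_slices: int = DEFAULT_MIN_SLICES,
    spacing: tuple[float, float, float] | None = None,
    drift_mm: float = 0.0,
) -> np.ndarray:
    """Drop 3D components that do not persist across *min_slices* axial
    slices.

    Components are 26-connected. With ``drift_mm > 0`` (requires
    *spacing*), components whose footprints on adjacent slices fall within
    that in-plane physical distance are additionally treated as one: at
    5 mm slice spacing a collection following the curved inner table can
    shift in-plane by several voxels between slices, which strict voxel
    connectivity would misread as a break.
    """
    if min_slices < 2:
        raise ValueError("min_slices must be >= 2")
    labels, n = ndimage.label(mask, structure=_CUBE3)
    if n == 0:
        return mask.copy()

    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    if drift_mm > 0:
        if spacing is None:
            raise ValueError("spacing is required when drift_mm > 0")
        d = max(1, int(np.ceil(drift_mm / min(spacing[0], spacing[1]))))
        selem = ndimage.iterate_structure(
            ndimage.generate_binary_structure(2, 2), d
        ).astype(bool)
        for k in range(mask.shape[2] - 1):
            a = labels[:, :, k]
            b = labels[:, :, k + 1]
            if not a.any() or not b.any():
                continue
            for ida in np.unique(a[a > 0]):
                reach = ndimage.binary_dilation(a == ida, structure=selem)
                for idb in np.unique(b[reach & (b > 0)]):
                    union(int(ida), int(idb))

    groups = np.array([find(i) for i in range(n + 1)])
    merged = groups[labels]
    out = np.zeros_like(mask)
    for gid in np.unique(groups[1:]):
        comp = merged == gid
        comp &= mask
        ks = np.nonzero(comp.any(axis=(0, 1)))[0]
        if ks.size and ks[-1] - ks[0] + 1 >= min_slices:
            out |= comp
    return out


def smooth_3d(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    sigma_mm: tuple[float, float, float] = DEFAULT_SIGMA_MM,
    tau_s: float | None = DEFAULT_TAU_S,
    roi_band: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian-smooth the indicator field with a physical (mm) kernel and
    re-binarize; the result is clipped to the ROI band.

    With ``tau_s=None`` the binarization level is the blurred field's
    quantile that preserves the input voxel count: a fixed 0.5 level is
    unbiased only for straight boundaries and strictly erodes thin curved
    structures (mean-curvature shrinkage), which a subdural crescent a few
    voxels thick cannot afford. Smoothing then acts purely as a shape
    regularizer. Passing a float uses that fixed level instead.
    """
    if any(s <= 0 for s in sigma_mm):
        raise ValueError("sigma must be positive")
    n = int(np.count_nonzero(mask))
    if n == 0:
        return mask.copy()
    sigma_vox = tuple(s / sp for s, sp in zip(sigma_mm, spacing))
    blurred = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
    if tau_s is None:
        # quantile over the admissible domain only: blur leaks mass into the
        # skull and outside the band, which must not count against the mask
        flat = blurred[roi_band].ravel() if roi_band is not None else blurred.ravel()
        k = flat.size - min(n, flat.size)
        # n-th largest value keeps the pre-smoothing volume
        tau = np.partition(flat, k)[k] if k > 0 else flat.min()
        tau = max(tau, 1e-9)
    else:
        tau = tau_s
    out = blurred >= tau
    if roi_band is not None:
        out &= roi_band
    return out


def postprocess_mask(
    probability: np.ndarray,
    roi_band: np.ndarray,
    skull: np.ndarray,
    spacing: tuple[float, float, float],
    tau: float = 0.5,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    fill_radius_px: int = DEFAULT_FILL_RADIUS_PX,
    max_hole_px: int = DEFAULT_MAX_HOLE_PX,
    min_slices: int = DEFAULT_MIN_SLICES,
    continuity_drift_mm: float = 0.0,
    sigma_mm: tuple[float, float, float] = DEFAULT_SIGMA_MM,
    tau_s: float | None = DEFAULT_TAU_S,
) -> SegmentationResult:
    """Full chain: threshold → 2D clean → fill against skull → 3D
    continuity → 3D smoothing, clipped to the ROI band throughout."""
    initial = threshold_initial(probability, tau, roi_band)
    m = clean_2d(initial, min_area_px)
    m = fill_against_skull(m, skull, fill_radius_px, max_hole_px)
    m &= roi_band
    m = enforce_3d_continuity(m, min_slices, spacing=spacing, drift_mm=continuity_drift_mm)
    final = smooth_3d(m, spacing, sigma_mm, tau_s, roi_band=roi_band)
    return SegmentationResult(
        probability=probability,
        initial_mask=initial,
        final_mask=final,
        provenance={
            "tau": tau,
            "min_area_px": min_area_px,
            "fill_radius_px": fill_radius_px,
            "max_hole_px": max_hole_px,
            "min_slices": min_slices,
            "continuity_drift_mm": continuity_drift_mm,
            "sigma_mm": tuple(sigma_mm),
            "tau_s": tau_s,
        },
    )
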