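"""Hand-crafted per-superpixel features: histogram statistics, Gabor and
Laplacian-of-Gaussian filter banks, spherical location features, and age.

Texture features are computed from a fixed 25 x 25 pixel window around each
superpixel centroid, drawn from the mirror-padded (skull-free) slice so
bone never contaminates them. Filter banks are convolved once per slice and
pooled as the mean (magnitude for Gabor, signed for LoG) over each
superpixel's pixels.

The location features are spherical coordinates about an origin fixed at
the skull's center of mass on the lowest selected axial slice: radial
distance r, elevation phi above that slice's plane, signed azimuth theta
relative to the brain midline, plus the depth r' below the inner skull
surface. The midline is estimated data-driven as the in-plane principal
axis of the intracranial mask on the origin slice, which tolerates head
tilt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve

from .ct_io import CTVolume
from .preprocess import HeadMasks, fill_outside_support, mirror_pad
from .superpixel import SuperpixelMap

__all__ = [
    "GaborParams",
    "LocationFeatures",
    "SphericalFrame",
    "extract_window",
    "histogram_features",
    "gabor_kernel",
    "gabor_bank",
    "log_features",
    "compute_spherical_frame",
    "location_features",
    "assemble_feature_table",
    "HANDCRAFTED_COLUMNS",
]

FEATURE_SCHEMA_VERSION = "1"

WINDOW_SIZE_PX = 25
PAD_WIDTH_PX = WINDOW_SIZE_PX // 2  # 12

GABOR_WAVELENGTHS_PX = (2.0, 4.0, 8.0, 16.0)
GABOR_N_ORIENTATIONS = 8
#: Gaussian envelope tied to wavelength (about one octave bandwidth)
GABOR_SIGMA_FACTOR = 0.56

LOG_SIGMAS_PX = (1.0, 2.0, 4.0, 8.0, 16.0)

#: histogram binning for entropy/skewness/kurtosis (brain display window)
HIST_BINS = 32
HIST_RANGE_HU = (0.0, 100.0)

HIST_COLUMNS = [
    "hist_min",
    "hist_max",
    "hist_mean",
    "hist_sd",
    "sp_mean",
    "hist_skew",
    "hist_kurt",
    "hist_entropy",
    "smoothness",
]
GABOR_COLUMNS = [
    f"gabor_o{o}_w{int(w)}"
    for w in GABOR_WAVELENGTHS_PX
    for o in range(GABOR_N_ORIENTATIONS)
]
LOG_COLUMNS = [f"log_s{int(s)}" for s in LOG_SIGMAS_PX]
LOCATION_COLUMNS = ["loc_r", "loc_theta", "loc_phi", "loc_rprime"]
HANDCRAFTED_COLUMNS = HIST_COLUMNS + GABOR_COLUMNS + LOG_COLUMNS + LOCATION_COLUMNS + ["age"]


@dataclass(frozen=True)
class GaborParams:
    """Carrier frequency (cycles/pixel), envelope constants (pixels) and
    orientation (radians in [0, pi)) of one Gabor filter."""

    u0: float
    sigma_x: float
    sigma_y: float
    orientation: float = 0.0

    def __post_init__(self):
        if self.u0 <= 0 or self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("u0 and envelope constants must be positive")
        if not (0.0 <= self.orientation < math.pi):
            raise ValueError("orientation must lie in [0, pi)")


@dataclass(frozen=True)
class LocationFeatures:
    r: float  # mm, distance to origin
    theta: float  # rad, signed azimuth vs midline, (-pi, pi]
    phi: float  # rad, elevation vs the origin's axial plane, [-pi/2, pi/2]
    r_prime: float  # mm, depth below the inner skull surface


# ---------------------------------------------------------------- windows


def extract_window(
    padded_slice: np.ndarray,
    center: tuple[float, float],
    size: int = WINDOW_SIZE_PX,
    validity: Optional[np.ndarray] = None,
):
    """size x size patch centered on a superpixel centroid, taken from the
    mirror-padded slice. Errors if the window leaves the padded support."""
    half = size // 2
    r = int(round(center[0]))
    c = int(round(center[1]))
    r0, r1 = r - half, r + half + 1
    c0, c1 = c - half, c + half + 1
    if r0 < 0 or c0 < 0 or r1 > padded_slice.shape[0] or c1 > padded_slice.shape[1]:
        raise ValueError("window exceeds the image grid; pad_width misconfigured")
    if validity is not None and not validity[r0:r1, c0:c1].all():
        raise ValueError("window exceeds padded support; pad_width misconfigured")
    return padded_slice[r0:r1, c0:c1]


# ---------------------------------------------------------------- histogram


def _smoothness(patch_hu: np.ndarray) -> float:
    """Texture smoothness R = 1 - 1/(1 + sigma^2) with sigma computed on
    intensities rescaled to [0, 1] over the brain window; 0 for a flat
    patch, approaching 1 as variance grows."""
    lo, hi = HIST_RANGE_HU
    scaled = np.clip((patch_hu - lo) / (hi - lo), 0.0, 1.0)
    var = float(scaled.var())
    return 1.0 - 1.0 / (1.0 + var)


def histogram_features(patch: np.ndarray, superpixel_pixels: np.ndarray) -> np.ndarray:
    """The 9 histogram/statistics features for one superpixel.

    Order: window min, max, mean, sd; superpixel mean; histogram skewness,
    (excess) kurtosis, entropy in bits; smoothness. Skewness and kurtosis
    of a flat patch are defined as 0.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("empty patch")
    counts, edges = np.histogram(patch, bins=HIST_BINS, range=HIST_RANGE_HU)
    total = counts.sum()
    if total == 0:  # every value outside the window range; degenerate
        p = np.zeros(HIST_BINS)
    else:
        p = counts / total
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu = float((p * centers).sum())
    var = float((p * (centers - mu) ** 2).sum())
    if var > 0:
        sd_h = math.sqrt(var)
        skew = float((p * ((centers - mu) / sd_h) ** 3).sum())
        kurt = float((p * ((centers - mu) / sd_h) ** 4).sum()) - 3.0
    else:
        skew = kurt = 0.0
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0
    return np.array(
        [
            float(patch.min()),
            float(patch.max()),
            float(patch.mean()),
            float(patch.std()),
            float(np.asarray(superpixel_pixels, dtype=float).mean()),
            skew,
            kurt,
            entropy,
            _smoothness(patch),
        ]
    )


# ---------------------------------------------------------------- filters


def gabor_kernel(params: GaborParams, zero_dc: bool = False) -> np.ndarray:
    """Real Gabor kernel h(x, y) = exp(-1/2 [x'^2/sx^2 + y'^2/sy^2]) *
    cos(2 pi u0 x'), with (x', y') the rigidly rotated coordinates.

    x is the column axis, y the row axis; at orientation 0 the carrier
    varies along columns, so a vertical grating responds maximally.

    With ``zero_dc`` the sampled kernel is corrected to zero total sum by
    subtracting a Gaussian-envelope-proportional component: the raw
    discrete kernel leaks a small orientation-dependent DC response, which
    would make filter outputs depend on absolute intensity. The filter
    bank uses the corrected kernels; the raw kernel keeps its analytic
    value of 1 at the origin.
    """
    half = int(math.ceil(3.0 * max(params.sigma_x, params.sigma_y)))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    ct, st = math.cos(params.orientation), math.sin(params.orientation)
    xr = x * ct + y * st
    yr = -x * st + y * ct
    envelope = np.exp(-0.5 * (xr**2 / params.sigma_x**2 + yr**2 / params.sigma_y**2))
    kernel = envelope * np.cos(2.0 * math.pi * params.u0 * xr)
    if zero_dc:
        kernel = kernel - envelope * (kernel.sum() / envelope.sum())
    return kernel


@lru_cache(maxsize=1)
def _gabor_bank_kernels() -> tuple[tuple[GaborParams, np.ndarray], ...]:
    bank = []
    for wavelength in GABOR_WAVELENGTHS_PX:
        sigma = GABOR_SIGMA_FACTOR * wavelength
        for k in range(GABOR_N_ORIENTATIONS):
            params = GaborParams(
                u0=1.0 / wavelength,
                sigma_x=sigma,
                sigma_y=sigma,
                orientation=k * math.pi / GABOR_N_ORIENTATIONS,
            )
            bank.append((params, gabor_kernel(params, zero_dc=True)))
    return tuple(bank)


def _convolve_same_edge(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-size convolution with edge-replicated boundaries, so zero-sum
    kernels see no artificial step at the image border."""
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode="edge")
    return fftconvolve(padded, kernel, mode="valid")


def _pool_mean(response: np.ndarray, label_slice: np.ndarray, n: int) -> np.ndarray:
    """Mean of *response* over each superpixel (labels 1..n) on the slice."""
    flat_labels = label_slice.ravel()
    sums = np.bincount(flat_labels, weights=response.ravel(), minlength=n + 1)
    counts = np.bincount(flat_labels, minlength=n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    return means[1 : n + 1]


def gabor_bank(padded_slice: np.ndarray, label_slice: Optional[np.ndarray] = None):
    """Responses of the 8-orientation x 4-wavelength Gabor bank.

    With *label_slice* given (superpixel ids 1..n), returns an (n, 32)
    array of mean magnitude responses per superpixel; otherwise returns the
    stack of 32 magnitude-response images.
    """
    responses = [
        np.abs(_convolve_same_edge(padded_slice, kern))
        for _, kern in _gabor_bank_kernels()
    ]
    if label_slice is None:
        return np.stack(responses)
    n = int(label_slice.max())
    return np.column_stack([_pool_mean(r, label_slice, n) for r in responses])


def log_kernel(sigma: float) -> np.ndarray:
    """Sampled Laplacian-of-Gaussian kernel, DC-corrected to zero sum so a
    constant image yields exactly zero and (by symmetry) affine images are
    annihilated exactly."""
    half = int(math.ceil(3.0 * sigma))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    r2 = x**2 + y**2
    envelope = np.exp(-r2 / (2.0 * sigma**2))
    kernel = (r2 - 2.0 * sigma**2) / sigma**4 * envelope
    return kernel - envelope * (kernel.sum() / envelope.sum())


@lru_cache(maxsize=1)
def _log_kernels() -> tuple[np.ndarray, ...]:
    return tuple(log_kernel(s) for s in LOG_SIGMAS_PX)


def log_features(padded_slice: np.ndarray, label_slice: Optional[np.ndarray] = None):
    """Laplacian-of-Gaussian responses at the 5 configured scales; mean
    signed response per superpixel when *label_slice* is given."""
    responses = [_convolve_same_edge(padded_slice, kern) for kern in _log_kernels()]
    if label_slice is None:
        return np.stack(responses)
    n = int(label_slice.max())
    return np.column_stack([_pool_mean(r, label_slice, n) for r in responses])


# ---------------------------------------------------------------- location


@dataclass(frozen=True)
class SphericalFrame:
    """Origin and midline defining the spherical coordinate system."""

    origin_voxel: tuple[float, float, float]  # (row, col, slice), voxel units
    midline: tuple[float, float]  # unit vector (row, col), physical, anterior
    origin_slice: int


def compute_spherical_frame(
    masks: HeadMasks,
    geometry: CTVolume,
    min_area_px: int = 200,
) -> SphericalFrame:
    """Origin = skull center of mass on the lowest selected slice (first
    axial slice whose intracranial area exceeds *min_area_px*); midline =
    in-plane principal axis of the intracranial mask on that slice,
    oriented anterior (negative row direction)."""
    areas = masks.intracranial.sum(axis=(0, 1))
    eligible = np.nonzero(areas >= min_area_px)[0]
    if eligible.size == 0:
        raise ValueError("no axial slice with enough intracranial area")
    k0 = int(eligible[0])
    skull_slice = masks.skull[:, :, k0]
    if not skull_slice.any():
        raise ValueError("no skull on the origin slice")
    r0, c0 = ndimage.center_of_mass(skull_slice)

    rr, cc = np.nonzero(masks.intracranial[:, :, k0])
    pts = np.column_stack([rr * geometry.spacing[0], cc * geometry.spacing[1]])
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, int(np.argmax(eigvals))]
    # orient toward anterior (-row); tie-break toward +col
    if axis[0] > 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return SphericalFrame(
        origin_voxel=(float(r0), float(c0), float(k0)),
        midline=(float(axis[0]), float(axis[1])),
        origin_slice=k0,
    )


def location_features(
    center: tuple[float, float, float],
    masks: HeadMasks,
    geometry: CTVolume,
    frame: Optional[SphericalFrame] = None,
) -> LocationFeatures:
    """Spherical coordinates (r, theta, phi) of a voxel about the frame
    origin plus the inner-skull depth r'."""
    if frame is None:
        frame = compute_spherical_frame(masks, geometry)
    ci = tuple(int(round(v)) for v in center)
    if not masks.intracranial[ci]:
        raise ValueError(f"center {ci} is outside the intracranial mask")
    sp = geometry.spacing
    d = np.array(
        [
            (center[0] - frame.origin_voxel[0]) * sp[0],
            (center[1] - frame.origin_voxel[1]) * sp[1],
            (center[2] - frame.origin_voxel[2]) * sp[2],
        ]
    )
    r = float(np.linalg.norm(d))
    inplane = math.hypot(d[0], d[1])
    phi = math.atan2(d[2], inplane) if r > 0 else 0.0
    m = frame.midline
    theta = math.atan2(m[0] * d[1] - m[1] * d[0], m[0] * d[0] + m[1] * d[1])
    if inplane == 0:
        theta = 0.0
    r_prime = float(masks.inner_surface_distance[ci])
    return LocationFeatures(r=r, theta=theta, phi=phi, r_prime=r_prime)


# ---------------------------------------------------------------- assembly


def prepare_padded_slice(volume: CTVolume, masks: HeadMasks, k: int):
    """Skull-free, mirror-padded axial slice k plus its validity mask and a
    full-grid nearest-value extension for large filter kernels."""
    img = volume.voxels[:, :, k]
    intr = masks.intracranial[:, :, k]
    padded, validity = mirror_pad(img, intr, pad_width=PAD_WIDTH_PX)
    filled = fill_outside_support(padded, validity)
    return padded, validity, filled


def assemble_feature_table(
    volume: CTVolume,
    masks: HeadMasks,
    spmap: SuperpixelMap,
    labels: Optional[np.ndarray] = None,
    age: Optional[float] = None,
) -> pd.DataFrame:
    """One complete row per superpixel: the 51-column hand-crafted block
    (9 histogram + 32 Gabor + 5 LoG + 4 location + age) plus bookkeeping
    columns. Deterministic given its inputs; any NaN is a hard error."""
    if age is None:
        age = volume.patient_age if volume.patient_age is not None else 0.0
    frame = compute_spherical_frame(masks, volume)
    n = spmap.n_superpixels
    hist_block = np.zeros((n, len(HIST_COLUMNS)))
    gabor_block = np.zeros((n, len(GABOR_COLUMNS)))
    log_block = np.zeros((n, len(LOG_COLUMNS)))
    loc_block = np.zeros((n, 4))

    for k in np.unique(spmap.slice_index):
        padded, validity, filled = prepare_padded_slice(volume, masks, int(k))
        label_slice = spmap.label_image[:, :, int(k)]
        on_slice = np.nonzero(spmap.slice_index == k)[0]
        gab = gabor_bank(filled, label_slice)
        log = log_features(filled, label_slice)
        for i in on_slice:
            sp_id = i + 1
            gabor_block[i] = gab[sp_id - 1]
            log_block[i] = log[sp_id - 1]
            region = label_slice == sp_id
            patch = extract_window(
                padded, (spmap.centers[i, 0], spmap.centers[i, 1]), validity=validity
            )
            hist_block[i] = histogram_features(patch, padded[region])
            center = spmap.centers[i]
            ci = (int(round(center[0])), int(round(center[1])), int(k))
            if not masks.intracranial[ci]:
                # concave regions can round their centroid onto the skull;
                # snap to the region pixel nearest the centroid
                rr, cc = np.nonzero(region)
                j = np.argmin((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                center = (float(rr[j]), float(cc[j]), float(k))
            loc = location_features(center, masks, volume, frame)
            loc_block[i] = (loc.r, loc.theta, loc.phi, loc.r_prime)

    table = pd.DataFrame(
        np.hstack([hist_block, gabor_block, log_block, loc_block]),
        columns=HIST_COLUMNS + GABOR_COLUMNS + LOG_COLUMNS + LOCATION_COLUMNS,
    )
    table.insert(0, "scan_id", volume.scan_id)
    table.insert(1, "superpixel_id", spmap.ids())
    table.insert(2, "slice", spmap.slice_index)
    table["age"] = float(age)
    if labels is not None:
        table["label"] = np.asarray(labels, dtype=bool)
    table.attrs["schema_version"] = FEATURE_SCHEMA_VERSION

    feat = table[HANDCRAFTED_COLUMNS]
    if feat.isna().any().any():
        bad = feat.isna().any()
        col = bad[bad].index[0]
        row = int(table.loc[feat[col].isna(), "superpixel_id"].iloc[0])
        raise ValueError(f"NaN in feature {col!r} for superpixel {row}")
    return table
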