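"""Synthetic head-CT phantoms with ground-truth subdural lesions.

The generator emulates the imaging structure the segmentation pipeline
relies on: a high-density ellipsoidal skull shell, a textured brain
interior, an optional central CSF cavity, and crescent-shaped subdural
lesions hugging the inner skull surface. Lesion intensity classes follow
the clinical convention — acute hyperdense (brighter than brain), subacute
isodense, chronic hypodense — and a "mixed" lesion stacks an acute layer
against the skull over a deeper chronic layer.

Crescents are built as the region between the inner-skull ellipsoid and a
copy of it displaced away from the lesion side, clipped to an angular
sector; the displacement is solved by bisection so the realized voxel
volume matches the requested volume. Blood is homogeneous apart from
acquisition noise, whereas the brain carries a smooth correlated texture
field — the same homogeneous-vs-parenchyma contrast that makes isodense
hematomas recognizable on real CT.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .ct_io import CTVolume

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "cohort_manifest",
]

LESION_TYPES = ("acute", "subacute", "chronic", "mixed")

#: relative tolerance of the realized lesion volume vs the target
VOLUME_RTOL = 0.10
#: maximum crescent displacement (mm); keeps lesions within the 32 mm band
MAX_THICKNESS_MM = 28.0


@dataclass(frozen=True)
class LesionSpec:
    """One crescentic subdural lesion.

    Parameters
    ----------
    type:
        ``acute`` / ``subacute`` / ``chronic`` / ``mixed``.
    target_volume_cc:
        Requested ground-truth volume in cc; the realized voxelized volume
        is solved to within :data:`VOLUME_RTOL`.
    side:
        ``left`` or ``right`` hemisphere (column axis).
    angle_deg:
        In-plane direction of the crescent apex, degrees; 90 is left
        (+column), 270 right. Defaults by side.
    halfwidth_deg:
        Angular half-extent of the sector. ``None`` picks a volume-dependent
        default (bigger lesions get wider sectors).
    """

    type: str = "acute"
    target_volume_cc: float = 30.0
    side: str = "left"
    angle_deg: Optional[float] = None
    halfwidth_deg: Optional[float] = None

    def __post_init__(self):
        if self.type not in LESION_TYPES:
            raise ValueError(f"unknown lesion type {self.type!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.target_volume_cc <= 0:
            raise ValueError("target_volume_cc must be positive")

    @property
    def apex_angle_rad(self) -> float:
        if self.angle_deg is not None:
            return math.radians(self.angle_deg)
        return math.radians(90.0 if self.side == "left" else 270.0)

    @property
    def sector_halfwidth_rad(self) -> float:
        if self.halfwidth_deg is not None:
            return math.radians(self.halfwidth_deg)
        # severe collections spread over much of the hemisphere rather than
        # pooling deeply: wider sectors keep maximum depth growing slowly
        # with volume, mirroring the 3.2 cm clinical depth bound
        v = self.target_volume_cc
        if v < 40:
            return math.radians(70.0)
        if v < 90:
            return math.radians(90.0)
        if v < 150:
            return math.radians(105.0)
        return math.radians(115.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, tissue intensities, and noise of a synthetic head."""

    shape: tuple[int, int, int] = (224, 224, 18)
    spacing: tuple[float, float, float] = (0.75, 0.75, 5.0)
    skull_hu: float = 1000.0
    brain_hu: float = 35.0
    csf_hu: float = 5.0
    acute_hu: float = 70.0
    subacute_hu: float = 35.0
    chronic_hu: float = 15.0
    air_hu: float = -1000.0
    noise_sd: float = 4.0
    texture_sd: float = 6.0  # correlated brain-texture amplitude, HU
    skull_thickness_mm: float = 6.0
    #: thin subarachnoid CSF layer along the inner table; subdural blood
    #: displaces it, so lesions abut the skull directly while normal cortex
    #: is separated from bone by this rim
    csf_rim_mm: float = 2.0
    lesions: tuple[LesionSpec, ...] = ()
    patient_age: Optional[float] = None
    scan_id: str = "phantom"
    seed: int = 0

    def __post_init__(self):
        if not (self.skull_hu > self.acute_hu > self.brain_hu > self.chronic_hu):
            raise ValueError("intensity ordering skull > acute > brain > chronic violated")


@dataclass
class PhantomCase:
    """A generated phantom with its ground truth."""

    volume: CTVolume
    ground_truth: np.ndarray
    per_lesion_masks: list[np.ndarray]
    config: PhantomConfig

    @property
    def true_volume_cc(self) -> float:
        return float(self.ground_truth.sum()) * self.volume.voxel_volume_mm3 / 1000.0

    @property
    def lesion_type(self) -> str:
        if not self.config.lesions:
            return "none"
        return self.config.lesions[0].type


# ---------------------------------------------------------------- geometry


def _grids_mm(shape, spacing):
    r = (np.arange(shape[0]) - (shape[0] - 1) / 2) * spacing[0]
    c = (np.arange(shape[1]) - (shape[1] - 1) / 2) * spacing[1]
    z = (np.arange(shape[2]) - (shape[2] - 1) / 2) * spacing[2]
    return np.meshgrid(r, c, z, indexing="ij")


def _head_semiaxes(shape, spacing):
    # outer skull ellipsoid sized to leave an air margin inside the grid
    ext = [(n - 1) * s / 2 for n, s in zip(shape, spacing)]
    # heads are longer anterior-posterior (rows) than wide (columns)
    return (0.88 * ext[0], 0.80 * ext[1], 0.90 * ext[2])


#: exponent of the z-profile; 2 is a true ellipsoid, higher values flatten
#: the parasagittal walls toward the near-vertical profile of a real cranium
Z_PROFILE_EXPONENT = 4


def _ellipsoid_rho(R, C, Z, semiaxes, offset=(0.0, 0.0, 0.0)):
    """Generalized radius of a superellipsoid cranium: elliptical in-plane,
    with a flattened (|z/c|^q, q > 2) vertical profile so the skull wall is
    near-vertical over most of the head height, as in a real skull."""
    a, b, c = semiaxes
    q = Z_PROFILE_EXPONENT
    s = ((R - offset[0]) / a) ** 2 + ((C - offset[1]) / b) ** 2
    t = np.abs((Z - offset[2]) / c) ** q
    return (s ** (q / 2) + t) ** (1.0 / q)


def _crescent_mask(R, C, Z, inner_semiaxes, spec: LesionSpec, displacement_mm: float):
    """Crescent = inside inner skull, outside the same ellipsoid displaced
    away from the lesion apex, clipped to the angular sector."""
    u = np.array([-math.cos(spec.apex_angle_rad), math.sin(spec.apex_angle_rad)])
    rho_in = _ellipsoid_rho(R, C, Z, inner_semiaxes)
    off = (-displacement_mm * u[0], -displacement_mm * u[1], 0.0)
    rho_shift = _ellipsoid_rho(R, C, Z, inner_semiaxes, offset=off)
    theta = np.arctan2(C, -R)  # in-plane angle; 0 = anterior (-row)
    dtheta = np.angle(np.exp(1j * (theta - spec.apex_angle_rad)))
    # subdural blood lies directly against the inner table: the crescent
    # extends to (but never into) the skull
    return (
        (rho_in < 1.0)
        & (rho_shift >= 1.0)
        & (np.abs(dtheta) <= spec.sector_halfwidth_rad)
    )


def _solve_crescent(R, C, Z, inner_semiaxes, spec, voxel_cc):
    """Bisection on the displacement so the voxel volume hits the target."""
    target = spec.target_volume_cc

    def vol(s):
        return _crescent_mask(R, C, Z, inner_semiaxes, spec, s).sum() * voxel_cc

    lo, hi = 0.0, MAX_THICKNESS_MM
    v_hi = vol(hi)
    if v_hi < target * (1 - VOLUME_RTOL):
        raise ValueError(
            f"lesion of {target:.1f} cc infeasible: at most {v_hi:.1f} cc fits "
            f"in a {math.degrees(spec.sector_halfwidth_rad):.0f} deg sector"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if vol(mid) < target:
            lo = mid
        else:
            hi = mid
    mask = _crescent_mask(R, C, Z, inner_semiaxes, spec, hi)
    realized = mask.sum() * voxel_cc
    if abs(realized - target) > VOLUME_RTOL * target:
        raise ValueError(
            f"could not realize {target:.1f} cc (got {realized:.1f} cc) on this grid"
        )
    return mask


def _texture_field(shape, rng, sigma_vox=(6.0, 6.0, 1.0)):
    """Smooth unit-variance random field for brain parenchyma texture."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


# ---------------------------------------------------------------- generation


def generate_phantom(config: PhantomConfig):
    """Render one phantom head.

    Returns
    -------
    (volume, ground_truth, per_lesion_masks)
        The CT volume in HU, the union ground-truth lesion mask, and one
        boolean mask per configured lesion.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    shape, spacing = config.shape, config.spacing
    R, C, Z = _grids_mm(shape, spacing)
    outer = _head_semiaxes(shape, spacing)
    t = config.skull_thickness_mm
    inner = tuple(a - t for a in outer)

    rho_out = _ellipsoid_rho(R, C, Z, outer)
    rho_in = _ellipsoid_rho(R, C, Z, inner)
    skull = (rho_out <= 1.0) & (rho_in > 1.0)
    interior = rho_in <= 1.0

    # central CSF cavity (ventricle stand-in), well inside the ROI-band depth
    vent = _ellipsoid_rho(R, C, Z, (0.18 * inner[0], 0.22 * inner[1], 0.4 * inner[2])) <= 1.0
    vent &= interior

    voxel_cc = float(np.prod(spacing)) / 1000.0
    lesion_masks = []
    for spec in config.lesions:
        mask = _solve_crescent(R, C, Z, inner, spec, voxel_cc)
        mask &= ~vent
        lesion_masks.append(mask)
    ground_truth = np.zeros(shape, dtype=bool)
    for m in lesion_masks:
        ground_truth |= m

    hu = np.full(shape, config.air_hu)
    hu[interior] = config.brain_hu
    hu[vent] = config.csf_hu
    if config.csf_rim_mm > 0:
        depth = ndimage.distance_transform_edt(interior, sampling=spacing)
        rim = interior & (depth <= config.csf_rim_mm) & ~ground_truth
        hu[rim] = config.csf_hu
    texture = _texture_field(shape, rng)
    brain_only = interior & ~vent & ~ground_truth & (hu > config.csf_hu)
    hu[brain_only] += config.texture_sd * texture[brain_only]

    class_hu = {
        "acute": config.acute_hu,
        "subacute": config.subacute_hu,
        "chronic": config.chronic_hu,
    }
    for spec, mask in zip(config.lesions, lesion_masks):
        if spec.type == "mixed":
            # stack: outer (skull-adjacent) layer acute, deeper layer chronic
            rho_vals = rho_in[mask]
            split = np.median(rho_vals)
            outer_layer = mask & (rho_in >= split)
            hu[mask] = config.chronic_hu
            hu[outer_layer] = config.acute_hu
        else:
            hu[mask] = class_hu[spec.type]

    hu[skull] = config.skull_hu
    hu = hu + config.noise_sd * rng.standard_normal(shape)

    volume = CTVolume(
        voxels=hu,
        spacing=spacing,
        patient_age=config.patient_age,
        scan_id=config.scan_id,
    )
    return volume, ground_truth, lesion_masks


# ---------------------------------------------------------------- cohorts

DEFAULT_STRATA = ((8.0, 25.0), (25.0, 50.0), (50.0, 120.0), (120.0, 220.0))


def generate_cohort(
    n: int,
    volume_strata: Sequence[tuple[float, float]] = DEFAULT_STRATA,
    seed: int = 0,
    n_normal: int = 0,
    config: PhantomConfig = PhantomConfig(),
) -> list[PhantomCase]:
    """Generate *n* lesion cases round-robin across volume strata, plus
    *n_normal* lesion-free controls; deterministic under *seed*.

    Lesion types cycle through acute/chronic/mixed/subacute and alternate
    sides so each stratum mixes classes and hemispheres.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    strata = [tuple(map(float, s)) for s in volume_strata]
    if not strata:
        raise ValueError("volume_strata must not be empty")
    for lo, hi in strata:
        if not (0 < lo < hi):
            raise ValueError(f"invalid stratum ({lo}, {hi})")

    # chronic and mixed collections skew elderly (brain atrophy leaves room
    # for silent expansion); acute trauma skews younger
    age_ranges = {
        "acute": (25, 70),
        "subacute": (40, 80),
        "chronic": (62, 90),
        "mixed": (58, 90),
        "none": (25, 90),
    }
    cases: list[PhantomCase] = []
    root = np.random.SeedSequence(seed)
    for i in range(n + n_normal):
        rng = np.random.default_rng(root.spawn(1)[0])
        if i < n:
            # stratum index advances out of phase with the 4-type cycle so
            # lesion type and volume stratum decorrelate across the cohort
            lo, hi = strata[(i + i // len(LESION_TYPES)) % len(strata)]
            target = float(rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo)))
            ltype = LESION_TYPES[i % 4]
            if target < 25.0 and ltype == "mixed":
                # small collections skew acute: mixed (acute-on-chronic)
                # lesions arise from rebleeding into an already large
                # chronic collection, so tiny mixed lesions are implausible
                ltype = "acute"
            side = "left" if i % 2 == 0 else "right"
            if target >= 50.0:
                # larger collections present bilaterally with a smaller
                # contralateral lesion of complementary chronicity, sharing
                # the stratum's total volume; this mirrors the combined
                # acute-plus-chronic presentations common in the elderly
                other = {"acute": "chronic", "chronic": "acute",
                         "subacute": "mixed", "mixed": "subacute"}[ltype]
                lesions: tuple[LesionSpec, ...] = (
                    LesionSpec(type=ltype, target_volume_cc=0.65 * target, side=side),
                    LesionSpec(
                        type=other,
                        target_volume_cc=0.35 * target,
                        side="right" if side == "left" else "left",
                    ),
                )
            else:
                lesions = (LesionSpec(type=ltype, target_volume_cc=target, side=side),)
            scan_id = f"phantom-{i:03d}-{ltype}"
        else:
            ltype = "none"
            lesions = ()
            scan_id = f"phantom-{i:03d}-normal"
        age = float(np.round(rng.uniform(*age_ranges[ltype]), 1))
        case_cfg = replace(
            config,
            lesions=lesions,
            seed=int(rng.integers(0, 2**31 - 1)),
            patient_age=age,
            scan_id=scan_id,
        )
        volume, gt, per_lesion = generate_phantom(case_cfg)
        cases.append(PhantomCase(volume, gt, per_lesion, case_cfg))
    return cases


def cohort_manifest(cases: Sequence[PhantomCase]) -> pd.DataFrame:
    """Tabular summary (scan id, lesion type, true volume, age) of a cohort."""
    rows = [
        {
            "scan_id": c.volume.scan_id,
            "lesion_type": c.lesion_type,
            "true_volume_cc": round(c.true_volume_cc, 3),
            "age": c.volume.patient_age,
        }
        for c in cases
    ]
    return pd.DataFrame(rows)
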