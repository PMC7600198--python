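"""Shared fixtures: small, fast phantoms for unit tests.

Unit tests run on a reduced grid (96 x 96 x 10 at 1 x 1 x 5 mm) so each
pipeline stage stays fast; the acceptance tests use the generator's
defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

from sdhseg.config import PipelineConfig
from sdhseg.phantom import LesionSpec, PhantomConfig, generate_phantom
from sdhseg.preprocess import compute_head_masks
from sdhseg.superpixel import generate_superpixels, label_superpixels

SMALL_SHAPE = (96, 96, 10)
SMALL_SPACING = (1.0, 1.0, 5.0)


def small_config(**kw) -> PhantomConfig:
    kw.setdefault("shape", SMALL_SHAPE)
    kw.setdefault("spacing", SMALL_SPACING)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def acute_case():
    """A small acute-lesion phantom: (volume, ground truth, lesion masks)."""
    cfg = small_config(
        lesions=(LesionSpec(type="acute", target_volume_cc=12.0),),
        seed=42,
        patient_age=55.0,
        scan_id="fixture-acute",
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def acute_masks(acute_case):
    volume, _, _ = acute_case
    return compute_head_masks(volume)


@pytest.fixture(scope="session")
def acute_spmap(acute_case, acute_masks):
    volume, _, _ = acute_case
    return generate_superpixels(volume, acute_masks.roi_band)


@pytest.fixture(scope="session")
def acute_labels(acute_case, acute_spmap):
    _, gt, _ = acute_case
    return label_superpixels(acute_spmap, gt)


@pytest.fixture(scope="session")
def lesion_free_case():
    cfg = small_config(seed=7, scan_id="fixture-normal")
    return generate_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
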