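import numpy as np
import pytest

import flatquant as fq

#: pipeline configuration used for synthetic renders: the simulator has no
#: additive haze, so background subtraction (which would treat large bright
#: clusters as background) is off
SYNTH_CONFIG = fq.RunConfig(background_subtraction=False)


def make_spec(**overrides) -> fq.FlatmountSpec:
    """A fast-rendering flatmount spec for tests; overrides applied on top."""
    base = dict(
        image_height=256,
        image_width=256,
        n_cells=150,
        seed=1,
        expressing_fraction_central=0.5,
        expressing_fraction_peripheral=0.5,
    )
    base.update(overrides)
    return fq.FlatmountSpec(**base)


def noiseless(**overrides) -> fq.FlatmountSpec:
    """Spec in the clean limit: no noise, no vignetting, no artifacts."""
    base = dict(noise_gain=0.0, read_noise_sd=0.0, vignette_strength=0.0, n_artifacts=0)
    base.update(overrides)
    return make_spec(**base)


def truth_exclusions(truth: fq.GroundTruth) -> tuple:
    """Ground-truth exclusion regions: everything outside tissue, plus artifacts."""
    return (~truth.tissue_mask, truth.artifact_mask)


def eye_input(truth, image, eye_id="e1", mouse_id="m1", group="g1", eye="OD"):
    return fq.EyeInput(
        image=image,
        eye_id=eye_id,
        mouse_id=mouse_id,
        group=group,
        eye=eye,
        optic_nerve_center=truth.optic_nerve_center,
        exclusion_regions=truth_exclusions(truth),
    )


def measurable_mask(truth: fq.GroundTruth) -> np.ndarray:
    return truth.tissue_mask & ~truth.artifact_mask


def oracle_area_share(truth: fq.GroundTruth) -> float:
    """Ground-truth expressing-pixel share of the measurable area, percent."""
    meas = measurable_mask(truth)
    return 100.0 * truth.expressing_pixel_mask()[meas].sum() / meas.sum()


@pytest.fixture(scope="session")
def default_eye():
    """One rendered eye at default noise, with its ground truth."""
    spec = make_spec()
    truth = fq.generate_mosaic(spec)
    image = fq.render_image(truth, spec)
    return spec, truth, image


@pytest.fixture(scope="session")
def noiseless_eye():
    spec = noiseless()
    truth = fq.generate_mosaic(spec)
    image = fq.render_image(truth, spec)
    return spec, truth, image


@pytest.fixture(scope="session")
def nuclear_eye():
    """Nuclear-localized reporter render (the fetal-style image)."""
    spec = make_spec(
        reporter_localization="nuclear",
        expressing_fraction_central=0.835,
        expressing_fraction_peripheral=0.835,
        n_cells=200,
        image_height=320,
        image_width=320,
    )
    truth = fq.generate_mosaic(spec)
    image = fq.render_image(truth, spec)
    return spec, truth, image
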