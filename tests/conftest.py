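import pytest
from hypothesis import HealthCheck, settings

from swirclass import cube, phantom, preprocess

settings.register_profile(
    "deterministic", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale phantom configuration shared by the slower tests."""
    return phantom.PhantomConfig(image_shape=(64, 48), seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return phantom.generate_study(small_config, n_individuals=4, n_controls=1)


@pytest.fixture(scope="session")
def small_cubes(small_config, small_study):
    return [cube.build_cube(out.frames, out.darks,
                            small_config.saturation_threshold, cube_id=out.cube_id)
            for out in small_study]


@pytest.fixture(scope="session")
def labeled_auc(small_cubes, small_study):
    """AUC-normalized labeled spectra of the four dye-positive cubes."""
    return [preprocess.extract_labeled_spectra(c, out.rois, "auc")
            for c, out in zip(small_cubes[:4], small_study[:4])]
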