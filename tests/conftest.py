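import numpy as np
import pytest

from granulekit.synthetic import CondensateClassSpec, NoiseSpec, SceneSpec


def make_scene_spec(seed: int = 0, *, n_cells: int = 2, noise_sd: float = 0.0,
                    poisson: bool = False, docking_fraction: float = 0.0,
                    n_sg: int = 5, n_pb: int = 0, n_foci: int = 0,
                    shape=(1, 256, 256), cytoplasm_scale: float = 2.0) -> SceneSpec:
    """A small two-cell field: diffuse GFP cytoplasm with bright SG puncta,
    optional P-bodies on the stain channel and nuclear foci."""
    condensates = []
    if n_sg:
        condensates.append(CondensateClassSpec(
            name="sg", compartment="cytoplasmic", count_mean=n_sg,
            radius_mean_um=0.4, peak_intensity={"gfp": 200.0}))
    if n_pb:
        condensates.append(CondensateClassSpec(
            name="pbody", compartment="cytoplasmic", count_mean=n_pb,
            radius_mean_um=0.3, peak_intensity={"stain": 150.0}))
    if n_foci:
        condensates.append(CondensateClassSpec(
            name="foci", compartment="nuclear", count_mean=n_foci,
            radius_mean_um=0.3, peak_intensity={"gfp": 250.0}))
    return SceneSpec(
        image_shape=shape, n_cells=n_cells, cytoplasm_scale=cytoplasm_scale,
        cytoplasm_intensity={"gfp": 20.0, "stain": 20.0},
        condensates=condensates, docking_fraction=docking_fraction,
        noise=NoiseSpec(gaussian_sd=noise_sd, poisson=poisson), seed=seed)


@pytest.fixture
def scene_spec():
    return make_scene_spec(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
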