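"""Shared fixtures: small random volumes and session-scoped phantoms."""

from __future__ import annotations

import numpy as np
import pytest

from mitotap.phantom import demo_spec, generate_phantom, make_cj_phantom, render_grayscale
from mitotap.volumes import LabelVolume, ScalarVolume, VoxelGrid


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def grid16() -> VoxelGrid:
    return VoxelGrid((16, 16, 16), (10.0, 10.0, 10.0))


@pytest.fixture
def random_byte_volume(rng, grid16) -> ScalarVolume:
    return ScalarVolume(
        grid16, rng.integers(0, 256, size=grid16.shape, dtype=np.uint8), vrange=(0, 255)
    )


@pytest.fixture(scope="session")
def cj_phantom():
    """Sphere with 5 junction-contacting and 3 detached tubular cristae."""
    return make_cj_phantom(n_contact=5, n_detached=3)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Full pipeline result on the 4-mitochondrion demo phantom."""
    from mitotap.pipeline import quantify_dataset

    mito, cristae, truth = generate_phantom(demo_spec(seed=7))
    gray = render_grayscale(mito, cristae, noise_sd=10.0, seed=7)
    out = tmp_path_factory.mktemp("demo_run")
    result = quantify_dataset(
        {"defaults": {"seed": 7}},
        volumes={
            "mito": mito,
            "lamellar": cristae.lamellar,
            "tubular": cristae.tubular,
            "grayscale": gray,
        },
        out_dir=out,
    )
    result["truth"] = truth
    return result
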