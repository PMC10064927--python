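import numpy as np
import pytest

from isletkit import synthetic as syn
from isletkit.mask_io import DEFAULT_ENCODING, LabelMask, TissueClass, label_islets


@pytest.fixture(scope="session")
def small_scene():
    """A deterministic mixed scene (discs, blobs, one embedded islet)."""
    spec = syn.SceneSpec(
        shape_px=(256, 256),
        pixel_size_um=2.0,
        islets=(
            syn.IsletSpec(center=(60, 60), eq_diameter_um=150.0, shape="disc"),
            syn.IsletSpec(center=(70, 190), eq_diameter_um=80.0, shape="blob"),
            syn.IsletSpec(center=(180, 70), eq_diameter_um=220.0, shape="blob"),
            syn.IsletSpec(
                center=(190, 200), eq_diameter_um=60.0, shape="disc", embedded=True
            ),
        ),
        n_exocrine_distractors=2,
        seed=42,
    )
    image, mask, truths = syn.make_scene(spec)
    return spec, image, mask, truths


@pytest.fixture(scope="session")
def small_components(small_scene):
    _, _, mask, _ = small_scene
    return label_islets(mask)


@pytest.fixture(scope="session")
def bundle_19(tmp_path_factory):
    """A 19-image synthetic bundle written to disk (engine input format)."""
    out = tmp_path_factory.mktemp("bundle19")
    bundle = syn.make_bundle(out, n_images=19, seed=5, shape_px=(384, 384))
    return out, bundle


def mask_from_bool(islet: np.ndarray) -> LabelMask:
    classes = np.where(islet, np.int8(TissueClass.ISLET), np.int8(TissueClass.BACKGROUND))
    return LabelMask(classes=classes, encoding=dict(DEFAULT_ENCODING))


@pytest.fixture(scope="session")
def random_bool_masks():
    """100 random 64x64 boolean masks for oracle-equivalence properties."""
    rng = np.random.default_rng(2024)
    return [rng.random((64, 64)) < p for p in rng.uniform(0.2, 0.7, size=100)]
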