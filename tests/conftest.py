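import numpy as np
import pytest

import specfood as sf


@pytest.fixture(scope="session")
def default_spec() -> sf.GeneratorSpec:
    """The default study conditions: 6 classes, two confusable pairs planted
    at 890 nm, 8 views, jitter and sensor noise on."""
    return sf.GeneratorSpec()


@pytest.fixture(scope="session")
def default_dataset(default_spec):
    """In-memory default synthetic dataset (stacks + label table)."""
    return sf.generate_stacks(default_spec)


@pytest.fixture(scope="session")
def tiny_spec() -> sf.GeneratorSpec:
    """Small, fast dataset for I/O and CLI tests."""
    return sf.GeneratorSpec(n_classes=2, n_views=2, image_size=(64, 64),
                            confusable_pairs=(sf.ConfusablePair(0, 1),),
                            val_view_period=2, seed=3)


def make_shot(pixels, wavelength="RGB", mask=None, **kw):
    return sf.ImageShot(item_id=kw.pop("item_id", 0),
                        view_index=kw.pop("view_index", 0),
                        camera_index=kw.pop("camera_index", 0),
                        wavelength=sf.wl(wavelength), pixels=pixels, mask=mask)
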