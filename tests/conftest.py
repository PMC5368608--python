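"""Shared fixtures: small phantoms built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from cinestrain import (
    LaxPhantomSpec,
    SaxPhantomSpec,
    build_lax_phantom,
    build_sax_phantom,
)


@pytest.fixture(scope="session")
def sax_spec() -> SaxPhantomSpec:
    # compact cycle for fast tracking tests; default radii / contraction / noise
    return SaxPhantomSpec(n_frames=15, peak_frame=6, image_size=96, seed=3)


@pytest.fixture(scope="session")
def sax_phantom(sax_spec):
    return build_sax_phantom(sax_spec)


@pytest.fixture(scope="session")
def lax_spec() -> LaxPhantomSpec:
    return LaxPhantomSpec(n_frames=15, peak_frame=6, image_size=96, length=70.0, seed=3)


@pytest.fixture(scope="session")
def lax_phantom(lax_spec):
    return build_lax_phantom(lax_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
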