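"""Shared fixtures: compact phantoms generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import warpgauge as wg


@pytest.fixture(scope="session")
def head_spec():
    return wg.default_head_spec()


@pytest.fixture(scope="session")
def phantom_pair(head_spec):
    """Reference volume + analytic landmarks (compact 64^3 head)."""
    return wg.generate_phantom(head_spec)


@pytest.fixture(scope="session")
def reference(phantom_pair):
    return phantom_pair[0]


@pytest.fixture(scope="session")
def landmarks(phantom_pair):
    return phantom_pair[1]


@pytest.fixture(scope="session")
def brain_mask(reference):
    mask, _ = wg.extract_brain(reference)
    return mask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
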