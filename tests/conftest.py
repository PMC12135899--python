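"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (per-candidate loops, per-pixel
loops) so they stay independent of the vectorized implementation paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from axoquant import SyntheticSpec, generate_roi_image

_REL_TIE_TOL = 1e-12


def otsu_brute_force(values: np.ndarray) -> int:
    """Exhaustive search over all 256 integer cuts for 8-bit data.

    Maximizes w0*w1*(mu0-mu1)^2 with class0 = v <= t; among cuts within
    relative 1e-12 of the maximum (exact mathematical ties), the lowest wins.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    sigmas = np.full(256, -1.0)
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / n
        w1 = hi.size / n
        sigmas[t] = w0 * w1 * (lo.mean() - hi.mean()) ** 2
    smax = sigmas.max()
    assert smax > 0, "degenerate histogram handed to the oracle"
    for t in range(256):
        if sigmas[t] >= smax * (1.0 - _REL_TIE_TOL):
            return t
    raise AssertionError("unreachable")


def random_bimodal_values(rng: np.random.Generator, n_components: int | None = None) -> np.ndarray:
    """In-mask 8-bit intensity sample from a 1-3 component Gaussian mixture."""
    k = n_components or int(rng.integers(1, 4))
    parts = []
    for _ in range(k):
        mu = rng.uniform(20, 235)
        sd = rng.uniform(4, 30)
        n = int(rng.integers(150, 1500))
        parts.append(rng.normal(mu, sd, n))
    v = np.clip(np.rint(np.concatenate(parts)), 0, 255).astype(np.uint8)
    if np.ptp(v) == 0:  # guard: the threshold needs two distinct values
        v[0] = min(int(v[0]) + 1, 255)
    return v


@pytest.fixture
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=42)


@pytest.fixture
def sample(default_spec):
    return generate_roi_image(default_spec)
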