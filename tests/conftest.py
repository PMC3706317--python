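from __future__ import annotations

import numpy as np
import pytest

from mapprofile import BinaryMap, GridMeta, ScoreMap


@pytest.fixture
def meta_small() -> GridMeta:
    return GridMeta(n_rows=5, n_cols=6, cell_size=1.0 / 6.0, origin=(-10.0, 60.0))


def random_pair(
    meta: GridMeta,
    seed: int,
    binary: bool,
    mask_fraction: float = 0.15,
) -> tuple[ScoreMap | BinaryMap, ScoreMap | BinaryMap]:
    """Two independent random maps sharing one random mask."""
    rng = np.random.default_rng(seed)
    mask = rng.random(meta.shape) > mask_fraction
    if not mask.any():
        mask[0, 0] = True
    if binary:
        a = BinaryMap(meta, (rng.random(meta.shape) < 0.5).astype(int) * mask, mask)
        b = BinaryMap(meta, (rng.random(meta.shape) < 0.5).astype(int) * mask, mask)
    else:
        a = ScoreMap(meta, rng.random(meta.shape), mask)
        b = ScoreMap(meta, rng.random(meta.shape), mask)
    return a, b
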