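"""Binary test patterns with known box-counting dimension.

The Sierpinski triangle at depth ``d`` is built on a ``2^d`` grid via the
bitwise identity ``filled(i, j) = (i & j) == 0``, which yields exactly
``3^d`` filled unit cells and the self-similarity dimension
``log 3 / log 2``.
"""

from __future__ import annotations

import numpy as np

from ..imageops import BinaryMask

__all__ = ["gen_fractal_pattern"]


def gen_fractal_pattern(
    kind: str,
    depth: int = 7,
    size: int = 512,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> tuple[BinaryMask, float | None]:
    """Generate a named binary pattern and its theoretical dimension.

    kinds: ``line`` (D=1), ``filled_square`` (D=2),
    ``sierpinski_triangle`` (D=log3/log2, uses ``depth``),
    ``random_clusters`` (no theoretical D).
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if kind == "line":
        mask = np.zeros((size, size), dtype=bool)
        mask[size // 2, :] = True
        dim = 1.0
    elif kind == "filled_square":
        mask = np.ones((size, size), dtype=bool)
        dim = 2.0
    elif kind == "sierpinski_triangle":
        n = 2**depth
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = (i & j) == 0
        assert int(mask.sum()) == 3**depth
        dim = float(np.log(3) / np.log(2))
    elif kind == "random_clusters":
        rng = np.random.default_rng(seed)
        mask = np.zeros((size, size), dtype=bool)
        n_clusters = max(3, size // 64)
        centers = rng.uniform(0.1 * size, 0.9 * size, size=(n_clusters, 2))
        for cy, cx in centers:
            pts = rng.normal([cy, cx], size * 0.03, size=(size * 2, 2))
            pts = np.clip(np.round(pts).astype(int), 0, size - 1)
            mask[pts[:, 0], pts[:, 1]] = True
        dim = None
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return BinaryMask(mask, pixel_size, {"op": "gen_fractal_pattern", "kind": kind}), dim
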