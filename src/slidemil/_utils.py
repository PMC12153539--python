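"""Small shared numerics helpers."""

from __future__ import annotations

import numpy as np


def block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    """Downsample a 2-D or 2-D-multichannel array by non-overlapping block
    averaging.

    Trailing rows/columns that do not fill a complete ``factor x factor``
    block are discarded (never padded), so the output shape is
    ``(H // factor, W // factor[, C])``.  Returns float64.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"downsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return np.asarray(arr, dtype=np.float64)
    h, w = arr.shape[:2]
    hh, ww = h // factor, w // factor
    if hh == 0 or ww == 0:
        raise ValueError(
            f"array of shape {arr.shape} too small for downsample factor {factor}"
        )
    a = np.asarray(arr[: hh * factor, : ww * factor], dtype=np.float64)
    if a.ndim == 2:
        return a.reshape(hh, factor, ww, factor).mean(axis=(1, 3))
    return a.reshape(hh, factor, ww, factor, -1).mean(axis=(1, 3))


def to_uint8(arr: np.ndarray) -> np.ndarray:
    """Round a float array in [0, 255] to uint8 with clipping."""
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax."""
    x = np.asarray(x, dtype=np.float64)
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
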