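"""Binary morphology from the set-theoretic definitions.

Erosion: the output pixel at (x, y) is foreground iff the structuring
element B, translated so its origin sits at (x, y), is entirely contained
in the foreground set A.  Dilation: the output pixel is foreground iff the
translated B intersects A.  Both are evaluated literally over the translate
offsets of B (vectorised as shifted-array combines), not via convolution
thresholding.

Border policy: cells outside the image are background by default, so an
element hanging over the border can never be "entirely contained" —
erosion is false there.  ``border="foreground"`` treats out-of-bounds
cells as foreground instead; that variant is what makes the duality
``dilate(A, B) == ~erode(~A, reflect(B))`` exact when A has finite support
(the complement of A extends as foreground beyond the image).
"""

from __future__ import annotations

import numpy as np

from .types import StructuringElement

__all__ = ["erode", "dilate", "close", "open_"]


def _shifted(mask: np.ndarray, d: tuple, fill: bool) -> np.ndarray:
    """mask translated so out[x] = mask[x + d], padding with ``fill``."""
    dr, dc = int(d[0]), int(d[1])
    h, w = mask.shape
    out = np.full((h, w), fill, dtype=bool)
    src_r0, src_r1 = max(0, dr), min(h, h + dr)
    src_c0, src_c1 = max(0, dc), min(w, w + dc)
    if src_r0 >= src_r1 or src_c0 >= src_c1:
        return out
    dst_r0, dst_r1 = src_r0 - dr, src_r1 - dr
    dst_c0, dst_c1 = src_c0 - dc, src_c1 - dc
    out[dst_r0:dst_r1, dst_c0:dst_c1] = mask[src_r0:src_r1, src_c0:src_c1]
    return out


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool, copy=False)


def erode(mask: np.ndarray, se: StructuringElement, border: str = "background") -> np.ndarray:
    """Erosion A ⊖ B: true where every cell of the translated B lies in A."""
    mask = _as_bool(mask)
    if border not in ("background", "foreground"):
        raise ValueError("border must be 'background' or 'foreground'")
    fill = border == "foreground"
    out = np.ones_like(mask)
    for d in se.offsets:
        out &= _shifted(mask, d, fill)
    return out


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Dilation A ⊕ B: true where the translated B intersects A."""
    mask = _as_bool(mask)
    out = np.zeros_like(mask)
    for d in se.offsets:
        out |= _shifted(mask, d, False)
    return out


def close(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Closing: dilation followed by erosion (fills gaps narrower than B)."""
    return erode(dilate(mask, se), se)


def open_(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Opening: erosion followed by dilation (removes specks smaller than B)."""
    return dilate(erode(mask, se), se)
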