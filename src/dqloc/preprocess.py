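"""Image preprocessing: region-of-interest cropping and speckle denoising.

Speckle in the phantoms is multiplicative, ``I * (1 + sigma * eps)``; the
denoisers here are its counter.  Block-matching collaborative filtering
(``bm3d``) is supported when the optional ``bm3d`` package is installed;
non-local means and median filtering are always available and are the
defaults used throughout the package.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_nl_means

from .phantom import Annotation, BScan

__all__ = ["crop", "translate_annotation", "denoise", "DENOISE_METHODS"]

DENOISE_METHODS = ("bm3d", "nlm", "median", "none")


def crop(scan: BScan, rect: tuple[int, int, int, int]) -> BScan:
    """Return the sub-image at ``rect = (x0, y0, width, height)``.

    Annotations are not touched; use :func:`translate_annotation` to move
    them into the cropped frame.
    """
    x0, y0, w, h = rect
    if w <= 0 or h <= 0:
        raise ValueError(f"crop rect must have positive size, got {rect}")
    if x0 < 0 or y0 < 0 or x0 + w > scan.width or y0 + h > scan.height:
        raise ValueError(
            f"crop rect {rect} outside image bounds "
            f"{scan.width}x{scan.height}"
        )
    sub = scan.pixels[y0:y0 + h, x0:x0 + w].copy()
    return BScan(sub, scan.patient_id, scan.frame_index)


def translate_annotation(ann: Annotation, x0: int, y0: int) -> Annotation:
    """Shift annotation coordinates into the frame of ``crop(..., (x0, y0, ...))``."""
    lx, ly = ann.left_point
    rx, ry = ann.right_point
    return Annotation(left_point=(lx - x0, ly - y0),
                      right_point=(rx - x0, ry - y0))


def denoise(scan: BScan, method: str = "nlm", strength: float = 10.0) -> BScan:
    """Denoise a scan; returns a new scan of identical shape in [0, 255].

    ``strength`` is an estimate of the noise standard deviation in gray
    levels.  ``strength=0`` is the identity for nlm/median.  The bm3d
    backend requires the optional ``bm3d`` package.
    """
    if method not in DENOISE_METHODS:
        raise ValueError(f"unknown denoise method {method!r}; "
                         f"choose from {DENOISE_METHODS}")
    img = scan.pixels.astype(np.float64)
    if method == "none" or strength <= 0 and method in ("nlm", "median"):
        return BScan(scan.pixels.copy(), scan.patient_id, scan.frame_index)
    if method == "median":
        size = max(1, 2 * int(round(strength / 10.0)) + 1)
        out = ndimage.median_filter(img, size=size)
    elif method == "nlm":
        sigma = strength / 255.0
        out = denoise_nl_means(img / 255.0, h=0.8 * sigma, sigma=sigma,
                               patch_size=5, patch_distance=6,
                               fast_mode=True) * 255.0
    else:  # bm3d
        try:
            import bm3d as _bm3d
        except ImportError as exc:
            raise RuntimeError(
                "denoise(method='bm3d') needs the optional bm3d package; "
                "install dqloc[bm3d] or use method='nlm'"
            ) from exc
        out = _bm3d.bm3d(img / 255.0, sigma_psd=strength / 255.0) * 255.0
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return BScan(out, scan.patient_id, scan.frame_index)
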