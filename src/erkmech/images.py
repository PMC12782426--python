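"""FRET/CFP ratio imaging.

The ERK biosensor reports activity as the ratio of the FRET channel to
the CFP donor channel. Each channel frame is Gaussian-blurred to attenuate
high-frequency noise, background fluorescence is subtracted, and the
pixel-wise ratio is formed; pixels whose denominator is not positive after
background subtraction are masked as NaN rather than producing spurious
ratios.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .features import SmoothingConfig

logger = logging.getLogger(__name__)


class RatioResult(NamedTuple):
    ratio: np.ndarray  # same shape as the input stacks; invalid pixels NaN
    n_invalid: int


def ratio_image(
    fret_stack: np.ndarray,
    cfp_stack: np.ndarray,
    background: tuple[float, float] = (0.0, 0.0),
    cfg: SmoothingConfig | None = None,
) -> RatioResult:
    """Pixel-wise FRET/CFP ratio stack.

    ``background`` gives the per-channel constant background (FRET, CFP).
    Smoothing (sigma ``cfg.image_sigma``, per frame) precedes background
    subtraction and division. Nonpositive-denominator pixels are flagged
    NaN and counted.
    """
    if cfg is None:
        cfg = SmoothingConfig()
    fret = np.asarray(fret_stack, dtype=float)
    cfp = np.asarray(cfp_stack, dtype=float)
    if fret.shape != cfp.shape:
        raise ValueError(f"stack shapes differ: {fret.shape} vs {cfp.shape}")
    if fret.ndim == 2:
        fret = fret[None]
        cfp = cfp[None]
        squeeze = True
    else:
        squeeze = False
    bg_f, bg_c = background
    num = np.empty_like(fret)
    den = np.empty_like(cfp)
    for i in range(fret.shape[0]):
        num[i] = gaussian_filter(fret[i], cfg.image_sigma) - bg_f
        den[i] = gaussian_filter(cfp[i], cfg.image_sigma) - bg_c
    invalid = den <= 0
    n_invalid = int(invalid.sum())
    if n_invalid:
        logger.warning("ratio_image: %d pixels with nonpositive denominator masked", n_invalid)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(invalid, np.nan, num / np.where(invalid, 1.0, den))
    if squeeze:
        ratio = ratio[0]
    return RatioResult(ratio, n_invalid)


def read_stack(path) -> np.ndarray:
    """Read a (multi-page) TIFF channel stack as a float array of shape
    (frames, rows, cols); a single-page file yields one frame."""
    import tifffile

    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a 2D/3D image stack, got shape {stack.shape}")
    return stack


def erk_at_centroids(ratio_frame: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Read the ratio value at cell centroids (nearest pixel); positions in
    (x, y) pixel coordinates, image indexed [row=y, col=x]."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    cols = np.clip(np.rint(pos[:, 0]).astype(int), 0, ratio_frame.shape[1] - 1)
    rows = np.clip(np.rint(pos[:, 1]).astype(int), 0, ratio_frame.shape[0] - 1)
    return ratio_frame[rows, cols]
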