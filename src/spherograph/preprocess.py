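"""Channel conditioning before segmentation and intensity measurement.

Two independent paths:

* the marker channel is cleaned with a top-hat by reconstruction
  (:func:`clean_marker`), which removes the smooth diffuse background while
  keeping the punctate marker signal;
* the nuclei channel is enhanced for instance segmentation
  (:func:`enhance_nuclei`): CLAHE, a morphological opening, an area closing
  and an edge-preserving bilateral filter, in that order.

Both operations are deterministic and never mutate their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import exposure, morphology, restoration

__all__ = ["EnhanceParams", "clean_marker", "enhance_nuclei"]


def clean_marker(marker: np.ndarray, radius: int = 3) -> np.ndarray:
    """Remove diffuse background from the marker channel.

    Subtracts from the image its morphological reconstruction by dilation
    (seed = image eroded with a disc of ``radius`` pixels, mask = image).
    The reconstruction is an estimate of the smooth background, so the
    difference keeps only peaks narrower than the structuring element — the
    classic white top-hat by reconstruction. The result is pointwise
    non-negative and never exceeds the input.

    Parameters
    ----------
    marker : 2-D non-negative array
    radius : disc radius of the erosion, in pixels (>= 1). Peaks narrower
        than roughly this scale survive; broader structure is removed.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.ndim != 2:
        raise ValueError("marker must be a 2-D grid")
    if not np.all(np.isfinite(marker)):
        raise ValueError("marker contains non-finite pixels")
    if np.any(marker < 0):
        raise ValueError("marker intensities must be non-negative")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    seed = morphology.erosion(marker, morphology.disk(radius))
    background = morphology.reconstruction(seed, marker, method="dilation")
    out = marker - background
    # reconstruction <= mask analytically; clip only guards float round-off
    return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class EnhanceParams:
    """Parameters of the nuclei-enhancement chain.

    The defaults are sized for MCF-7 nuclei imaged at 0.12 µm/px: the
    opening disc (2 px) detaches touching nuclei without eroding them away,
    and the area-closing threshold (64 px²) fills dark intra-nuclear spots
    well below the area of a nucleus (~10⁴ px²).
    """

    clahe_clip: float = 0.01  # normalized CLAHE clip limit
    clahe_tiles: int = 8  # CLAHE tile grid (tiles per image side)
    opening_radius: int = 2  # px, disc footprint
    area_closing_px: int = 64  # px², dark structures smaller than this are filled
    bilateral_sigma_spatial: float = 5.0  # px
    bilateral_sigma_range: float = 0.1  # fraction of the intensity range


def enhance_nuclei(
    nuclei: np.ndarray, params: EnhanceParams | None = None
) -> np.ndarray:
    """Enhance the nuclear channel for segmentation.

    Applies, in order: CLAHE (local contrast), morphological opening
    (separates touching nuclei), area closing (fills small dark holes inside
    nuclei) and a bilateral filter (edge-preserving denoising). Output is
    normalized to [0, 1]; an all-zero image is returned unchanged with a
    warning.
    """
    params = params or EnhanceParams()
    img = np.asarray(nuclei, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclei must be a 2-D grid")
    if not np.all(np.isfinite(img)):
        raise ValueError("nuclei contains non-finite pixels")
    if np.any(img < 0):
        raise ValueError("nuclei intensities must be non-negative")
    vmax = img.max()
    if vmax == 0:
        warnings.warn("all-zero nuclei image; returned unchanged", stacklevel=2)
        return img.copy()
    img = img / vmax

    kernel = tuple(max(8, s // params.clahe_tiles) for s in img.shape)
    img = exposure.equalize_adapthist(
        img, kernel_size=kernel, clip_limit=params.clahe_clip
    )
    img = morphology.opening(img, morphology.disk(params.opening_radius))
    img = morphology.area_closing(img, area_threshold=params.area_closing_px)
    img = restoration.denoise_bilateral(
        img,
        sigma_color=params.bilateral_sigma_range * (img.max() - img.min() or 1.0),
        sigma_spatial=params.bilateral_sigma_spatial,
    )
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    return img
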