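"""AFM height maps: container, leveling and noise estimation.

An AFM scan is a rectangular grid of surface heights. Before any particle
is measured, the raw map has to be *leveled*: a background plane (sample
tilt) and per-scan-row offsets (piezo drift between lines) are fitted on
background pixels only and subtracted, so that the bare substrate sits at
z = 0 and particle heights are read off a flat reference.

Conventions used throughout the package:

* heights are in nanometres, stored row-major with the origin at the
  top-left pixel;
* ``x = column * pixel_size_nm`` and ``y = row * pixel_size_nm``;
* leveled maps have background median ~ 0, so brush-spot tops sit at
  their physical 2-3 nm and particle apexes at their full height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HeightMap",
    "LevelReport",
    "plane_level",
    "line_level",
    "estimate_noise",
    "background_mask",
]

#: MAD -> Gaussian sigma conversion factor.
MAD_TO_SIGMA = 1.4826


@dataclass
class HeightMap:
    """A rectangular grid of surface heights in nm.

    Parameters
    ----------
    heights
        2-D float array, shape ``(rows, cols)``, heights in nm.
    pixel_size_nm
        Edge length of one (square) pixel in nm.
    metadata
        Free-form provenance (scan size, channel, source file, seed ...).
    """

    heights: np.ndarray
    pixel_size_nm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise ValueError("heights must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if not (self.pixel_size_nm > 0):
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def field_size_nm(self) -> tuple[float, float]:
        """(width, height) of the scanned field in nm."""
        r, c = self.heights.shape
        return c * self.pixel_size_nm, r * self.pixel_size_nm

    def copy_with(self, heights: np.ndarray) -> "HeightMap":
        return HeightMap(heights, self.pixel_size_nm, dict(self.metadata))


@dataclass
class LevelReport:
    """Background fit diagnostics from :func:`plane_level`.

    ``coefficients`` are the fitted polynomial coefficients in pixel
    coordinates (order 1: ``[c0, cx, cy]``; order 2 adds
    ``[cxx, cxy, cyy]``); ``sigma_nm`` is the robust residual roughness of
    the background after subtraction.
    """

    coefficients: np.ndarray
    sigma_nm: float

    def __post_init__(self) -> None:
        if self.sigma_nm < 0:
            raise ValueError("sigma_nm must be >= 0")


def _design_matrix(rows: np.ndarray, cols: np.ndarray, order: int) -> np.ndarray:
    terms = [np.ones_like(cols, dtype=float), cols.astype(float), rows.astype(float)]
    if order == 2:
        terms += [cols.astype(float) ** 2, (cols * rows).astype(float), rows.astype(float) ** 2]
    return np.stack(terms, axis=-1)


def _robust_sigma(values: np.ndarray) -> float:
    med = np.median(values)
    return MAD_TO_SIGMA * float(np.median(np.abs(values - med)))


def background_mask(heights: np.ndarray, n_pass: int = 2, clip: float = 3.0) -> np.ndarray:
    """Boolean mask of background (substrate) pixels.

    Iteratively excludes pixels more than ``clip`` robust sigmas *above*
    the current background median — particles and brush spots protrude
    upward, so only the upper tail is clipped.
    """
    mask = np.ones(heights.shape, dtype=bool)
    for _ in range(n_pass):
        vals = heights[mask]
        med = np.median(vals)
        sigma = _robust_sigma(vals)
        if sigma == 0:
            break
        mask = heights <= med + clip * sigma
        if not mask.any():
            mask = np.ones(heights.shape, dtype=bool)
            break
    return mask


def plane_level(hmap: HeightMap, order: int = 1) -> tuple[HeightMap, LevelReport]:
    """Fit and subtract a polynomial background surface.

    A least-squares polynomial of the given order (1 = plane, 2 =
    quadratic bow) is fitted to background pixels only; particles and
    brush spots are excluded by an iterative mask that drops pixels more
    than 3 robust sigmas above the current fit (two passes). The fitted
    surface is subtracted and the background re-centred so its median is
    zero.

    Returns the leveled map and a :class:`LevelReport`.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    h = hmap.heights
    if h.size < (order + 1) ** 2:
        raise ValueError("grid too small for requested order")

    rr, cc = np.mgrid[0 : h.shape[0], 0 : h.shape[1]]
    mask = np.ones(h.shape, dtype=bool)
    coef = np.zeros(3 if order == 1 else 6)
    for _ in range(3):  # initial fit + two masked refits
        if mask.sum() < 0.10 * h.size:
            warnings.warn(
                "background mask below 10% of pixels; fitting on all pixels",
                stacklevel=2,
            )
            mask = np.ones(h.shape, dtype=bool)
        a = _design_matrix(rr[mask], cc[mask], order)
        coef, *_ = np.linalg.lstsq(a, h[mask], rcond=None)
        fitted = (_design_matrix(rr.ravel(), cc.ravel(), order) @ coef).reshape(h.shape)
        resid = h - fitted
        sigma = _robust_sigma(resid[mask])
        if sigma == 0:
            break
        mask = resid <= np.median(resid[mask]) + 3.0 * sigma

    leveled = h - fitted
    leveled = leveled - np.median(leveled[mask])
    report = LevelReport(coefficients=np.asarray(coef), sigma_nm=_robust_sigma(leveled[mask]))
    return hmap.copy_with(leveled), report


def line_level(hmap: HeightMap) -> HeightMap:
    """Remove per-scan-row offsets.

    Subtracts from each row the median of its background pixels (mask as
    in :func:`plane_level`); rows fully covered by features are left
    unchanged. Operates on an already plane-leveled map.
    """
    h = hmap.heights
    mask = background_mask(h)
    out = h.copy()
    for i in range(h.shape[0]):
        row_bg = h[i, mask[i]]
        if row_bg.size:
            out[i] -= np.median(row_bg)
    return hmap.copy_with(out)


def estimate_noise(hmap: HeightMap) -> float:
    """Robust background height noise sigma (nm) of a leveled map.

    Uses median absolute deviation x 1.4826 over background pixels, so
    the estimate tolerates a substantial particle cover fraction.
    """
    h = hmap.heights
    mask = background_mask(h)
    vals = h[mask]
    return _robust_sigma(vals)
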