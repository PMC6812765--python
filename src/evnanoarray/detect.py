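"""Detection and morphometry of dome-like particles on leveled height maps.

The detection operator is built for nanopatterned substrates, where the
brush spots themselves protrude 2-3 nm and must not be confused with the
much narrower particle domes sitting on them:

1. the leveled map is lightly smoothed (Gaussian, 0.5 px);
2. a white top-hat with a flat disk (radius ``background_radius_nm``,
   chosen larger than any particle footprint radius but smaller than the
   brush-spot radius) removes the brush discs and any residual slowly
   varying background, leaving each dome measured from its local base;
3. seeds are the regional maxima of the top-hat image with prominence at
   least ``seed_threshold_nm`` (h-maxima transform);
4. each seed's footprint is the connected region above the fractional
   contour ``f * h_seed``; pixels contested between seeds go to the
   nearest seed.

Heights themselves are never read off the top-hat image: each particle's
apex height is the maximum of the (smoothed) leveled map inside its
footprint minus the median height on a 2-px annulus around it — on a
brush spot that annulus sits on the brush top, so by default the
reported ``h`` excludes the 2-3 nm brush (a membrane-only height, to
match the 7 nm acceptance floor derived from bilayer thickness). Set
``baseline="substrate"`` to reference the substrate plane instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .image import HeightMap, estimate_noise

__all__ = [
    "DetectionParams",
    "Region",
    "Particle",
    "detect_particles",
    "measure_particle",
    "measure_particles",
    "assign_to_spots",
    "particles_to_frame",
    "particles_from_frame",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the detection/measurement operator.

    ``seed_threshold_nm=None`` resolves at run time to
    ``max(1.0, 3 * noise sigma)`` of the map. ``footprint_fraction`` is
    the contour fraction f: the footprint is traced at ``f * h`` and the
    measured axes corrected by ``1/sqrt(1-f^2)`` (exact for the
    ellipsoidal dome). ``background_radius_nm`` is the top-hat disk
    radius; it must exceed the largest expected particle footprint
    radius and stay below the brush-spot radius.
    """

    seed_threshold_nm: float | None = None
    footprint_fraction: float = 0.1
    min_area_px: int = 4
    spot_margin_nm: float = 50.0
    background_radius_nm: float = 60.0
    smooth_sigma_px: float = 0.5
    baseline: str = "local_annulus"

    def __post_init__(self) -> None:
        if not (0 < self.footprint_fraction < 1):
            raise ValueError("footprint_fraction must be in (0, 1)")
        if self.seed_threshold_nm is not None and self.seed_threshold_nm < 0:
            raise ValueError("seed_threshold_nm must be >= 0")
        if self.min_area_px < 1 or self.spot_margin_nm < 0 or self.background_radius_nm <= 0:
            raise ValueError("invalid detection parameters")
        if self.baseline not in ("local_annulus", "substrate"):
            raise ValueError("baseline must be 'local_annulus' or 'substrate'")


@dataclass
class Region:
    """One candidate particle: footprint pixel coordinates plus its seed."""

    seed_rc: tuple[int, int]
    rows: np.ndarray
    cols: np.ndarray
    seed_height_nm: float  # top-hat prominence at the seed

    @property
    def area_px(self) -> int:
        return self.rows.size


@dataclass
class Particle:
    """Measured morphometry of one detected particle (lengths in nm)."""

    particle_id: int
    x_nm: float
    y_nm: float
    major_nm: float
    minor_nm: float
    d_nm: float
    h_nm: float
    ar: float
    D_nm: float
    klass: str = "unclassified"
    spot_id: int | None = None
    border: bool = False


def _smoothed(heights: np.ndarray, sigma_px: float) -> np.ndarray:
    if sigma_px <= 0:
        return heights
    return ndimage.gaussian_filter(heights, sigma_px, mode="nearest")


def _resolve_threshold(hmap: HeightMap, params: DetectionParams) -> float:
    if params.seed_threshold_nm is not None:
        return params.seed_threshold_nm
    return max(1.0, 3.0 * estimate_noise(hmap))


def detect_particles(hmap: HeightMap, params: DetectionParams = DetectionParams()) -> list[Region]:
    """Find candidate particle regions on a leveled map.

    Returns a list of :class:`Region`, sorted by decreasing seed
    prominence; an empty list (not an error) when nothing is found.
    """
    heights = hmap.heights
    px = hmap.pixel_size_nm
    if np.ptp(heights) > 0:
        n_top = int((heights == heights.max()).sum())
        if n_top > max(16, 0.001 * heights.size):
            warnings.warn("many pixels at the maximum height: possible saturation/clipping",
                          stacklevel=2)

    threshold = _resolve_threshold(hmap, params)
    sm = _smoothed(heights, params.smooth_sigma_px)
    r_px = max(int(np.ceil(params.background_radius_nm / px)), 2)
    disk = skmorph.disk(r_px)
    # Background = grey opening of a strongly smoothed copy: the opening
    # removes structures narrower than the disk (the particle domes) while
    # the strong pre-smoothing suppresses the opening's noise-minimum bias;
    # the final small dilation pushes the background's (blurred, slightly
    # eroded) brush-disc edges back out past the true rim so edge slivers
    # do not masquerade as particles.
    bg_sigma = max(4 * params.smooth_sigma_px, 2.0)
    bg_src = ndimage.gaussian_filter(heights, bg_sigma, mode="nearest")
    background = ndimage.grey_dilation(
        ndimage.grey_opening(bg_src, footprint=disk),
        footprint=skmorph.disk(int(np.ceil(2 * bg_sigma))),
    )
    tophat = np.clip(sm - background, 0.0, None)

    maxima = skmorph.h_maxima(tophat, threshold)
    labels, n_seeds = ndimage.label(maxima)
    if n_seeds == 0:
        return []
    # one seed per labeled maximum plateau: the top-hat argmax within it
    seeds: list[tuple[int, int]] = []
    for lab_id, idx in enumerate(ndimage.find_objects(labels), start=1):
        patch = np.where(labels[idx] == lab_id, tophat[idx], -np.inf)
        r, c = np.unravel_index(np.argmax(patch), patch.shape)
        seeds.append((r + idx[0].start, c + idx[1].start))
    seed_heights = np.array([tophat[rc] for rc in seeds])
    order = np.argsort(seed_heights)[::-1]

    win = max(16, int(np.ceil(1.5 * params.background_radius_nm / px)))
    owner = np.full(heights.shape, -1, dtype=np.int32)
    kept: list[tuple[int, tuple[int, int], float]] = []
    f = params.footprint_fraction
    for rank, si in enumerate(order):
        r0, c0 = seeds[si]
        h_seed = seed_heights[si]
        lo_r, hi_r = max(r0 - win, 0), min(r0 + win + 1, heights.shape[0])
        lo_c, hi_c = max(c0 - win, 0), min(c0 + win + 1, heights.shape[1])
        local = tophat[lo_r:hi_r, lo_c:hi_c] >= f * h_seed
        lab, _ = ndimage.label(local)
        comp = lab == lab[r0 - lo_r, c0 - lo_c]
        rr, cc = np.nonzero(comp)
        rr, cc = rr + lo_r, cc + lo_c
        prev = owner[rr, cc]
        fresh = prev == -1
        contested = ~fresh
        take = fresh.copy()
        if contested.any():
            # contested pixels go to the nearest seed
            d_new = (rr[contested] - r0) ** 2 + (cc[contested] - c0) ** 2
            d_old = np.empty(d_new.shape)
            for j in np.unique(prev[contested]):
                rj, cj = kept[j][1]
                sel = prev[contested] == j
                d_old[sel] = (rr[contested][sel] - rj) ** 2 + (cc[contested][sel] - cj) ** 2
            take[np.nonzero(contested)[0][d_new < d_old]] = True
        owner[rr[take], cc[take]] = rank
        kept.append((rank, (r0, c0), float(h_seed)))

    regions: list[Region] = []
    rows_all, cols_all = np.nonzero(owner >= 0)
    ids = owner[rows_all, cols_all]
    for rank, seed_rc, h_seed in kept:
        sel = ids == rank
        if sel.sum() < params.min_area_px:
            continue
        regions.append(Region(seed_rc, rows_all[sel], cols_all[sel], h_seed))
    return regions


_ANNULUS_SE = skmorph.disk(2)


def measure_particle(
    region: Region,
    hmap: HeightMap,
    params: DetectionParams = DetectionParams(),
    particle_id: int = 0,
) -> Particle:
    """Measure footprint axes, apex height, AR and suspension diameter D.

    The local baseline is the median height on a 2-px annulus around the
    footprint (or the substrate plane z = 0 when
    ``params.baseline == "substrate"``); ``h`` is the footprint's maximum
    height above that baseline; the equivalent-ellipse axis lengths come
    from the footprint mask's second central moments, corrected by
    ``1/sqrt(1-f^2)`` for the fractional contour; ``d`` is their mean,
    ``AR = h/d`` and ``D = (d^2 h)^(1/3)``. Regions whose annulus runs
    off the map edge are flagged ``border`` and should be excluded from
    population statistics.
    """
    if region.area_px == 0:
        raise ValueError("empty region")
    px = hmap.pixel_size_nm
    heights = hmap.heights
    margin = 4
    lo_r = max(region.rows.min() - margin, 0)
    hi_r = min(region.rows.max() + margin + 1, heights.shape[0])
    lo_c = max(region.cols.min() - margin, 0)
    hi_c = min(region.cols.max() + margin + 1, heights.shape[1])
    crop = _smoothed(heights[lo_r:hi_r, lo_c:hi_c], params.smooth_sigma_px)
    mask = np.zeros(crop.shape, dtype=bool)
    mask[region.rows - lo_r, region.cols - lo_c] = True

    dilated = ndimage.binary_dilation(mask, structure=_ANNULUS_SE)
    annulus = dilated & ~mask
    border = (
        region.rows.min() - 2 < 0
        or region.cols.min() - 2 < 0
        or region.rows.max() + 2 >= heights.shape[0]
        or region.cols.max() + 2 >= heights.shape[1]
    )
    if params.baseline == "substrate":
        baseline = 0.0
    elif annulus.any():
        baseline = float(np.median(crop[annulus]))
    else:
        baseline = 0.0
        border = True

    h = float(crop[mask].max() - baseline)

    # intensity-weighted centroid
    weights = np.clip(crop - baseline, 0.0, None) * mask
    rr, cc = np.nonzero(mask)
    wsum = weights[rr, cc].sum()
    if wsum > 0:
        r_cen = float((rr * weights[rr, cc]).sum() / wsum)
        c_cen = float((cc * weights[rr, cc]).sum() / wsum)
    else:
        r_cen, c_cen = float(rr.mean()), float(cc.mean())

    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    corr = 1.0 / np.sqrt(1.0 - params.footprint_fraction ** 2)
    major = float(props.axis_major_length) * px * corr
    minor = float(props.axis_minor_length) * px * corr
    d = (major + minor) / 2
    ar = h / d if d > 0 else np.nan
    D = (d ** 2 * h) ** (1 / 3) if d > 0 and h > 0 else np.nan
    return Particle(
        particle_id=particle_id,
        x_nm=(c_cen + lo_c) * px,
        y_nm=(r_cen + lo_r) * px,
        major_nm=major,
        minor_nm=minor,
        d_nm=d,
        h_nm=h,
        ar=float(ar),
        D_nm=float(D),
        border=bool(border),
    )


def measure_particles(
    regions: list[Region],
    hmap: HeightMap,
    params: DetectionParams = DetectionParams(),
) -> list[Particle]:
    """Measure every detected region; ids follow detection order."""
    return [measure_particle(reg, hmap, params, particle_id=i) for i, reg in enumerate(regions)]


def assign_to_spots(
    particles: list[Particle],
    layout,
    params: DetectionParams = DetectionParams(),
) -> tuple[list[Particle], pd.DataFrame]:
    """Assign particles to their nearest tethering spot and tabulate
    occupancy.

    A particle is assigned when its centroid lies within the spot radius
    plus ``spot_margin_nm`` of a spot center; a spot is occupied iff at
    least one EV-classified particle is assigned to it. Returns the
    particles (spot_id filled in place) and a per-spot occupancy table.
    """
    if len(layout) == 0:
        raise ValueError("layout has no spots")
    tree = cKDTree(np.column_stack([layout.x_nm, layout.y_nm]))
    occupied = np.zeros(len(layout), dtype=bool)
    for p in particles:
        dist, j = tree.query([p.x_nm, p.y_nm])
        if dist <= layout.diameter_nm[j] / 2 + params.spot_margin_nm:
            p.spot_id = int(layout.spot_id[j])
            if p.klass == "EV":
                occupied[j] = True
        else:
            p.spot_id = None
    occ = pd.DataFrame({"spot_id": layout.spot_id, "occupied": occupied})
    return particles, occ


def particles_to_frame(particles: list[Particle]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "particle_id": [p.particle_id for p in particles],
            "x_nm": [p.x_nm for p in particles],
            "y_nm": [p.y_nm for p in particles],
            "major_nm": [p.major_nm for p in particles],
            "minor_nm": [p.minor_nm for p in particles],
            "d_nm": [p.d_nm for p in particles],
            "h_nm": [p.h_nm for p in particles],
            "ar": [p.ar for p in particles],
            "D_nm": [p.D_nm for p in particles],
            "class": [p.klass for p in particles],
            "spot_id": [-1 if p.spot_id is None else p.spot_id for p in particles],
            "border_flag": [p.border for p in particles],
        }
    )


def particles_from_frame(frame: pd.DataFrame) -> list[Particle]:
    out = []
    for _, row in frame.iterrows():
        out.append(
            Particle(
                particle_id=int(row["particle_id"]),
                x_nm=float(row["x_nm"]),
                y_nm=float(row["y_nm"]),
                major_nm=float(row["major_nm"]),
                minor_nm=float(row["minor_nm"]),
                d_nm=float(row["d_nm"]),
                h_nm=float(row["h_nm"]),
                ar=float(row["ar"]),
                D_nm=float(row["D_nm"]),
                klass=str(row["class"]),
                spot_id=None if int(row["spot_id"]) < 0 else int(row["spot_id"]),
                border=bool(row["border_flag"]),
            )
        )
    return out
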