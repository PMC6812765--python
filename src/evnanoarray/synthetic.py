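"""Synthetic nanoarray AFM scenes with ground truth.

The study system is a silicon chip carrying a square lattice of ~200 nm
PEG-lipid brush spots (2-3 nm tall) on which individual extracellular
vesicles (EVs) are tethered. An adsorbed vesicle flattens into an oblate
dome; assuming its volume is conserved, a vesicle of suspension diameter
``D`` adsorbed with aspect ratio ``AR = h/d`` has footprint diameter

    d = D * AR**(-1/3)        and apex height        h = D * AR**(2/3),

so that ``D**3 = d**2 * h`` exactly. Small lipoprotein-like particles
(< 20 nm, AR 0.3-0.6) co-purify with EVs and appear at the periphery of
the spots.

This module renders such scenes as noisy AFM height maps — square spot
lattice, brush discs, ellipsoidal particle domes, plane tilt, per-row
scan offsets, Gaussian height noise and optional tip broadening — and
records the full ground truth, so every downstream stage (leveling,
detection, morphometry, population statistics) is testable without any
deposited raw data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import HeightMap

__all__ = [
    "DistSpec",
    "LayoutSpec",
    "NanospotLayout",
    "TrueParticle",
    "RenderConfig",
    "TruthTable",
    "make_layout",
    "sample_population",
    "render_scene",
    "simulate_scene",
    "CELL_LINES",
]


# ---------------------------------------------------------------------------
# Distributions

@dataclass(frozen=True)
class DistSpec:
    """A one-dimensional sampling distribution with optional truncation.

    ``kind`` is one of ``normal`` (params mean, sd), ``uniform``
    (low, high), ``lognormal`` (mean, sd of the underlying normal) or
    ``constant`` (value,). Samples outside ``(low, high]``-style bounds
    are rejected and redrawn; persistent rejection raises.
    """

    kind: str
    params: tuple
    low: float | None = None
    high: float | None = None

    _MAX_ROUNDS = 100

    def _draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "normal":
            return rng.normal(self.params[0], self.params[1], n)
        if self.kind == "uniform":
            return rng.uniform(self.params[0], self.params[1], n)
        if self.kind == "lognormal":
            return rng.lognormal(self.params[0], self.params[1], n)
        if self.kind == "constant":
            return np.full(n, float(self.params[0]))
        raise ValueError(f"unknown distribution kind '{self.kind}'")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` values honouring the truncation bounds."""
        out = np.empty(0)
        for _ in range(self._MAX_ROUNDS):
            draw = self._draw(rng, max(n - out.size, 1))
            if self.low is not None:
                draw = draw[draw > self.low]
            if self.high is not None:
                draw = draw[draw <= self.high]
            out = np.concatenate([out, draw])
            if out.size >= n:
                return out[:n]
        raise ValueError(
            f"distribution {self.kind}{self.params} cannot produce values in "
            f"({self.low}, {self.high}] after {self._MAX_ROUNDS} rounds"
        )


def normal(mean: float, sd: float, low: float | None = None, high: float | None = None) -> DistSpec:
    return DistSpec("normal", (mean, sd), low, high)


def uniform(low: float, high: float) -> DistSpec:
    return DistSpec("uniform", (low, high))


def constant(value: float) -> DistSpec:
    return DistSpec("constant", (value,))


#: Per-cell-line generator presets. Suspension diameters D follow the
#: population means/sds measured from the tethered vesicles; the AR
#: spread (sd 0.04, truncated to (0, 1]) is an assumption — only the
#: group means are reported for the real populations.
CELL_LINES: dict[str, dict[str, DistSpec]] = {
    "Sk-Br-3": {"D": normal(27.7, 4.7, low=0.0), "ar": normal(0.20, 0.04, low=0.0, high=1.0)},
    "HEK293": {"D": normal(25.0, 2.6, low=0.0), "ar": normal(0.18, 0.04, low=0.0, high=1.0)},
}


# ---------------------------------------------------------------------------
# Layout

@dataclass(frozen=True)
class LayoutSpec:
    """Square-lattice tethering-spot layout parameters (all lengths nm).

    The default pitch 1414.2 nm reproduces the chip's printed spot
    density of 5.0e5 spots/mm^2 (density = (1e6 / pitch)^2); the brush
    height of each spot is drawn uniformly from
    ``[brush_height_low_nm, brush_height_high_nm]``.
    """

    field_width_nm: float
    field_height_nm: float
    pitch_nm: float = 1414.2
    spot_diameter_nm: float = 200.0
    brush_height_low_nm: float = 2.0
    brush_height_high_nm: float = 3.0
    lattice: str = "square"

    def __post_init__(self) -> None:
        for name in ("field_width_nm", "field_height_nm", "pitch_nm", "spot_diameter_nm"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.pitch_nm < self.spot_diameter_nm:
            raise ValueError("pitch_nm must be >= spot_diameter_nm")
        if self.brush_height_low_nm > self.brush_height_high_nm:
            raise ValueError("brush height bounds out of order")
        if self.lattice != "square":
            raise ValueError("only square lattices are supported")

    @property
    def density_per_mm2(self) -> float:
        """Spot density implied by the pitch, in spots/mm^2."""
        return (1e6 / self.pitch_nm) ** 2


@dataclass
class NanospotLayout:
    """Realized tethering-spot lattice: one record per spot."""

    spot_id: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    diameter_nm: np.ndarray
    brush_height_nm: np.ndarray
    pitch_nm: float
    field_width_nm: float
    field_height_nm: float

    def __len__(self) -> int:
        return self.spot_id.size

    @property
    def density_per_mm2(self) -> float:
        return (1e6 / self.pitch_nm) ** 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": self.spot_id,
                "x_nm": self.x_nm,
                "y_nm": self.y_nm,
                "diameter_nm": self.diameter_nm,
                "brush_height_nm": self.brush_height_nm,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, pitch_nm: float | None = None,
                   field_width_nm: float | None = None,
                   field_height_nm: float | None = None) -> "NanospotLayout":
        x = frame["x_nm"].to_numpy(float)
        y = frame["y_nm"].to_numpy(float)
        if pitch_nm is None:
            ux = np.unique(np.round(np.diff(np.unique(x)), 6))
            pitch_nm = float(ux.min()) if ux.size else float(x.max() + 1)
        return cls(
            spot_id=frame["spot_id"].to_numpy(int),
            x_nm=x,
            y_nm=y,
            diameter_nm=frame["diameter_nm"].to_numpy(float),
            brush_height_nm=frame["brush_height_nm"].to_numpy(float),
            pitch_nm=pitch_nm,
            field_width_nm=field_width_nm or float(x.max() + pitch_nm / 2),
            field_height_nm=field_height_nm or float(y.max() + pitch_nm / 2),
        )


def make_layout(spec: LayoutSpec, seed: int | np.random.Generator = 0) -> NanospotLayout:
    """Build the square spot lattice covering the field.

    Spot centers sit at ``(i + 1/2) * pitch``; per-spot brush heights are
    drawn uniformly from the bounds in ``spec``. Deterministic given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nx = int(spec.field_width_nm // spec.pitch_nm)
    ny = int(spec.field_height_nm // spec.pitch_nm)
    if nx < 1 or ny < 1:
        raise ValueError(
            f"field {spec.field_width_nm} x {spec.field_height_nm} nm smaller "
            f"than one pitch ({spec.pitch_nm} nm): empty layout"
        )
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))
    x = (ix.ravel() + 0.5) * spec.pitch_nm
    y = (iy.ravel() + 0.5) * spec.pitch_nm
    n = x.size
    return NanospotLayout(
        spot_id=np.arange(n),
        x_nm=x,
        y_nm=y,
        diameter_nm=np.full(n, spec.spot_diameter_nm),
        brush_height_nm=rng.uniform(spec.brush_height_low_nm, spec.brush_height_high_nm, n),
        pitch_nm=spec.pitch_nm,
        field_width_nm=spec.field_width_nm,
        field_height_nm=spec.field_height_nm,
    )


# ---------------------------------------------------------------------------
# Particles

@dataclass
class TrueParticle:
    """Ground-truth particle: suspension diameter, adsorbed geometry, class."""

    center_x_nm: float
    center_y_nm: float
    D_true_nm: float
    ar_true: float
    d_true_nm: float
    h_true_nm: float
    klass: str = "EV"
    spot_id: int | None = None

    def __post_init__(self) -> None:
        if not (self.D_true_nm > 0):
            raise ValueError("D_true_nm must be > 0")
        if not (0 < self.ar_true <= 1):
            raise ValueError("ar_true must lie in (0, 1]")
        for val, ref in ((self.d_true_nm, self.D_true_nm * self.ar_true ** (-1 / 3)),
                         (self.h_true_nm, self.D_true_nm * self.ar_true ** (2 / 3))):
            if abs(val - ref) > 1e-9 * max(abs(ref), 1.0):
                raise ValueError("inconsistent (D, ar, d, h) geometry")

    @classmethod
    def from_suspension(cls, D_nm: float, ar: float, x_nm: float = 0.0, y_nm: float = 0.0,
                        klass: str = "EV", spot_id: int | None = None) -> "TrueParticle":
        """Volume-conserving adsorption of a sphere of diameter ``D_nm``."""
        return cls(x_nm, y_nm, D_nm, ar, D_nm * ar ** (-1 / 3), D_nm * ar ** (2 / 3),
                   klass, spot_id)

    @classmethod
    def from_footprint(cls, d_nm: float, ar: float, x_nm: float = 0.0, y_nm: float = 0.0,
                       klass: str = "EV", spot_id: int | None = None) -> "TrueParticle":
        """Construct from adsorbed geometry; D follows from D^3 = d^2 h."""
        h = ar * d_nm
        return cls(x_nm, y_nm, (d_nm ** 2 * h) ** (1 / 3), ar, d_nm, h, klass, spot_id)


def sample_population(
    n: int,
    D_dist: DistSpec,
    ar_dist: DistSpec,
    seed: int | np.random.Generator = 0,
    klass: str = "EV",
) -> list[TrueParticle]:
    """Draw ``n`` particles: D and AR sampled independently, adsorbed
    geometry set by volume conservation. Centers are left at the origin
    until the particles are placed on a layout."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D_dist = replace(D_dist, low=max(D_dist.low or 0.0, 0.0))
    ar_dist = replace(ar_dist, low=max(ar_dist.low or 0.0, 0.0),
                      high=min(ar_dist.high if ar_dist.high is not None else 1.0, 1.0))
    D = D_dist.sample(rng, n)
    ar = ar_dist.sample(rng, n)
    return [TrueParticle.from_suspension(Di, ai, klass=klass) for Di, ai in zip(D, ar)]


# ---------------------------------------------------------------------------
# Rendering

@dataclass(frozen=True)
class RenderConfig:
    """Scan-emulation parameters (all lengths nm).

    ``tilt_x``/``tilt_y`` are the background plane slope in nm per nm;
    ``line_offset_sd_nm`` draws one offset per scan row;
    ``tip_radius_nm > 0`` enables tip broadening (grayscale dilation by a
    spherical-cap structuring element, applied to the physical surface
    before tilt/offsets/noise).
    """

    pixel_size_nm: float = 5.0
    noise_sd_nm: float = 0.3
    tilt_x: float = 0.0
    tilt_y: float = 0.0
    line_offset_sd_nm: float = 0.0
    tip_radius_nm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pixel_size_nm > 0):
            raise ValueError("pixel_size_nm must be > 0")
        if min(self.noise_sd_nm, self.line_offset_sd_nm, self.tip_radius_nm) < 0:
            raise ValueError("sigmas and tip radius must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of one rendered scene: particles plus per-spot records."""

    particles: list[TrueParticle]
    spots: pd.DataFrame  # spot_id, brush_height_nm, occupied
    seed: int | None = None

    def particles_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "particle_id": np.arange(len(self.particles)),
                "x_nm": [p.center_x_nm for p in self.particles],
                "y_nm": [p.center_y_nm for p in self.particles],
                "D_true_nm": [p.D_true_nm for p in self.particles],
                "d_true_nm": [p.d_true_nm for p in self.particles],
                "h_true_nm": [p.h_true_nm for p in self.particles],
                "ar_true": [p.ar_true for p in self.particles],
                "class": [p.klass for p in self.particles],
                "spot_id": [p.spot_id if p.spot_id is not None else -1 for p in self.particles],
            }
        )

    def occupancy(self) -> float:
        if len(self.spots) == 0:
            raise ValueError("layout has no spots")
        return float(self.spots["occupied"].mean())

    def validate(self, layout: NanospotLayout) -> None:
        """Check that every occupied spot holds >= 1 EV within its radius."""
        evs = [p for p in self.particles if p.klass == "EV"]
        for _, row in self.spots[self.spots["occupied"]].iterrows():
            i = int(np.flatnonzero(layout.spot_id == row["spot_id"])[0])
            r = layout.diameter_nm[i] / 2
            ok = any(
                np.hypot(p.center_x_nm - layout.x_nm[i], p.center_y_nm - layout.y_nm[i]) <= r
                for p in evs
            )
            if not ok:
                raise ValueError(f"occupied spot {row['spot_id']} has no EV within radius")


def _paint_max(surface: np.ndarray, rows: slice, cols: slice, patch: np.ndarray) -> None:
    np.maximum(surface[rows, cols], patch, out=surface[rows, cols])


def _dome_patch(shape: tuple[int, int], px: float, cx: float, cy: float,
                d: float, h: float, base: float) -> tuple[slice, slice, np.ndarray] | None:
    """Window and height patch for one dome z(r) = h*sqrt(1-(2r/d)^2)."""
    r_px = d / 2 / px
    c0, r0 = cx / px, cy / px
    lo_r, hi_r = int(np.floor(r0 - r_px)) - 1, int(np.ceil(r0 + r_px)) + 2
    lo_c, hi_c = int(np.floor(c0 - r_px)) - 1, int(np.ceil(c0 + r_px)) + 2
    lo_r, hi_r = max(lo_r, 0), min(hi_r, shape[0])
    lo_c, hi_c = max(lo_c, 0), min(hi_c, shape[1])
    if lo_r >= hi_r or lo_c >= hi_c:
        return None
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    u2 = ((cc - c0) ** 2 + (rr - r0) ** 2) / r_px ** 2
    patch = np.where(u2 < 1.0, base + h * np.sqrt(np.clip(1.0 - u2, 0.0, 1.0)), -np.inf)
    return slice(lo_r, hi_r), slice(lo_c, hi_c), patch


def _tip_structure(radius_nm: float, px: float) -> tuple[np.ndarray, np.ndarray]:
    """Spherical-cap structuring element for tip dilation.

    Returns (footprint, structure): structure(u) = sqrt(R^2-|u|^2) - R,
    zero at the apex and negative outward, so dilation never lowers any
    height and leaves isolated apexes unchanged.
    """
    r_px = int(np.ceil(radius_nm / px))
    uu, vv = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1] * px
    rho2 = uu ** 2 + vv ** 2
    footprint = rho2 <= radius_nm ** 2
    structure = np.where(footprint, np.sqrt(np.clip(radius_nm ** 2 - rho2, 0.0, None)) - radius_nm, 0.0)
    return footprint, structure


def render_scene(
    layout: NanospotLayout,
    particles: list[TrueParticle],
    cfg: RenderConfig,
) -> tuple[HeightMap, TruthTable]:
    """Render a scene to a noisy height map plus its ground truth.

    The physical surface is the pointwise maximum of the flat substrate
    (z = 0), the brush discs, and each particle's ellipsoidal dome raised
    on the brush of the spot it sits on; tip broadening (if enabled)
    dilates that surface; plane tilt, per-row offsets and Gaussian pixel
    noise are added afterwards.
    """
    rng = np.random.default_rng(cfg.seed)
    px = cfg.pixel_size_nm
    nrow = int(round(layout.field_height_nm / px))
    ncol = int(round(layout.field_width_nm / px))
    if nrow < 1 or ncol < 1:
        raise ValueError("field smaller than one pixel")
    if particles:
        min_d = min(p.d_true_nm for p in particles)
        if px > min_d / 4:
            warnings.warn(
                f"pixel size {px} nm under-resolves the smallest footprint "
                f"({min_d:.1f} nm); expect biased morphometry",
                stacklevel=2,
            )
        for p in particles:
            if not (0 <= p.center_x_nm <= layout.field_width_nm
                    and 0 <= p.center_y_nm <= layout.field_height_nm):
                raise ValueError("particle center outside the field")

    surface = np.zeros((nrow, ncol))

    # brush discs
    for i in range(len(layout)):
        res = _dome_patch(surface.shape, px, layout.x_nm[i], layout.y_nm[i],
                          layout.diameter_nm[i], 0.0, layout.brush_height_nm[i])
        if res is not None:
            rows, cols, patch = res
            _paint_max(surface, rows, cols, np.where(np.isfinite(patch), patch, 0.0))

    # particle domes, raised on the brush of the spot they sit on
    spot_xy = np.column_stack([layout.x_nm, layout.y_nm]) if len(layout) else np.empty((0, 2))
    for p in particles:
        base = 0.0
        if len(layout):
            dist = np.hypot(spot_xy[:, 0] - p.center_x_nm, spot_xy[:, 1] - p.center_y_nm)
            j = int(np.argmin(dist))
            if dist[j] <= layout.diameter_nm[j] / 2:
                base = float(layout.brush_height_nm[j])
        res = _dome_patch(surface.shape, px, p.center_x_nm, p.center_y_nm,
                          p.d_true_nm, p.h_true_nm, base)
        if res is not None:
            rows, cols, patch = res
            _paint_max(surface, rows, cols, np.where(np.isfinite(patch), patch, 0.0))

    if cfg.tip_radius_nm > 0:
        footprint, structure = _tip_structure(cfg.tip_radius_nm, px)
        surface = ndimage.grey_dilation(surface, footprint=footprint, structure=structure)

    xx = np.arange(ncol) * px
    yy = np.arange(nrow) * px
    surface = surface + cfg.tilt_x * xx[None, :] + cfg.tilt_y * yy[:, None]
    if cfg.line_offset_sd_nm > 0:
        surface = surface + rng.normal(0.0, cfg.line_offset_sd_nm, nrow)[:, None]
    if cfg.noise_sd_nm > 0:
        surface = surface + rng.normal(0.0, cfg.noise_sd_nm, surface.shape)

    # per-spot occupancy from the particles actually rendered
    occupied = np.zeros(len(layout), dtype=bool)
    for p in particles:
        if p.klass != "EV" or not len(layout):
            continue
        dist = np.hypot(spot_xy[:, 0] - p.center_x_nm, spot_xy[:, 1] - p.center_y_nm)
        j = int(np.argmin(dist))
        if dist[j] <= layout.diameter_nm[j] / 2:
            occupied[j] = True
    spots = pd.DataFrame(
        {"spot_id": layout.spot_id, "brush_height_nm": layout.brush_height_nm,
         "occupied": occupied}
    )
    truth = TruthTable(particles=list(particles), spots=spots, seed=cfg.seed)
    hmap = HeightMap(
        surface,
        px,
        metadata={"seed": cfg.seed, "source": "evnanoarray.synthetic.render_scene"},
    )
    return hmap, truth


def simulate_scene(
    layout_spec: LayoutSpec,
    cfg: RenderConfig,
    occupancy: float = 0.20,
    D_dist: DistSpec | None = None,
    ar_dist: DistSpec | None = None,
    n_ldl: int = 0,
    ldl_d_dist: DistSpec | None = None,
    ldl_ar_dist: DistSpec | None = None,
    evs_per_spot: int = 1,
    seed: int | None = None,
) -> tuple[HeightMap, TruthTable, NanospotLayout]:
    """Full scene: layout, tethered EVs on a fraction of spots, optional
    lipoprotein-like particles on the spot peripheries, rendered map.

    By default one EV per occupied spot (the platform's premise of
    individual immobilization); ``evs_per_spot`` allows multi-occupancy
    for robustness experiments. Lipoprotein-like particles are placed
    uniformly on an annulus at spot radius +/- 20 nm.
    """
    if not (0 <= occupancy <= 1):
        raise ValueError("occupancy must be in [0, 1]")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    D_dist = D_dist or CELL_LINES["Sk-Br-3"]["D"]
    ar_dist = ar_dist or CELL_LINES["Sk-Br-3"]["ar"]
    ldl_d_dist = ldl_d_dist or uniform(10.0, 18.0)
    ldl_ar_dist = ldl_ar_dist or uniform(0.3, 0.6)

    layout = make_layout(layout_spec, rng)
    n_occ = int(round(occupancy * len(layout)))
    occ_idx = rng.choice(len(layout), size=n_occ, replace=False)

    particles: list[TrueParticle] = []
    evs = sample_population(n_occ * evs_per_spot, D_dist, ar_dist, rng)
    for k, p in enumerate(evs):
        i = occ_idx[k % n_occ]
        # jitter within the central third of the spot so the dome stays on it
        r_max = max(layout.diameter_nm[i] / 2 - p.d_true_nm / 2, 0.0) / 3
        theta = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, r_max)
        p.center_x_nm = float(layout.x_nm[i] + rad * np.cos(theta))
        p.center_y_nm = float(layout.y_nm[i] + rad * np.sin(theta))
        p.spot_id = int(layout.spot_id[i])
        particles.append(p)

    if n_ldl > 0:
        d_vals = ldl_d_dist.sample(rng, n_ldl)
        ar_vals = ldl_ar_dist.sample(rng, n_ldl)
        host = rng.integers(0, len(layout), n_ldl)
        for dv, av, i in zip(d_vals, ar_vals, host):
            r_spot = layout.diameter_nm[i] / 2
            rad = rng.uniform(max(r_spot - 20.0, 0.0), r_spot + 20.0)
            theta = rng.uniform(0, 2 * np.pi)
            x = float(np.clip(layout.x_nm[i] + rad * np.cos(theta), 0, layout_spec.field_width_nm))
            y = float(np.clip(layout.y_nm[i] + rad * np.sin(theta), 0, layout_spec.field_height_nm))
            particles.append(TrueParticle.from_footprint(dv, av, x, y, klass="LDL_like",
                                                         spot_id=int(layout.spot_id[i])))

    hmap, truth = render_scene(layout, particles, replace(cfg, seed=int(rng.integers(2 ** 31))))
    truth.seed = seed
    hmap.metadata["seed"] = seed
    return hmap, truth, layout
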