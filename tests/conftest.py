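"""Shared fixtures: small rendered scenes with known ground truth."""

import numpy as np
import pytest

import evnanoarray as ev


@pytest.fixture
def single_spot_layout():
    """One 200-nm spot (brush 2.5 nm) centred in a 1 x 1 um field."""
    spec = ev.LayoutSpec(1000, 1000, pitch_nm=1000, spot_diameter_nm=200,
                         brush_height_low_nm=2.5, brush_height_high_nm=2.5)
    return ev.make_layout(spec, seed=0)


@pytest.fixture
def bare_layout():
    """A layout whose single spot has zero brush height: flat substrate."""
    spec = ev.LayoutSpec(1000, 1000, pitch_nm=1000, spot_diameter_nm=200,
                         brush_height_low_nm=0.0, brush_height_high_nm=0.0)
    return ev.make_layout(spec, seed=0)


def render_single_dome(layout, d=60.0, ar=0.2, pixel=2.0, noise=0.0, tip=0.0,
                       center=(500.5, 500.5), seed=0, **cfg_kwargs):
    """One dome at the spot centre; returns (map, truth, particle)."""
    p = ev.TrueParticle.from_footprint(d, ar, center[0], center[1])
    cfg = ev.RenderConfig(pixel_size_nm=pixel, noise_sd_nm=noise,
                          tip_radius_nm=tip, seed=seed, **cfg_kwargs)
    hmap, truth = ev.render_scene(layout, [p], cfg)
    return hmap, truth, p


@pytest.fixture
def dome_scene(single_spot_layout):
    return render_single_dome(single_spot_layout)


def analytic_ellipsoid_map(a_nm=80.0, b_nm=40.0, h_nm=12.0, pixel=2.0, size_nm=400.0):
    """Hand-built map of one elliptical dome on a flat substrate."""
    n = int(size_nm / pixel)
    x = (np.arange(n) + 0.5) * pixel - size_nm / 2
    xx, yy = np.meshgrid(x, x)
    u2 = (2 * xx / a_nm) ** 2 + (2 * yy / b_nm) ** 2
    z = h_nm * np.sqrt(np.clip(1 - u2, 0, None))
    return ev.HeightMap(z, pixel)
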