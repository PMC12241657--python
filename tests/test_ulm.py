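"""SVD clutter filtering, Richardson-Lucy, and vascular mapping."""

import numpy as np
import pytest

from sonocell.scene import make_tissue_field, make_tumor_scene
from sonocell.ulm import (
    CasoratiStack,
    SVDFilterSpec,
    build_casorati,
    make_clutter_bubble_stack,
    rl_deconvolve,
    svd_filter,
    synthesize_flow_stack,
    vascular_map,
)


def overlap(out, comp):
    """Retained fraction of a known component in the filtered output."""
    return float(np.real(np.vdot(comp, out)) / np.real(np.vdot(comp, comp)))


def test_casorati_shape_and_roundtrip():
    stack = np.arange(12.0).reshape(3, 2, 2)
    cas = build_casorati(stack)
    assert cas.matrix.shape == (4, 3)
    assert np.array_equal(cas.to_frames(), stack)


def test_casorati_parseval():
    rng = np.random.default_rng(0)
    stack = rng.normal(size=(30, 16, 16))
    cas = build_casorati(stack)
    s = cas.singular_values
    fro2 = np.sum(cas.matrix**2)
    assert abs(np.sum(s**2) - fro2) / fro2 < 1e-9


def test_identical_frames_are_rank_one():
    frame = np.random.default_rng(1).normal(size=(8, 8))
    cas = build_casorati(np.stack([frame] * 12))
    s = cas.singular_values
    assert s[1] / s[0] < 1e-10


def test_static_stack_fully_removed_in_bubble_mode():
    frame = np.random.default_rng(2).normal(size=(16, 16))
    stack = np.stack([frame] * 20)
    out = svd_filter(build_casorati(stack), SVDFilterSpec())
    assert np.sum(np.abs(out) ** 2) / np.sum(stack**2) < 1e-12


def test_svd_filter_validates():
    with pytest.raises(ValueError):
        SVDFilterSpec(low_fraction=0.6, high_fraction=0.5)
    small = build_casorati(np.random.default_rng(0).normal(size=(5, 4, 4)))
    with pytest.raises(ValueError):
        svd_filter(small, SVDFilterSpec())


def test_two_component_stack_separation():
    """Clutter suppressed, moving bubble retained; tissue_only inverts."""
    stack, tissue, bubble = make_clutter_bubble_stack(
        frame_shape=(48, 48), n_frames=200, clutter_rank=20, n_bubble_pixels=66
    )
    cas = build_casorati(stack)
    out = svd_filter(cas, SVDFilterSpec())
    assert overlap(out, bubble) >= 0.9
    assert abs(overlap(out, tissue)) < 1e-2  # >= 40 dB suppression

    out_t = svd_filter(cas, SVDFilterSpec(mode="tissue_only"))
    assert overlap(out_t, tissue) > 0.99
    assert abs(overlap(out_t, bubble)) < 0.35


def test_monotone_clutter_suppression():
    """Raising low_fraction never increases retained static energy."""
    stack, tissue, _ = make_clutter_bubble_stack(
        frame_shape=(48, 48), n_frames=200, clutter_rank=20, n_bubble_pixels=66
    )
    cas = build_casorati(stack)
    kept = [
        abs(overlap(svd_filter(cas, SVDFilterSpec(low_fraction=lf)), tissue))
        for lf in (0.02, 0.05, 0.10, 0.20)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(kept, kept[1:]))


def test_rl_fixed_points():
    rng = np.random.default_rng(3)
    img = rng.random((32, 32))
    assert np.array_equal(rl_deconvolve(img, 0.0, 10), img)  # delta PSF
    flat = np.full((32, 32), 2.5)
    assert np.allclose(rl_deconvolve(flat, 2.0, 10), flat, rtol=1e-6)
    with pytest.raises(ValueError):
        rl_deconvolve(img - 1.0, 2.0, 10)


def test_rl_sharpens_blurred_point_and_conserves_flux():
    from scipy import ndimage

    img = np.zeros((64, 64))
    img[32, 32] = 1.0
    blurred = ndimage.gaussian_filter(img, 3.0)
    dec = rl_deconvolve(blurred, 3.0, 10)

    def fwhm(profile):
        p = profile / profile.max()
        above = np.flatnonzero(p >= 0.5)
        return above[-1] - above[0] + 1

    assert fwhm(dec[32]) <= 0.7 * fwhm(blurred[32])
    assert dec.sum() == pytest.approx(blurred.sum(), rel=1e-3)


def test_rl_matches_reference_implementation():
    """Agree with an explicit-kernel RL (scikit-image) on a compact blob.

    The reference runs on a reflect-padded image (matching the boundary
    handling) and both start from the flat initial estimate scikit-image
    uses.
    """
    from scipy import ndimage
    from skimage.restoration import richardson_lucy

    img = np.zeros((64, 64))
    img[30, 34] = 1.0
    img[36, 28] = 0.5
    blurred = ndimage.gaussian_filter(img, 2.0)

    # explicit normalized Gaussian kernel equivalent to the filter
    ax = np.arange(-8, 9)
    k1 = np.exp(-0.5 * (ax / 2.0) ** 2)
    kernel = np.outer(k1, k1)
    kernel /= kernel.sum()
    pad = 16
    padded = np.pad(blurred, pad, mode="reflect")
    ref = richardson_lucy(padded, kernel, num_iter=10, clip=False)[pad:-pad, pad:-pad]
    mine = rl_deconvolve(blurred, 2.0, 10, initial="flat")
    core = (slice(16, 48), slice(16, 48))
    assert np.allclose(mine[core], ref[core], rtol=1e-3, atol=1e-6)


def test_vascular_map_single_vessel_localizations():
    """Localizations from a single straight vessel fall on its centerline."""
    scene, lines = make_tumor_scene(
        n_vessels=1, vessel_tortuosity=0.0, periphery_bias=0.0, seed=3,
        bubbles_per_vessel=1, vessel_radius=100e-6, scatterers_per_resolution_cell=10.0,
    )
    stack = synthesize_flow_stack(scene, lines, n_frames=150, dt=0.01,
                                  transits_per_bubble=6, seed=3)
    _, locs = vascular_map(stack)
    assert len(locs) >= 5
    x0, x1 = scene.x_limits
    z0, z1 = scene.z_limits
    path = lines[0]
    pc = (path[:, 0] - x0) / (x1 - x0) * 127
    pr = (path[:, 1] - z0) / (z1 - z0) * 127
    d = np.min(np.hypot(locs[:, 0][:, None] - pr[None, :], locs[:, 1][:, None] - pc[None, :]), axis=1)
    radius_px = 100e-6 / (x1 - x0) * 127
    assert np.mean(d <= radius_px) >= 0.9


def test_vascular_map_resolves_parallel_vessels():
    """Two parallel vessels two system-FWHM apart appear as two ridges,
    and the recovered separation is within one pixel of truth."""
    ctx_scene = make_tissue_field
    from sonocell.acoustics import IMAGING_CONTEXT

    scene = make_tissue_field(IMAGING_CONTEXT, seed=5, x_limits=(-3e-3, 3e-3),
                              z_limits=(2e-3, 8e-3))
    # PSF sigma 2 px -> FWHM 4.71 px; separation 2 FWHM ~ 9.4 px -> in metres
    px = (scene.x_limits[1] - scene.x_limits[0]) / 127
    sep_px = 2 * 2.3548 * 2.0
    sep_m = sep_px * px
    z = np.linspace(3e-3, 7e-3, 200)
    line1 = np.column_stack([np.full_like(z, -sep_m / 2), z])
    line2 = np.column_stack([np.full_like(z, +sep_m / 2), z])
    scene.metadata.update(
        bubble_paths=[(0, 0.0), (1, 0.0)], flow_speed=10e-3, vessel_radius=50e-6
    )
    stack = synthesize_flow_stack(scene, [line1, line2], n_frames=150, dt=0.01,
                                  transits_per_bubble=6, seed=5)
    vmap, _ = vascular_map(stack)
    # collapse axially (rows) over the vessel span; find the two ridges
    profile = vmap[100:400, :].mean(axis=0)
    peaks = [
        i for i in range(1, profile.size - 1)
        if profile[i] >= profile[i - 1] and profile[i] >= profile[i + 1]
        and profile[i] > 0.5 * profile.max()
    ]
    assert len(peaks) >= 2
    found_sep = (max(peaks) - min(peaks)) / 2.0  # output grid is 2x upsampled
    assert found_sep == pytest.approx(sep_px, abs=1.0)


def test_tissue_only_stack_yields_no_localizations():
    """A stack without bubbles produces no localizations above threshold."""
    from sonocell.acoustics import IMAGING_CONTEXT

    scene = make_tissue_field(IMAGING_CONTEXT, seed=6)
    scene.metadata.update(bubble_paths=[], flow_speed=10e-3)
    stack = synthesize_flow_stack(scene, [], n_frames=150, dt=0.01, seed=6)
    vmap, locs = vascular_map(stack)
    # residual is noise: any local maxima are not organized into a vessel
    # and the map has no dominant structure
    assert vmap.max() < 10 * np.median(vmap)
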