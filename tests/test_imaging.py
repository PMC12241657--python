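"""Beamforming, AMPI combination, FWHM/CBR quantification, persistence."""

import numpy as np
import pytest

from sonocell.bubble_dynamics import DrivingPulse
from sonocell.imaging import (
    BeamformedImage,
    FrameStack,
    ampi_combine,
    channel_roi_mask,
    contrast_to_background_db,
    das_beamform,
    gel_background_mask,
    image_scene,
    measure_fwhm,
    signal_persistence,
)
from sonocell.rf_simulation import ArraySpec, RFFrameSet, bmode_event, simulate_rf
from sonocell.scene import KIND_BUBBLE, Channel, make_vessel_phantom

from conftest import point_scene

ARRAY = ArraySpec()


def synthetic_image(envelope: np.ndarray, pitch: float = 25e-6) -> BeamformedImage:
    nz, nx = envelope.shape
    return BeamformedImage(
        x=np.arange(nx) * pitch, z=5e-3 + np.arange(nz) * pitch,
        complex_data=envelope.astype(complex),
    )


def test_beamform_zero_rf_gives_zero_image(imaging_context):
    rf = RFFrameSet(
        data=np.zeros((1, 128, 800)),
        events=[bmode_event(1e5, imaging_context)],
        array=ARRAY,
        context=imaging_context,
    )
    img = das_beamform(rf, np.linspace(-1e-3, 1e-3, 32), np.linspace(4e-3, 6e-3, 32))
    assert np.all(img.envelope == 0.0)


def test_beamform_point_localization_and_determinism(imaging_context):
    scene = point_scene(position=(0.4e-3, 5.2e-3))
    img = image_scene(scene, "bmode", mi=0.14)
    iz, ix = np.unravel_index(np.argmax(img.envelope), img.envelope.shape)
    pitch = img.x[1] - img.x[0]
    assert abs(img.x[ix] - 0.4e-3) <= 1.001 * pitch
    assert abs(img.z[iz] - 5.2e-3) <= 1.001 * pitch
    img2 = image_scene(scene, "bmode", mi=0.14)
    assert np.array_equal(img.complex_data, img2.complex_data)


def test_two_point_resolution(imaging_context):
    """Two scatterers 3 lateral FWHM apart beamform to two distinct peaks."""
    single = image_scene(point_scene(position=(0.0, 5e-3)), "bmode", mi=0.14)
    fwhm_m = measure_fwhm(single, axis="lateral") * 1e-6
    sep = 3 * fwhm_m
    from sonocell.scene import Scene

    pair = Scene(
        positions=np.array([[-sep / 2, 5e-3], [sep / 2, 5e-3]]),
        reflectivity=np.ones(2),
        kind=np.zeros(2, dtype=np.int8),
        velocities=np.zeros((2, 2)),
        x_limits=(-1.5e-3, 1.5e-3),
        z_limits=(3.4e-3, 6.6e-3),
    )
    img = image_scene(pair, "bmode", mi=0.14)
    iz = np.argmin(np.abs(img.z - 5e-3))
    profile = img.envelope[iz]
    i1 = np.argmin(np.abs(img.x + sep / 2))
    i2 = np.argmin(np.abs(img.x - sep / 2))
    v1, v2 = profile[i1 - 1 : i1 + 2].max(), profile[i2 - 1 : i2 + 2].max()
    dip = profile[i1 + 2 : i2 - 1].min()
    assert v1 > 0.5 * profile.max() and v2 > 0.5 * profile.max()
    assert dip < 0.5 * min(v1, v2)


def test_ampi_combine_quadratic_scatterer_closed_form(imaging_context):
    """For a memoryless echo a*p + b*p^2, the three-pulse sum leaves
    exactly 1.5 b p^2 (the nonlinear parts that differ between half- and
    full-amplitude drive)."""
    t = np.arange(0, 2e-6, 1.0 / imaging_context.sampling_rate)
    pulse = DrivingPulse(frequency=15.625e6, pnp=1e5, n_cycles=2)
    p = pulse.waveform(t)
    a, b = 0.8, 3e-7

    def frameset(drive_wave):
        echo = a * drive_wave + b * drive_wave**2
        return RFFrameSet(
            data=np.broadcast_to(echo, (1, 128, t.size)).copy(),
            events=[bmode_event(1e5, imaging_context)],
            array=ARRAY,
            context=imaging_context,
        )

    residual = ampi_combine(frameset(-p), frameset(p / 2), frameset(p / 2))
    expected = 1.5 * b * p**2
    assert np.allclose(residual.data[0, 0], expected, rtol=1e-9, atol=1e-12)


def test_ampi_suppresses_tissue_but_keeps_bubble(imaging_context):
    """On a bubble + gel phantom the AMPI residual keeps the bubble and
    drops the gel by tens of dB relative to its B-Mode level."""
    scene = make_vessel_phantom(3.11e2, 1.0, imaging_context, seed=4, count_mode="exact")
    bmode = image_scene(scene, "bmode", mi=0.14, seed=4)
    ampi = image_scene(scene, "ampi", mi=0.14, seed=4)
    gel = gel_background_mask(bmode, scene.channel)
    tissue_suppression_db = 20 * np.log10(
        ampi.envelope[gel].mean() / bmode.envelope[gel].mean()
    )
    assert tissue_suppression_db < -40.0
    roi = channel_roi_mask(bmode, scene.channel)
    assert ampi.envelope[roi].max() > 100 * ampi.envelope[gel].mean()


def test_ampi_cbr_not_worse_than_bmode(imaging_context):
    scene = make_vessel_phantom(3.11e3, 1.0, imaging_context, seed=8, count_mode="exact")
    bmode = image_scene(scene, "bmode", mi=0.14, seed=8, noise_sigma=0.5)
    ampi = image_scene(scene, "ampi", mi=0.14, seed=8, noise_sigma=0.5)
    roi = channel_roi_mask(bmode, scene.channel)
    bg = gel_background_mask(bmode, scene.channel)
    assert contrast_to_background_db(ampi, roi, bg) >= contrast_to_background_db(bmode, roi, bg)


def test_fwhm_closed_forms():
    """Gaussian profile: 2.3548 sigma; triangle of base B: B/2."""
    pitch = 25e-6
    x = (np.arange(201) - 100) * pitch
    sigma = 130e-6
    gauss = np.exp(-0.5 * (x / sigma) ** 2)
    img = synthetic_image(np.tile(gauss, (11, 1)))
    assert measure_fwhm(img, axis="lateral") == pytest.approx(2.3548 * sigma * 1e6, rel=5e-3)

    base = 1.2e-3
    tri = np.clip(1 - np.abs(x) / (base / 2), 0, None)
    img = synthetic_image(np.tile(tri, (11, 1)))
    assert measure_fwhm(img, axis="lateral") == pytest.approx(base / 2 * 1e6, rel=5e-3)


def test_fwhm_requires_half_crossing():
    img = synthetic_image(np.ones((11, 51)))
    with pytest.raises(ValueError):
        measure_fwhm(img, axis="lateral")


def test_point_target_lateral_fwhm_within_system_bracket(imaging_context):
    """A point at 8 mm depth beamforms to a lateral FWHM between the
    diffraction limit (40.5 um) and the measured system value (123 um)."""
    scene = point_scene(position=(0.0, 7.9e-3), z_limits=(6.5e-3, 8.0e-3 - 1e-9))
    img = image_scene(scene, "bmode", mi=0.14)
    fwhm = measure_fwhm(img, axis="lateral")
    assert 40.5 <= fwhm <= 123.0


def test_cbr_trivial_values():
    rng = np.random.default_rng(0)
    env = rng.rayleigh(1.0, (40, 40))
    img = synthetic_image(env)
    roi = np.zeros_like(env, dtype=bool)
    bg = np.zeros_like(env, dtype=bool)
    roi[:10] = True
    bg[20:30] = True
    identical = contrast_to_background_db(
        synthetic_image(np.ones((40, 40))), roi, bg
    )
    assert identical == pytest.approx(0.0, abs=1e-12)
    ten_x = np.ones((40, 40))
    ten_x[:10] = 10.0
    assert contrast_to_background_db(synthetic_image(ten_x), roi, bg) == pytest.approx(20.0)
    with pytest.raises(ValueError):
        contrast_to_background_db(img, roi, roi)


def test_persistence_static_and_exponential_loss():
    """A static stack is flat; per-frame loss (1-q)^f reproduces the
    closed-form decline."""
    base = np.ones((20, 20))
    x = np.arange(20) * 25e-6
    z = 5e-3 + np.arange(20) * 25e-6

    def frame(scale):
        return BeamformedImage(x=x, z=z, complex_data=(scale * base).astype(complex))

    roi = np.ones_like(base, dtype=bool)
    n = 40
    static = FrameStack(frames=[frame(1.0)] * n, timestamps=np.arange(n, dtype=float))
    curve, decline = signal_persistence(static, roi)
    assert decline == pytest.approx(0.0, abs=1e-12)
    assert np.all(np.diff(curve) <= 1e-12)

    q = 0.002
    lossy = FrameStack(
        frames=[frame((1 - q) ** f) for f in range(n)], timestamps=np.arange(n, dtype=float)
    )
    _, decline = signal_persistence(lossy, roi)
    assert decline == pytest.approx(1 - (1 - q) ** (n - 1), rel=0.02)
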