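import dataclasses

import numpy as np
import pytest

from srqt2.acquisition import (AcquisitionProtocol, ResolutionError,
                               block_average, decay_image,
                               multi_orientation_protocols,
                               reference_protocols, relative_snr,
                               rician_noise, signal_model,
                               simulate_acquisition)
from srqt2.phantoms import GroundTruthPhantom, RoiInfo
from srqt2.volumes import GridSpec, ImageVolume


def _block_phantom(t2_field, m0_field, spacing):
    grid_spacing = (spacing,) * 3
    mk = lambda a: ImageVolume(np.asarray(a, float), grid_spacing)
    labels = (np.asarray(t2_field) > 0).astype(float)
    return GroundTruthPhantom(m0=mk(m0_field), t2=mk(t2_field), labels=mk(labels),
                              roi_table={1: RoiInfo("block", 100.0, 100.0)})


# ---------------------------------------------------------------- signal model

def test_signal_model_values():
    assert signal_model(1000.0, 112.0, 0.0) == pytest.approx(1000.0, abs=0)
    # independent high-precision evaluation of exp(-te/t2)
    assert signal_model(1000.0, 112.0, 122.8) == pytest.approx(
        1000.0 * np.exp(-122.8 / 112.0), rel=1e-12)
    assert signal_model(1000.0, 112.0, 122.8) == pytest.approx(334.1, abs=0.05)
    assert signal_model(1000.0, 112.0, 241.6) == pytest.approx(115.7, abs=0.05)


def test_signal_model_monotone_in_te():
    tes = np.linspace(0, 400, 50)
    s = signal_model(1000.0, 95.0, tes)
    assert np.all(np.diff(s) < 0)


def test_signal_model_rejects_nonpositive_t2():
    with pytest.raises(ValueError):
        signal_model(1000.0, 0.0, 100.0)
    with pytest.raises(ValueError):
        signal_model(1000.0, -5.0, 100.0)


# ---------------------------------------------------------------- Rician noise

def test_rician_zero_sigma_is_identity():
    x = np.random.default_rng(0).uniform(0, 50, (6, 6, 6))
    assert np.array_equal(rician_noise(x, 0.0, seed=1), x)


def test_rician_background_mean_matches_rayleigh():
    zeros = np.zeros((64, 64, 64))
    out = rician_noise(zeros, 10.0, seed=42)
    expect = 10.0 * np.sqrt(np.pi / 2.0)
    assert out.mean() == pytest.approx(expect, rel=0.01)


def test_rician_high_snr_sd_approaches_gaussian():
    x = np.full((50, 50, 50), 1000.0)
    out = rician_noise(x, 10.0, seed=3)
    assert out.std() == pytest.approx(10.0, rel=0.05)


def test_rician_deterministic_per_seed():
    x = np.full((16, 16, 16), 30.0)
    assert np.array_equal(rician_noise(x, 5.0, 9), rician_noise(x, 5.0, 9))
    assert not np.array_equal(rician_noise(x, 5.0, 9), rician_noise(x, 5.0, 10))


def test_rician_rejects_negative_sigma():
    with pytest.raises(ValueError):
        rician_noise(np.zeros((4, 4, 4)), -1.0, 0)


# ---------------------------------------------------------- forward simulation

def test_degenerate_simulation_equals_decay_image(brain_phantom):
    proto = AcquisitionProtocol(orientation="axial", te=122.8, tr=2000.0,
                                etl=20, inplane_spacing=1.5,
                                slice_thickness=1.5, noise_sigma=0.0)
    out = simulate_acquisition(brain_phantom, proto, seed=0)
    want = decay_image(brain_phantom, 122.8)
    assert np.array_equal(out.data, want.data)


def test_thick_slice_equals_brute_force_block_mean():
    rng = np.random.default_rng(5)
    t2 = rng.uniform(50, 200, (12, 12, 10))
    m0 = rng.uniform(500, 1500, (12, 12, 10))
    ph = _block_phantom(t2, m0, spacing=1.0)
    proto = AcquisitionProtocol(orientation="axial", te=100.0, tr=2000.0,
                                etl=20, inplane_spacing=1.0,
                                slice_thickness=5.0, noise_sigma=0.0)
    out = simulate_acquisition(ph, proto, seed=0)
    fine = decay_image(ph, 100.0).data
    brute = fine.reshape(12, 12, 2, 5).mean(axis=3)
    assert np.allclose(out.data, brute, rtol=1e-12)


def test_half_filled_slab_partial_volume():
    """Slab with signal in 2 of 5 fine voxels reads 2/5 of the plateau."""
    t2 = np.zeros((10, 10, 5))
    m0 = np.zeros((10, 10, 5))
    t2[:, :, :2] = 1e9   # negligible decay: plateau ~100
    m0[:, :, :2] = 100.0
    ph = _block_phantom(t2, m0, spacing=1.0)
    proto = AcquisitionProtocol(orientation="axial", te=1.0, tr=2000.0, etl=20,
                                inplane_spacing=1.0, slice_thickness=5.0)
    out = simulate_acquisition(ph, proto, seed=0)
    assert out.data.shape == (10, 10, 1)
    assert np.allclose(out.data, 40.0, rtol=1e-6)


def test_inplane_block_average_brute_force():
    rng = np.random.default_rng(6)
    t2 = rng.uniform(60, 150, (8, 8, 12))
    m0 = rng.uniform(800, 1200, (8, 8, 12))
    ph = _block_phantom(t2, m0, spacing=0.75)
    proto = AcquisitionProtocol(orientation="axial", te=120.0, tr=2000.0,
                                etl=20, inplane_spacing=1.5,
                                slice_thickness=4.5, noise_sigma=0.0)
    out = simulate_acquisition(ph, proto, seed=0)
    fine = decay_image(ph, 120.0).data
    brute = fine.reshape(4, 2, 4, 2, 2, 6).mean(axis=(1, 3, 5))
    assert np.allclose(out.data, brute, rtol=1e-12)


def test_noise_free_intensity_conserved():
    rng = np.random.default_rng(7)
    t2 = rng.uniform(60, 150, (12, 12, 10))
    m0 = rng.uniform(800, 1200, (12, 12, 10))
    ph = _block_phantom(t2, m0, spacing=1.0)
    vol = ImageVolume(decay_image(ph, 100.0).data, (1.0, 1.0, 1.0))
    coarse = block_average(vol, (2.0, 2.0, 5.0))
    ratio = (2.0 * 2.0 * 5.0) / 1.0
    assert coarse.data.sum() * ratio == pytest.approx(vol.data.sum(), rel=1e-3)


def test_noiseless_voxels_non_increasing_in_te(brain_phantom):
    base = dict(orientation="axial", tr=2000.0, etl=20, noise_sigma=0.0)
    imgs = [simulate_acquisition(
        brain_phantom, AcquisitionProtocol(te=te, **base), seed=0).data
        for te in (122.8, 182.4, 241.6)]
    assert np.all(imgs[1] <= imgs[0] + 1e-9)
    assert np.all(imgs[2] <= imgs[1] + 1e-9)


def test_same_seed_bit_identical(brain_phantom):
    proto = AcquisitionProtocol(orientation="axial", te=122.8, tr=2000.0,
                                etl=20, noise_sigma=25.0)
    a = simulate_acquisition(brain_phantom, proto, seed=11)
    b = simulate_acquisition(brain_phantom, proto, seed=11)
    assert np.array_equal(a.data, b.data)


def test_phantom_too_coarse_rejected():
    t2 = np.full((8, 8, 8), 100.0)
    ph = _block_phantom(t2, t2, spacing=2.0)
    proto = AcquisitionProtocol(orientation="axial", te=100.0, tr=2000.0,
                                etl=20, inplane_spacing=1.5,
                                slice_thickness=5.0)
    with pytest.raises(ResolutionError):
        simulate_acquisition(ph, proto, seed=0)


def test_protocol_validation():
    with pytest.raises(ValueError):
        AcquisitionProtocol(orientation="oblique", te=100, tr=2000, etl=20)
    with pytest.raises(ValueError):
        AcquisitionProtocol(orientation="axial", te=100, tr=90, etl=20)
    with pytest.raises(ValueError):
        AcquisitionProtocol(orientation="axial", te=100, tr=2000, etl=20,
                            noise_sigma=-1.0)
    assert AcquisitionProtocol(orientation="sagittal", te=100, tr=2000,
                               etl=20).slice_axis == 0
    assert AcquisitionProtocol(orientation="coronal", te=100, tr=2000,
                               etl=20).slice_axis == 1


# ----------------------------------------------------------------- SNR scaling

def test_relative_snr_identity():
    ref = reference_protocols()
    assert relative_snr(ref, ref) == pytest.approx(1.0, abs=0)


def test_relative_snr_anisotropic_vs_isotropic_protocols():
    """11.25 vs 3.375 mm^3 voxels and 817 vs 701 s of scanning: ~3.6x."""
    ref = reference_protocols()
    iso = [dataclasses.replace(p, inplane_spacing=1.5, slice_thickness=1.5)
           for p in multi_orientation_protocols()]
    got = relative_snr(ref, iso)
    want = (11.25 / 3.375) * np.sqrt(817.0 / 701.0)
    assert got == pytest.approx(want, rel=1e-9)
    assert got == pytest.approx(3.60, abs=0.005)


def test_relative_snr_square_root_time_law():
    a = [AcquisitionProtocol(orientation="axial", te=100, tr=2000, etl=20,
                             acq_time=400.0)]
    b = [AcquisitionProtocol(orientation="axial", te=100, tr=2000, etl=20,
                             acq_time=100.0)]
    assert relative_snr(a, b) == pytest.approx(2.0, rel=1e-12)


def test_relative_snr_validation():
    ok = reference_protocols()
    with pytest.raises(ValueError):
        relative_snr([], ok)
    bad = [dataclasses.replace(ok[0], acq_time=0.0)]
    with pytest.raises(ValueError):
        relative_snr(bad, ok)
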