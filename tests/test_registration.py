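import numpy as np
import pytest

from srqt2.acquisition import decay_image, rician_noise, simulate_acquisition
from srqt2.metrics import resample_labels
from srqt2.registration import (RegistrationError, build_sr_template,
                                register_rigid)
from srqt2.transforms import RigidTransform
from srqt2.volumes import GridSpec, ImageVolume, resample


def _center(vol):
    return tuple(vol.grid.center())


# ------------------------------------------------------------- register_rigid

def test_self_registration_is_identity(noiseless_acqs):
    _, acqs = noiseless_acqs
    t = register_rigid(acqs[0], acqs[0])
    assert np.all(np.abs(t.rotation) < 0.05)
    assert np.all(np.abs(t.translation) < 0.05)


def test_known_translation_recovered(noiseless_acqs, brain_phantom):
    _, acqs = noiseless_acqs
    iso, _ = resample(acqs[0], RigidTransform.identity(),
                      brain_phantom.grid)
    m = RigidTransform(translation=(3.0, -2.0, 1.0), center=_center(iso))
    moved, _ = resample(iso, m.inverse(), iso.grid)
    t = register_rigid(moved, iso)
    assert np.all(np.abs(np.subtract(t.translation, (3.0, -2.0, 1.0))) < 0.2)
    assert np.all(np.abs(t.rotation) < 0.2)


def test_known_rotation_recovered_under_noise(noiseless_acqs):
    """5 degrees about Z at roughly in-vivo SNR, recovered within 0.5.

    The two images share one echo time, so the correlation metric is the
    appropriate choice (mutual information is for cross-contrast pairs).
    """
    _, acqs = noiseless_acqs
    m = RigidTransform(rotation=(5.0, 0.0, 0.0), center=_center(acqs[0]))
    moved, _ = resample(acqs[0], m.inverse(), acqs[0].grid)
    moving = moved.copy_with(rician_noise(moved.data, 66.7, seed=3))
    fixed = acqs[0].copy_with(rician_noise(acqs[0].data, 66.7, seed=4))
    t = register_rigid(moving, fixed, metric="ncc")
    assert abs(t.rotation[0] - 5.0) < 0.5
    assert np.all(np.abs(t.rotation[1:]) < 0.5)
    assert np.all(np.abs(t.translation) < 0.5)


def test_no_overlap_raises_with_diagnostic():
    a = ImageVolume(np.ones((16, 16, 16)), (1.0, 1.0, 1.0), origin=(0, 0, 0))
    b = ImageVolume(np.ones((16, 16, 16)), (1.0, 1.0, 1.0),
                    origin=(500.0, 500.0, 500.0))
    with pytest.raises(RegistrationError, match="overlap"):
        register_rigid(a, b)


def test_unknown_metric_rejected(noiseless_acqs):
    _, acqs = noiseless_acqs
    with pytest.raises(ValueError, match="metric"):
        register_rigid(acqs[0], acqs[0], metric="mutual_information")


# ------------------------------------------------------------------ SR build

def test_identical_isotropic_inputs_average_to_themselves():
    rng = np.random.default_rng(1)
    grid = GridSpec((32, 32, 32), (1.5, 1.5, 1.5))
    xs, ys, zs = grid.world_coordinates()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    c = grid.center()
    blob = 1000.0 * np.exp(-((X - c[0]) ** 2 + (Y - c[1]) ** 2
                             + (Z - c[2]) ** 2) / 200.0)
    vol = ImageVolume(blob, grid.spacing)
    sr = build_sr_template([vol, ImageVolume(blob.copy(), grid.spacing),
                            ImageVolume(blob.copy(), grid.spacing)],
                           target_spacing=1.5, n_iterations=2)
    assert sr.template.data.shape == blob.shape
    assert np.allclose(sr.template.data, blob, atol=1e-6 * blob.max())


def test_template_beats_every_single_orientation(sr_single_te, brain_phantom):
    """SR of three orthogonal thick-slice views outresolves any one of them."""
    truth = decay_image(brain_phantom, 122.8)
    tr, _ = resample(truth, RigidTransform.identity(), sr_single_te.grid)
    fg = tr.data > 1.0

    def rmse(arr):
        return float(np.sqrt(np.mean((arr - tr.data)[fg] ** 2)))

    t_rmse = rmse(sr_single_te.template.data)
    for up in sr_single_te.aligned_inputs:
        assert t_rmse < rmse(up.data)


def test_template_within_range_of_aligned_inputs(sr_single_te):
    """Per-voxel mean property: template between min and max contribution."""
    stack = np.stack([a.data for a in sr_single_te.aligned_inputs])
    valid = np.all(np.stack(sr_single_te.validity_masks), axis=0)
    lo = stack.min(axis=0)[valid]
    hi = stack.max(axis=0)[valid]
    t = sr_single_te.template.data[valid]
    tol = 1e-6 * float(hi.max())
    assert np.all(t >= lo - tol) and np.all(t <= hi + tol)


def test_input_order_invariance(noiseless_single_te_acqs, sr_single_te):
    _, acqs = noiseless_single_te_acqs
    sr_b = build_sr_template([acqs[1], acqs[2], acqs[0]],
                             target_spacing=1.5, n_iterations=3)
    ref = sr_single_te.template.data
    scale = float(np.sqrt(np.mean(ref ** 2)))
    rms = float(np.sqrt(np.mean((sr_b.template.data - ref) ** 2)))
    assert rms / scale < 0.001


def test_template_error_non_increasing_over_iterations(
        noiseless_single_te_acqs, brain_phantom):
    _, acqs = noiseless_single_te_acqs
    truth = decay_image(brain_phantom, 122.8)

    def rmse(sr):
        tr, _ = resample(truth, RigidTransform.identity(), sr.grid)
        fg = tr.data > 1.0
        return float(np.sqrt(np.mean((sr.template.data - tr.data)[fg] ** 2)))

    r1 = rmse(build_sr_template(acqs, 1.5, n_iterations=1))
    r3 = rmse(build_sr_template(acqs, 1.5, n_iterations=3))
    assert r3 <= r1 * 1.02  # decreasing or flat within tolerance


def test_aligned_inputs_preserve_te_contrast(sr_multi_te, brain_phantom,
                                             noiseless_acqs):
    """ROI-mean ratios across aligned TE images follow the decay model.

    The 7 mm interior criterion leaves margin for sub-voxel alignment
    error on top of the 5 mm slab footprint.
    """
    protos, _ = noiseless_acqs
    tes = [p.te for p in protos]
    labels = resample_labels(brain_phantom, sr_multi_te.aligned_inputs[0],
                             footprint_mm=7.0)
    for code, roi in brain_phantom.target_rois().items():
        sel = labels == code
        base = sr_multi_te.aligned_inputs[0].data[sel].mean()
        for k in (1, 2):
            pred = np.exp(-(tes[k] - tes[0]) / roi.t2_ms)
            meas = sr_multi_te.aligned_inputs[k].data[sel].mean() / base
            assert abs(meas / pred - 1.0) < 0.03, (roi.name, k)


def test_forward_inverse_transforms_compose_to_identity(sr_multi_te):
    for pair in sr_multi_te.transforms:
        m = pair.to_template.compose(pair.from_template).as_matrix()
        assert np.allclose(m, np.eye(4), atol=1e-6)


def test_known_shift_recovered_and_template_quality_kept(
        brain_phantom, noiseless_acqs, sr_multi_te):
    """A 4 mm shifted input is recovered within 0.3 mm; template RMSE holds."""
    protos, acqs = noiseless_acqs
    m = RigidTransform(translation=(4.0, 0.0, 0.0),
                       center=tuple(brain_phantom.grid.center()))
    moved = simulate_acquisition(brain_phantom, protos[1], motion=m, seed=1)
    sr = build_sr_template([acqs[0], moved, acqs[2]], 1.5, n_iterations=3)
    got = sr.transforms[1].from_template.translation
    assert np.all(np.abs(np.subtract(got, (4.0, 0.0, 0.0))) < 0.3)

    truth = decay_image(brain_phantom, 122.8)

    def rmse(sr_res):
        tr, _ = resample(truth, RigidTransform.identity(), sr_res.grid)
        fg = tr.data > 1.0
        return float(np.sqrt(np.mean((sr_res.template.data - tr.data)[fg] ** 2)))

    # template intensity scale differs across TEs; compare to the multi-TE
    # motion-free build, which shares inputs 0 and 2 with this one
    assert rmse(sr) < 1.05 * rmse(sr_multi_te)


def test_too_few_inputs_rejected():
    vol = ImageVolume(np.ones((16, 16, 16)), (1.5, 1.5, 1.5))
    with pytest.raises(ValueError, match="2 inputs"):
        build_sr_template([vol], target_spacing=1.5)


def test_target_spacing_coarser_than_inputs_rejected(noiseless_acqs):
    _, acqs = noiseless_acqs
    with pytest.raises(ValueError, match="spacing"):
        build_sr_template(acqs, target_spacing=2.0)
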