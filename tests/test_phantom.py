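"""Forward model: painting, smoothing, the 17-template bank, model fitting
and scan synthesis."""

import numpy as np
import pytest
from scipy import signal

from centamine.atlas import Volume
from centamine.phantom import (
    DEFAULT_HC_VALUES,
    FWHM_TO_SIGMA,
    TemplateSpec,
    apply_deficit,
    fit_template_model,
    gaussian_smooth,
    paint_template,
    synthesize_scan,
    values_by_code,
)
from centamine.transform import AffineTransform


def test_painting_is_exact(atlas_small):
    values = {name: 1.0 for name in DEFAULT_HC_VALUES}
    values["pre_caudate"] = 2.0
    values["post_caudate"] = 2.0
    painted = paint_template(atlas_small, values)
    caud = atlas_small.mask("caudate")
    assert painted.data[caud].mean() == 2.0
    assert painted.data[atlas_small.mask("putamen")].mean() == 1.0
    assert painted.data[~atlas_small.head_mask()].max() == 0.0


def test_painting_missing_value_raises(atlas_small):
    values = dict(DEFAULT_HC_VALUES)
    del values["accumbens"]
    with pytest.raises(ValueError, match="missing"):
        paint_template(atlas_small, values)


def test_fwhm_sigma_conversion():
    # sigma = FWHM / (2 sqrt(2 ln 2)) = FWHM / 2.35482
    assert np.isclose(12.0 * FWHM_TO_SIGMA, 12.0 / 2.35482, atol=1e-5)
    assert np.isclose(12.0 * FWHM_TO_SIGMA / 2.0, 2.548, atol=1e-3)  # voxels at 2 mm


def test_smoothing_conserves_mass(atlas_small):
    painted = paint_template(atlas_small, DEFAULT_HC_VALUES)
    for fwhm in (4.0, 12.0, 20.0):
        sm = gaussian_smooth(painted, fwhm)
        assert abs(sm.sum() - painted.sum()) / painted.sum() < 1e-6


def test_smoothing_small_fwhm_approaches_identity(atlas_small):
    painted = paint_template(atlas_small, DEFAULT_HC_VALUES)
    sm = gaussian_smooth(painted, 0.5)  # sigma << voxel
    assert np.allclose(sm.data, painted.data, atol=1e-6)
    with pytest.raises(ValueError):
        gaussian_smooth(painted, 0.0)


def test_smoothing_matches_dense_convolution_oracle(atlas_small):
    """Separable filtering equals explicit FFT convolution with the same
    truncated, normalized Gaussian kernel."""
    painted = paint_template(atlas_small, DEFAULT_HC_VALUES)
    fwhm = 12.0
    sm = gaussian_smooth(painted, fwhm)
    kern1d = []
    for vs in painted.grid.voxel_size_mm:
        sigma = fwhm * FWHM_TO_SIGMA / vs
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        kern1d.append(k / k.sum())
    kernel = (
        kern1d[0][:, None, None] * kern1d[1][None, :, None] * kern1d[2][None, None, :]
    )
    oracle = signal.fftconvolve(painted.data, kernel, mode="same")
    interior = atlas_small.head_mask()  # zero-pad vs wrap differs only at edges
    assert np.allclose(sm.data[interior], oracle[interior], atol=1e-9)


def test_template_spec_validation():
    rows = list(TemplateSpec().rows)
    rows[0] = (0.9, 1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        TemplateSpec(rows=tuple(rows))
    with pytest.raises(ValueError):
        TemplateSpec(rows=TemplateSpec().rows[:16])
    with pytest.raises(ValueError):
        TemplateSpec(fwhm_mm=-1.0)


@pytest.mark.parametrize(
    "index, putamen_l, putamen_r, caudate_l, caudate_r",
    [(0, 1.0, 1.0, 1.0, 1.0), (3, 0.25, 1.0, 1.0, 1.0), (16, 0.0, 0.0, 0.25, 0.25)],
)
def test_template_bank_scaling(bank_small, atlas_small,
                               index, putamen_l, putamen_r, caudate_l, caudate_r):
    """Stage templates equal the forward model with per-row scaled values."""
    hc = values_by_code(atlas_small, DEFAULT_HC_VALUES)
    values = dict(hc)
    for name, side, frac in (
        ("putamen", "left", putamen_l),
        ("putamen", "right", putamen_r),
        ("caudate", "left", caudate_l),
        ("caudate", "right", caudate_r),
    ):
        for code in atlas_small.codes_for(name, side):
            values[code] = hc[code] * frac
    expected = gaussian_smooth(paint_template(atlas_small, values), 12.0)
    assert np.array_equal(bank_small.volumes[index].data, expected.data)


def test_template_one_is_healthy_template(bank_small, atlas_small):
    hc = gaussian_smooth(paint_template(atlas_small, DEFAULT_HC_VALUES), 12.0)
    assert np.array_equal(bank_small.volumes[0].data, hc.data)


def test_forward_model_linearity(atlas_small):
    v1, _ = synthesize_scan(atlas_small, DEFAULT_HC_VALUES)
    alpha = 3.7
    scaled = {k: alpha * v for k, v in DEFAULT_HC_VALUES.items()}
    v2, _ = synthesize_scan(atlas_small, scaled)
    assert np.allclose(v2.data, alpha * v1.data, rtol=1e-12)


def test_fit_recovers_forward_model_parameters(atlas_small):
    """Self-consistency: fitting a noise-free forward-model image returns the
    generating regional values (within 1% relative) and FWHM (within 0.2 mm)."""
    rng = np.random.default_rng(11)
    truth = {
        code: DEFAULT_HC_VALUES[info.name] * rng.uniform(0.8, 1.2)
        for code, info in atlas_small.region_table.items()
    }
    target = gaussian_smooth(paint_template(atlas_small, truth), 12.0)
    fit = fit_template_model(target, atlas_small)
    assert abs(fit.fwhm_mm - 12.0) < 0.2
    for code, val in truth.items():
        assert abs(fit.values[code] - val) / val < 0.01


def test_fit_flat_zero_target(atlas_small):
    fit = fit_template_model(Volume(np.zeros(atlas_small.grid.shape), atlas_small.grid),
                             atlas_small)
    assert all(v == 0.0 for v in fit.values.values())
    assert not fit.converged  # fwhm unidentifiable, flagged


def test_fit_residual_matches_noise_floor(atlas_small):
    rng = np.random.default_rng(5)
    target = gaussian_smooth(paint_template(atlas_small, DEFAULT_HC_VALUES), 12.0)
    sigma = 0.01 * target.data.max()
    noisy = Volume(target.data + rng.normal(0, sigma, target.data.shape),
                   target.grid)
    fit = fit_template_model(noisy, atlas_small)
    n = target.data.size
    # residual norm ~ sigma * sqrt(n)
    assert 0.8 < fit.residual / (sigma * np.sqrt(n)) < 1.2


def test_synthesize_deterministic_under_seed(atlas_small):
    kwargs = dict(noise_sigma=0.05, seed=123,
                  affine=AffineTransform(translation=(3.0, -2.0, 1.0)))
    v1, _ = synthesize_scan(atlas_small, DEFAULT_HC_VALUES, **kwargs)
    v2, _ = synthesize_scan(atlas_small, DEFAULT_HC_VALUES, **kwargs)
    assert np.array_equal(v1.data, v2.data)


def test_synthesize_identity_noise_free_equals_template(atlas_small, bank_small):
    v, truth = synthesize_scan(atlas_small, DEFAULT_HC_VALUES, global_scale=2.5)
    assert np.allclose(v.data, 2.5 * bank_small.volumes[0].data, rtol=1e-12)
    assert truth.global_scale == 2.5


def test_deficit_scan_regional_mean_vs_convolution_oracle(atlas_small):
    """A 25% putamen phantom's putamen mean equals the dense-convolution
    prediction (painted deficit + smoothing spill-in)."""
    vals = apply_deficit(atlas_small, DEFAULT_HC_VALUES,
                         {("putamen", "left"): 0.25, ("putamen", "right"): 0.25})
    scan, _ = synthesize_scan(atlas_small, vals)
    painted = paint_template(atlas_small, vals)
    kern1d = []
    for vs in painted.grid.voxel_size_mm:
        sigma = 12.0 * FWHM_TO_SIGMA / vs
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        kern1d.append(k / k.sum())
    kernel = (
        kern1d[0][:, None, None] * kern1d[1][None, :, None] * kern1d[2][None, None, :]
    )
    oracle = signal.fftconvolve(painted.data, kernel, mode="same")
    pmask = atlas_small.mask("putamen")
    assert np.isclose(scan.data[pmask].mean(), oracle[pmask].mean(), rtol=1e-9)


def test_apply_deficit_rejects_bad_fraction(atlas_small):
    with pytest.raises(ValueError):
        apply_deficit(atlas_small, DEFAULT_HC_VALUES, {"putamen": 1.5})


def test_synthesize_rejects_singular_affine(atlas_small):
    bad = AffineTransform(scale=(0.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        synthesize_scan(atlas_small, DEFAULT_HC_VALUES, affine=bad)
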