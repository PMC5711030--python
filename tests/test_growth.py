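import numpy as np
import pytest

from gliofront import growth
from gliofront.growth import (ConfluencySeries, ImageStack, allee_fit,
                              confluency_series, local_std, rate_curve,
                              segment, window_rates)
from gliofront.synthetic import (CultureSimSpec, default_allee_rate,
                                 synth_confluency, synth_images)


def _textured_frames(coverages, seed=3, shape=(512, 512), radius=20):
    series = ConfluencySeries("f0", np.arange(len(coverages), dtype=float),
                              np.asarray(coverages, dtype=float))
    return synth_images(series, cell_radius_px=radius, shape=shape,
                        seed=seed)


def test_local_std_window_validation():
    with pytest.raises(ValueError):
        local_std(np.zeros((8, 8)), window_px=4)
    with pytest.raises(ValueError):
        local_std(np.zeros((8, 8)), window_px=1)


def test_segment_shift_invariance():
    stack, masks = _textured_frames([0.10])
    m1 = segment(stack.frames[0], window_px=3)
    m2 = segment(stack.frames[0] + 0.7, window_px=3)
    assert np.array_equal(m1, m2)


def test_segment_constant_frame_warns_empty():
    with pytest.warns(UserWarning):
        m = segment(np.full((64, 64), 0.5), window_px=3)
    assert not m.any()


def test_segment_recovers_mask_coverage():
    stack, masks = _textured_frames([0.05, 0.15])
    for frame, mask in zip(stack.frames, masks):
        est = segment(frame, window_px=3).mean()
        assert est == pytest.approx(mask.mean(), abs=0.01)


def test_confluency_series_monotone_with_coverage():
    stack, _ = _textured_frames([0.02, 0.08, 0.20])
    series = confluency_series(stack, window_px=3)
    assert np.all(np.diff(series.A) > 0)


def test_window_rates_exact_on_linear_series():
    t = np.arange(0.0, 96.0, 0.5)
    A = 0.05 + 0.001 * t
    s = ConfluencySeries("lin", t, A)
    rates = window_rates(s, DT=30.0)
    assert len(rates) > 0
    for wr in rates:
        assert wr.b == pytest.approx(0.001, rel=1e-9)
        assert wr.r2 == pytest.approx(1.0, abs=1e-12)
        assert wr.A_at_T == pytest.approx(0.05 + 0.001 * wr.T, rel=1e-12)


def test_window_rates_exponential_secant():
    """For A = A0 e^{g t}, the window slope divided by A(T) equals the
    secant rate (e^{g DT} - 1)/DT ... up to the linear-fit average, which
    for g*DT << 1 is g to first order."""
    g, DT = 0.01, 30.0
    t = np.arange(0.0, 96.0, 1.0 / 6.0)
    s = ConfluencySeries("exp", t, 0.01 * np.exp(g * t))
    rates = window_rates(s, DT=DT)
    r = np.array([wr.b / wr.A_at_T for wr in rates])
    # all windows see the same relative slope; it overestimates g by
    # about g*DT/2 (convexity), here ~15%
    assert np.ptp(r) / r.mean() < 1e-6
    assert r.mean() == pytest.approx(g * (1 + g * DT / 2), rel=0.02)


def test_window_rates_needs_enough_samples():
    s = ConfluencySeries("sparse", np.array([0.0, 20.0, 40.0]),
                         np.array([0.1, 0.12, 0.15]))
    with pytest.warns(UserWarning):
        assert window_rates(s, DT=30.0) == []


def test_rate_curve_bins_and_neff():
    spec = CultureSimSpec(seed=5)
    series, _ = synth_confluency(spec)
    rates = [w for s in series for w in window_rates(s, DT=30.0)]
    curve = rate_curve(rates)
    assert len(curve.A_bins) >= 4
    assert np.all(curve.n_eff <= curve.n)
    assert np.all(curve.n >= 1)
    assert curve.DT == pytest.approx(30.0)


def test_flat_rate_curve_prefers_logistic():
    """Noise-free logistic cultures: the nested logistic law wins the AIC
    comparison and the quadratic fit is not preferred."""
    def r_log(A):
        return 0.02 * (1.0 - np.asarray(A) / 0.9)

    r_log.params = {"rho": 0.02, "K": 0.9, "beta": None}
    spec = CultureSimSpec(r_curve=r_log, noise_sd=0.0, duration_h=240.0)
    series, _ = synth_confluency(spec, n_series=12)
    rates = [w for s in series for w in window_rates(s, DT=30.0)]
    fit = allee_fit(rate_curve(rates))
    assert fit.logistic_preferred


def test_zero_noise_parameter_recovery():
    spec = CultureSimSpec(noise_sd=0.0, duration_h=240.0)
    series, truth = synth_confluency(spec, n_series=12)
    rates = [w for s in series for w in window_rates(s, DT=30.0)]
    fit = allee_fit(rate_curve(rates))
    assert fit.converged and not fit.logistic_preferred
    # beta carries a small bin-centre discretisation bias (rates are
    # labelled at bin centres, contributions fill bins asymmetrically)
    assert fit.beta == pytest.approx(0.05, abs=0.02)
    assert fit.K == pytest.approx(0.9, rel=0.05)
    assert fit.rho == pytest.approx(0.02, rel=0.05)
    # the fitted curve's interior maximum sits at K(1-beta)/2
    A = np.linspace(0.05, 0.6, 2001)
    A_star = A[np.argmax(fit.predict(A))]
    assert A_star == pytest.approx(0.9 * 0.95 / 2, abs=0.02)


def test_allee_fit_requires_bins():
    curve = rate_curve([growth.WindowRate("s", 0.0, 30.0, 1e-3, 0.1, 1.0)])
    with pytest.raises(ValueError):
        allee_fit(curve)


def test_confluency_tsv_round_trip(tmp_path):
    spec = CultureSimSpec(seed=11, duration_h=24.0)
    series, _ = synth_confluency(spec, n_series=3)
    path = tmp_path / "conf.tsv"
    growth.write_confluency_tsv(series, path)
    back = growth.read_confluency_tsv(path)
    assert len(back) == 3
    for a, b in zip(series, back):
        assert a.series_id == b.series_id
        np.testing.assert_allclose(a.times, b.times)
        np.testing.assert_allclose(a.A, b.A)


def test_image_stack_validation():
    with pytest.raises(ValueError):
        ImageStack(np.zeros((2, 8, 8)), np.array([1.0, 0.5]), "x")
    with pytest.raises(ValueError):
        ConfluencySeries("x", np.array([0.0, 1.0]), np.array([0.5, 1.5]))
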