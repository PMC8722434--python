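import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegfp
from eegfp.connectivity import (
    GCMatrixError,
    SingularFitError,
    connectivity_dataset,
    features_to_matrix,
    fit_bvar,
    fit_univariate_ar,
    gc_matrix,
    granger_causality,
    load_features_tsv,
    mi_vector,
    mutual_information,
    save_features_tsv,
)
from eegfp.preprocess import Epoch


def _epoch(data, fs=250.0, subject="S01", session="A", index=0):
    return Epoch(np.asarray(data, float), fs, subject, session, index)


# ---------------------------------------------------------------------------
# BVAR / AR fits


def test_bvar_white_noise_cross_coefficients_vanish():
    rng = np.random.default_rng(0)
    x, y = rng.standard_normal((2, 20_000))
    fit = fit_bvar(x, y, 15)
    assert np.max(np.abs(fit.a_xy)) < 0.05
    assert np.max(np.abs(fit.a_yx)) < 0.05
    assert fit.resid_var_x_full == pytest.approx(1.0, abs=0.05)
    assert fit.resid_var_y_full == pytest.approx(1.0, abs=0.05)


def test_bvar_recovers_planted_lag1_coefficient():
    rng = np.random.default_rng(1)
    n = 20_000
    y = rng.standard_normal(n + 1)
    x = 0.5 * y[:-1] + rng.standard_normal(n)
    fit = fit_bvar(x, y[1:], 15)
    assert fit.a_xy[0] == pytest.approx(0.5, abs=0.03)
    assert np.max(np.abs(fit.a_xy[1:])) < 0.05


def test_univariate_ar_recovers_ar1():
    rng = np.random.default_rng(2)
    n = 20_000
    x = np.empty(n)
    x[0] = 0.0
    e = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = 0.9 * x[t - 1] + e[t]
    fit = fit_univariate_ar(x, 15)
    assert fit.coefficients[0] == pytest.approx(0.9, abs=0.03)
    assert fit.resid_var == pytest.approx(1.0, abs=0.05)


def test_white_noise_restricted_variance():
    rng = np.random.default_rng(3)
    fit = fit_univariate_ar(rng.standard_normal(20_000), 15)
    assert fit.resid_var == pytest.approx(1.0, abs=0.05)


def test_degenerate_inputs_raise_singular_fit():
    rng = np.random.default_rng(4)
    y = rng.standard_normal(1000)
    with pytest.raises(SingularFitError):
        fit_bvar(np.ones(1000), y, 5)
    with pytest.raises(SingularFitError):
        fit_univariate_ar(np.zeros(1000), 5)
    with pytest.raises(SingularFitError):
        granger_causality(y, y.copy(), 5)  # identical series: collinear design


def test_length_guards():
    rng = np.random.default_rng(5)
    with pytest.raises(ValueError):
        fit_univariate_ar(rng.standard_normal(40), 15)  # < 3p
    with pytest.raises(ValueError):
        fit_bvar(rng.standard_normal(60), rng.standard_normal(60), 15)  # < 5p


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(10, 50),
    coupling=st.floats(-0.4, 0.4),
)
def test_ols_matches_bruteforce_normal_equations(seed, n, coupling):
    """p=1 fits agree with a hand-rolled normal-equations solver to 1e-10."""
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n)
    x = coupling * np.concatenate([[0.0], y[:-1]]) + rng.standard_normal(n)

    # brute force: beta = (D'D)^-1 D'target over samples 1..n-1
    d_full = np.column_stack([x[:-1], y[:-1]])
    beta = np.linalg.inv(d_full.T @ d_full) @ (d_full.T @ x[1:])
    resid = x[1:] - d_full @ beta
    v_full = np.mean(resid**2)

    fit = fit_bvar(x, y, 1)
    assert fit.a_xx[0] == pytest.approx(beta[0], abs=1e-10)
    assert fit.a_xy[0] == pytest.approx(beta[1], abs=1e-10)
    assert fit.resid_var_x_full == pytest.approx(v_full, abs=1e-10)

    d_rest = x[:-1, None]
    b_rest = float((d_rest.T @ d_rest)[0, 0] ** -1 * (d_rest.T @ x[1:])[0])
    v_rest = np.mean((x[1:] - b_rest * x[:-1]) ** 2)
    ar = fit_univariate_ar(x, 1)
    assert ar.coefficients[0] == pytest.approx(b_rest, abs=1e-10)
    assert ar.resid_var == pytest.approx(v_rest, abs=1e-10)


# ---------------------------------------------------------------------------
# Granger causality


def test_gc_independent_series_near_zero():
    rng = np.random.default_rng(6)
    x, y = rng.standard_normal((2, 20_000))
    assert granger_causality(x, y, 15) < 0.01


def test_gc_analytic_oracle_ln_1_25():
    """x(n) = 0.5 y(n-1) + e_x with unit noise: V_{x|x}=1.25, V_{x|x,y}=1,
    so GC_{y->x} = ln(1.25); the reverse direction carries nothing."""
    rng = np.random.default_rng(7)
    n = 20_000
    y = rng.standard_normal(n + 1)
    x = 0.5 * y[:-1] + rng.standard_normal(n)
    y = y[1:]
    assert granger_causality(x, y, 15) == pytest.approx(np.log(1.25), abs=0.02)
    assert granger_causality(y, x, 15) < 0.01


def test_gc_estimate_converges_with_sample_size():
    errors = []
    for n in (2_000, 20_000):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(n + 1)
        x = 0.5 * y[:-1] + rng.standard_normal(n)
        errors.append(abs(granger_causality(x, y[1:], 15) - np.log(1.25)))
    assert errors[1] < errors[0]
    assert errors[1] < 0.02


def test_gc_invariant_under_common_rescaling():
    rng = np.random.default_rng(9)
    n = 5_000
    y = rng.standard_normal(n + 1)
    x = 0.4 * y[:-1] + rng.standard_normal(n)
    y = y[1:]
    base = granger_causality(x, y, 10)
    scaled = granger_causality(1e3 * x, 1e3 * y, 10)
    assert scaled == pytest.approx(base, rel=1e-6)


def test_gc_matrix_structure(noise_epoch):
    g = gc_matrix(noise_epoch, 15)
    assert g.shape == (32, 32)
    np.testing.assert_array_equal(np.diag(g), 0.0)
    off = g[~np.eye(32, dtype=bool)]
    assert off.size == 992
    assert np.all(off >= 0.0)
    assert g.ravel().size == 1024  # row-major GC feature length


def test_gc_matrix_agrees_with_pairwise_route():
    rng = np.random.default_rng(10)
    ep = _epoch(rng.standard_normal((5, 400)))
    g = gc_matrix(ep, 6)
    for i, j in [(0, 1), (2, 4), (3, 0)]:
        pair = granger_causality(ep.data[i], ep.data[j], 6)
        assert g[i, j] == pytest.approx(pair, abs=1e-6)


def test_gc_matrix_recovers_planted_edge():
    """A single planted coupling j->i dominates the epoch-averaged matrix."""
    model = eegfp.make_subject_model(
        n_channels=6, order=1, base_coupling=0.0, n_planted=1, seed=13,
        planted_strength=0.5, plant_within=range(6),
    )
    ((i, j),) = model.planted_edges
    rec = eegfp.simulate_session(
        model, eegfp.SessionSpec("A", 1, 0.0),
        duration_s=100.0, fs=125.0, noise_scale=0.05, seed=0,
    )
    epochs = eegfp.segment(rec, 2.0)
    assert len(epochs) == 50
    mean_g = np.mean([gc_matrix(ep, 8) for ep in epochs], axis=0)
    np.fill_diagonal(mean_g, -np.inf)
    assert np.unravel_index(np.argmax(mean_g), mean_g.shape) == (i, j)


def test_gc_matrix_rejects_short_epochs():
    with pytest.raises(ValueError):
        gc_matrix(_epoch(np.random.default_rng(0).standard_normal((3, 40))), 15)


def test_gc_matrix_names_degenerate_pair():
    rng = np.random.default_rng(14)
    data = rng.standard_normal((4, 300))
    data[2] = 0.0  # dead channel
    with pytest.raises(GCMatrixError, match="2"):
        gc_matrix(_epoch(data), 5)


# ---------------------------------------------------------------------------
# mutual information


def test_mi_of_identical_16_level_series_is_4_bits():
    x = np.tile(np.arange(16.0), 100)
    est = mutual_information(x, x, 16, warn=False)
    assert est.mi == pytest.approx(4.0, abs=1e-12)
    assert est.joint_hist.sum() == x.size
    np.testing.assert_array_equal(est.marginal_x, est.joint_hist.sum(axis=1))
    np.testing.assert_array_equal(est.marginal_y, est.joint_hist.sum(axis=0))


def test_mi_independent_series_small():
    rng = np.random.default_rng(15)
    x = rng.uniform(size=10_000)
    y = rng.uniform(size=10_000)
    est = mutual_information(x, y, 16, warn=False)
    # plug-in bias bound ~ (B-1)^2 / (2 N ln 2) ~ 0.016 bits
    assert est.mi < 0.05


def test_mi_symmetric_bit_identical():
    rng = np.random.default_rng(16)
    x = rng.standard_normal(3_000)
    y = 0.5 * x + rng.standard_normal(3_000)
    a = mutual_information(x, y, 16, warn=False)
    b = mutual_information(y, x, 16, warn=False)
    assert a.mi == b.mi  # exactly, not approximately
    np.testing.assert_array_equal(a.joint_hist, b.joint_hist.T)


def test_mi_nonnegative_and_monotone_ordering():
    rng = np.random.default_rng(17)
    x = rng.standard_normal(5_000)
    noisy = x + 2.0 * rng.standard_normal(5_000)
    indep = rng.standard_normal(5_000)
    mi_self = mutual_information(x, x, 16, warn=False).mi
    mi_noisy = mutual_information(x, noisy, 16, warn=False).mi
    mi_indep = mutual_information(x, indep, 16, warn=False).mi
    assert mi_self > mi_noisy > mi_indep >= 0.0


def test_mi_invariant_under_affine_maps():
    rng = np.random.default_rng(18)
    x = rng.standard_normal(4_000)
    y = rng.standard_normal(4_000)
    a = mutual_information(x, y, 16, warn=False)
    b = mutual_information(4.0 * x - 1.0, 0.25 * y + 7.0, 16, warn=False)
    np.testing.assert_array_equal(a.joint_hist, b.joint_hist)
    assert a.mi == pytest.approx(b.mi, abs=1e-12)


def test_mi_constant_input_is_zero_with_warning():
    with pytest.warns(UserWarning):
        est = mutual_information(np.ones(1000), np.random.default_rng(0).standard_normal(1000), 16, warn=False)
    assert est.mi == 0.0


def test_mi_natural_log_base_option():
    rng = np.random.default_rng(19)
    x = rng.standard_normal(3_000)
    y = 0.8 * x + rng.standard_normal(3_000)
    bits = mutual_information(x, y, 16, warn=False).mi
    nats = mutual_information(x, y, 16, base=np.e, warn=False).mi
    assert nats == pytest.approx(bits * np.log(2), rel=1e-12)


def test_mi_vector_length_and_extremes():
    rng = np.random.default_rng(20)
    data = rng.standard_normal((32, 2_000))
    data[1] = data[0]  # identical pair
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        v = mi_vector(_epoch(data), 16)
    assert v.shape == (496,)
    assert np.all(v >= 0.0)
    assert np.argmax(v) == 0  # pair (0, 1) is the first upper-triangle entry


def test_mi_vector_independent_channels_near_zero():
    rng = np.random.default_rng(21)
    ep = _epoch(rng.standard_normal((32, 10_000)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        v = mi_vector(ep, 16)
    assert np.all(v < 0.05)


# ---------------------------------------------------------------------------
# datasets


def test_dataset_shapes_labels_and_determinism():
    rng = np.random.default_rng(22)
    epochs = [
        _epoch(rng.standard_normal((32, 300)), subject=f"S{k % 2}", index=k)
        for k in range(6)
    ]
    gc = connectivity_dataset(epochs, "GC", order=5)
    assert len(gc) == 6
    assert all(f.values.shape == (1024,) for f in gc)
    assert [f.subject_id for f in gc] == [f"S{k % 2}" for k in range(6)]
    mi = connectivity_dataset(epochs, "MI", n_bins=8)
    assert all(f.values.shape == (496,) for f in mi)
    again = connectivity_dataset(epochs, "GC", order=5)
    for a, b in zip(gc, again):
        np.testing.assert_array_equal(a.values, b.values)


def test_dataset_skips_bad_epochs_up_to_threshold(caplog):
    rng = np.random.default_rng(23)
    good = [_epoch(rng.standard_normal((4, 300)), index=k) for k in range(20)]
    bad_data = rng.standard_normal((4, 300))
    bad_data[0] = 0.0
    bad = [_epoch(bad_data, index=99)]
    out = connectivity_dataset(good + bad, "GC", order=5)
    assert len(out) == 20  # the degenerate epoch was skipped
    with pytest.raises(GCMatrixError):
        connectivity_dataset(bad * 3 + good[:3], "GC", order=5)


def test_dataset_rejects_empty_and_unknown_kind():
    with pytest.raises(ValueError):
        connectivity_dataset([], "GC")
    with pytest.raises(ValueError):
        connectivity_dataset([_epoch(np.zeros((2, 100)))], "PLV")


def test_features_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(24)
    epochs = [_epoch(rng.standard_normal((32, 300)), index=k) for k in range(3)]
    feats = connectivity_dataset(epochs, "GC", order=5)
    path = tmp_path / "gc.tsv"
    save_features_tsv(feats, path)
    back = load_features_tsv(path, "GC")
    x0, s0, _ = features_to_matrix(feats)
    x1, s1, _ = features_to_matrix(back)
    np.testing.assert_allclose(x0, x1, rtol=1e-12)
    np.testing.assert_array_equal(s0, s1)
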