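"""PLS core: NIPALS against least-squares and scikit-learn oracles,
venetian folds, LV selection, VIP, external split, metrics."""

import numpy as np
import pytest

from vinespec.chemometrics import (
    cross_validate,
    evaluate,
    external_split,
    first_local_minimum,
    model_from_json,
    model_to_json,
    pls_fit,
    predict,
    venetian_folds,
    vip_scores,
)
from vinespec.preprocessing import PreprocConfig, apply_pipeline
from vinespec.sensors import SENSOR_2

WL = SENSOR_2.wavelengths


# --------------------------------------------------------------------- fitting


def test_single_predictor_pls_equals_simple_regression(rng):
    x = rng.normal(size=30)
    y = 2.5 * x - 1.0 + rng.normal(0, 0.1, 30)
    model = pls_fit(x[:, None], y, 1)
    slope, intercept = np.polyfit(x, y, 1)
    np.testing.assert_allclose(model.b[0], slope, rtol=1e-10)
    pred = model.predict_preprocessed(np.array([[0.7]]))
    np.testing.assert_allclose(pred, slope * 0.7 + intercept, rtol=1e-10)


def test_full_rank_pls_reaches_least_squares_solution(rng):
    """Full-LV PLS1 on a tall full-rank matrix must equal the
    normal-equations (OLS) solution."""
    X = rng.normal(size=(20, 5))
    y = rng.normal(size=20)
    model = pls_fit(X, y, 5)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    b_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
    np.testing.assert_allclose(model.b, b_ols, rtol=1e-6)


def test_constant_response_gives_null_model():
    X = np.random.default_rng(0).normal(size=(10, 4))
    model = pls_fit(X, np.full(10, -1.3), 2)
    np.testing.assert_allclose(model.b, 0.0, atol=1e-12)
    np.testing.assert_allclose(model.predict_preprocessed(X), -1.3)
    assert model.deflation_stopped_early


def test_scores_are_mutually_orthogonal(rng):
    X = rng.normal(size=(40, 30))
    y = rng.normal(size=40)
    model = pls_fit(X, y, 8)
    G = model.T.T @ model.T
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()


def test_pls_matches_sklearn_predictions(rng):
    """Independent implementation cross-check: scikit-learn's PLSRegression
    (SIMPLS-like NIPALS for one response) must produce the same fitted values."""
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    X = rng.normal(size=(30, 12))
    y = X @ rng.normal(size=12) + rng.normal(0, 0.2, 30)
    for a in (1, 3, 6):
        ours = pls_fit(X, y, a)
        ref = sklearn.PLSRegression(n_components=a, scale=False).fit(X, y)
        np.testing.assert_allclose(
            ours.predict_preprocessed(X), ref.predict(X).ravel(), rtol=1e-8, atol=1e-10
        )


def test_pls_fit_input_validation(rng):
    X = rng.normal(size=(10, 4))
    y = rng.normal(size=10)
    with pytest.raises(ValueError):
        pls_fit(X, y, 11)
    with pytest.raises(ValueError):
        pls_fit(X[:1], y[:1], 1)


# ------------------------------------------------------------------ venetians


def test_venetian_fold_pattern():
    np.testing.assert_array_equal(venetian_folds(10, 10), np.arange(10))
    f = venetian_folds(23, 10)
    counts = np.bincount(f, minlength=10)
    np.testing.assert_array_equal(counts, [3, 3, 3, 2, 2, 2, 2, 2, 2, 2])
    np.testing.assert_array_equal(f, np.arange(23) % 10)


def test_venetian_rejects_degenerate_k():
    with pytest.raises(ValueError):
        venetian_folds(10, 1)
    with pytest.raises(ValueError):
        venetian_folds(5, 10)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ([0.30, 0.20, 0.25, 0.10], 2),
        ([0.5, 0.4, 0.3, 0.2], 4),  # monotone decreasing -> last
        ([0.2, 0.2, 0.1, 0.3], 3),  # tie advances
        ([0.1, 0.5], 1),
        ([0.3], 1),
    ],
)
def test_first_local_minimum_rule(seq, expected):
    assert first_local_minimum(seq) == expected


def test_cv_recovers_low_rank_structure(rng):
    """y linear in 3 latent spectral factors (noise at the 1e-5 level):
    the first-local-minimum rule must stop at a small model with near-zero
    error."""
    n = 60
    L = np.vstack([np.exp(-0.5 * ((WL - m) / 60) ** 2) for m in (1000, 1400, 1700)])
    S = rng.normal(size=(n, 3))
    X = S @ L + rng.normal(0, 1e-5, size=(n, L.shape[1]))
    y = S @ np.array([0.5, -0.3, 0.2])
    cv = cross_validate(X, y, k=10, a_max=8)
    assert cv.chosen_lv <= 4
    assert cv.rmsecv < 0.02


def test_cv_centering_stays_inside_folds(rng):
    """Leakage probe: shuffling y must destroy cross-validated skill."""
    X = rng.normal(size=(80, 40))
    y = X @ rng.normal(size=40)
    good = cross_validate(X, y, k=10, a_max=5)
    shuffled = cross_validate(X, rng.permutation(y), k=10, a_max=5)
    assert good.r2cv > 0.9
    assert shuffled.r2cv < 0.2


# ------------------------------------------------------------------------ VIP


def test_vip_mean_square_is_one(rng):
    X = rng.normal(size=(50, 25))
    y = rng.normal(size=50)
    for a in (1, 4, 9):
        v = vip_scores(pls_fit(X, y, a))
        assert np.mean(v.scores**2) == pytest.approx(1.0, abs=1e-8)


def test_vip_single_predictor_is_one(rng):
    v = vip_scores(pls_fit(rng.normal(size=(12, 1)), rng.normal(size=12), 1))
    np.testing.assert_allclose(v.scores, [1.0])


def test_vip_localizes_a_single_active_band(rng):
    """Signal only in the 1454 nm band: VIP maxima must fall inside
    1404-1504 nm and off-band channels (beyond 3 band widths) must stay
    below the influence threshold."""
    W = rng.uniform(0.3, 0.8, 100)
    G = np.exp(-0.5 * ((WL - 1454.0) / 45.0) ** 2)
    X = 0.5 * np.exp(-np.outer(0.5 + 0.8 * W, G)) * rng.uniform(0.95, 1.05, (100, 1))
    Z = apply_pipeline(X, WL, PreprocConfig())
    model = pls_fit(Z, -W, 2, wavelengths=WL)
    v = vip_scores(model)
    assert 1404.0 <= WL[np.argmax(v.scores)] <= 1504.0
    off_band = (WL < 1454 - 3 * 45) | (WL > 1454 + 3 * 45)
    assert v.scores[off_band].max() < 1.0


# ------------------------------------------------------------------- splitting


def test_external_split_contract(rng):
    dates = np.repeat([f"d{i}" for i in range(6)], 36)
    y = -rng.uniform(0.8, 2.2, dates.size)
    train, val = external_split(dates, y, per_date=7, rng_seed=11)
    assert val.size == 42  # 6 x 7, ~20% of 216
    assert train.size == 216 - 42
    assert np.intersect1d(train, val).size == 0
    for d in np.unique(dates):
        sel = dates == d
        yv = y[val][dates[val] == d]
        assert yv.size == 7
        assert y[sel].max() not in yv and y[sel].min() not in yv
    # seeded reproducibility
    train2, val2 = external_split(dates, y, per_date=7, rng_seed=11)
    np.testing.assert_array_equal(val, val2)
    _, val3 = external_split(dates, y, per_date=7, rng_seed=12)
    assert not np.array_equal(val, val3)


def test_external_split_rejects_small_dates(rng):
    dates = np.repeat(["a", "b"], 8)
    y = -rng.uniform(1, 2, 16)
    with pytest.raises(ValueError, match="'a'|'b'"):
        external_split(dates, y, per_date=7)


# --------------------------------------------------------------------- metrics


def test_evaluate_reference_cases():
    y = np.array([-1.0, -1.5, -2.0])
    assert evaluate(y, y) == (1.0, 0.0)
    r2, _ = evaluate(y, np.full(3, y.mean()))
    assert r2 == pytest.approx(0.0)
    r2, rmse = evaluate(y, np.array([-1.1, -1.4, -2.1]))
    assert rmse == pytest.approx(0.1)


def test_predict_reproduces_training_fit_and_mean(rng):
    X = rng.uniform(0.2, 0.8, size=(30, WL.size))
    y = -rng.uniform(0.8, 2.0, 30)
    cfg = PreprocConfig()
    Z = apply_pipeline(X, WL, cfg)
    model = pls_fit(Z, y, 4, wavelengths=WL, preproc=cfg)
    np.testing.assert_allclose(
        predict(model, X, WL), model.predict_preprocessed(Z), rtol=1e-12
    )
    # the training-mean preprocessed spectrum predicts the mean response
    mean_pred = model.predict_preprocessed(model.x_mean[None, :])
    np.testing.assert_allclose(mean_pred, model.y_mean, rtol=1e-10)


def test_predict_rejects_wrong_grid(rng):
    X = rng.uniform(0.2, 0.8, size=(12, WL.size))
    y = -rng.uniform(0.8, 2.0, 12)
    cfg = PreprocConfig()
    model = pls_fit(apply_pipeline(X, WL, cfg), y, 2, wavelengths=WL, preproc=cfg)
    with pytest.raises(ValueError, match="grid"):
        predict(model, X[:, :-1], WL[:-1])


def test_model_json_round_trip(rng):
    X = rng.uniform(0.2, 0.8, size=(15, WL.size))
    y = -rng.uniform(0.8, 2.0, 15)
    cfg = PreprocConfig()
    model = pls_fit(apply_pipeline(X, WL, cfg), y, 3, wavelengths=WL, preproc=cfg)
    clone = model_from_json(model_to_json(model))
    np.testing.assert_allclose(clone.b, model.b)
    np.testing.assert_allclose(predict(clone, X, WL), predict(model, X, WL))
    assert clone.preproc == model.preproc
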