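"""PLS regression core: NIPALS fitting, venetian-blind cross-validation,
latent-variable selection, VIP wavelength importance, external validation.

The response is stem water potential (psi, MPa, negative; more negative =
more stressed) and the predictors are preprocessed reflectance channels.
PLS1 is fitted with the classical NIPALS recursion; model complexity (the
number of latent variables, LV) is chosen by ten-fold venetian-blind
cross-validation at the first local minimum of RMSECV — the lowest LV count
whose error is below the next model's, which need not be the global
minimum.  Wavelength influence is summarized by Variable Importance in the
Projection (VIP): the share of explained response sum of squares carried by
each channel across LVs, normalized so the mean squared score is 1; channels
with VIP > 1 are called influential.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocessing import PreprocConfig, apply_pipeline
from .spectra import GeoPoint


@dataclass
class SampleRecord:
    """One modelling sample: a block-averaged spectrum and its psi reference."""

    spectrum: np.ndarray
    psi: float
    date: str
    block_id: str
    treatment: str = ""
    geo: GeoPoint | None = None

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.psi > 0:
            raise ValueError("stem water potential must be <= 0 MPa")
        if not np.all(np.isfinite(self.spectrum)):
            raise ValueError("sample spectrum contains non-finite values")


@dataclass
class PLSModel:
    """Fitted PLS1 model: weights, loadings, scores, regression vector."""

    n_lv: int
    W: np.ndarray  # x-weights, (p, A), unit columns
    P: np.ndarray  # x-loadings, (p, A)
    q: np.ndarray  # y-loadings, (A,)
    T: np.ndarray  # scores, (n, A), mutually orthogonal
    b: np.ndarray  # regression vector, (p,)
    x_mean: np.ndarray
    y_mean: float
    wavelengths: np.ndarray | None = None
    preproc: PreprocConfig | None = None
    deflation_stopped_early: bool = False
    meta: dict = field(default_factory=dict)

    def predict_preprocessed(self, X: np.ndarray) -> np.ndarray:
        """Predict from an already-preprocessed matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.b + self.y_mean


@dataclass
class CVResult:
    rmsecv_by_lv: np.ndarray  # MPa, index a-1 -> A=a
    chosen_lv: int
    r2cv: float
    rmsecv: float
    folds: np.ndarray  # fold index per sample
    predictions: np.ndarray  # cross-validated prediction at chosen_lv


@dataclass
class VIPResult:
    scores: np.ndarray
    influential: np.ndarray  # wavelengths (or channel indices) with score > 1
    wavelengths: np.ndarray | None = None


@dataclass
class ModelMetrics:
    r2c: float | None = None
    rmsec: float | None = None
    r2cv: float | None = None
    rmsecv: float | None = None
    r2p: float | None = None
    rmsep: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    wavelengths: np.ndarray | None = None,
    preproc: PreprocConfig | None = None,
) -> PLSModel:
    """NIPALS PLS1 on a (n, p) matrix and response vector.

    Centering is internal (column means of X, mean of y).  For each
    component a: w_a = X'y / |X'y|; t_a = X w_a; q_a = t_a'y / t_a't_a;
    p_a = X't_a / t_a't_a; then X and y are deflated.  The regression vector
    is b = W (P'W)^-1 q, so predictions are (X - x_mean) b + y_mean.

    If a deflated residual becomes orthogonal to y the recursion stops early
    and the model is returned with fewer components and a warning flag.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must lie in [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    stopped = False
    tol = 1e-12 * max(1.0, float(np.abs(Xc).max()) * float(np.abs(yc).max() or 1.0))
    a_used = 0
    for a in range(n_lv):
        cov = Xc.T @ yc
        norm = np.linalg.norm(cov)
        if norm <= tol:
            stopped = True
            break
        w = cov / norm
        t = Xc @ w
        tt = float(t @ t)
        if tt <= tol:
            stopped = True
            break
        qa = float(t @ yc) / tt
        pa = Xc.T @ t / tt
        W[:, a] = w
        T[:, a] = t
        P[:, a] = pa
        q[a] = qa
        Xc = Xc - np.outer(t, pa)
        yc = yc - qa * t
        a_used += 1
    if a_used == 0:
        # y uncorrelated with X (e.g. constant response): null model
        b = np.zeros(p)
        return PLSModel(
            n_lv=0, W=W[:, :0], P=P[:, :0], q=q[:0], T=T[:, :0], b=b,
            x_mean=x_mean, y_mean=y_mean, wavelengths=wavelengths,
            preproc=preproc, deflation_stopped_early=True,
        )
    W, P, T, q = W[:, :a_used], P[:, :a_used], T[:, :a_used], q[:a_used]
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_lv=a_used, W=W, P=P, q=q, T=T, b=b, x_mean=x_mean, y_mean=y_mean,
        wavelengths=wavelengths, preproc=preproc,
        deflation_stopped_early=stopped,
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def venetian_folds(n: int, k: int = 10) -> np.ndarray:
    """Interleaved ('venetian blind') fold assignment: sample i -> fold i mod k."""
    if k < 2:
        raise ValueError("venetian blinds need k >= 2 (k=1 leaves no held-out data)")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    return np.arange(n) % k


def first_local_minimum(rmsecv: Sequence[float]) -> int:
    """LV count at the first local minimum of the RMSECV curve.

    Returns the smallest A (1-based) with RMSECV(A) < RMSECV(A+1); ties are
    treated as still decreasing, and a monotone non-increasing curve selects
    the last A.
    """
    r = np.asarray(rmsecv, dtype=float)
    if r.size == 0:
        raise ValueError("empty RMSECV sequence")
    for a in range(r.size - 1):
        if r[a] < r[a + 1]:
            return a + 1
    return int(r.size)


def cross_validate(X: np.ndarray, y: np.ndarray, k: int = 10, a_max: int = 20) -> CVResult:
    """Ten-fold venetian-blind cross-validation over A = 1..a_max.

    Each fold's model is fitted (and centred) on the remaining samples only,
    then predicts the held-out ones; RMSECV(A) pools all held-out residuals.
    The retained complexity follows the first-local-minimum rule.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    folds = venetian_folds(n, k)
    min_train = min(int(np.sum(folds != f)) for f in range(k))
    a_cap = min(a_max, min_train - 1, p)
    if a_cap < 1:
        raise ValueError("not enough samples per training fold for even one LV")
    preds = np.full((n, a_cap), np.nan)
    for f in range(k):
        test = folds == f
        train = ~test
        model = pls_fit(X[train], y[train], a_cap)
        Xc = X[test] - model.x_mean
        for a in range(1, model.n_lv + 1):
            Wa, Pa, qa = model.W[:, :a], model.P[:, :a], model.q[:a]
            ba = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
            preds[test, a - 1] = Xc @ ba + model.y_mean
        if model.n_lv < a_cap:  # early NIPALS stop: higher-A prediction is unchanged
            for a in range(model.n_lv + 1, a_cap + 1):
                preds[test, a - 1] = preds[test, model.n_lv - 1]
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen = first_local_minimum(rmsecv)
    resid = preds[:, chosen - 1] - y
    sst = float(np.sum((y - y.mean()) ** 2))
    r2cv = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    return CVResult(
        rmsecv_by_lv=rmsecv,
        chosen_lv=chosen,
        r2cv=r2cv,
        rmsecv=float(rmsecv[chosen - 1]),
        folds=folds,
        predictions=preds[:, chosen - 1],
    )


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------


def vip_scores(model: PLSModel) -> VIPResult:
    """Variable Importance in the Projection for a fitted PLS1 model.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / |w_a|)^2 / sum_a SSY_a ), where
    SSY_a = q_a^2 t_a't_a is the response sum of squares explained by
    component a.  The mean of squared scores is exactly 1, so scores above 1
    flag wavelengths that carry more than an average share of the signal.
    """
    if model.n_lv < 1:
        raise ValueError("VIP requires a fitted model with at least one LV")
    p = model.W.shape[0]
    ssy = model.q**2 * np.einsum("ia,ia->a", model.T, model.T)
    wnorm2 = np.sum(model.W**2, axis=0)
    contrib = (model.W**2 / wnorm2) @ ssy
    scores = np.sqrt(p * contrib / ssy.sum())
    wl = model.wavelengths
    influential = (wl if wl is not None else np.arange(p))[scores > 1.0]
    return VIPResult(scores=scores, influential=np.asarray(influential), wavelengths=wl)


# ---------------------------------------------------------------------------
# external validation split
# ---------------------------------------------------------------------------


def external_split(
    dates: Sequence[str],
    y: Sequence[float],
    per_date: int = 7,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-date external-validation draw, shielding the date extremes.

    For every date, samples equal to that date's maximum or minimum psi are
    excluded from eligibility (outlier shielding), then ``per_date`` samples
    are drawn without replacement into the validation set; everything else
    — extremes included — stays in the training set.  With six dates of 36
    samples this yields 42 validation samples, about 20% of the data.
    Returns (train_indices, validation_indices), both sorted.
    """
    dates = np.asarray(dates)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(rng_seed)
    val_idx: list[int] = []
    for d in np.unique(dates):
        idx = np.flatnonzero(dates == d)
        yd = y[idx]
        eligible = idx[(yd != yd.max()) & (yd != yd.min())]
        if eligible.size < per_date:
            raise ValueError(
                f"date {d!r} has only {eligible.size} eligible samples "
                f"(need {per_date} after shielding the extremes)"
            )
        val_idx.extend(rng.choice(eligible, size=per_date, replace=False))
    val = np.sort(np.asarray(val_idx, dtype=int))
    train = np.setdiff1d(np.arange(dates.size), val)
    return train, val


# ---------------------------------------------------------------------------
# metrics and prediction
# ---------------------------------------------------------------------------


def evaluate(y_true: Sequence[float], y_pred: Sequence[float]) -> tuple[float, float]:
    """(R^2, RMSE): coefficient of determination about the evaluation-set
    mean, and root mean squared error in MPa."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise ValueError("need at least two samples to evaluate")
    sse = float(np.sum((y_pred - y_true) ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(sse / y_true.size))
    return r2, rmse


def predict(model: PLSModel, X_raw: np.ndarray, wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Predict psi from raw (un-preprocessed) spectra on the training grid.

    Applies the model's stored preprocessing, centres with the training
    means, and returns X_c b + y_mean, one value per spectrum.
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    if model.wavelengths is not None:
        wavelengths = None if wavelengths is None else np.asarray(wavelengths, float)
        if (
            wavelengths is None
            or wavelengths.shape != model.wavelengths.shape
            or not np.allclose(wavelengths, model.wavelengths)
        ):
            raise ValueError(
                "wavelength grid mismatch: expected "
                f"{model.wavelengths[0]:.1f}-{model.wavelengths[-1]:.1f} nm "
                f"({model.wavelengths.size} channels)"
            )
    X = (
        apply_pipeline(X_raw, model.wavelengths, model.preproc)
        if model.preproc is not None and model.wavelengths is not None
        else X_raw
    )
    return model.predict_preprocessed(X)


# ---------------------------------------------------------------------------
# high-level training and serialization
# ---------------------------------------------------------------------------


def train_model(
    X_raw: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray,
    preproc: PreprocConfig | None = None,
    k: int = 10,
    a_max: int = 20,
) -> tuple[PLSModel, CVResult, ModelMetrics]:
    """Preprocess, cross-validate, fit at the selected LV, report metrics."""
    preproc = preproc if preproc is not None else PreprocConfig()
    X = apply_pipeline(X_raw, wavelengths, preproc)
    cv = cross_validate(X, np.asarray(y, float), k=k, a_max=a_max)
    model = pls_fit(X, y, cv.chosen_lv, wavelengths=np.asarray(wavelengths, float), preproc=preproc)
    r2c, rmsec = evaluate(y, model.predict_preprocessed(X))
    metrics = ModelMetrics(r2c=r2c, rmsec=rmsec, r2cv=cv.r2cv, rmsecv=cv.rmsecv)
    return model, cv, metrics


def model_to_json(model: PLSModel, metrics: ModelMetrics | None = None, provenance: dict | None = None) -> str:
    payload = {
        "n_lv": model.n_lv,
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "b": model.b.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "wavelengths": None if model.wavelengths is None else model.wavelengths.tolist(),
        "preproc": None if model.preproc is None else model.preproc.to_dict(),
        "deflation_stopped_early": model.deflation_stopped_early,
        "metrics": metrics.to_dict() if metrics is not None else {},
        "provenance": provenance or {},
    }
    return json.dumps(payload, indent=1)


def model_from_json(text: str) -> PLSModel:
    d = json.loads(text)
    W = np.asarray(d["W"], float)
    return PLSModel(
        n_lv=d["n_lv"],
        W=W,
        P=np.asarray(d["P"], float),
        q=np.asarray(d["q"], float),
        T=np.zeros((0, d["n_lv"])),  # scores are training artefacts, not persisted
        b=np.asarray(d["b"], float),
        x_mean=np.asarray(d["x_mean"], float),
        y_mean=float(d["y_mean"]),
        wavelengths=None if d["wavelengths"] is None else np.asarray(d["wavelengths"], float),
        preproc=None if d["preproc"] is None else PreprocConfig.from_dict(d["preproc"]),
        deflation_stopped_early=bool(d.get("deflation_stopped_early", False)),
        meta=d.get("metrics", {}),
    )


def data_checksum(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    return h.hexdigest()[:16]
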