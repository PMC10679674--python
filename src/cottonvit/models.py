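"""Regression models and evaluation metrics.

Three predictors map selected features to seedling height: partial
least squares regression (latent-variable linear model, 3 components
by default), epsilon-insensitive support-vector regression with an RBF
kernel, and the 1-D CNN of :mod:`cottonvit.cnn`.  Fit quality is
summarized, on train and test folds alike, by the Pearson correlation
R between predictions and observations and the root-mean-square error
RMSE = sqrt(sum (yhat_i - y_i)^2 / n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .cnn import Conv1dRegressor


@dataclass
class ModelSpec:
    kind: str = "PLSR"                    # PLSR | SVR | CNN
    plsr_components: int = 3
    svr_C: float = 10.0
    svr_epsilon: float = 0.1
    svr_gamma: str | float = "scale"      # 1 / (VN * var) by default
    cnn_conv1_filters: int = 64
    cnn_conv2_filters: int = 128
    cnn_kernel_size: int = 3
    cnn_fc_units: int = 256
    cnn_lr: float = 1e-4
    cnn_epochs: int = 50
    cnn_batch: int = 4
    rng_seed: int = 0

    def validate(self) -> None:
        if self.kind not in {"PLSR", "SVR", "CNN"}:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.plsr_components < 1:
            raise ValueError("plsr_components must be >= 1")


@dataclass
class ModelResult:
    spec: ModelSpec
    VN: int
    R_C: float
    RMSE_C: float
    R_P: float
    RMSE_P: float
    train_pred: np.ndarray
    test_pred: np.ndarray
    loss_curve: list | None = None
    extras: dict = field(default_factory=dict)


class _PLSRModel:
    def __init__(self, spec: ModelSpec):
        self.spec = spec

    def fit(self, X, y):
        X = np.asarray(X, float)
        rank_cap = min(X.shape[0] - 1, X.shape[1])
        if self.spec.plsr_components > rank_cap:
            raise ValueError(
                f"{self.spec.plsr_components} PLS components exceed the rank cap "
                f"{rank_cap}")
        # autoscaled PLS1: fused feature blocks mix reflectance (~1e-2
        # variance) with GLCM features (~1e1), so centering alone lets one
        # block drown the other
        self._pls = PLSRegression(n_components=self.spec.plsr_components, scale=True)
        self._pls.fit(X, np.asarray(y, float).ravel())
        return self

    @property
    def coef_(self) -> np.ndarray:
        return np.asarray(self._pls.coef_).reshape(-1)

    def predict(self, X):
        return self._pls.predict(np.asarray(X, float)).ravel()


class _SVRModel:
    def __init__(self, spec: ModelSpec):
        self.spec = spec

    def fit(self, X, y):
        self._scaler = StandardScaler().fit(X)
        self._svr = SVR(kernel="rbf", C=self.spec.svr_C,
                        epsilon=self.spec.svr_epsilon, gamma=self.spec.svr_gamma)
        self._svr.fit(self._scaler.transform(X), np.asarray(y, float).ravel())
        return self

    def predict(self, X):
        return self._svr.predict(self._scaler.transform(X))


def make_model(spec: ModelSpec):
    """Instantiate the (unfitted) model a spec describes."""
    spec.validate()
    if spec.kind == "PLSR":
        return _PLSRModel(spec)
    if spec.kind == "SVR":
        return _SVRModel(spec)
    return Conv1dRegressor(conv1_filters=spec.cnn_conv1_filters,
                           conv2_filters=spec.cnn_conv2_filters,
                           kernel_size=spec.cnn_kernel_size,
                           fc_units=spec.cnn_fc_units, lr=spec.cnn_lr,
                           epochs=spec.cnn_epochs, batch_size=spec.cnn_batch,
                           rng_seed=spec.rng_seed)


def fit_plsr(X_train, y_train, spec: ModelSpec | None = None):
    return _PLSRModel(spec or ModelSpec(kind="PLSR")).fit(X_train, y_train)


def fit_svr(X_train, y_train, spec: ModelSpec | None = None):
    return _SVRModel(spec or ModelSpec(kind="SVR")).fit(X_train, y_train)


def fit_cnn(X_train, y_train, spec: ModelSpec | None = None):
    spec = spec or ModelSpec(kind="CNN")
    return make_model(ModelSpec(**{**spec.__dict__, "kind": "CNN"})).fit(X_train, y_train)


def evaluate(model, X, y) -> tuple[float, float]:
    """(Pearson R between predictions and targets, RMSE)."""
    y = np.asarray(y, float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 samples to evaluate")
    pred = np.asarray(model.predict(X), float).ravel()
    if np.std(pred) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in predictions or targets: R undefined")
    r = float(np.corrcoef(pred, y)[0, 1])
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return r, rmse


def svr_grid_search(X_train, y_train, X_val, y_val,
                    Cs=(1.0, 10.0, 100.0), epsilons=(0.05, 0.1, 0.5)) -> ModelSpec:
    """Pick SVR (C, epsilon) by validation RMSE over a small grid."""
    best, best_spec = np.inf, None
    for C in Cs:
        for eps in epsilons:
            spec = ModelSpec(kind="SVR", svr_C=C, svr_epsilon=eps)
            model = _SVRModel(spec).fit(X_train, y_train)
            rmse = float(np.sqrt(np.mean((model.predict(X_val) - np.ravel(y_val)) ** 2)))
            if rmse < best:
                best, best_spec = rmse, spec
    return best_spec
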