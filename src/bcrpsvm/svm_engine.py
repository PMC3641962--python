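"""Soft-margin kernel SVM training, prediction and grid search.

The decision function is the standard dual form

    f(x) = Σ_i α_i y_i K(s_i, x) + b,   0 ≤ α_i ≤ C

with the RBF kernel K(x, y) = exp(−γ‖x−y‖²), a linear kernel ⟨x, y⟩, or a
polynomial kernel (γ⟨x, y⟩ + c0)^d. The quadratic program is solved by
scikit-learn's libsvm binding; this module owns the kernel mathematics, the
trained-model representation (support vectors, dual coefficients and bias
are stored and evaluated here), the exponential grid search with stratified
cross-validation, and the plain-text model file format.

Hyperparameter search follows the conventional coarse exponential grid
C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} (step 2 in the exponent) with 5-fold
stratified cross-validated accuracy; ties prefer smaller C, then smaller γ.
A decision value of exactly 0 maps to the positive class (substrate).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .chem_io import NON_SUBSTRATE, SUBSTRATE
from .descriptors import DescriptorMatrix
from .preprocess import ScalingParams

#: default exponential grids
C_GRID: tuple[float, ...] = tuple(2.0 ** np.arange(-5, 16, 2))
GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** np.arange(-15, 4, 2))


class SVMError(ValueError):
    pass


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "rbf"  # linear | polynomial | rbf
    gamma: float = 1.0
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial", "rbf"):
            raise SVMError(f"unknown kernel {self.kind!r}")
        if self.kind in ("rbf", "polynomial") and not self.gamma > 0:
            raise SVMError("gamma must be positive")
        if self.degree < 1:
            raise SVMError("degree must be >= 1")


@dataclass(frozen=True)
class SVMConfig:
    C: float = 1.0
    kernel: KernelSpec = field(default_factory=KernelSpec)
    class_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise SVMError("C must be positive")


def kernel_value(k: KernelSpec, x: Sequence[float], y: Sequence[float]) -> float:
    """Evaluate the kernel on a single pair of feature vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SVMError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(_kernel_matrix(k, x[None, :], y[None, :])[0, 0])


def _kernel_matrix(k: KernelSpec, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if k.kind == "linear":
        return a @ b.T
    if k.kind == "polynomial":
        return (k.gamma * (a @ b.T) + k.coef0) ** k.degree
    sq = (
        np.sum(a * a, axis=1)[:, None]
        + np.sum(b * b, axis=1)[None, :]
        - 2.0 * (a @ b.T)
    )
    return np.exp(-k.gamma * np.clip(sq, 0.0, None))


def _encode(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray([1 if l == SUBSTRATE else -1 for l in labels])
    return y


def _fit_svc(X: np.ndarray, y: np.ndarray, cfg: SVMConfig) -> SVC:
    kernel_map = {"linear": "linear", "polynomial": "poly", "rbf": "rbf"}
    cw = None
    if cfg.class_weights:
        cw = {1: cfg.class_weights.get(SUBSTRATE, 1.0),
              -1: cfg.class_weights.get(NON_SUBSTRATE, 1.0)}
    svc = SVC(
        C=cfg.C,
        kernel=kernel_map[cfg.kernel.kind],
        gamma=cfg.kernel.gamma,
        degree=cfg.kernel.degree,
        coef0=cfg.kernel.coef0,
        class_weight=cw,
        cache_size=64,
    )
    svc.fit(X, y)
    return svc


@dataclass
class TrainedModel:
    """A frozen classifier: features, scaling, kernel/C and fitted state.

    The decision function is evaluated here from the stored support
    vectors and dual coefficients (not by calling back into the solver),
    so a model loaded from its text file predicts without any refit.
    Inputs to :meth:`predict` are expected on the scaled [−1, 1] feature
    scale; ``scaling`` is carried so callers holding raw descriptors can
    apply it first.
    """

    feature_names: list[str]
    config: SVMConfig
    support_vectors: np.ndarray  # (k, p) scaled feature space
    dual_coef: np.ndarray  # (k,) = alpha_i * y_i
    intercept: float
    scaling: ScalingParams | None = None
    fingerprint: str = ""

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _matrix(self, dm) -> np.ndarray:
        if isinstance(dm, DescriptorMatrix):
            dm = dm.frame
        if isinstance(dm, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in dm.columns]
            if missing:
                raise SVMError(f"matrix is missing model features: {missing}")
            return dm[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(dm, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise SVMError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return X

    def decision_values(self, dm) -> np.ndarray:
        X = self._matrix(dm)
        K = _kernel_matrix(self.config.kernel, X, self.support_vectors)
        return K @ self.dual_coef + self.intercept

    def predict(self, dm) -> tuple[list[str], np.ndarray]:
        """Labels plus raw decision values; a decision value of exactly 0
        is classified as substrate (documented tie rule)."""
        d = self.decision_values(dm)
        labels = [SUBSTRATE if v >= 0 else NON_SUBSTRATE for v in d]
        return labels, d


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train(
    dm,
    labels: Sequence[str],
    cfg: SVMConfig,
    feature_names: Sequence[str] | None = None,
    scaling: ScalingParams | None = None,
) -> TrainedModel:
    """Fit a soft-margin SVM on an (already scaled) feature matrix.

    ``dm`` may be a DescriptorMatrix, DataFrame or ndarray; in the array
    case ``feature_names`` names the columns.
    """
    if isinstance(dm, DescriptorMatrix):
        frame = dm.frame
    elif isinstance(dm, pd.DataFrame):
        frame = dm
    else:
        X = np.asarray(dm, dtype=float)
        names = list(feature_names) if feature_names is not None else [
            f"f{k}" for k in range(X.shape[1])
        ]
        frame = pd.DataFrame(X, columns=names)
    if feature_names is not None:
        frame = frame[list(feature_names)]
    X = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise SVMError("non-finite values in training matrix")
    y = _encode(list(labels))
    if len(set(y.tolist())) < 2:
        raise SVMError("training data contains a single class")
    svc = _fit_svc(X, y, cfg)
    # libsvm orders dual_coef by class blocks; with y in {-1,+1} the stored
    # coefficients are already alpha_i * y_i for classes_ == [-1, 1]
    return TrainedModel(
        feature_names=[str(c) for c in frame.columns],
        config=cfg,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        scaling=scaling,
        fingerprint=_fingerprint(X, y),
    )


def predict(model: TrainedModel, dm) -> tuple[list[str], np.ndarray]:
    return model.predict(dm)


@dataclass
class GridSearchResult:
    grid: list[tuple[float, float, float]]  # (C, gamma, CV accuracy)
    best_C: float
    best_gamma: float
    best_accuracy: float
    folds: int
    seed: int

    def best_config(self, kernel_kind: str = "rbf", degree: int = 3, coef0: float = 0.0) -> SVMConfig:
        return SVMConfig(
            C=self.best_C,
            kernel=KernelSpec(kernel_kind, gamma=self.best_gamma, degree=degree, coef0=coef0),
        )


def grid_search(
    dm,
    labels: Sequence[str],
    C_grid: Sequence[float] = C_GRID,
    gamma_grid: Sequence[float] = GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
    kernel_kind: str = "rbf",
    degree: int = 3,
    coef0: float = 0.0,
) -> GridSearchResult:
    """Exhaustive (C, γ) search by stratified k-fold cross-validated accuracy.

    Folds are fixed once per call (seeded shuffle) and shared by every grid
    point, so the search is fully reproducible. Ties prefer the smaller C,
    then the smaller γ. If the minority class is smaller than ``folds`` the
    fold count is reduced (never below 2).
    """
    if folds < 2:
        raise SVMError("folds must be >= 2")
    if not len(C_grid) or not len(gamma_grid):
        raise SVMError("grids must be non-empty")
    if isinstance(dm, DescriptorMatrix):
        X = dm.values
    elif isinstance(dm, pd.DataFrame):
        X = dm.to_numpy(dtype=float)
    else:
        X = np.asarray(dm, dtype=float)
    y = _encode(list(labels))
    minority = min(np.sum(y == 1), np.sum(y == -1))
    if minority < 2:
        raise SVMError("each class needs at least 2 members for stratified CV")
    folds_used = int(min(folds, minority))
    skf = StratifiedKFold(n_splits=folds_used, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    if kernel_kind == "linear":
        gamma_grid = [1.0]  # γ is inert for the linear kernel

    grid: list[tuple[float, float, float]] = []
    best = None  # (acc, C, gamma)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            cfg = SVMConfig(C=C, kernel=KernelSpec(kernel_kind, gamma=gamma,
                                                   degree=degree, coef0=coef0))
            correct = 0
            for tr, te in splits:
                svc = _fit_svc(X[tr], y[tr], cfg)
                correct += int((svc.predict(X[te]) == y[te]).sum())
            acc = correct / len(y)
            grid.append((float(C), float(gamma), acc))
            if best is None or acc > best[0]:
                best = (acc, float(C), float(gamma))
    return GridSearchResult(
        grid=grid,
        best_C=best[1],
        best_gamma=best[2],
        best_accuracy=best[0],
        folds=folds_used,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plain-text model files

_MODEL_MAGIC = "bcrpsvm-model v1"


def save_model(model: TrainedModel, path: str | Path) -> None:
    lines = [
        _MODEL_MAGIC,
        f"kernel: {model.config.kernel.kind}",
        f"C: {model.config.C!r}",
        f"gamma: {model.config.kernel.gamma!r}",
        f"degree: {model.config.kernel.degree}",
        f"coef0: {model.config.kernel.coef0!r}",
        f"intercept: {model.intercept!r}",
        f"fingerprint: {model.fingerprint}",
        "features: " + "\t".join(model.feature_names),
    ]
    if model.scaling is not None:
        lines.append("scaling_min: " + "\t".join(repr(float(v)) for v in model.scaling.mins))
        lines.append("scaling_max: " + "\t".join(repr(float(v)) for v in model.scaling.maxs))
    lines.append(f"n_sv: {len(model.dual_coef)}")
    for coef, sv in zip(model.dual_coef, model.support_vectors):
        lines.append("\t".join([repr(float(coef))] + [repr(float(v)) for v in sv]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> TrainedModel:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _MODEL_MAGIC:
        raise SVMError(f"{path}: not a bcrpsvm model file")
    fields: dict[str, str] = {}
    i = 1
    while not lines[i].startswith("n_sv:"):
        key, val = lines[i].split(":", 1)
        fields[key.strip()] = val.strip()
        i += 1
    n_sv = int(lines[i].split(":", 1)[1])
    rows = [ln.split("\t") for ln in lines[i + 1 : i + 1 + n_sv]]
    dual = np.array([float(r[0]) for r in rows])
    svs = np.array([[float(v) for v in r[1:]] for r in rows])
    features = fields["features"].split("\t")
    scaling = None
    if "scaling_min" in fields:
        scaling = ScalingParams(
            columns=features,
            mins=np.array([float(v) for v in fields["scaling_min"].split("\t")]),
            maxs=np.array([float(v) for v in fields["scaling_max"].split("\t")]),
            fitted_on="loaded",
        )
    cfg = SVMConfig(
        C=float(fields["C"]),
        kernel=KernelSpec(
            fields["kernel"],
            gamma=float(fields["gamma"]),
            degree=int(fields["degree"]),
            coef0=float(fields["coef0"]),
        ),
    )
    return TrainedModel(
        feature_names=features,
        config=cfg,
        support_vectors=svs,
        dual_coef=dual,
        intercept=float(fields["intercept"]),
        scaling=scaling,
        fingerprint=fields.get("fingerprint", ""),
    )
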