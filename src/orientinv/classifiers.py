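"""Seven classifiers behind a single train/predict contract.

========  =======================================================
name      model and the fixed hyperparameters used by default
========  =======================================================
svm       RBF-kernel SVM, one-vs-one, C = 5, gamma = 0.1
ann       3-layer sigmoid network trained by back-propagation;
          hidden width = round(mean(log2(2K), 2K - 1)), learning
          rate 0.3, weights initialized uniformly in [0, 0.2],
          stops when the error reduction relative to the mean of
          the previous 10 epochs falls below 0.01
bdm       per-class multivariate Gaussian, own covariance (MAP)
ldc       as bdm but with the unweighted average of the per-class
          covariances shared by all classes (linear boundaries)
knn       k-nearest neighbours, k = 7, Euclidean distance
rf        random forest, 100 trees, information-gain splitting
omp       sparse-representation classifier: greedy orthogonal
          matching pursuit over the training dictionary, residual
          tolerance 1e-3, minimum class-restricted residual wins
========  =======================================================

SVM, k-NN and the random forest are backed by scikit-learn; the Bayesian
classifiers, the back-propagation network and the matching-pursuit
classifier are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

log = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("svm", "ann", "bdm", "ldc", "knn", "rf", "omp")


@dataclass
class ClassifierSpec:
    """Classifier selected by name, with optional hyperparameter overrides."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}")


# ---------------------------------------------------------------------------
# SVM parameter grids (two-level search used to fix C = 5, gamma = 0.1)
# ---------------------------------------------------------------------------

def svm_coarse_grid() -> tuple[np.ndarray, np.ndarray]:
    """Coarse (C, gamma) grid: decades -5..15 and -15..3 in hundredfold steps."""
    return 10.0 ** np.arange(-5, 16, 2), 10.0 ** np.arange(-15, 4, 2)


def svm_fine_grid() -> tuple[np.ndarray, np.ndarray]:
    """Fine grid 100*P x P around the coarse optimum (10, 0.1)."""
    P = np.array([0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.7, 1.0, 3.0, 5.0])
    return 100.0 * P, P


# ---------------------------------------------------------------------------
# Gaussian classifiers (BDM / LDC)
# ---------------------------------------------------------------------------

class GaussianClassifier:
    """Maximum-a-posteriori Gaussian classifier with equal priors.

    ``shared_covariance=False`` fits one covariance per class (quadratic
    boundaries); ``True`` uses the unweighted average of the per-class
    covariances for every class, which makes the boundaries hyperplanes.
    Singular covariances are ridge-regularized with a logged epsilon.
    """

    def __init__(self, shared_covariance: bool = False):
        self.shared_covariance = shared_covariance

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        d = X.shape[1]
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        covs = np.stack([np.cov(X[y == c].T, ddof=1).reshape(d, d)
                         for c in self.classes_])
        if self.shared_covariance:
            covs = np.broadcast_to(covs.mean(axis=0), covs.shape)
        self._factors = [self._factorize(c) for c in covs]
        return self

    @staticmethod
    def _factorize(cov: np.ndarray):
        eps = 0.0
        scale = max(np.trace(cov) / cov.shape[0], 1e-12)
        for _ in range(12):
            try:
                chol = linalg.cho_factor(cov + eps * np.eye(cov.shape[0]), lower=True)
                if eps:
                    log.info("ridge-regularized a singular class covariance "
                             "(epsilon=%.3g)", eps)
                logdet = 2.0 * np.log(np.diag(chol[0])).sum()
                return chol, logdet
            except linalg.LinAlgError:
                eps = max(eps * 10.0, scale * 1e-10)
        raise linalg.LinAlgError("covariance could not be regularized")

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class Gaussian log-likelihoods (up to a shared constant)."""
        X = np.asarray(X, dtype=float)
        scores = np.empty((X.shape[0], self.classes_.size))
        for k, (mean, (chol, logdet)) in enumerate(zip(self.means_, self._factors)):
            z = linalg.cho_solve(chol, (X - mean).T)
            scores[:, k] = -0.5 * (logdet + ((X - mean).T * z).sum(axis=0))
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]


# ---------------------------------------------------------------------------
# Back-propagation network (ANN)
# ---------------------------------------------------------------------------

def hidden_width(n_classes: int) -> int:
    """Hidden-layer width: nearest integer to the mean of log2(2K) and 2K-1.

    The two expressions bracket the number of hyperplanes needed when class
    boundaries intersect freely (optimistic) and when they are parallel
    (pessimistic).
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    k = float(n_classes)
    return int(round(0.5 * (np.log2(2.0 * k) + (2.0 * k - 1.0))))


class BackpropNetwork:
    """Three-layer sigmoid network trained by on-line back-propagation.

    One scalar output per class; prediction takes the largest output.  The
    epoch error is the mean over samples of the squared one-hot residual
    summed over outputs.  Training stops when the error reduction relative
    to the average of the previous ``patience`` epochs drops below
    ``stop_threshold`` (or at ``max_epochs``, as a safety cap).
    """

    def __init__(self, learning_rate: float = 0.3, init_range: float = 0.2,
                 stop_threshold: float = 0.01, patience: int = 10,
                 max_epochs: int = 1000, seed: int = 0):
        self.learning_rate = learning_rate
        self.init_range = init_range
        self.stop_threshold = stop_threshold
        self.patience = patience
        self.max_epochs = max_epochs
        self.seed = seed

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        k = self.classes_.size
        h = hidden_width(k)
        rng = np.random.default_rng(self.seed)
        d = X.shape[1]
        self.W1 = rng.uniform(0.0, self.init_range, size=(d + 1, h))
        self.W2 = rng.uniform(0.0, self.init_range, size=(h + 1, k))
        targets = (y[:, None] == self.classes_[None, :]).astype(float)

        lr = self.learning_rate
        history: list[float] = []
        for _epoch in range(self.max_epochs):
            sq_err = 0.0
            for i in range(X.shape[0]):
                x1 = np.append(X[i], 1.0)
                hid = self._sigmoid(x1 @ self.W1)
                h1 = np.append(hid, 1.0)
                out = self._sigmoid(h1 @ self.W2)
                err = targets[i] - out
                sq_err += float(err @ err)
                delta_out = err * out * (1.0 - out)
                delta_hid = (self.W2[:-1] @ delta_out) * hid * (1.0 - hid)
                self.W2 += lr * np.outer(h1, delta_out)
                self.W1 += lr * np.outer(x1, delta_hid)
            epoch_err = sq_err / X.shape[0]
            if len(history) >= self.patience:
                recent = float(np.mean(history[-self.patience:]))
                if recent - epoch_err < self.stop_threshold:
                    history.append(epoch_err)
                    break
            history.append(epoch_err)
        self.training_errors_ = history
        return self

    def _forward(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        ones = np.ones((X.shape[0], 1))
        hid = self._sigmoid(np.hstack([X, ones]) @ self.W1)
        return self._sigmoid(np.hstack([hid, ones]) @ self.W2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._forward(X), axis=1)]


# ---------------------------------------------------------------------------
# Orthogonal matching pursuit / sparse-representation classifier
# ---------------------------------------------------------------------------

def omp_sparse_code(x: np.ndarray, dictionary: np.ndarray, tol: float = 1e-3,
                    max_atoms: int | None = None):
    """Greedy sparse coding of ``x`` over unit-norm dictionary columns.

    At each iteration the column most correlated with the residual joins the
    support and the coefficients are refit by least squares, so the residual
    norm never increases.  Stops when the residual norm is <= ``tol`` or the
    support reaches ``max_atoms`` (default: the full dictionary).

    Returns ``(support, coefficients, residual_norm)``.
    """
    x = np.asarray(x, dtype=float)
    D = np.asarray(dictionary, dtype=float)
    n_atoms = D.shape[1]
    max_atoms = n_atoms if max_atoms is None else min(max_atoms, n_atoms)
    support: list[int] = []
    coef = np.zeros(0)
    r = x.copy()
    r_norm = float(np.linalg.norm(r))
    while r_norm > tol and len(support) < max_atoms:
        corr = np.abs(D.T @ r)
        corr[support] = -1.0
        j = int(np.argmax(corr))
        support.append(j)
        coef, *_ = np.linalg.lstsq(D[:, support], x, rcond=None)
        r = x - D[:, support] @ coef
        new_norm = float(np.linalg.norm(r))
        if new_norm >= r_norm - 1e-15:  # numerically stalled
            break
        r_norm = new_norm
    return support, coef, r_norm


class OmpClassifier:
    """Sparse-representation classification with class-wise residuals.

    Training stores the training vectors as a column dictionary with unit L2
    norm; test vectors are scaled to unit norm as well, so the residual
    tolerance acts relative to the test vector's magnitude.  After the global
    pursuit, the representation error using only each class's members of the
    selected support ranks the classes (``residual_mode='support'``); classes
    absent from the support score the full test norm.  With
    ``residual_mode='class_dict'`` the residual is instead the least-squares
    error over each class's complete dictionary.
    """

    def __init__(self, tol: float = 1e-3, residual_mode: str = "support",
                 max_atoms: int | None = None):
        if residual_mode not in ("support", "class_dict"):
            raise ValueError("residual_mode must be 'support' or 'class_dict'")
        self.tol = tol
        self.residual_mode = residual_mode
        self.max_atoms = max_atoms

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        norms = np.linalg.norm(X, axis=1)
        keep = norms > 0.0
        self._D = (X[keep] / norms[keep, None]).T
        self._labels = np.asarray(y)[keep]
        self.classes_ = np.unique(self._labels)
        return self

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        support, _, _ = omp_sparse_code(x, self._D, tol=self.tol,
                                        max_atoms=self.max_atoms)
        res = np.empty(self.classes_.size)
        for k, c in enumerate(self.classes_):
            if self.residual_mode == "support":
                cols = [j for j in support if self._labels[j] == c]
            else:
                cols = np.nonzero(self._labels == c)[0]
            if len(cols) == 0:
                res[k] = np.linalg.norm(x)
                continue
            coef, *_ = np.linalg.lstsq(self._D[:, cols], x, rcond=None)
            res[k] = np.linalg.norm(x - self._D[:, cols] @ coef)
        return res

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        norms = np.linalg.norm(X, axis=1)
        Xn = X / np.where(norms > 0.0, norms, 1.0)[:, None]
        return self.classes_[[int(np.argmin(self._residuals(x))) for x in Xn]]


# ---------------------------------------------------------------------------
# Factory and the train/predict contract
# ---------------------------------------------------------------------------

def make_classifier(spec: ClassifierSpec | str, seed: int = 0):
    """Instantiate an unfitted classifier from a spec or a name."""
    if isinstance(spec, str):
        spec = ClassifierSpec(spec)
    p = spec.params
    if spec.name == "svm":
        return SVC(C=p.get("C", 5.0), gamma=p.get("gamma", 0.1), kernel="rbf")
    if spec.name == "ann":
        return BackpropNetwork(seed=seed, **p)
    if spec.name == "bdm":
        return GaussianClassifier(shared_covariance=False)
    if spec.name == "ldc":
        return GaussianClassifier(shared_covariance=True)
    if spec.name == "knn":
        return KNeighborsClassifier(n_neighbors=p.get("k", 7))
    if spec.name == "rf":
        return RandomForestClassifier(
            n_estimators=p.get("n_trees", 100), criterion="entropy",
            max_features="sqrt", random_state=seed)
    return OmpClassifier(tol=p.get("tol", 1e-3),
                         residual_mode=p.get("residual_mode", "support"))


def train(spec: ClassifierSpec | str, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit the classifier named by ``spec`` and return the trained model.

    All stochastic classifiers draw their randomness from ``seed`` only, so a
    fixed seed reproduces the fitted model bit for bit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    return make_classifier(spec, seed=seed).fit(X, y)


def predict(model, X: np.ndarray) -> np.ndarray:
    """Predict labels; the feature dimension must match training."""
    X = np.asarray(X, dtype=float)
    expected = getattr(model, "n_features_in_", None)
    if expected is None and hasattr(model, "means_"):
        expected = model.means_.shape[1]
    elif expected is None and hasattr(model, "W1"):
        expected = model.W1.shape[0] - 1
    elif expected is None and hasattr(model, "_D"):
        expected = model._D.shape[0]
    if expected is not None and X.shape[1] != expected:
        raise ValueError(f"feature dimension {X.shape[1]} does not match "
                         f"training dimension {expected}")
    return model.predict(X)
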