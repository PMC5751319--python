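"""Gaussian kernel discriminant analysis and kernel reconstruction errors.

Kernel discriminant analysis (KDA) performs Fisher discriminant analysis
implicitly in the feature space induced by a kernel.  With the Gaussian
kernel

    K(x, y) = exp(-||x - y||^2 / s^2),

the discriminant directions are linear combinations of the mapped training
samples, w_k = sum_j a_jk phi(x_j), and the coefficient matrix ``alpha``
solves the generalized eigenproblem of the kernelized between-class scatter
M~ against the kernelized within-class scatter L~:

    M~ = sum_i N_i (M_i - M)(M_i - M)^T
    L~ = sum_i K_i (E - (1/N_i) 1) K_i^T

where ``M_i`` holds the class-mean kernel column, ``M`` the grand-mean
kernel column and ``K_i`` the N x N_i block of kernel values against class
``i``.  L~ has rank at most N - C, so a small ridge ``mu * I`` is added
before solving.

After the solve the retained columns of ``alpha`` are re-orthonormalized in
the kernel metric (a_k^T K a_l = delta_kl) so that the projected feature
map W = [w_1..w_d] is an orthonormal basis of the discriminant subspace.
That makes the kernel reconstruction error of any query x

    RE(x) = ||phi(x) - W t(x)||^2 = K(x, x) - ||t(x)||^2 = 1 - ||t(x)||^2

with t(x) the d-vector of projections -- the quantity the scale-selection
objective is built on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .dataset import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "gaussian_kernel",
    "kernel_matrix",
    "KDAModel",
    "fit_kda",
]


def gaussian_kernel(x, y, s: float) -> float:
    """Gaussian kernel exp(-||x-y||^2 / s^2) between two vectors.

    Always in (0, 1]; equals 1 iff x == y.
    """
    if s <= 0:
        raise ValueError(f"scale must be positive, got {s}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / s**2))


def kernel_matrix(X, s: float, Y=None) -> np.ndarray:
    """Pairwise Gaussian kernel table.

    With one argument: the symmetric N x N Gram matrix of ``X`` (unit
    diagonal).  With ``Y``: the rectangular table K(X_i, Y_j).
    """
    if s <= 0:
        raise ValueError(f"scale must be positive, got {s}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty sample collection")
    if Y is None:
        d2 = cdist(X, X, "sqeuclidean")
        K = np.exp(-d2 / s**2)
        # exact symmetry and unit diagonal despite float noise in cdist
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 1.0)
        return K
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    return np.exp(-cdist(X, Y, "sqeuclidean") / s**2)


def _scatter_matrices(K: np.ndarray, y: np.ndarray, class_sizes: np.ndarray):
    """Kernelized between- and within-class scatter (M~, L~) from a Gram matrix."""
    N = K.shape[0]
    M = K.mean(axis=1)  # grand mean column
    Mt = np.zeros((N, N))
    Lt = np.zeros((N, N))
    for c, Nc in enumerate(class_sizes):
        cols = np.flatnonzero(y == c)
        Ki = K[:, cols]  # N x Ni
        Mi = Ki.mean(axis=1)
        diff = Mi - M
        Mt += Nc * np.outer(diff, diff)
        # Ki (E - (1/Ni) 1) Ki^T == centered-block Gram; zero when Ni == 1
        if Nc > 1:
            Kc = Ki - Mi[:, None]
            Lt += Kc @ Ki.T
        else:
            logger.debug("class %d has a single sample; zero within-class block", c)
    Mt = 0.5 * (Mt + Mt.T)
    Lt = 0.5 * (Lt + Lt.T)
    return Mt, Lt


@dataclass
class KDAModel:
    """A fitted Gaussian KDA model.

    Attributes
    ----------
    train : LabeledDataset
        The training samples the kernel expansion runs over.
    scale : float
        Gaussian kernel scale parameter ``s``.
    alpha : ndarray of shape (N, d)
        Expansion coefficients; columns are kernel-orthonormal
        (``alpha[:, k] @ K @ alpha[:, l] == delta_kl``).
    d : int
        Retained discriminant dimension, ``1 <= d <= C - 1``.
    eigenvalues : ndarray of shape (d,)
        Generalized eigenvalues, largest first.
    between, within : ndarray of shape (N, N)
        The scatter matrices M~ and L~ the model was solved from.
    mu : float
        Ridge added to L~ before the eigensolve.
    """

    train: LabeledDataset
    scale: float
    alpha: np.ndarray
    d: int
    eigenvalues: np.ndarray
    between: np.ndarray
    within: np.ndarray
    mu: float

    def project(self, x) -> np.ndarray:
        """Discriminant coordinates t(x) = alpha^T [K(x, x_j)]_j.

        Accepts a single vector (returns shape ``(d,)``) or a matrix of
        query rows (returns shape ``(n, d)``).
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        q = np.atleast_2d(x)
        if q.shape[1] != self.train.n_features:
            raise ValueError(
                f"query dimension {q.shape[1]} != training dimension {self.train.n_features}"
            )
        kvec = kernel_matrix(q, self.scale, self.train.X)  # n x N
        coords = kvec @ self.alpha  # n x d
        return coords[0] if single else coords

    def reconstruction_error(self, x) -> np.ndarray | float:
        """Kernel reconstruction error RE(x) = 1 - ||t(x)||^2, clamped to [0, 1]."""
        coords = np.atleast_2d(self.project(x))
        re = 1.0 - np.sum(coords**2, axis=1)
        worst = float(np.max(np.maximum(-re, re - 1.0), initial=0.0))
        if worst > 1e-8:
            logger.warning("clamping reconstruction errors; violation %.3e", worst)
        re = np.clip(re, 0.0, 1.0)
        return float(re[0]) if np.asarray(x).ndim == 1 else re

    def to_json(self) -> str:
        """Serialize the model (training data included) to a JSON document."""
        payload = {
            "scale": self.scale,
            "d": self.d,
            "mu": self.mu,
            "eigenvalues": self.eigenvalues.tolist(),
            "alpha": self.alpha.tolist(),
            "train": {
                "X": self.train.X.tolist(),
                "y": self.train.y.tolist(),
                "ids": self.train.ids,
                "class_names": self.train.class_names,
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "KDAModel":
        """Rebuild a model serialized by :meth:`to_json` (scatter matrices recomputed)."""
        payload = json.loads(text)
        train = LabeledDataset(
            np.asarray(payload["train"]["X"]),
            np.asarray(payload["train"]["y"]),
            ids=payload["train"]["ids"],
            class_names=payload["train"]["class_names"],
        )
        K = kernel_matrix(train.X, payload["scale"])
        Mt, Lt = _scatter_matrices(K, train.y, train.class_sizes)
        return cls(
            train=train,
            scale=payload["scale"],
            alpha=np.asarray(payload["alpha"]),
            d=payload["d"],
            eigenvalues=np.asarray(payload["eigenvalues"]),
            between=Mt,
            within=Lt,
            mu=payload["mu"],
        )


def _kernel_orthonormalize(A: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Gram-Schmidt on the columns of A under the inner product <u, v> = u^T K v."""
    Q = np.zeros_like(A)
    for j in range(A.shape[1]):
        v = A[:, j].copy()
        for i in range(j):
            v -= (Q[:, i] @ (K @ v)) * Q[:, i]
        norm2 = float(v @ K @ v)
        if norm2 <= 1e-14:
            raise np.linalg.LinAlgError(
                "degenerate discriminant direction during kernel orthonormalization; "
                "try a larger regularization or a different scale"
            )
        Q[:, j] = v / np.sqrt(norm2)
    return Q


def fit_kda(data: LabeledDataset, s: float, d: int, mu: float | None = None) -> KDAModel:
    """Fit Gaussian KDA at scale ``s`` retaining ``d`` discriminant directions.

    Parameters
    ----------
    data : LabeledDataset
        Training samples; every class must be nonempty.
    s : float
        Gaussian kernel scale, > 0.
    d : int
        Number of retained eigenvectors; must satisfy ``1 <= d <= C - 1``.
    mu : float, optional
        Ridge added to the within-class scatter.  Default
        ``max(1e-8 * trace(L~) / N, 1e-12)``.

    Returns
    -------
    KDAModel
        With ``alpha`` kernel-orthonormal and eigenvalues sorted descending.
    """
    C = data.n_classes
    if not 1 <= d <= C - 1:
        raise ValueError(
            f"retained dimension d={d} violates 1 <= d <= C-1 = {C - 1} "
            f"(the discriminant subspace has at most C-1 directions)"
        )
    if s <= 0:
        raise ValueError(f"scale must be positive, got {s}")

    K = kernel_matrix(data.X, s)
    Mt, Lt = _scatter_matrices(K, data.y, data.class_sizes)
    N = data.n_samples
    if mu is None:
        mu = max(1e-8 * float(np.trace(Lt)) / N, 1e-12)
    Lreg = Lt + mu * np.eye(N)

    try:
        w, V = scipy.linalg.eigh(Mt, Lreg)
    except np.linalg.LinAlgError as err:  # pragma: no cover - scipy raises rarely here
        raise np.linalg.LinAlgError(
            f"generalized eigensolve failed ({err}); try a larger regularization mu"
        ) from err
    if not (np.all(np.isfinite(w)) and np.all(np.isfinite(V))):
        raise np.linalg.LinAlgError(
            "non-finite eigen-solution; try a larger regularization mu"
        )
    order = np.argsort(w)[::-1][:d]  # stable for ties: argsort then reversed slice
    eigenvalues = w[order]
    A = V[:, order]

    A = _kernel_orthonormalize(A, K)
    # deterministic sign: first coefficient of noticeable magnitude positive
    for k in range(d):
        col = A[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            A[:, k] = -col

    return KDAModel(
        train=data,
        scale=float(s),
        alpha=A,
        d=d,
        eigenvalues=eigenvalues,
        between=Mt,
        within=Lt,
        mu=float(mu),
    )
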