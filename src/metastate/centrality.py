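"""Node centrality on weighted functional networks.

Degree centrality is the weighted node strength, CD(i) = sum_j A_ij.
Eigenvector centrality is the leading eigenvector of the (nonnegative)
weighted adjacency matrix: CE = (1/lambda_1) A CE. Negative surviving
weights are zeroed before the eigenvector computation — Perron-Frobenius
guarantees a nonnegative leading eigenvector only for nonnegative matrices.

The per-window centrality vectors are z-normalized (mean 0, sample SD 1)
to form the samples handed to clustering.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LabeledMatrix
from .netbuild import WindowedNetworkSequence, _threshold_values

logger = logging.getLogger(__name__)

#: above this size the dense eigendecomposition gives way to power iteration
DENSE_MAX_N = 256
POWER_TOL = 1e-10
POWER_MAX_ITER = 10_000
#: relative gap below which the leading eigenvalue is treated as degenerate
DEGENERACY_TOL = 1e-10


@dataclasses.dataclass
class CentralitySequence:
    """Window x region matrix of z-normalized centrality scores."""

    scores: np.ndarray
    labels: list[str]
    kind: str  # "degree" | "eigenvector"
    density: float = 1.0
    constant_rows: list[int] = dataclasses.field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.scores.shape[0]


def _as_array(W) -> np.ndarray:
    if isinstance(W, LabeledMatrix):
        W.require_square_symmetric(atol=1e-9)
        return W.values
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(W, W.T, atol=1e-9):
        raise ValueError("adjacency must be symmetric")
    return W


def degree_centrality(W) -> np.ndarray:
    """Weighted strength: row sums excluding the diagonal."""
    A = _as_array(W)
    return A.sum(axis=1) - np.diag(A)


def _power_iteration(A: np.ndarray) -> tuple[float, np.ndarray]:
    n = A.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    for _ in range(POWER_MAX_ITER):
        w = A @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("centrality undefined: matrix annihilates the iterate")
        w /= norm
        new_lam = float(w @ A @ w)
        if abs(new_lam - lam) <= POWER_TOL * max(1.0, abs(new_lam)) and np.allclose(
            w, v, atol=POWER_TOL
        ):
            return new_lam, w
        v, lam = w, new_lam
    return lam, v


def eigenvector_centrality(W) -> np.ndarray:
    """Leading eigenvector of W, sign-fixed nonnegative, unit Euclidean norm.

    Negative entries are zeroed first. Raises on an all-zero matrix and on a
    degenerate (tied) leading eigenvalue. Disconnected graphs use the
    full-matrix eigenvector (mass concentrates on the dominant component);
    isolated nodes are logged.
    """
    A = _as_array(W).copy()
    np.fill_diagonal(A, 0.0)
    A[A < 0] = 0.0
    if not A.any():
        raise ValueError("centrality undefined for an all-zero matrix")
    strength = A.sum(axis=1)
    isolated = np.flatnonzero(strength == 0)
    if isolated.size:
        logger.warning("isolated nodes in eigenvector centrality: %s", isolated.tolist())
    n = A.shape[0]
    if n <= DENSE_MAX_N:
        vals, vecs = np.linalg.eigh(A)
        lam1, lam2 = vals[-1], vals[-2]
        if lam1 - lam2 <= DEGENERACY_TOL * max(1.0, abs(lam1)):
            raise ValueError("degenerate leading eigenvalue: centrality not unique")
        v = vecs[:, -1]
    else:
        lam1, v = _power_iteration(A)
    if v.sum() < 0:
        v = -v
    v[np.abs(v) < 1e-14] = 0.0
    if (v < 0).any():
        # numerically possible only for near-degenerate spectra
        v = np.abs(v)
    return v / np.linalg.norm(v)


def z_normalize_rows(scores: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Row-wise (x - mean) / sample SD; constant rows become all-zero and
    their indices are returned."""
    scores = np.asarray(scores, dtype=float)
    mean = scores.mean(axis=1, keepdims=True)
    sd = scores.std(axis=1, ddof=1, keepdims=True)
    # constant up to float rounding of the row mean
    scale = np.maximum(np.abs(mean), 1.0)
    constant = np.flatnonzero((sd <= 1e-12 * scale).ravel())
    sd = np.where(sd <= 1e-12 * scale, 0.0, sd)
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (scores - mean) / sd_safe
    out[constant] = 0.0
    return out, constant.tolist()


_KIND_FN = {"degree": degree_centrality, "eigenvector": eigenvector_centrality}


def centrality_sequence(
    wseq: WindowedNetworkSequence, kind: str = "eigenvector", density: float = 1.0
) -> CentralitySequence:
    """Per-window centrality on density-thresholded matrices, row z-normalized."""
    if kind not in _KIND_FN:
        raise ValueError(f"unknown centrality kind '{kind}'")
    fn = _KIND_FN[kind]
    rows = []
    for w, mat in enumerate(wseq.matrices):
        m = _threshold_values(mat, density) if density < 1.0 else mat
        try:
            rows.append(fn(m))
        except ValueError as exc:
            raise ValueError(f"window {w}: {exc}") from exc
    scores, constant = z_normalize_rows(np.stack(rows))
    if constant:
        logger.warning("constant centrality rows (zeroed): windows %s", constant)
    return CentralitySequence(
        scores=scores, labels=list(wseq.labels), kind=kind, density=density,
        constant_rows=constant,
    )


class WindowedCentrality(BaseEstimator, TransformerMixin):
    """Transformer from a windowed network sequence to z-scored centrality.

    ``density < 1`` applies proportional thresholding per window before the
    centrality computation (use 1.0 if the windows are already thresholded).
    """

    def __init__(self, kind: str = "eigenvector", density: float = 0.40):
        self.kind = kind
        self.density = density

    def fit(self, X, y=None):
        return self

    def transform(self, X: WindowedNetworkSequence) -> CentralitySequence:
        return centrality_sequence(X, kind=self.kind, density=self.density)
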