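"""Spearman correlation input layer for network estimation.

Rank correlations are the robust choice for ordinal Likert items: they are
invariant under monotone transforms of each item and less sensitive to the
coarse discreteness of 0-3 response scales than Pearson correlations.
Because a rank-correlation matrix is not guaranteed positive definite, a
spectral repair step is provided so that downstream log-determinant
likelihoods are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix with provenance.

    Attributes
    ----------
    values : (p, p) ndarray
        Symmetric matrix, unit diagonal, entries in [-1, 1].
    n_effective : int
        Number of complete observations the matrix was computed from.
    labels : list of str
        Variable names, aligned with rows/columns.
    """

    values: np.ndarray
    n_effective: int
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("correlation matrix must be square")
        if not self.labels:
            self.labels = [f"V{i}" for i in range(p)]
        if len(self.labels) != p:
            raise ValueError("labels length does not match matrix size")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def spearman_matrix(data) -> CorrelationMatrix:
    """Spearman (midrank) correlation matrix of a node data matrix.

    Parameters
    ----------
    data : DataFrame or (n, p) array
        Complete-case respondent x node matrix.

    Raises
    ------
    ValueError
        If fewer than 3 observations, or a column is constant (the offending
        node is named in the message).
    """
    if isinstance(data, pd.DataFrame):
        labels = list(data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        labels = [f"V{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations for Spearman correlation")
    if np.isnan(X).any():
        raise ValueError("missing values present; run complete-case filtering first")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s): {bad}")
    # midrank transform per column, then Pearson of ranks
    R = np.empty_like(X)
    for j in range(p):
        R[:, j] = stats.rankdata(X[:, j], method="average")
    C = np.corrcoef(R, rowvar=False)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    np.clip(C, -1.0, 1.0, out=C)
    return CorrelationMatrix(values=C, n_effective=n, labels=labels)


def nearest_positive_definite(C: CorrelationMatrix | np.ndarray, eps: float = 1e-6):
    """Repair a symmetric correlation matrix to be positive definite.

    Alternates eigenvalue clipping (floor ``eps``) with unit-diagonal
    restoration until the smallest eigenvalue clears the floor. A matrix
    that is already positive definite is returned unchanged.
    """
    if isinstance(C, CorrelationMatrix):
        A = C.values
        wrap = True
    else:
        A = np.asarray(C, dtype=float)
        wrap = False
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("input must be symmetric")
    w = np.linalg.eigvalsh(A)
    if w[0] >= eps:
        return C
    B = A.copy()
    for _ in range(200):
        w, V = np.linalg.eigh(B)
        if w[0] >= eps * (1 - 1e-9):
            break
        w = np.maximum(w, eps)
        B = (V * w) @ V.T
        B = 0.5 * (B + B.T)
        d = np.sqrt(np.diag(B))
        B = B / np.outer(d, d)
        np.fill_diagonal(B, 1.0)
    if wrap:
        return CorrelationMatrix(values=B, n_effective=C.n_effective, labels=list(C.labels))
    return B
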