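"""Sparse Gaussian graphical model estimation with EBIC model selection.

The estimated object is a regularized partial-correlation network: an L1
penalty (graphical lasso) shrinks conditional associations exactly to zero,
and the penalty weight is chosen by minimizing the extended Bayesian
information criterion

    EBIC(lambda) = -2 L + E log n + 4 E gamma log p

where L is the Gaussian log-likelihood of the penalized precision matrix,
E the number of retained edges, and gamma (default 0.5) the hyperprior
weight trading sparsity against fit. This mirrors the "EBICglasso"
procedure standard in network psychometrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glasso import _glasso_cd, _glasso_path_cd
from .association import CorrelationMatrix, nearest_positive_definite, spearman_matrix

#: entries of an iteratively computed precision matrix below this magnitude
#: are treated as structural zeros when counting edges
ZERO_TOL = 1e-10


class GlassoError(RuntimeError):
    """Raised when the penalized estimation fails to converge or the input
    is numerically unusable."""


@dataclass
class WeightedNetwork:
    """Symmetric partial-correlation network with node metadata."""

    weights: np.ndarray
    labels: list
    node_groups: dict | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        p = self.weights.shape[0]
        if self.weights.shape != (p, p):
            raise ValueError("weight matrix must be square")
        if len(self.labels) != p:
            raise ValueError("labels length does not match matrix size")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(np.abs(self.weights) >= 1):
            raise ValueError("partial correlations must lie in (-1, 1)")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(np.abs(self.weights[iu]) > ZERO_TOL))

    def edge_list(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(self.p, k=1)
        keep = np.abs(self.weights[iu, ju]) > ZERO_TOL
        return pd.DataFrame({
            "node_i": [self.labels[i] for i in iu[keep]],
            "node_j": [self.labels[j] for j in ju[keep]],
            "weight": self.weights[iu[keep], ju[keep]],
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)

    def to_graphml(self, path, partition=None) -> None:
        """Write the network as GraphML with edge ``weight`` attributes and
        node ``group`` (scale membership) / optional ``community``
        attributes."""
        import igraph as ig

        iu, ju = np.triu_indices(self.p, k=1)
        keep = np.abs(self.weights[iu, ju]) > ZERO_TOL
        g = ig.Graph(n=self.p, edges=list(zip(iu[keep].tolist(), ju[keep].tolist())))
        g.vs["name"] = list(self.labels)
        if self.node_groups:
            g.vs["group"] = [str(self.node_groups.get(l, "")) for l in self.labels]
        if partition is not None:
            memb = partition.membership_dict(self.labels) if hasattr(
                partition, "membership_dict") else partition
            g.vs["community"] = [int(memb[l]) for l in self.labels]
        g.es["weight"] = self.weights[iu[keep], ju[keep]].tolist()
        g.write_graphml(str(path))


@dataclass
class GlassoPath:
    """Penalty path with per-lambda precisions, likelihoods and EBIC values."""

    lambdas: np.ndarray
    precisions: np.ndarray  # (n_lam, p, p)
    logliks: np.ndarray
    ebics: np.ndarray
    selected_index: int
    nonmonotone_edge_counts: bool = False

    @property
    def edge_counts(self) -> np.ndarray:
        p = self.precisions.shape[1]
        iu = np.triu_indices(p, k=1)
        return np.array([
            np.count_nonzero(np.abs(K[iu]) > ZERO_TOL) for K in self.precisions
        ])


def lambda_grid(S, n_lambda: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced decreasing penalty grid from lambda_max (the largest
    absolute off-diagonal of S, at which the network is empty) down to
    ``lambda_max * min_ratio``."""
    A = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    p = A.shape[0]
    off = np.abs(A[~np.eye(p, dtype=bool)])
    lam_max = float(off.max()) if off.size else 0.0
    if lam_max <= 0:
        warnings.warn("all off-diagonal correlations are zero; using a single lambda=0")
        return np.array([0.0])
    if n_lambda == 1:
        return np.array([lam_max])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def glasso_fit(S, lam: float, max_outer: int = 200, tol: float = 1e-7,
               max_inner: int = 1000, inner_tol: float = 1e-9) -> np.ndarray:
    """Single graphical-lasso fit at penalty ``lam`` (diagonal unpenalized).

    Returns the penalized precision matrix with exact zeros on shrunk
    entries. ``lam = 0`` returns the unpenalized MLE ``inv(S)``.
    """
    A = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        sign, _ = np.linalg.slogdet(A)
        if sign <= 0:
            raise GlassoError("S is not positive definite; cannot invert at lam=0")
        return np.linalg.inv(A)
    p = A.shape[0]
    W = A.copy()
    B = np.zeros((p - 1, p))
    K, ok = _glasso_cd(A, float(lam), W, B, max_outer, tol, max_inner, inner_tol)
    if not ok:
        raise GlassoError(
            f"graphical lasso did not converge at lam={lam:.4g} "
            f"within {max_outer} sweeps (p={p})")
    _check_pd(K)
    return K


def glasso_objective(K: np.ndarray, S, lam: float) -> float:
    """Penalized negative log-likelihood (minimization form):
    -log det K + tr(SK) + lam * sum_{i!=j} |K_ij|."""
    A = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf
    off = np.abs(K).sum() - np.abs(np.diag(K)).sum()
    return -logdet + float(np.trace(A @ K)) + lam * off


def gaussian_loglik(S, K: np.ndarray, n: int) -> float:
    """Gaussian log-likelihood L = (n/2)(log det K - tr(S K)), additive
    constants dropped."""
    A = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise GlassoError("precision matrix is not positive definite")
    return 0.5 * n * (logdet - float(np.trace(A @ K)))


def ebic(L: float, K: np.ndarray, n: int, p: int, gamma: float = 0.5,
         zero_tol: float = ZERO_TOL) -> float:
    """Extended BIC: -2L + E log n + 4 E gamma log p, with E the number of
    nonzero upper-triangle off-diagonals of K. gamma=0 recovers BIC."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    iu = np.triu_indices(p, k=1)
    E = int(np.count_nonzero(np.abs(K[iu]) > zero_tol))
    return -2.0 * L + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def precision_to_partial(K: np.ndarray) -> np.ndarray:
    """Partial correlations rho_ij = -K_ij / sqrt(K_ii K_jj); zero diagonal."""
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    P = -K / np.sqrt(np.outer(d, d))
    P = 0.5 * (P + P.T)
    np.fill_diagonal(P, 0.0)
    return P


def _check_pd(K: np.ndarray) -> None:
    sign, _ = np.linalg.slogdet(K)
    if sign <= 0 or np.any(np.diag(K) <= 0):
        w = np.linalg.eigvalsh(0.5 * (K + K.T))
        raise GlassoError(f"estimated precision not PD; eigenvalues {w}")


def ebic_glasso_select(S, n: int, gamma: float = 0.5, n_lambda: int = 100,
                       min_ratio: float = 0.01, labels=None, node_groups=None,
                       tol: float = 1e-5, inner_tol: float = 1e-7,
                       ) -> tuple[WeightedNetwork, GlassoPath]:
    """Fit the penalty path and select the minimal-EBIC network.

    Parameters
    ----------
    S : CorrelationMatrix or array
        Input correlation matrix (PD-repaired internally if needed).
    n : int
        Sample size behind S, used in the likelihood and EBIC.
    gamma : float
        EBIC hyperparameter; 0.5 favors sparsity.

    Returns
    -------
    (WeightedNetwork, GlassoPath)
    """
    if isinstance(S, CorrelationMatrix):
        labels = labels if labels is not None else list(S.labels)
        S = nearest_positive_definite(S)
        A = S.values
    else:
        A = np.asarray(S, dtype=float)
        if np.linalg.eigvalsh(A)[0] < 1e-6:
            A = nearest_positive_definite(A)
    p = A.shape[0]
    if labels is None:
        labels = [f"V{i}" for i in range(p)]
    lambdas = lambda_grid(A, n_lambda=n_lambda, min_ratio=min_ratio)
    if lambdas[0] == 0.0:
        Ks = np.linalg.inv(A)[None, :, :]
        flags = np.ones(1, dtype=np.int64)
    else:
        Ks, flags = _glasso_path_cd(A, lambdas, 200, tol, 500, inner_tol)
    if not flags.all():
        bad = np.flatnonzero(flags == 0)
        raise GlassoError(f"path fit failed to converge at lambda indices {bad.tolist()}")
    logliks = np.array([gaussian_loglik(A, K, n) for K in Ks])
    ebics = np.array([ebic(L, K, n, p, gamma) for L, K in zip(logliks, Ks)])
    selected = int(np.argmin(ebics))
    path = GlassoPath(lambdas=lambdas, precisions=Ks, logliks=logliks,
                      ebics=ebics, selected_index=selected)
    counts = path.edge_counts
    path.nonmonotone_edge_counts = bool(np.any(np.diff(counts) < 0))
    K_sel = Ks[selected].copy()
    K_sel[np.abs(K_sel) <= ZERO_TOL] = 0.0
    np.fill_diagonal(K_sel, np.diag(Ks[selected]))
    W = precision_to_partial(K_sel)
    net = WeightedNetwork(
        weights=W, labels=list(labels), node_groups=node_groups,
        provenance={"gamma": gamma, "lambda": float(lambdas[selected]),
                    "n": int(n), "n_lambda": int(len(lambdas)),
                    "min_ratio": float(min_ratio)})
    return net, path


def estimate_network(data, gamma: float = 0.5, n_lambda: int = 100,
                     min_ratio: float = 0.01,
                     node_groups=None) -> tuple[WeightedNetwork, GlassoPath]:
    """Spearman correlations -> PD repair -> EBIC-glasso selection.

    The standard estimation route for ordinal item data; `data` is a
    complete-case DataFrame or array of respondents x nodes.
    """
    C = spearman_matrix(data)
    return ebic_glasso_select(C, n=C.n_effective, gamma=gamma,
                              n_lambda=n_lambda, min_ratio=min_ratio,
                              labels=C.labels, node_groups=node_groups)
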