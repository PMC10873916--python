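"""Synthetic ordinal survey data from known sparse Gaussian graphical models.

Generation follows the latent-Gaussian threshold model: a sparse
partial-correlation matrix defines (via the unit-diagonal precision
convention K_ii = 1, K_ij = -rho_ij) a multivariate Gaussian; latent draws
are discretized per node by ordered thresholds into Likert categories.
A two-group variant multiplies one group's nonzero partials by a global
factor and plants specific edge differences, emulating a contrast in which
one subpopulation's symptom network is uniformly more densely connected.

Every generator is fully seeded; identical seeds give identical tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CANONICAL_NODES, NODE_SCALES, ItemMeta, ItemResponseTable

#: minimum eigenvalue margin enforced on implied precision matrices
PD_MARGIN = 0.05


class PDRepairError(ValueError):
    """Raised when a generating partial-correlation matrix cannot be made
    positive definite."""


@dataclass
class SyntheticSpec:
    """Ground-truth generating model for one population.

    Attributes
    ----------
    n_respondents : int
        Default sample size for :func:`sample_ordinal_responses`.
    true_partial : (p, p) ndarray
        Symmetric zero-diagonal partial-correlation matrix.
    node_labels : list of str
    community_assignment : dict
        node label -> community id (contiguous ints).
    thresholds : list of ndarray
        Per-node strictly increasing latent cut-points; K cut-points yield
        K+1 ordinal categories.
    node_mins : list of int
        Smallest category value per node (0 for symptom/stressor items,
        1 for the 1-7 support items).
    seed : int
    """

    n_respondents: int
    true_partial: np.ndarray
    node_labels: list
    community_assignment: dict
    thresholds: list
    seed: int
    node_mins: list | None = None
    item_scales: dict | None = None

    def __post_init__(self):
        P = np.asarray(self.true_partial, dtype=float)
        p = P.shape[0]
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        if P.shape != (p, p) or not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("true_partial must be square symmetric")
        if np.any(np.diag(P) != 0):
            raise ValueError("true_partial must have zero diagonal")
        if np.any(np.abs(P) >= 1):
            raise ValueError("partial correlations must lie in (-1, 1)")
        if len(self.node_labels) != p or len(self.thresholds) != p:
            raise ValueError("labels/thresholds length mismatch")
        for t in self.thresholds:
            t = np.asarray(t, dtype=float)
            if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0):
                raise ValueError("thresholds must be strictly increasing, >= 1 cut")
        if set(self.community_assignment) != set(self.node_labels):
            raise ValueError("community assignment must cover exactly the nodes")
        if self.node_mins is None:
            self.node_mins = [0] * p
        self.true_partial = P
        w = np.linalg.eigvalsh(np.eye(p) - P)
        if w[0] <= 0:
            raise PDRepairError(f"implied precision not PD; min eigenvalue {w[0]:.4g}")

    @property
    def p(self) -> int:
        return self.true_partial.shape[0]

    def to_json(self, path) -> None:
        obj = {
            "n_respondents": self.n_respondents,
            "true_partial": self.true_partial.ravel().tolist(),
            "node_labels": list(self.node_labels),
            "community_assignment": {k: int(v) for k, v in self.community_assignment.items()},
            "thresholds": [np.asarray(t).tolist() for t in self.thresholds],
            "node_mins": list(self.node_mins),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            obj = json.load(fh)
        p = len(obj["node_labels"])
        return cls(
            n_respondents=obj["n_respondents"],
            true_partial=np.array(obj["true_partial"]).reshape(p, p),
            node_labels=obj["node_labels"],
            community_assignment=obj["community_assignment"],
            thresholds=[np.array(t) for t in obj["thresholds"]],
            node_mins=obj["node_mins"],
            seed=obj["seed"],
        )


@dataclass
class TwoGroupSpec:
    """Two-population contrast: group 1's nonzero partials are scaled by
    ``strength_multiplier`` and specific edge differences are planted on
    top, so group 1's true global strength exceeds group 0's whenever the
    multiplier exceeds 1."""

    base: SyntheticSpec
    strength_multiplier: float
    planted_edge_diffs: list = field(default_factory=list)
    group_sizes: tuple = (500, 500)

    def __post_init__(self):
        if self.strength_multiplier <= 0:
            raise ValueError("strength_multiplier must be positive")
        if any(s <= 0 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        labels = set(self.base.node_labels)
        for i, j, _ in self.planted_edge_diffs:
            if i not in labels or j not in labels or i == j:
                raise ValueError(f"planted edge ({i}, {j}) refers to invalid node pair")
        # validate both implied precisions are PD (construction repairs if needed)
        self.group_partial(0)
        self.group_partial(1)

    def group_partial(self, g: int) -> np.ndarray:
        P = self.base.true_partial.copy()
        if g == 1:
            P = P * self.strength_multiplier
            idx = {lab: k for k, lab in enumerate(self.base.node_labels)}
            for i, j, delta in self.planted_edge_diffs:
                a, b = idx[i], idx[j]
                P[a, b] += delta
                P[b, a] += delta
        return _repair_pd(P)

    def group_spec(self, g: int) -> SyntheticSpec:
        n = self.group_sizes[g]
        return replace(self.base, n_respondents=n, true_partial=self.group_partial(g),
                       seed=self.base.seed + g)

    def true_global_strength(self, g: int) -> float:
        P = self.group_partial(g)
        iu = np.triu_indices(P.shape[0], k=1)
        return float(np.abs(P[iu]).sum())


def _repair_pd(P: np.ndarray, margin: float = PD_MARGIN) -> np.ndarray:
    """Symmetric rescaling of the off-diagonals so the implied unit-diagonal
    precision I - P has min eigenvalue >= margin. Deterministic; preserves
    the sparsity pattern and relative weights."""
    p = P.shape[0]
    w = np.linalg.eigvalsh(np.eye(p) - P)
    lam_min = w[0]
    if lam_min >= margin:
        return P
    denom = 1.0 - lam_min
    if denom <= 0:
        raise PDRepairError("degenerate spectrum; cannot rescale to PD")
    c = (1.0 - margin) / denom
    out = P * c
    w2 = np.linalg.eigvalsh(np.eye(p) - out)
    if w2[0] < margin * (1 - 1e-9):
        raise PDRepairError(f"PD repair failed; min eigenvalue {w2[0]:.4g}")
    return out


def equal_probability_thresholds(n_categories: int) -> np.ndarray:
    """Standard-normal cut-points splitting the latent scale into
    ``n_categories`` equally probable ordinal bins."""
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    return stats.norm.ppf(np.arange(1, n_categories) / n_categories)


def make_random_sparse_ggm(p: int, edge_density: float, weight_range=(0.2, 0.4),
                           community_sizes: list | None = None, seed: int = 0,
                           n_respondents: int = 1000, n_categories: int = 4,
                           within_weight: float = 3.0,
                           negative_fraction: float = 0.0) -> SyntheticSpec:
    """Random sparse ground-truth network with optional planted communities.

    Exactly ``round(edge_density * p(p-1)/2)`` edges are drawn; when
    ``community_sizes`` is given, within-community pairs are ``within_weight``
    times as likely to carry an edge as between-community pairs. Edge
    magnitudes are uniform in ``weight_range``; the implied precision is
    made positive definite by deterministic off-diagonal rescaling.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = [f"V{i}" for i in range(p)]
    if community_sizes is None:
        comm = {lab: 0 for lab in labels}
    else:
        if sum(community_sizes) != p:
            raise ValueError("community sizes must sum to p")
        comm = {}
        k = 0
        for cid, size in enumerate(community_sizes):
            for _ in range(size):
                comm[labels[k]] = cid
                k += 1
    iu, ju = np.triu_indices(p, k=1)
    m = int(round(edge_density * len(iu)))
    P = np.zeros((p, p))
    if m > 0:
        cvec = np.array([comm[labels[i]] for i in range(p)])
        within = cvec[iu] == cvec[ju]
        probs = np.where(within, within_weight, 1.0).astype(float)
        probs /= probs.sum()
        chosen = rng.choice(len(iu), size=m, replace=False, p=probs)
        lo, hi = weight_range
        mags = rng.uniform(lo, hi, size=m)
        signs = np.where(rng.random(m) < negative_fraction, -1.0, 1.0)
        P[iu[chosen], ju[chosen]] = mags * signs
        P[ju[chosen], iu[chosen]] = mags * signs
    P = _repair_pd(P)
    thr = [equal_probability_thresholds(n_categories) for _ in range(p)]
    return SyntheticSpec(n_respondents=n_respondents, true_partial=P,
                         node_labels=labels, community_assignment=comm,
                         thresholds=thr, seed=seed)


def partial_to_precision(P: np.ndarray) -> np.ndarray:
    """Unit-diagonal precision implied by a partial-correlation matrix:
    K_ii = 1, K_ij = -rho_ij."""
    p = P.shape[0]
    return np.eye(p) - np.asarray(P, dtype=float)


def ggm_to_covariance(spec: SyntheticSpec | np.ndarray) -> np.ndarray:
    """Latent correlation matrix implied by the generating partials.

    Inverts the unit-diagonal precision and standardizes to unit variances
    (standardization leaves partial correlations untouched). Round-trips
    with :func:`netpsych.ggm.precision_to_partial` to within 1e-10.
    """
    P = spec.true_partial if isinstance(spec, SyntheticSpec) else np.asarray(spec)
    K = partial_to_precision(P)
    w = np.linalg.eigvalsh(K)
    if w[0] <= 0:
        raise PDRepairError(f"implied precision not PD; eigenvalues {w}")
    S = np.linalg.inv(K)
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return S


def sample_ordinal_responses(spec: SyntheticSpec, n: int | None = None,
                             seed: int | None = None) -> ItemResponseTable:
    """Draw latent multivariate-Gaussian scores and discretize each node by
    its thresholds into ordinal categories.

    A column that comes out constant (degenerate thresholds at this sample
    size) is flagged in the table's ``meta['constant_columns']``.
    """
    n = spec.n_respondents if n is None else n
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    S = ggm_to_covariance(spec)
    L = np.linalg.cholesky(S)
    Z = rng.standard_normal((n, spec.p)) @ L.T
    values = {}
    meta = {}
    constant = []
    for j, lab in enumerate(spec.node_labels):
        t = np.asarray(spec.thresholds[j], dtype=float)
        v = np.searchsorted(t, Z[:, j]) + spec.node_mins[j]
        values[lab] = v
        if len(np.unique(v)) == 1:
            constant.append(lab)
        scale = (spec.item_scales or {}).get(lab, NODE_SCALES.get(lab, "OTHER"))
        meta[lab] = ItemMeta(scale=scale, min=int(spec.node_mins[j]),
                             max=int(spec.node_mins[j] + len(t)))
    if constant:
        warnings.warn(f"constant column(s) after discretization: {constant}")
    table_meta = {"seed": seed, "constant_columns": constant}
    return ItemResponseTable(values=pd.DataFrame(values), item_meta=meta,
                             meta=table_meta)


def sample_two_group(tg: TwoGroupSpec, seed: int | None = None) -> ItemResponseTable:
    """Sample both groups and stack them with a binary ``group`` label
    (1 = the globally stronger network)."""
    seed = tg.base.seed if seed is None else seed
    frames, metas, glabels = [], {}, []
    for g in (0, 1):
        t = sample_ordinal_responses(tg.group_spec(g), n=tg.group_sizes[g],
                                     seed=seed + g)
        frames.append(t.values)
        metas.update(t.item_meta)
        glabels.extend([g] * tg.group_sizes[g])
    values = pd.concat(frames, ignore_index=True)
    return ItemResponseTable(values=values, item_meta=metas,
                             group=pd.Series(glabels, name="group"),
                             meta={"seed": seed})


def _study_true_partial(rng: np.random.Generator):
    """28-node generating network shaped like the study's analysis matrix:
    three scale-aligned symptom communities, cross-scale bridges, weak
    stressor->symptom edges and negative support->symptom edges (including
    support-from-family -> suicidality)."""
    labels = list(CANONICAL_NODES)
    idx = {lab: k for k, lab in enumerate(labels)}
    p = len(labels)
    P = np.zeros((p, p))

    def put(a, b, w):
        P[idx[a], idx[b]] = w
        P[idx[b], idx[a]] = w

    blocks = {
        0: [f"PHQ{i}" for i in range(1, 10)],
        1: [f"GAD{i}" for i in range(1, 8)],
        2: [f"IES{i}" for i in range(1, 7)],
    }
    # dense-ish chains plus random extras within each symptom scale
    for nodes in blocks.values():
        for a, b in zip(nodes[:-1], nodes[1:]):
            put(a, b, rng.uniform(0.22, 0.32))
        extra = max(1, len(nodes) - 3)
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 2:]]
        for k in rng.choice(len(pairs), size=extra, replace=False):
            put(*pairs[k], rng.uniform(0.12, 0.2))
    # cross-scale bridges between depression and anxiety, anxiety and stress
    put("PHQ2", "GAD2", rng.uniform(0.1, 0.16))
    put("PHQ4", "GAD4", rng.uniform(0.08, 0.14))
    put("GAD2", "IES2", rng.uniform(0.08, 0.14))
    put("IES1", "PHQ3", rng.uniform(0.06, 0.12))
    # stressor block: weakly interconnected, weak links into symptoms
    put("FW", "MF", 0.18)
    put("MF", "PHY", 0.15)
    put("FFC", "FW", 0.12)
    put("FFC", "GAD6", 0.10)   # conflict stress -- irritability
    put("PHY", "IES1", 0.10)
    put("FW", "PHQ4", 0.08)
    put("MF", "IES5", 0.07)
    # support nodes: mutually tied, negative edges into symptoms
    put("SSFm", "SSFr", 0.30)
    put("SSFm", "PHQ9", -0.09)  # family support -- suicidality
    put("SSFm", "PHQ3", -0.05)
    put("SSFm", "GAD6", -0.05)
    put("SSFr", "PHQ9", -0.05)
    comm = {lab: {"PHQ": 0, "GAD": 1, "IES": 2}.get(NODE_SCALES[lab], 3)
            for lab in labels}
    return labels, _repair_pd(P), comm


def make_study_fixture(seed: int = 0, group_sizes=(1500, 1500),
                       strength_multiplier: float = 1.3,
                       planted_edge_diffs: list | None = None,
                       ) -> tuple[ItemResponseTable, TwoGroupSpec]:
    """Study-shaped two-group fixture on the 28 canonical nodes.

    Group 1 plays the role of the subpopulation with the uniformly stronger
    network; on top of the global multiplier, a few specific edges are
    strengthened to give the per-edge comparison something to find.
    """
    rng = np.random.default_rng(seed)
    labels, P, comm = _study_true_partial(rng)
    thresholds = []
    mins = []
    for lab in labels:
        scale = NODE_SCALES[lab]
        if scale in ("PHQ", "GAD", "IES"):
            thresholds.append(equal_probability_thresholds(4))
            mins.append(0)
        elif scale == "STRESSOR":
            thresholds.append(equal_probability_thresholds(3))
            mins.append(0)
        else:  # SUPPORT, 1-7
            thresholds.append(equal_probability_thresholds(7))
            mins.append(1)
    base = SyntheticSpec(n_respondents=sum(group_sizes), true_partial=P,
                         node_labels=labels, community_assignment=comm,
                         thresholds=thresholds, node_mins=mins, seed=seed)
    if planted_edge_diffs is None:
        planted_edge_diffs = [
            ("PHQ9", "GAD1", 0.07),
            ("GAD4", "GAD7", 0.16),
            ("IES1", "PHY", 0.13),
        ]
    tg = TwoGroupSpec(base=base, strength_multiplier=strength_multiplier,
                      planted_edge_diffs=planted_edge_diffs,
                      group_sizes=tuple(group_sizes))
    table = sample_two_group(tg)
    return table, tg
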