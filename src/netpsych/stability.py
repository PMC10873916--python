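"""Bootstrap accuracy and stability of the estimated network.

Two resampling schemes, both re-running the full Spearman + EBIC-glasso
pipeline per replicate with the settings of the original fit:

* nonparametric bootstrap (resampling respondents with replacement) for
  edge-weight percentile CIs and bootstrapped difference tests;
* case-dropping bootstrap (subsampling without replacement at increasing
  drop proportions) for centrality stability, summarized by the
  CS-coefficient: the largest drop proportion at which, with the required
  certainty (default 95%), the subset expected-influence vector still
  correlates at least 0.7 with the full-sample one. CS >= 0.5 is the
  conventional bar for good stability.

Replicates whose estimation fails are excluded and counted, keeping the
resampling distribution honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ggm import GlassoError, estimate_network
from .metrics import expected_influence


@dataclass
class BootstrapEnsemble:
    """Replicate networks from the nonparametric bootstrap."""

    weights: np.ndarray        # (B_ok, p, p) replicate partial matrices
    eis: np.ndarray            # (B_ok, p) replicate expected influences
    labels: list
    seed: int
    settings: dict = field(default_factory=dict)
    n_failed: int = 0

    @property
    def B(self) -> int:
        return self.weights.shape[0]


@dataclass
class CaseDropProfile:
    """Correlation-with-full-sample distribution per drop proportion."""

    proportions: np.ndarray
    correlations: np.ndarray   # (n_prop, B), NaN where estimation failed
    seed: int
    flagged: list = field(default_factory=list)

    def quantile_frame(self) -> pd.DataFrame:
        q = np.nanquantile(self.correlations, [0.025, 0.5, 0.975], axis=1)
        return pd.DataFrame({"proportion": self.proportions,
                             "q2.5": q[0], "median": q[1], "q97.5": q[2]})


def nonparametric_bootstrap(data, B: int, seed: int, gamma: float = 0.5,
                            n_lambda: int = 100, min_ratio: float = 0.01,
                            indices: np.ndarray | None = None) -> BootstrapEnsemble:
    """Resample respondents with replacement B times and re-estimate the
    network per resample.

    ``indices`` (B, n) overrides the random resampling — passing the
    identity row reproduces the original estimate exactly, which is the
    degenerate-resample contract used in testing.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = data.values if hasattr(data, "values") else data
    X = pd.DataFrame(X)
    n = len(X)
    rng = np.random.default_rng(seed)
    if indices is None:
        indices = rng.integers(0, n, size=(B, n))
    weights, eis = [], []
    n_failed = 0
    for b in range(B):
        sub = X.iloc[indices[b]]
        try:
            net, _ = estimate_network(sub, gamma=gamma, n_lambda=n_lambda,
                                      min_ratio=min_ratio)
        except (GlassoError, ValueError):
            n_failed += 1
            continue
        weights.append(net.weights)
        eis.append(expected_influence(net))
    if not weights:
        raise GlassoError("every bootstrap replicate failed to estimate")
    return BootstrapEnsemble(weights=np.array(weights), eis=np.array(eis),
                             labels=list(X.columns), seed=seed,
                             settings={"gamma": gamma, "n_lambda": n_lambda,
                                       "min_ratio": min_ratio, "B": B},
                             n_failed=n_failed)


def edge_ci(ensemble: BootstrapEnsemble, level: float = 0.95) -> pd.DataFrame:
    """Percentile bootstrap CI per edge (upper-triangle pairs)."""
    if ensemble.B == 0:
        raise ValueError("empty ensemble")
    p = ensemble.weights.shape[1]
    iu, ju = np.triu_indices(p, k=1)
    vals = ensemble.weights[:, iu, ju]
    alpha = (1 - level) / 2
    lo = np.quantile(vals, alpha, axis=0)
    hi = np.quantile(vals, 1 - alpha, axis=0)
    return pd.DataFrame({
        "node_i": [ensemble.labels[i] for i in iu],
        "node_j": [ensemble.labels[j] for j in ju],
        "mean": vals.mean(axis=0), "lower": lo, "upper": hi,
    })


def difference_test(ensemble: BootstrapEnsemble, kind: str, a, b,
                    level: float = 0.95) -> dict:
    """Bootstrapped difference test between two edges or two nodes' EI.

    ``kind`` is "edge" (a, b are (node_i, node_j) label pairs) or "ei"
    (a, b are node labels). Significant iff the percentile CI of the
    difference excludes zero.
    """
    lab = {l: k for k, l in enumerate(ensemble.labels)}

    def series(el):
        if kind == "edge":
            i, j = el
            return ensemble.weights[:, lab[i], lab[j]]
        if kind == "ei":
            return ensemble.eis[:, lab[el]]
        raise ValueError("kind must be 'edge' or 'ei'")

    diff = series(a) - series(b)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(diff, [alpha, 1 - alpha])
    return {"significant": bool(lo > 0 or hi < 0), "ci_of_difference": (float(lo), float(hi)),
            "mean_difference": float(diff.mean())}


DEFAULT_PROPORTIONS = np.round(np.arange(0.05, 0.76, 0.05), 2)


def case_dropping_bootstrap(data, proportions=None, B: int = 100,
                            seed: int = 0, gamma: float = 0.5,
                            n_lambda: int = 100, min_ratio: float = 0.01,
                            cor_method: str = "spearman",
                            min_subset: int = 30) -> CaseDropProfile:
    """Case-dropping stability of expected influence.

    For each drop proportion, B subsamples of (1 - proportion) * n
    respondents are drawn without replacement, the network re-estimated and
    the subset EI vector correlated (Spearman by default) with the
    full-sample EI. Proportions whose subset is smaller than ``min_subset``
    or whose replicates all fail are flagged.
    """
    proportions = DEFAULT_PROPORTIONS if proportions is None else np.asarray(proportions, dtype=float)
    if np.any(np.diff(proportions) <= 0) or proportions.max() >= 1 or proportions.min() <= 0:
        raise ValueError("proportions must be strictly increasing within (0, 1)")
    X = pd.DataFrame(data.values if hasattr(data, "values") else data)
    n = len(X)
    net_full, _ = estimate_network(X, gamma=gamma, n_lambda=n_lambda, min_ratio=min_ratio)
    ei_full = expected_influence(net_full)
    rng = np.random.default_rng(seed)
    corr = np.full((len(proportions), B), np.nan)
    flagged = []
    corrfun = stats.spearmanr if cor_method == "spearman" else stats.pearsonr
    for pi, prop in enumerate(proportions):
        m = int(round((1 - prop) * n))
        if m < min_subset:
            flagged.append(float(prop))
            continue
        for b in range(B):
            idx = rng.choice(n, size=m, replace=False)
            try:
                net, _ = estimate_network(X.iloc[idx], gamma=gamma,
                                          n_lambda=n_lambda, min_ratio=min_ratio)
            except (GlassoError, ValueError):
                continue
            ei = expected_influence(net)
            if np.std(ei) == 0 or np.std(ei_full) == 0:
                r = 0.0
            else:
                r = corrfun(ei, ei_full)[0]
            corr[pi, b] = r
        if np.isnan(corr[pi]).all():
            flagged.append(float(prop))
    return CaseDropProfile(proportions=proportions, correlations=corr,
                           seed=seed, flagged=flagged)


def cs_coefficient(profile: CaseDropProfile, cor_threshold: float = 0.7,
                   certainty: float = 0.95) -> float:
    """Correlation-stability coefficient: the largest tested drop proportion
    at which at least ``certainty`` of subsamples correlate >= cor_threshold
    with the full-sample centrality; 0 if none does."""
    cs = 0.0
    for pi, prop in enumerate(profile.proportions):
        row = profile.correlations[pi]
        ok = row[~np.isnan(row)]
        if ok.size == 0:
            continue
        if (ok >= cor_threshold).mean() >= certainty:
            cs = float(prop)
    return cs
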