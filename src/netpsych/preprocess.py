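"""Raw survey items -> analysis-ready node matrix, plus descriptive statistics.

The raw input is a respondent x item table of ordinal responses: symptom
scales (PHQ-9 depression, GAD-7 anxiety, IES-6 acute/traumatic stress, all
0-3), stressor domain ratings (0-4), and two single-item social-support
ratings (1-7), with an optional binary group label. Preprocessing excludes
incomplete responses on the core measures, merges correlated stressor
domains by averaging, collapses stressor ratings to three levels, and
assembles the canonical node ordering used by the network stages. The
descriptive machinery (scale totals, probable caseness at a cutoff of 10,
Cronbach's alpha, 2x2 odds ratios) mirrors a standard symptom-survey
results table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SCALES = ("PHQ", "GAD", "IES", "STRESSOR", "SUPPORT", "OTHER")

#: canonical node ordering of the 28-node analysis matrix
CANONICAL_NODES = (
    [f"PHQ{i}" for i in range(1, 10)]
    + [f"GAD{i}" for i in range(1, 8)]
    + [f"IES{i}" for i in range(1, 7)]
    + ["FW", "PHY", "MF", "FFC", "SSFm", "SSFr"]
)

NODE_SCALES = {
    **{f"PHQ{i}": "PHQ" for i in range(1, 10)},
    **{f"GAD{i}": "GAD" for i in range(1, 8)},
    **{f"IES{i}": "IES" for i in range(1, 7)},
    "FW": "STRESSOR", "PHY": "STRESSOR", "MF": "STRESSOR", "FFC": "STRESSOR",
    "SSFm": "SUPPORT", "SSFr": "SUPPORT",
}


@dataclass
class ItemMeta:
    scale: str
    min: int
    max: int

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.min > self.max:
            raise ValueError("min must be <= max")


@dataclass
class ItemResponseTable:
    """Respondent x item ordinal matrix with item metadata and optional
    binary group label."""

    values: pd.DataFrame
    item_meta: dict  # item name -> ItemMeta
    group: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for col in self.values.columns:
            if col not in self.item_meta:
                raise ValueError(f"item {col!r} missing metadata")
            m = self.item_meta[col]
            v = self.values[col].dropna()
            if len(v) and ((v < m.min).any() or (v > m.max).any()):
                raise ValueError(f"item {col!r} has values outside [{m.min}, {m.max}]")
        if self.group is not None:
            g = pd.Series(self.group).dropna()
            if not set(g.unique()) <= {0, 1}:
                raise ValueError("group labels must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.values)

    def items_of_scale(self, scale: str) -> list:
        return [c for c in self.values.columns if self.item_meta[c].scale == scale]

    def to_csv(self, path) -> None:
        out = self.values.copy()
        if self.group is not None:
            out["group"] = self.group.values
        out.to_csv(path, index=False)


@dataclass
class NodeDataMatrix:
    """Complete-case respondent x node matrix feeding network estimation."""

    values: pd.DataFrame
    node_groups: dict  # node -> scale membership
    group: pd.Series | None = None

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("node matrix must be complete-case")
        for c in self.values.columns:
            if c not in self.node_groups:
                raise ValueError(f"node {c!r} missing group membership")

    @property
    def node_labels(self) -> list:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return len(self.values)


def filter_complete_cases(table: ItemResponseTable, core_items: list) -> ItemResponseTable:
    """Drop respondents missing any core item; the count removed is recorded
    in the returned table's ``meta['n_removed']``."""
    missing = [c for c in core_items if c not in table.values.columns]
    if missing:
        raise KeyError(f"core items not in table: {missing}")
    keep = table.values[core_items].notna().all(axis=1)
    if not keep.any():
        raise ValueError("no complete cases remain after filtering")
    values = table.values.loc[keep].reset_index(drop=True)
    group = table.group.loc[keep].reset_index(drop=True) if table.group is not None else None
    meta = dict(table.meta)
    meta["n_removed"] = int((~keep).sum())
    return ItemResponseTable(values=values, item_meta=table.item_meta,
                             group=group, meta=meta)


def score_scale(table: ItemResponseTable, scale_id: str) -> pd.Series:
    """Total score of a symptom scale: plain sum of its items."""
    items = table.items_of_scale(scale_id)
    if not items:
        raise ValueError(f"no items belong to scale {scale_id!r}")
    sub = table.values[items]
    if sub.isna().any().any():
        raise ValueError(f"missing values in scale {scale_id!r}; filter complete cases first")
    return sub.sum(axis=1)


def classify_probable_case(total, threshold: int = 10):
    """Probable caseness: total score >= threshold (default 10)."""
    t = np.asarray(total)
    if np.any(t < 0):
        raise ValueError("total scores must be nonnegative")
    return t >= threshold


def merge_stressor_domains(a, b):
    """Average two correlated stressor-domain ratings (each 0-4)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any((a < 0) | (a > 4)) or np.any((b < 0) | (b > 4)):
        raise ValueError("stressor ratings must lie in [0, 4]")
    return (a + b) / 2.0


def collapse_stressor_levels(rating):
    """Collapse a (possibly merged, fractional) stressor rating to
    0 = not stressful, 1 = a little stressful, 2 = stressful or worse.

    Boundary convention for fractional merged means: 0 -> 0, (0, 2) -> 1,
    >= 2 -> 2, preserving the 'two or more is stressful' anchor.
    """
    r = np.asarray(rating, dtype=float)
    if np.any(r < 0):
        raise ValueError("stressor ratings must be nonnegative")
    out = np.where(r >= 2, 2, np.where(r > 0, 1, 0))
    return out if out.ndim else int(out)


def cronbach_alpha(items) -> float:
    """Internal-consistency reliability:
    alpha = k/(k-1) * (1 - sum of item variances / variance of total)."""
    X = np.asarray(items, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    if np.isnan(X).any():
        raise ValueError("missing values not allowed")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of the total score")
    item_var = X.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1 - item_var / total_var)


def odds_ratio(table2x2) -> dict:
    """Odds ratio of a 2x2 table [[a, b], [c, d]] with Wald 95% CI and
    continuity-corrected chi-square p-value.

    A zero cell triggers the Haldane-Anscombe 0.5 correction for the OR and
    CI (flagged in the result); the chi-square test uses the raw counts.
    """
    T = np.asarray(table2x2, dtype=float)
    if T.shape != (2, 2) or np.any(T < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    corrected = bool(np.any(T == 0))
    Tc = T + 0.5 if corrected else T
    a, b, c, d = Tc.ravel()
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    ci = (math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se))
    if T.sum() > 0 and not np.any(T.sum(axis=0) == 0) and not np.any(T.sum(axis=1) == 0):
        _, p, _, _ = stats.chi2_contingency(T, correction=True)
    else:
        p = float("nan")
    return {"OR": or_, "CI95": ci, "p": p, "haldane_corrected": corrected}


def build_node_matrix(table: ItemResponseTable, merge_plan: list | None = None,
                      node_order: list | None = None) -> NodeDataMatrix:
    """Assemble the analysis node matrix.

    Symptom (PHQ/GAD/IES) and support items pass through unchanged; stressor
    domain pairs in ``merge_plan`` (item_a, item_b, new_name) are averaged
    then collapsed to three levels; unmerged stressor items are collapsed
    individually. Nodes are ordered canonically when ``node_order`` is not
    given: PHQ1..9, GAD1..7, IES1..6, then stressors, then support.
    """
    merge_plan = merge_plan or []
    if table.values.isna().any().any():
        raise ValueError("node matrix requires complete cases; filter first")
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    merged_sources = set()
    for a, b, name in merge_plan:
        for it in (a, b):
            if it not in table.values.columns:
                raise KeyError(f"merge plan references unknown item {it!r}")
            if table.item_meta[it].scale != "STRESSOR":
                raise ValueError(f"merge plan item {it!r} is not a stressor")
        merged = merge_stressor_domains(table.values[a], table.values[b])
        cols[name] = collapse_stressor_levels(merged)
        groups[name] = "STRESSOR"
        merged_sources.update((a, b))
    for c in table.values.columns:
        scale = table.item_meta[c].scale
        if scale == "STRESSOR":
            if c in merged_sources:
                continue
            cols[c] = collapse_stressor_levels(table.values[c].to_numpy(dtype=float))
        elif scale in ("PHQ", "GAD", "IES", "SUPPORT"):
            cols[c] = table.values[c].to_numpy(dtype=float)
        else:
            continue
        groups[c] = scale
    df = pd.DataFrame(cols)
    if node_order is None:
        order = [n for n in CANONICAL_NODES if n in df.columns]
        order += [n for n in df.columns if n not in order]
    else:
        unknown = [n for n in node_order if n not in df.columns]
        if unknown:
            raise KeyError(f"unknown nodes in requested order: {unknown}")
        order = list(node_order)
    df = df[order]
    return NodeDataMatrix(values=df, node_groups=groups, group=table.group)


def summary_table(table: ItemResponseTable, threshold: int = 10) -> pd.DataFrame:
    """Descriptive summary mirroring a sample-characteristics table:
    per-scale caseness counts/percentages overall and by group, with odds
    ratios for the group contrast when a group label is present."""
    rows = []
    for scale in ("PHQ", "GAD", "IES"):
        if not table.items_of_scale(scale):
            continue
        total = score_scale(table, scale)
        case = classify_probable_case(total, threshold)
        row = {"scale": scale, "n": table.n,
               "n_cases": int(case.sum()),
               "pct_cases": 100.0 * case.mean(),
               "alpha": cronbach_alpha(table.values[table.items_of_scale(scale)])}
        if table.group is not None:
            g = table.group.to_numpy()
            t2 = np.array([
                [int((case & (g == 1)).sum()), int((~case & (g == 1)).sum())],
                [int((case & (g == 0)).sum()), int((~case & (g == 0)).sum())],
            ])
            orr = odds_ratio(t2)
            row.update(OR=orr["OR"], OR_lo=orr["CI95"][0], OR_hi=orr["CI95"][1],
                       OR_p=orr["p"])
        rows.append(row)
    return pd.DataFrame(rows)
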