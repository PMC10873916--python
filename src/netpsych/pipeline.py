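"""End-to-end analysis driver: estimation, inference, stability,
communities and (optionally) two-group comparison in one call.

A single global seed spawns independent per-stage RNG streams, so enabling
or disabling a stage never perturbs another stage's draws, and a run is
reproducible bit-for-bit from the manifest alone. All artifacts are
written as CSV/JSON into the configured output directory, cross-referenced
in ``manifest.json``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import spearman_matrix
from .communities import CommunityPartition, adjusted_rand_index, ega
from .comparison import edge_difference_report, nct
from .ggm import ZERO_TOL, WeightedNetwork, ebic_glasso_select
from .metrics import centrality_table, global_strength
from .preprocess import NODE_SCALES, NodeDataMatrix
from .stability import (case_dropping_bootstrap, cs_coefficient, edge_ci,
                        nonparametric_bootstrap)
from .synthetic import TwoGroupSpec, make_study_fixture


@dataclass
class AnalysisConfig:
    """Settings for one full analysis run."""

    input_path: str | None = None
    output_dir: str = "netpsych_run"
    group_col: str | None = None
    gamma: float = 0.5
    n_lambda: int = 100
    min_ratio: float = 0.01
    bootstrap_B: int = 1000
    casedrop_B: int = 100
    casedrop_proportions: list = field(
        default_factory=lambda: np.round(np.arange(0.05, 0.76, 0.05), 2).tolist())
    nct_n_perm: int = 1000
    nct_seed: int = 123
    seed: int = 0
    walktrap_steps: int = 4

    def __post_init__(self):
        if self.bootstrap_B < 1 or self.casedrop_B < 1 or self.nct_n_perm < 1:
            raise ValueError("B and n_perm settings must be >= 1")
        for name in ("seed", "nct_seed"):
            if int(getattr(self, name)) != getattr(self, name):
                raise ValueError(f"{name} must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class ReportBundle:
    """Outputs of one run, with the manifest that reproduces it."""

    networks: dict            # name -> WeightedNetwork
    centrality: dict          # name -> DataFrame
    partitions: dict          # name -> CommunityPartition
    edge_cis: pd.DataFrame | None
    casedrop_cs: float | None
    nct_result: object | None
    manifest: dict
    out_dir: Path


def _stage_seeds(seed: int, names) -> dict:
    """Independent, reproducible per-stage integer seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: int(c.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
            for name, c in zip(names, children)}


def _write_network(net: WeightedNetwork, out: Path, name: str, manifest: dict) -> None:
    adj = out / f"network_{name}_adjacency.csv"
    net.to_frame().to_csv(adj)
    edges = out / f"network_{name}_edges.csv"
    net.edge_list().to_csv(edges, index=False)
    prov = out / f"network_{name}_provenance.json"
    with open(prov, "w") as fh:
        json.dump(net.provenance, fh, indent=1)
    manifest["files"] += [adj.name, edges.name, prov.name]


def run_full_analysis(config: AnalysisConfig, data=None) -> ReportBundle:
    """Execute the whole pipeline under one config.

    ``data`` may be a prebuilt :class:`NodeDataMatrix` or a DataFrame whose
    columns are the analysis nodes (plus an optional group column named by
    ``config.group_col``); otherwise ``config.input_path`` is read as CSV.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": asdict(config), "files": [],
                "stage_seeds": _stage_seeds(config.seed,
                                            ["bootstrap", "casedrop", "nct", "simulation"]),
                "counts": {}}
    try:
        if isinstance(data, NodeDataMatrix):
            df = data.values.copy()
            group = data.group
        else:
            if data is None:
                if config.input_path is None:
                    raise ValueError("config.input_path required when no data is passed")
                data = pd.read_csv(config.input_path)
            df = pd.DataFrame(data).copy()
            group = None
            if config.group_col is not None:
                if config.group_col not in df.columns:
                    raise ValueError(f"group column {config.group_col!r} not found")
                group = df.pop(config.group_col)
        df = df.dropna().reset_index(drop=True)
        if group is not None:
            group = group.loc[:len(df) - 1].reset_index(drop=True)
        node_groups = {c: NODE_SCALES.get(c, "OTHER") for c in df.columns}

        # --- estimation -------------------------------------------------
        C = spearman_matrix(df)
        net, path = ebic_glasso_select(C, n=C.n_effective, gamma=config.gamma,
                                       n_lambda=config.n_lambda,
                                       min_ratio=config.min_ratio,
                                       labels=C.labels, node_groups=node_groups)
        networks = {"overall": net}

        # --- communities ------------------------------------------------
        partitions: dict[str, CommunityPartition] = {}
        _, part = ega(df, gamma=config.gamma, steps=config.walktrap_steps,
                      n_lambda=config.n_lambda, min_ratio=config.min_ratio)
        partitions["overall"] = part

        # --- metrics ----------------------------------------------------
        centrality = {"overall": centrality_table(net, partition=part, data=df,
                                                  zscore=True)}

        # --- stability --------------------------------------------------
        ens = nonparametric_bootstrap(df, B=config.bootstrap_B,
                                      seed=manifest["stage_seeds"]["bootstrap"],
                                      gamma=config.gamma, n_lambda=config.n_lambda,
                                      min_ratio=config.min_ratio)
        cis = edge_ci(ens)
        manifest["counts"]["bootstrap_failed"] = ens.n_failed
        profile = case_dropping_bootstrap(
            df, proportions=np.asarray(config.casedrop_proportions),
            B=config.casedrop_B, seed=manifest["stage_seeds"]["casedrop"],
            gamma=config.gamma, n_lambda=config.n_lambda, min_ratio=config.min_ratio)
        cs = cs_coefficient(profile)

        # --- two-group comparison --------------------------------------
        nct_result = None
        if group is not None:
            g = np.asarray(group)
            for gval, name in ((1, "group1"), (0, "group0")):
                sub = df.loc[g == gval]
                Cg = spearman_matrix(sub)
                ng, _ = ebic_glasso_select(Cg, n=Cg.n_effective, gamma=config.gamma,
                                           n_lambda=config.n_lambda,
                                           min_ratio=config.min_ratio,
                                           labels=Cg.labels, node_groups=node_groups)
                networks[name] = ng
                _, pg = ega(sub, gamma=config.gamma, steps=config.walktrap_steps,
                            n_lambda=config.n_lambda, min_ratio=config.min_ratio)
                partitions[name] = pg
                centrality[name] = centrality_table(ng, partition=pg, data=sub,
                                                    zscore=True)
            nct_result = nct(df.loc[g == 1], df.loc[g == 0],
                             n_perm=config.nct_n_perm, seed=config.nct_seed,
                             gamma=config.gamma, n_lambda=config.n_lambda,
                             min_ratio=config.min_ratio)
            manifest["counts"]["nct_retried"] = nct_result.n_retried

        # --- write artifacts -------------------------------------------
        for name, nw in networks.items():
            _write_network(nw, out, name, manifest)
        for name, tab in centrality.items():
            f = out / f"centrality_{name}.csv"
            tab.to_csv(f)
            manifest["files"].append(f.name)
        for name, pt in partitions.items():
            f = out / f"communities_{name}.csv"
            pt.to_frame().to_csv(f, index=False)
            manifest["files"].append(f.name)
            gml = out / f"network_{name}.graphml"
            networks[name].to_graphml(gml, partition=pt)
            d = out / f"dendrogram_{name}.json"
            with open(d, "w") as fh:
                json.dump({"merges": [list(m) for m in pt.merges]}, fh)
            manifest["files"] += [gml.name, d.name]
        cis.to_csv(out / "edge_bootstrap_ci.csv", index=False)
        profile.quantile_frame().to_csv(out / "casedrop_profile.csv", index=False)
        manifest["files"] += ["edge_bootstrap_ci.csv", "casedrop_profile.csv"]
        stability_summary = {"cs_coefficient": cs,
                             "bootstrap_B": ens.B, "bootstrap_failed": ens.n_failed}
        with open(out / "stability_summary.json", "w") as fh:
            json.dump(stability_summary, fh, indent=1)
        manifest["files"].append("stability_summary.json")
        if nct_result is not None:
            with open(out / "nct_result.json", "w") as fh:
                json.dump(nct_result.to_dict(), fh, indent=1)
            nct_result.edge_table.to_csv(out / "nct_edge_table.csv", index=False)
            edge_difference_report(nct_result).to_csv(
                out / "nct_significant_edges.csv", index=False)
            manifest["files"] += ["nct_result.json", "nct_edge_table.csv",
                                  "nct_significant_edges.csv"]
    except Exception:
        with open(out / "FAILED", "w") as fh:
            fh.write("run aborted; see traceback\n")
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return ReportBundle(networks=networks, centrality=centrality,
                        partitions=partitions, edge_cis=cis, casedrop_cs=cs,
                        nct_result=nct_result, manifest=manifest, out_dir=out)


def score_recovery(net: WeightedNetwork, true_partial: np.ndarray,
                   partition: CommunityPartition | None = None,
                   true_communities=None) -> dict:
    """Edge-recovery and community-recovery scores against ground truth."""
    p = net.p
    iu = np.triu_indices(p, k=1)
    est = np.abs(net.weights[iu]) > ZERO_TOL
    true = np.abs(np.asarray(true_partial)[iu]) > 0
    tp = int((est & true).sum())
    fn = int((~est & true).sum())
    fp = int((est & ~true).sum())
    tn = int((~est & ~true).sum())
    out = {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_true_edges": tp + fn, "n_estimated_edges": tp + fp,
    }
    if partition is not None and true_communities is not None:
        truth = np.array([true_communities[lab] for lab in net.labels])
        out["community_ari"] = adjusted_rand_index(partition.membership, truth)
    return out


def simulate_and_run(seed: int = 0, config: AnalysisConfig | None = None,
                     two_group: TwoGroupSpec | None = None,
                     group_sizes=(1500, 1500), strength_multiplier: float = 1.3,
                     ) -> tuple[ReportBundle, dict]:
    """Generate the study-shaped fixture, run the full pipeline on it, and
    score estimation against the generating truth."""
    if two_group is None:
        table, two_group = make_study_fixture(seed=seed, group_sizes=group_sizes,
                                              strength_multiplier=strength_multiplier)
    else:
        from .synthetic import sample_two_group
        table = sample_two_group(two_group, seed=seed)
    if config is None:
        config = AnalysisConfig(seed=seed)
    df = table.values.copy()
    df["group"] = table.group.values
    config.group_col = "group"
    bundle = run_full_analysis(config, data=df)
    base = two_group.base
    recovery = score_recovery(bundle.networks["overall"], base.true_partial,
                              partition=bundle.partitions["overall"],
                              true_communities=base.community_assignment)
    gs1 = global_strength(bundle.networks["group1"])
    gs0 = global_strength(bundle.networks["group0"])
    recovery.update({
        "estimated_global_strength_group1": gs1,
        "estimated_global_strength_group0": gs0,
        "true_global_strength_group1": two_group.true_global_strength(1),
        "true_global_strength_group0": two_group.true_global_strength(0),
        "strength_ordering_correct": bool(
            (gs1 > gs0) == (two_group.true_global_strength(1)
                            > two_group.true_global_strength(0))),
    })
    with open(bundle.out_dir / "recovery_report.json", "w") as fh:
        json.dump(recovery, fh, indent=1)
    bundle.manifest["files"].append("recovery_report.json")
    return bundle, recovery
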