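"""End-to-end orchestration: load, filter, impute, fit, bootstrap, report.

A single seeded run produces the fitted moderated network (JSON plus
per-group weighted edge lists and GraphML), the bootstrap stability
table, local network metrics with between-group correlations, a
characteristics-table comparison of the moderator groups, trajectory
features with the Louvain partition when prescription records are given,
and a fixed force-directed layout shared by all group renderings. Every
output records the seeds used; identical config and seed reproduce
byte-identical numeric outputs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .datasets import SymptomDataset
from .preprocess import apply_missingness_filter, impute_items
from .mgm import EstimatorConfig, ModeratedMGM, fit_moderated_mgm
from .stability import moderation_stability
from .net_metrics import compare_metrics, compute_local_metrics
from .cohort_stats import compare_groups
from .trajectories import louvain_subgroups, trajectory_features, PrescriptionRecord, FEATURE_COLUMNS

__all__ = ["RunConfig", "run_pipeline", "layout_positions"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    symptoms_csv: str | None = None
    prescriptions_csv: str | None = None
    group_levels: tuple[str, ...] = ("NAC", "ADHD-nostim", "ADHD-stim")
    seed: int = 0
    bootstrap_B: int = 500
    run_bootstrap: bool = True
    max_missing_fraction: float = 0.5
    imputation_m: int = 5
    imputation_iterations: int = 10
    complete_cases_only: bool = False
    covariate_nodes: tuple[str, ...] = ()
    gamma: float = 0.5
    rule: str = "OR"
    reference_group: str | None = None
    clustering_variant: str = "zhang"
    min_community_size: int = 10
    dex_equivalence: float = 2.0
    output_dir: str = "modnet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("group_levels", "covariate_nodes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def estimator_config(self) -> EstimatorConfig:
        return EstimatorConfig(
            gamma=self.gamma,
            rule=self.rule,
            reference_group=self.reference_group,
            covariate_nodes=tuple(self.covariate_nodes),
        )


def layout_positions(
    W: np.ndarray, nodes: tuple[str, ...], seed: int | None = 0
) -> pd.DataFrame:
    """Force-directed (Fruchterman-Reingold) 2-D layout of one network.

    Computed once on a reference network (typically the shared base) and
    reused for every group rendering so the layouts stay comparable.
    Edge weights enter as attraction strengths via their absolute value.
    """
    if len(nodes) == 0:
        raise ValueError("empty network")
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if W[i, j] != 0:
                G.add_edge(nodes[i], nodes[j], weight=abs(float(W[i, j])))
    pos = nx.spring_layout(G, weight="weight", seed=seed)
    return pd.DataFrame(
        [{"node": n, "x": float(p[0]), "y": float(p[1])} for n, p in pos.items()]
    )


def _export_graphml(model: ModeratedMGM, group: str, path: Path) -> None:
    W = model.condition_on_group(group)
    G = nx.Graph()
    G.add_nodes_from(model.nodes)
    for i in range(len(model.nodes)):
        for j in range(i + 1, len(model.nodes)):
            if W[i, j] != 0:
                G.add_edge(model.nodes[i], model.nodes[j], weight=float(W[i, j]))
    nx.write_graphml(G, path)


def _cohort_table(dataset: SymptomDataset) -> pd.DataFrame:
    df = pd.concat(
        [
            dataset.groups.rename("group"),
            dataset.covariates,
            dataset.items.sum(axis=1, skipna=False).rename("symptom_sum"),
        ],
        axis=1,
    )
    present = [g for g in dataset.group_levels if g in set(df["group"])]
    frames = []
    for a, b in itertools.combinations(present, 2):
        tab = compare_groups(
            df, "group", a, b,
            continuous=["age"], binary=["sex"], ordinal=["symptom_sum"],
        )
        tab.insert(0, "comparison", f"{a} vs {b}")
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def _load_prescriptions(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, parse_dates=["birth_date", "assessment_date", "start_date", "end_date"]
    )
    required = {
        "participant_id", "birth_date", "assessment_date",
        "start_date", "end_date", "drug", "dose_mg_per_day",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prescription CSV lacks columns: {sorted(missing)}")
    return df


def _trajectory_stage(config: RunConfig, outdir: Path, log: dict) -> None:
    df = _load_prescriptions(config.prescriptions_csv)
    rows = []
    for pid, grp in df.groupby("participant_id", sort=True):
        records = [
            PrescriptionRecord(
                participant_id=str(pid),
                start_date=r.start_date.date(),
                end_date=r.end_date.date(),
                drug=r.drug,
                dose_mg_per_day=float(r.dose_mg_per_day),
            )
            for r in grp.itertuples()
        ]
        feats = trajectory_features(
            records,
            birth=grp["birth_date"].iloc[0].date(),
            assessment=grp["assessment_date"].iloc[0].date(),
            participant_id=str(pid),
            dex_equivalence=config.dex_equivalence,
        )
        rows.append(feats.as_row())
    feat_df = pd.DataFrame(rows).set_index("participant_id")
    treated = feat_df[~feat_df["never_treated"]][list(FEATURE_COLUMNS)]
    partition = louvain_subgroups(
        treated, min_community_size=config.min_community_size, seed=config.seed
    )
    feat_df["community"] = partition.labels
    feat_df["community_excluded"] = feat_df["community"].map(
        lambda c: partition.excluded.get(c, "") if pd.notna(c) else ""
    )
    feat_df.to_csv(outdir / "trajectory_features.csv")
    log["trajectories"] = {
        "n_participants": int(len(feat_df)),
        "n_never_treated": int(feat_df["never_treated"].sum()),
        "modularity_Q": partition.modularity,
        "community_sizes": {int(k): int(v) for k, v in partition.community_sizes.items()},
        "excluded_communities": partition.excluded,
    }


def run_pipeline(
    config: RunConfig, dataset: SymptomDataset | None = None
) -> dict:
    """Execute every configured stage; returns the stage log as a dict.

    ``dataset`` may be passed directly instead of ``config.symptoms_csv``.
    Any stage failure aborts with the stage name and cause.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    from importlib.metadata import version as _v
    try:
        pkg_version = _v("modnet")
    except Exception:
        pkg_version = "unknown"
    log: dict = {"seed": config.seed, "modnet_version": pkg_version, "stages": []}

    def stage(name):
        log["stages"].append(name)
        return name

    try:
        stage("load")
        if dataset is None:
            if config.symptoms_csv is None:
                raise ValueError("no symptom data: give a dataset or symptoms_csv")
            dataset = SymptomDataset.from_csv(
                config.symptoms_csv, group_levels=tuple(config.group_levels)
            )

        stage("missingness_filter")
        filtered, exclusions = apply_missingness_filter(
            dataset, max_missing_fraction=config.max_missing_fraction
        )
        exclusions.excluded.to_csv(outdir / "exclusions.csv", index=False)
        log["exclusions"] = int(exclusions.n_excluded)

        if config.complete_cases_only:
            stage("complete_cases")
            keep = ~filtered.missing_mask.any(axis=1)
            filtered = SymptomDataset(
                items=filtered.items.loc[keep],
                groups=filtered.groups.loc[keep],
                covariates=filtered.covariates.loc[keep],
                group_levels=filtered.group_levels,
            )
            log["imputation"] = "skipped (complete cases only)"
            completed = [filtered]
        else:
            stage("imputation")
            completed = impute_items(
                filtered,
                m=config.imputation_m,
                iterations=config.imputation_iterations,
                seed=config.seed,
            )
            log["imputation"] = {
                "m": config.imputation_m,
                "n_missing": int(filtered.items.isna().sum().sum()),
            }

        stage("fit")
        est_config = config.estimator_config()
        model = fit_moderated_mgm(completed, est_config)
        model.to_json(outdir / "model.json")
        for g in model.groups:
            safe = g.replace("/", "_")
            model.edge_list(g).to_csv(outdir / f"edges_{safe}.csv", index=False)
            _export_graphml(model, g, outdir / f"network_{safe}.graphml")
        log["moderation_effects"] = len(model.moderation)

        if config.run_bootstrap:
            stage("bootstrap")
            first = completed[0]
            report = moderation_stability(
                first, est_config, B=config.bootstrap_B, seed=config.seed,
                reference_model=model,
            )
            report.to_csv(outdir / "stability.csv")
            log["bootstrap"] = {"B": config.bootstrap_B}

        stage("metrics")
        metric_frames = []
        per_group = {}
        for g in model.groups:
            m = compute_local_metrics(
                model.condition_on_group(g), model.nodes, g,
                variant=config.clustering_variant,
            )
            per_group[g] = m
            metric_frames.append(m.to_frame())
        pd.concat(metric_frames, ignore_index=True).to_csv(
            outdir / "local_metrics.csv", index=False
        )
        corr_rows = []
        for a, b in itertools.combinations(model.groups, 2):
            for metric in ("strength", "clustering"):
                va = getattr(per_group[a], metric)
                vb = getattr(per_group[b], metric)
                try:
                    r = compare_metrics(va, vb)
                except ValueError:
                    r = np.nan
                corr_rows.append(
                    {"group_a": a, "group_b": b, "metric": metric, "pearson_r": r}
                )
        pd.DataFrame(corr_rows).to_csv(outdir / "metric_correlations.csv", index=False)

        stage("cohort_stats")
        _cohort_table(filtered).to_csv(outdir / "cohort_statistics.csv", index=False)

        if config.prescriptions_csv is not None:
            stage("trajectories")
            _trajectory_stage(config, outdir, log)

        stage("layout")
        layout = layout_positions(model.base_weights, model.nodes, seed=config.seed)
        layout.to_csv(outdir / "layout.csv", index=False)
        max_w = max(
            (float(np.abs(model.condition_on_group(g)).max()) for g in model.groups),
            default=0.0,
        )
        log["layout"] = {"max_edge_weight": max_w}  # shared scale across group figures

        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        return log
    except Exception as err:
        failed = log["stages"][-1] if log["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {err}") from err
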