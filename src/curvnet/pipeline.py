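"""Study orchestration: simulate/load -> measure -> compare -> correlate -> report.

A study is described by a ``StudyConfig`` (YAML/JSON on disk).  The data
source is either a synthetic-generator block or a node table plus cohort
manifest.  Borderline subjects are excluded before any statistics.  Four
local measures (strength, betweenness, clustering, curvature) are
compared nodewise between cohorts, each as its own Holm-Sidak family by
default; seven global measures are compared one-tailed under explicit
per-measure direction hypotheses; measures at significant nodes are then
correlated with the CI index.  All randomness derives from one root
seed, fanned out per subject, so reports regenerate byte-identically.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import curvnet
from curvnet import measures as gm
from curvnet.curvature import curvature_result
from curvnet.io import (
    CohortDataset,
    ValidationError,
    read_cohort_manifest,
    read_node_table,
    write_results_table,
)
from curvnet.stats import (
    correlate_with_ci,
    global_comparison,
    holm_sidak,
    nodewise_comparison,
)
from curvnet.synth import GeneratorConfig, generate_cohort_study

logger = logging.getLogger("curvnet")

LOCAL_MEASURES = ("strength", "betweenness", "clustering", "curvature")
GLOBAL_MEASURES = (
    "clustering_mean", "curvature", "density", "diameter",
    "global_efficiency", "characteristic_path_length", "small_worldness",
)


@dataclass
class StudyConfig:
    """Everything needed to run (and re-run) one study."""

    seed: int = 0
    out_dir: str = "study_out"
    alpha: float = 0.05
    # data source: exactly one of the two
    simulate: GeneratorConfig | None = None
    node_table: str | None = None
    manifest: str | None = None
    # measure parameters
    idleness: float = 0.5
    ground_metric: str = "hop"
    binarize: bool = False
    normalized_betweenness: bool = False
    n_null: int = 100          # surrogates for small-worldness
    swap_factor: int = 10
    # statistics
    global_directions: dict[str, str] = field(default_factory=dict)
    correct_correlations: bool = False
    combined_family: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.simulate is None and (self.node_table is None or self.manifest is None):
            raise ValidationError(
                "config needs either a 'simulate' block or node_table + manifest"
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        data = raw.pop("data", None)
        cfg = cls(
            simulate=GeneratorConfig(**sim) if sim is not None else None,
            node_table=(data or {}).get("node_table"),
            manifest=(data or {}).get("manifest"),
            **{k: v for k, v in raw.items() if k in cls.__dataclass_fields__},
        )
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        text = Path(path).read_text(encoding="utf-8")
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} is not a mapping")
        return cls.from_dict(raw)


@dataclass
class StudyReport:
    node_tables: dict[str, pd.DataFrame]
    global_table: pd.DataFrame
    correlation_table: pd.DataFrame
    summary: dict
    manifest: dict


def load_dataset(config: StudyConfig) -> CohortDataset:
    if config.simulate is not None:
        return generate_cohort_study(config.simulate)
    parcellation = read_node_table(config.node_table)
    return read_cohort_manifest(config.manifest, parcellation)


def compute_measure_tables(
    dataset: CohortDataset, config: StudyConfig
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Per-subject measure tables for all included (non-borderline) subjects.

    Returns ``(local_tables, global_table, meta)``: local tables are
    subject x node DataFrames per measure; the global table is subject x
    global-measure; meta carries subject_id, group, ci_index.
    """
    included = dataset.included()
    if not included:
        raise ValidationError("no included (MSNI/MSCI) subjects")
    parc = dataset.parcellation
    node_cols = [str(i) for i in parc.node_ids]
    local = {m: [] for m in LOCAL_MEASURES}
    glob_rows, meta_rows = [], []
    seeds = np.random.SeedSequence(config.seed).spawn(len(included))
    for s, ss in zip(included, seeds):
        if s.connectome is None:
            raise ValidationError(f"subject {s.subject_id}: no connectome")
        conn = s.connectome
        local["strength"].append(gm.node_strength(conn))
        local["betweenness"].append(
            gm.betweenness_centrality(conn, normalized=config.normalized_betweenness)
        )
        local["clustering"].append(gm.clustering_coefficient(conn))
        curv = curvature_result(conn, idleness=config.idleness,
                                ground_metric=config.ground_metric)
        local["curvature"].append(curv.node_curvatures)
        g = gm.global_measures(conn, n_null=config.n_null,
                               swap_factor=config.swap_factor,
                               seed=np.random.default_rng(ss),
                               binarize=config.binarize).as_dict()
        g["curvature"] = curv.global_curvature
        glob_rows.append(g)
        meta_rows.append({"subject_id": s.subject_id, "group": s.group,
                          "ci_index": s.ci_index})
    ids = [s.subject_id for s in included]
    local_tables = {
        m: pd.DataFrame(np.asarray(v), index=ids, columns=node_cols)
        for m, v in local.items()
    }
    global_table = pd.DataFrame(glob_rows, index=ids)[list(GLOBAL_MEASURES)]
    meta = pd.DataFrame(meta_rows)
    return local_tables, global_table, meta


def compare_stage(
    local_tables: dict[str, pd.DataFrame], global_table: pd.DataFrame,
    meta: pd.DataFrame, config: StudyConfig, node_ids=None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    msci = meta.loc[meta["group"] == "MSCI", "subject_id"]
    msni = meta.loc[meta["group"] == "MSNI", "subject_id"]
    if len(msci) < 2 or len(msni) < 2:
        raise ValidationError(
            f"need >= 2 subjects per cohort, got MSCI={len(msci)}, MSNI={len(msni)}"
        )
    node_tables: dict[str, pd.DataFrame] = {}
    if config.combined_family:
        # one Holm-Sidak family across all measures jointly
        frames = []
        for m, table in local_tables.items():
            frames.append(nodewise_comparison(
                table.loc[msci], table.loc[msni], alpha=1.0,  # no per-measure step
                measure_name=m, node_ids=node_ids,
            ))
        joint = pd.concat(frames, ignore_index=True)
        ok = joint["tested"].to_numpy()
        rej = np.zeros(len(joint), bool)
        adj = np.full(len(joint), np.nan)
        rej[ok], adj[ok] = holm_sidak(joint.loc[ok, "raw_p"].to_numpy(), config.alpha)
        joint["reject"], joint["adjusted_p"] = rej, adj
        node_tables = {m: joint[joint["measure_name"] == m].reset_index(drop=True)
                       for m in local_tables}
    else:
        for m, table in local_tables.items():
            node_tables[m] = nodewise_comparison(
                table.loc[msci], table.loc[msni], alpha=config.alpha,
                measure_name=m, node_ids=node_ids,
            )
    global_cmp = global_comparison(
        global_table.loc[msci], global_table.loc[msni],
        directions=config.global_directions, alpha=config.alpha,
    )
    return node_tables, global_cmp


def correlate_stage(
    local_tables: dict[str, pd.DataFrame], node_tables: dict[str, pd.DataFrame],
    meta: pd.DataFrame, config: StudyConfig,
) -> pd.DataFrame:
    """Pearson r between each significant node's measure and the CI index,
    pooled over all included subjects (two-tailed, uncorrected unless
    ``correct_correlations``)."""
    ci = meta.set_index("subject_id")["ci_index"]
    rows = []
    for m, table in node_tables.items():
        sig = table.loc[table["reject"], "node_id"]
        values = local_tables[m]
        for nid in sig:
            col = str(nid)
            r = correlate_with_ci(values[col].loc[ci.index], ci, node=int(nid),
                                  measure_name=m)
            rows.append({"node_id": r.node, "measure_name": m,
                         "pearson_r": r.pearson_r, "p_value": r.p_value, "n": r.n})
    out = pd.DataFrame(rows, columns=["node_id", "measure_name", "pearson_r",
                                      "p_value", "n"])
    if config.correct_correlations and len(out):
        rej, adj = holm_sidak(out["p_value"].to_numpy(), config.alpha)
        out["adjusted_p"], out["significant"] = adj, rej
    elif len(out):
        out["significant"] = out["p_value"] < config.alpha
    return out


def summarize(
    node_tables: dict[str, pd.DataFrame], dataset: CohortDataset,
) -> dict:
    """Significant-node summary grouped by community, with L/R counts."""
    parc = dataset.parcellation
    info = parc.table.set_index("node_id")
    summary: dict = {"measures": {}, "hemisphere_counts": {"L": 0, "R": 0}}
    for m, table in node_tables.items():
        sig = table[table["reject"]]
        nodes = []
        for _, row in sig.iterrows():
            nid = int(row["node_id"])
            nodes.append({
                "node_id": nid,
                "label": str(info.at[nid, "label"]),
                "community": str(info.at[nid, "community"]),
                "hemisphere": str(info.at[nid, "hemisphere"]),
                "direction": int(row["direction"]),
            })
            summary["hemisphere_counts"][str(info.at[nid, "hemisphere"])] += 1
        by_comm: dict[str, list] = {}
        for nd in nodes:
            by_comm.setdefault(nd["community"], []).append(nd)
        summary["measures"][m] = {"n_significant": len(nodes),
                                  "by_community": by_comm}
    return summary


def _run_manifest(config: StudyConfig, dataset: CohortDataset) -> dict:
    cfg = asdict(config)
    if config.simulate is not None:
        cfg["simulate"] = asdict(config.simulate)
    groups = pd.Series([s.group for s in dataset.subjects]).value_counts().to_dict()
    return {
        "curvnet_version": curvnet.__version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "config": cfg,
        "n_subjects": len(dataset.subjects),
        "group_counts": {k: int(v) for k, v in groups.items()},
        "n_nodes": dataset.parcellation.n_nodes,
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Execute every stage; deterministic for a fixed config."""
    dataset = load_dataset(config)
    n_borderline = len(dataset.group("borderline"))
    if n_borderline:
        logger.info("excluding %d borderline subject(s)", n_borderline)
    local_tables, global_table, meta = compute_measure_tables(dataset, config)
    node_tables, global_cmp = compare_stage(
        local_tables, global_table, meta, config,
        node_ids=dataset.parcellation.node_ids,
    )
    corr = correlate_stage(local_tables, node_tables, meta, config)
    summary = summarize(node_tables, dataset)
    return StudyReport(
        node_tables=node_tables, global_table=global_cmp,
        correlation_table=corr, summary=summary,
        manifest=_run_manifest(config, dataset),
    )


def write_report(report: StudyReport, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m, table in report.node_tables.items():
        write_results_table(table, out / f"nodewise_{m}.tsv")
    write_results_table(report.global_table, out / "global_comparison.tsv")
    write_results_table(report.correlation_table, out / "correlations.tsv")
    (out / "summary.json").write_text(json.dumps(report.summary, indent=2) + "\n",
                                      encoding="utf-8")
    (out / "run_manifest.json").write_text(json.dumps(report.manifest, indent=2) + "\n",
                                           encoding="utf-8")
    return out
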