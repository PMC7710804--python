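"""Synthetic connectome cohorts with planted, CI-coupled deficits.

The generator emulates the statistical shape of streamline-count
connectomes without any imaging: node centroids sit on a cortical-like
spherical shell, and a study-level template is drawn once — edge
existence decays exponentially with inter-node distance (spatially
clustered topology), template counts are log-normal (heavy-tailed).
Subjects share that template anatomy and vary around it through
independent per-edge log-normal noise, the way real cohorts share one
brain plan; integer rounding lets weak edges flicker across subjects.
Impairment is planted as graded attenuation of every edge incident to a
small set of target nodes: each impaired subject draws a latent
severity, all planted-node edges are multiplied by (1 - delta *
severity), and the same severity drives the subject's CI index through
a noisy logistic link.  Cohort labels are then assigned by thresholding
the CI index — exactly the path real subjects take — so widening the CI
noise produces borderline subjects for exclusion testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from curvnet.io import (
    CohortDataset,
    Connectome,
    Parcellation,
    SubjectRecord,
    ValidationError,
    write_results_table,
)
from curvnet.ci import classify

COMMUNITY_NAMES = [
    "ventral attention", "cingulo-opercular", "default mode",
    "visual", "somato-motor", "temporal", "other",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort generator.

    Cohort sizes default to 10 non-impaired vs 31 impaired subjects on a
    333-node parcellation.  ``effect_delta`` is the maximal fractional
    weight loss at planted nodes; ``planted_nodes`` are node IDs (as in
    the node table, 1-based).  ``ci_coupling`` is the logit-scale slope
    tying the CI index to the latent severity.
    """

    n_nodes: int = 333
    n_msni: int = 10
    n_msci: int = 31
    shell_radius: float = 70.0          # mm, cortical shell scale
    distance_decay_length: float = 45.0  # mm, edge-probability decay
    edge_scale: float = 1.0             # probability prefactor
    weight_mu: float = 2.5              # lognormal log-mean of counts
    weight_sigma: float = 1.0           # lognormal log-sd of counts
    subject_noise_sigma: float = 0.45   # per-subject, per-edge log-sd
    planted_nodes: tuple[int, ...] = (5, 17)
    effect_delta: float = 0.5
    severity_range: tuple[float, float] = (0.6, 1.0)
    ci_base: float = 0.1                # CI index of an unimpaired subject
    ci_coupling: float = 5.0            # logit-scale severity slope
    ci_noise_sigma: float = 0.2         # logit-scale noise sd
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_delta < 1.0:
            raise ValidationError("effect_delta must lie in [0, 1)")
        if self.n_msni < 2 or self.n_msci < 2:
            raise ValidationError("cohort sizes must be >= 2")
        if self.n_nodes < 2:
            raise ValidationError("need at least 2 nodes")
        bad = [p for p in self.planted_nodes if not 1 <= p <= self.n_nodes]
        if bad:
            raise ValidationError(f"planted node {bad[0]} outside parcellation")


def generate_parcellation(n_nodes: int, seed: int | None = None,
                          shell_radius: float = 70.0) -> Parcellation:
    """Random cortical-like parcellation: centroids on a spherical shell,
    hemispheres split by the sign of x, communities assigned round-robin."""
    rng = np.random.default_rng(seed)
    xyz = rng.normal(size=(n_nodes, 3))
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    xyz *= shell_radius * rng.uniform(0.8, 1.0, size=(n_nodes, 1))
    hemi = np.where(xyz[:, 0] < 0, "L", "R")
    comm = [COMMUNITY_NAMES[i % len(COMMUNITY_NAMES)] for i in range(n_nodes)]
    table = pd.DataFrame({
        "node_id": np.arange(1, n_nodes + 1),
        "label": [f"{h}_{c.replace(' ', '_')}_{i + 1}"
                  for i, (h, c) in enumerate(zip(hemi, comm))],
        "community": comm,
        "hemisphere": hemi,
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
    })
    return Parcellation(table=table)


def study_template(parcellation: Parcellation, config: GeneratorConfig) -> np.ndarray:
    """Study-level template count matrix shared by all subjects.

    Edge existence decays exponentially with centroid distance (one
    Bernoulli draw per pair), template counts are log-normal.  The
    template is a fixed function of (parcellation, config.seed): real
    cohorts share one anatomy, so topology is drawn once per study and
    subjects vary around it, not independently of each other.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    c = parcellation.centroids
    dist = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
    p = np.clip(config.edge_scale * np.exp(-dist / config.distance_decay_length), 0, 1)
    n = parcellation.n_nodes
    iu, ju = np.triu_indices(n, 1)
    present = rng.random(iu.size) < p[iu, ju]
    w0 = np.zeros((n, n))
    w0[iu[present], ju[present]] = rng.lognormal(
        config.weight_mu, config.weight_sigma, int(present.sum())
    )
    return w0 + w0.T


def generate_subject_connectome(
    parcellation: Parcellation,
    config: GeneratorConfig,
    group: str = "control",
    subject_seed: int | np.random.Generator | None = None,
    severity: float | None = None,
    template: np.ndarray | None = None,
) -> Connectome:
    """One subject's count matrix: template edges under per-edge noise.

    Every template edge weight is multiplied by an independent
    log-normal factor (sd ``subject_noise_sigma`` on the log scale);
    ``group='impaired'`` additionally attenuates every edge incident to
    a planted node by (1 - effect_delta * severity), with severity drawn
    from ``severity_range`` when not supplied.  Counts are rounded to
    integers; rounding to zero removes the edge, so weak connections
    flicker across subjects.
    """
    if group not in ("control", "impaired"):
        raise ValidationError(f"group must be 'control' or 'impaired', got {group!r}")
    rng = (subject_seed if isinstance(subject_seed, np.random.Generator)
           else np.random.default_rng(subject_seed))
    if template is None:
        template = study_template(parcellation, config)
    n = parcellation.n_nodes
    iu, ju = np.nonzero(np.triu(template, 1))
    w = template[iu, ju] * rng.lognormal(0.0, config.subject_noise_sigma, iu.size)
    if group == "impaired" and config.planted_nodes:
        if severity is None:
            severity = float(rng.uniform(*config.severity_range))
        pos = np.nonzero(np.isin(parcellation.node_ids, config.planted_nodes))[0]
        hit = np.isin(iu, pos) | np.isin(ju, pos)
        w[hit] *= 1.0 - config.effect_delta * severity
    counts = np.rint(w)
    W = np.zeros((n, n))
    keep = counts > 0
    W[iu[keep], ju[keep]] = counts[keep]
    W = W + W.T
    if not W.any():
        raise ValidationError("degenerate generator: produced an edgeless graph")
    return Connectome.from_array(parcellation, W)


def generate_cohort_study(config: GeneratorConfig) -> CohortDataset:
    """Full synthetic study: parcellation, connectomes and CI indices.

    The first ``n_msni`` subjects are latent controls (severity 0), the
    rest latent impaired; each subject's CI index is
    logistic(logit(ci_base) + ci_coupling * severity + noise) and the
    recorded group label comes from thresholding that index, never from
    the latent assignment.  Fully reproducible from ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    parc_ss, _template_ss, cohort_ss = root.spawn(3)
    parcellation = generate_parcellation(
        config.n_nodes, seed=parc_ss, shell_radius=config.shell_radius
    )
    template = study_template(parcellation, config)
    n_total = config.n_msni + config.n_msci
    cohort_rng = np.random.default_rng(cohort_ss)
    subject_seeds = cohort_ss.spawn(n_total)
    subjects = []
    for k in range(n_total):
        latent_impaired = k >= config.n_msni
        severity = (float(cohort_rng.uniform(*config.severity_range))
                    if latent_impaired else 0.0)
        conn = generate_subject_connectome(
            parcellation, config,
            group="impaired" if latent_impaired else "control",
            subject_seed=np.random.default_rng(subject_seeds[k]),
            severity=severity, template=template,
        )
        z = (logit(config.ci_base) + config.ci_coupling * severity
             + cohort_rng.normal(0.0, config.ci_noise_sigma))
        ci = float(np.clip(expit(z), 0.0, 1.0))
        subjects.append(SubjectRecord(
            subject_id=f"sub-{k + 1:03d}", group=classify(ci),
            ci_index=ci, connectome=conn,
        ))
    return CohortDataset(parcellation=parcellation, subjects=subjects)


def write_study(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write a study tree readable by the io module:
    node_table.tsv, matrices/<subject>.txt, manifest.tsv."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    write_results_table(dataset.parcellation.table, out / "node_table.tsv")
    rows = []
    for s in dataset.subjects:
        mpath = f"matrices/{s.subject_id}.txt"
        if s.connectome is not None:
            np.savetxt(out / mpath, s.connectome.weights, fmt="%.0f")
        rows.append({
            "subject_id": s.subject_id, "group": s.group,
            "ci_index": "" if s.ci_index is None else f"{s.ci_index:.6f}",
            "matrix_path": mpath,
        })
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False,
                              lineterminator="\n")
    return out
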