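"""Containers and text I/O for parcellations, connectomes and cohorts.

A study is defined by three plain-text inputs: a node table fixing the
parcellation (node identity, functional community, hemisphere, centroid
in mm), one delimited square matrix of streamline counts per subject,
and a cohort manifest tying subject IDs to group labels or
cognitive-impairment indices and matrix files.  The node table defines
the canonical node order; every matrix in a study must follow it.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

logger = logging.getLogger("curvnet")

NODE_TABLE_COLUMNS = ["node_id", "label", "community", "hemisphere", "x", "y", "z"]
GROUP_LABELS = frozenset({"MSNI", "MSCI", "borderline", "excluded", "unknown"})

#: asymmetries up to this are averaged away; anything larger is a wrong file
SYMMETRY_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class Parcellation:
    """Ordered node metadata shared by every connectome in a study.

    The row order of ``table`` is canonical: row k of every connectivity
    matrix refers to row k here, regardless of the numeric node IDs.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in NODE_TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"node table missing column {missing[0]!r}")
        ids = self.table["node_id"].to_numpy()
        uniq, counts = np.unique(ids, return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise ValidationError(f"duplicate node_id {dup}")
        if len(self.table) < 2:
            raise ValidationError("parcellation needs at least 2 nodes")
        bad = set(self.table["hemisphere"]) - {"L", "R"}
        if bad:
            raise ValidationError(f"hemisphere must be L or R, got {sorted(bad)}")

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def node_ids(self) -> np.ndarray:
        return self.table["node_id"].to_numpy()

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    @property
    def communities(self) -> list[str]:
        return self.table["community"].tolist()

    @property
    def hemispheres(self) -> list[str]:
        return self.table["hemisphere"].tolist()

    @property
    def centroids(self) -> np.ndarray:
        """(n_nodes, 3) centroid coordinates in mm."""
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)


def validate_weights(
    weights: np.ndarray, n_nodes: int, symmetry_tol: float = SYMMETRY_TOL
) -> np.ndarray:
    """Validate and clean a raw weight matrix; returns a float copy.

    Enforces: square of the parcellation size, finite, non-negative,
    symmetric within ``symmetry_tol`` (then averaged), zero diagonal
    (forced with a warning when violated).
    """
    W = np.array(weights, dtype=float)  # copy: the diagonal is forced below
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError(f"connectivity matrix must be square, got {W.shape}")
    if W.shape[0] != n_nodes:
        raise ValidationError(
            f"matrix is {W.shape[0]}x{W.shape[1]} but parcellation has {n_nodes} nodes"
        )
    if not np.isfinite(W).all():
        i, j = np.argwhere(~np.isfinite(W))[0]
        raise ValidationError(f"non-finite weight at ({i}, {j})")
    if (W < 0).any():
        i, j = np.argwhere(W < 0)[0]
        raise ValidationError(f"negative weight at ({i}, {j})")
    if not np.array_equal(W, W.T):  # fast path: exact symmetry, no averaging
        asym = np.abs(W - W.T).max()
        if asym > symmetry_tol:
            raise ValidationError(
                f"matrix asymmetric (max |W - W.T| = {asym:.3g} > {symmetry_tol:g})"
            )
        W = (W + W.T) / 2.0
    if np.diagonal(W).any():
        logger.warning("nonzero diagonal entries forced to 0")
    np.fill_diagonal(W, 0.0)
    return W


@dataclass(frozen=True)
class Connectome:
    """One subject's undirected weighted graph over a parcellation.

    Weights are streamline counts (unitless, non-negative); the matrix is
    symmetric with a zero diagonal.
    """

    parcellation: Parcellation
    weights: np.ndarray

    @classmethod
    def from_array(
        cls, parcellation: Parcellation, weights: np.ndarray,
        symmetry_tol: float = SYMMETRY_TOL,
    ) -> "Connectome":
        W = validate_weights(weights, parcellation.n_nodes, symmetry_tol)
        return cls(parcellation=parcellation, weights=W)

    @property
    def n_nodes(self) -> int:
        return self.parcellation.n_nodes

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_list(self) -> list[tuple[int, int, float]]:
        """(i, j, w) for every edge with i < j, in row-major order."""
        iu, ju = np.nonzero(np.triu(self.weights, 1))
        return [(int(i), int(j), float(self.weights[i, j])) for i, j in zip(iu, ju)]


@dataclass
class SubjectRecord:
    subject_id: str
    group: str = "unknown"
    ci_index: float | None = None
    connectome: Connectome | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValidationError(
                f"subject {self.subject_id}: unknown group {self.group!r}"
            )
        if self.ci_index is not None and not 0.0 <= self.ci_index <= 1.0:
            raise ValidationError(
                f"subject {self.subject_id}: ci_index {self.ci_index} outside [0, 1]"
            )

    @property
    def included(self) -> bool:
        """True for subjects entering the statistical comparison."""
        return self.group in ("MSNI", "MSCI")


@dataclass
class CohortDataset:
    """All subjects of a study, sharing one parcellation."""

    parcellation: Parcellation
    subjects: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate subject_id {dup!r}")
        for s in self.subjects:
            if s.connectome is not None and s.connectome.parcellation is not self.parcellation:
                if s.connectome.n_nodes != self.parcellation.n_nodes:
                    raise ValidationError(
                        f"subject {s.subject_id}: connectome does not match parcellation"
                    )

    def included(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.included]

    def group(self, label: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == label]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab/whitespace; utf-8-sig strips any BOM
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8-sig",
                     skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    for c in df.columns:
        if df[c].dtype == object:
            df[c] = df[c].str.strip()
    return df


def read_node_table(path: str | Path) -> Parcellation:
    """Read a parcellation node table (TSV/CSV with named header)."""
    df = _read_table(path)
    missing = [c for c in NODE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"node table {path}: missing column {missing[0]!r}")
    return Parcellation(table=df[NODE_TABLE_COLUMNS].reset_index(drop=True))


def read_connectivity_matrix(path: str | Path, parcellation: Parcellation) -> Connectome:
    """Read one subject's delimited square count matrix (optionally .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
        fh.seek(0)
        delimiter = "," if "," in first else None
        try:
            W = np.loadtxt(fh, delimiter=delimiter, ndmin=2)
        except ValueError as exc:
            raise ValidationError(f"cannot parse matrix {path}: {exc}") from exc
    return Connectome.from_array(parcellation, W)


def read_cohort_manifest(
    path: str | Path, parcellation: Parcellation, load_matrices: bool = True
) -> CohortDataset:
    """Read a cohort manifest and (optionally) all referenced matrices.

    Expected columns: ``subject_id``, plus ``group`` and/or ``ci_index``,
    plus ``matrix_path`` (relative paths resolve against the manifest's
    directory).  When only ``ci_index`` is given the group label is
    derived by thresholding the index.
    """
    from curvnet.ci import classify

    path = Path(path)
    df = _read_table(path)
    if "subject_id" not in df.columns:
        raise ValidationError(f"manifest {path}: missing column 'subject_id'")
    if "group" not in df.columns and "ci_index" not in df.columns:
        raise ValidationError(f"manifest {path}: needs a 'group' or 'ci_index' column")
    subjects = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        ci = None
        if "ci_index" in df.columns and pd.notna(row.get("ci_index")):
            ci = float(row["ci_index"])
        if "group" in df.columns and pd.notna(row.get("group")):
            group = str(row["group"])
        elif ci is not None:
            group = classify(ci)
        else:
            group = "unknown"
        conn = None
        if load_matrices and "matrix_path" in df.columns and pd.notna(row.get("matrix_path")):
            mpath = Path(str(row["matrix_path"]))
            if not mpath.is_absolute():
                mpath = path.parent / mpath
            if not mpath.exists():
                raise ValidationError(
                    f"subject {sid}: matrix file not found: {mpath}"
                )
            conn = read_connectivity_matrix(mpath, parcellation)
        subjects.append(SubjectRecord(subject_id=sid, group=group, ci_index=ci,
                                      connectome=conn))
    return CohortDataset(parcellation=parcellation, subjects=subjects)


def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with 6-significant-digit floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g",
                 encoding="utf-8", lineterminator="\n")
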