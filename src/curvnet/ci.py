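"""Cognitive-impairment (CI) index from MACFIMS parameter scores.

The MACFIMS battery is reduced to 20 parameters.  A parameter is failed
when the subject performs more than 1 normative standard deviation below
the normative mean (after flipping parameters where lower raw scores are
better).  The CI index is the fraction of failed parameters; subjects
with index < 0.2 are classified MSNI (not impaired), > 0.35 MSCI
(impaired), and values in [0.2, 0.35] are borderline and excluded from
all statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from curvnet.io import ValidationError

#: classification thresholds on the CI index
MSNI_UPPER = 0.2   # index strictly below -> MSNI
MSCI_LOWER = 0.35  # index strictly above -> MSCI; [0.2, 0.35] is borderline

N_PARAMETERS = 20

#: canonical names for the 20 reduced MACFIMS parameters
MACFIMS_PARAMETERS = [
    "pasat_2s", "pasat_3s", "sdmt",
    "cvlt2_total_learning", "cvlt2_delayed_recall", "cvlt2_recognition",
    "bvmtr_total_learning", "bvmtr_delayed_recall",
    "cowat_fas", "cowat_animals",
    "jlo", "dkefs_sorting_correct", "dkefs_sorting_description",
    "dkefs_sorting_recognition",
    "wcst_categories", "wcst_perseverative_errors",
    "stroop_color", "stroop_word", "stroop_interference",
    "grooved_pegboard",
]


@dataclass(frozen=True)
class MacfimsScores:
    """One subject's 20 parameter scores plus their normative reference."""

    subject_id: str
    parameters: dict[str, float]
    normative: pd.DataFrame  # columns: parameter, mean, sd, higher_is_better

    def __post_init__(self) -> None:
        if len(self.parameters) != N_PARAMETERS:
            raise ValidationError(
                f"subject {self.subject_id}: expected {N_PARAMETERS} MACFIMS "
                f"parameters, got {len(self.parameters)}"
            )
        if (self.normative["sd"] <= 0).any():
            bad = self.normative.loc[self.normative["sd"] <= 0, "parameter"].iloc[0]
            raise ValidationError(f"normative sd must be positive for {bad!r}")


@dataclass(frozen=True)
class CiClassification:
    ci_index: float
    n_failed: int
    label: str


def failure_indicators(scores: MacfimsScores) -> dict[str, bool]:
    """Per-parameter failure flags: z < -1 strictly, direction-corrected.

    A score exactly 1 sd below the mean is NOT a failure (the rule is
    "more than 1 sd below").  Parameters with ``higher_is_better=False``
    are sign-flipped before thresholding.
    """
    norm = scores.normative.set_index("parameter")
    flags: dict[str, bool] = {}
    for p in norm.index:
        if p not in scores.parameters:
            raise ValidationError(
                f"subject {scores.subject_id}: missing MACFIMS parameter {p!r}"
            )
        z = (scores.parameters[p] - norm.at[p, "mean"]) / norm.at[p, "sd"]
        if not bool(norm.at[p, "higher_is_better"]):
            z = -z
        flags[p] = bool(z < -1.0)
    return flags


def ci_index(flags: dict[str, bool] | np.ndarray) -> float:
    """CI index = fraction of failed parameters (n_failed / 20)."""
    values = np.asarray(list(flags.values()) if isinstance(flags, dict) else flags,
                        dtype=bool)
    if values.size != N_PARAMETERS:
        raise ValidationError(f"expected {N_PARAMETERS} flags, got {values.size}")
    return float(values.sum()) / N_PARAMETERS


def classify(ci_index_value: float) -> str:
    """Threshold the CI index: <0.2 MSNI, (0.35, 1] MSCI, else borderline."""
    if not 0.0 <= ci_index_value <= 1.0:
        raise ValidationError(f"CI index {ci_index_value} outside [0, 1]")
    if ci_index_value < MSNI_UPPER:
        return "MSNI"
    if ci_index_value > MSCI_LOWER:
        return "MSCI"
    return "borderline"


def classify_scores(scores: MacfimsScores) -> CiClassification:
    """Full chain: failure flags -> CI index -> cohort label."""
    flags = failure_indicators(scores)
    idx = ci_index(flags)
    return CiClassification(ci_index=idx, n_failed=int(sum(flags.values())),
                            label=classify(idx))


def read_normative_table(path: str | Path) -> pd.DataFrame:
    """Normative TSV/CSV: parameter, mean, sd, higher_is_better."""
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8-sig")
    needed = {"parameter", "mean", "sd", "higher_is_better"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"normative table missing column {sorted(missing)[0]!r}")
    df["higher_is_better"] = df["higher_is_better"].astype(bool)
    return df


def read_macfims_table(path: str | Path, normative: pd.DataFrame) -> list[MacfimsScores]:
    """Read per-subject MACFIMS scores (subject_id + 20 score columns)."""
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8-sig")
    if "subject_id" not in df.columns:
        raise ValidationError("MACFIMS table missing column 'subject_id'")
    params = list(normative["parameter"])
    out = []
    for _, row in df.iterrows():
        missing = [p for p in params if p not in df.columns or pd.isna(row[p])]
        if missing:
            raise ValidationError(
                f"subject {row['subject_id']}: missing MACFIMS parameter {missing[0]!r}"
            )
        out.append(MacfimsScores(
            subject_id=str(row["subject_id"]),
            parameters={p: float(row[p]) for p in params},
            normative=normative,
        ))
    return out
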