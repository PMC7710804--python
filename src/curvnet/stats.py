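"""Two-cohort comparison statistics with family-wise error control.

Nodewise comparisons are two-tailed pooled-variance (Student) t-tests —
the homoscedastic variant, not Welch — corrected across the node family
with the Holm-Sidak step-down procedure at alpha = 0.05.  Global
measures are compared with one-tailed pooled t-tests under the a-priori
hypothesis that robustness measures are higher in the non-impaired
cohort; the expected direction for every global measure must be given
explicitly.  Associations between node measures and the CI index are
plain Pearson correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from curvnet.io import ValidationError

logger = logging.getLogger("curvnet")

TAILS = ("two", "one_greater", "one_less")

#: expected one-tailed direction of each global measure under the
#: "robustness is higher in MSNI" hypothesis.  Characteristic path length
#: and diameter have no default: smaller could equally mean "more robust",
#: so callers must state a direction for them.
ROBUSTNESS_DIRECTIONS = {
    "clustering_mean": "msni_greater",
    "curvature": "msni_greater",
    "density": "msni_greater",
    "global_efficiency": "msni_greater",
    "small_worldness": "msni_greater",
}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    tail: str
    mean_diff: float


@dataclass(frozen=True)
class CorrelationResult:
    node: int
    measure_name: str
    pearson_r: float
    p_value: float
    n: int


def pooled_t_test(sample_a, sample_b, tail: str = "two") -> TestResult:
    """Two-sample pooled-variance t-test.

    ``tail='one_greater'`` tests mean(a) > mean(b); ``'one_less'`` the
    reverse.  Degrees of freedom are n_a + n_b - 2.
    """
    if tail not in TAILS:
        raise ValidationError(f"tail must be one of {TAILS}")
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("samples contain non-finite values")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 <= 0:
        raise ValidationError("degenerate samples: zero pooled variance")
    alt = {"two": "two-sided", "one_greater": "greater", "one_less": "less"}[tail]
    res = sps.ttest_ind(a, b, equal_var=True, alternative=alt)
    return TestResult(
        statistic=float(res.statistic), df=a.size + b.size - 2,
        p_value=float(res.pvalue), tail=tail, mean_diff=float(a.mean() - b.mean()),
    )


def holm_sidak(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down correction.

    Sorted p-values are compared against 1 - (1-alpha)^(1/(m-i+1)); the
    step-down stops at the first failure.  Adjusted p-values use the
    standard running-maximum construction.  Returns (reject, adjusted)
    in the input order.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # p = 1 hits log1p(-1) internally
        reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return reject, p_adj


def _cohort_matrix(values) -> np.ndarray:
    X = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    if X.ndim != 2:
        raise ValidationError("cohort measure table must be 2-D (subjects x nodes)")
    if X.shape[0] < 2:
        raise ValidationError("each cohort needs at least 2 subjects")
    return X


def nodewise_comparison(
    msci_values, msni_values, alpha: float = 0.05,
    measure_name: str = "measure", node_ids=None,
) -> pd.DataFrame:
    """Per-node two-tailed pooled t-tests, Holm-Sidak over the node family.

    Inputs are subjects x nodes arrays (or DataFrames) for each cohort.
    Nodes with zero variance in both cohorts and equal means cannot be
    tested; they are dropped from the correction family (m is reduced)
    and reported with ``tested = False``.  ``direction`` is the sign of
    (MSCI mean - MSNI mean).
    """
    A = _cohort_matrix(msci_values)   # impaired cohort
    B = _cohort_matrix(msni_values)   # non-impaired cohort
    if A.shape[1] != B.shape[1]:
        raise ValidationError("cohorts measured on different node sets")
    n_nodes = A.shape[1]
    if node_ids is None:
        node_ids = np.arange(1, n_nodes + 1)
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    testable = (va + vb) > 0
    if not testable.all():
        logger.info(
            "nodewise_comparison(%s): %d zero-variance node(s) dropped from family",
            measure_name, int((~testable).sum()),
        )
    res = sps.ttest_ind(A[:, testable], B[:, testable], equal_var=True, axis=0)
    raw_p = np.full(n_nodes, np.nan)
    tstat = np.full(n_nodes, np.nan)
    raw_p[testable] = res.pvalue
    tstat[testable] = res.statistic
    reject = np.zeros(n_nodes, bool)
    adj_p = np.full(n_nodes, np.nan)
    if testable.any():
        rej, adj = holm_sidak(raw_p[testable], alpha)
        reject[testable] = rej
        adj_p[testable] = adj
    diff = A.mean(axis=0) - B.mean(axis=0)
    direction = np.sign(np.where(np.isnan(diff), 0.0, diff)).astype(int)
    return pd.DataFrame({
        "node_id": np.asarray(node_ids),
        "measure_name": measure_name,
        "mean_msci": A.mean(axis=0),
        "mean_msni": B.mean(axis=0),
        "mean_diff": diff,
        "direction": direction,
        "t": tstat,
        "df": A.shape[0] + B.shape[0] - 2,
        "raw_p": raw_p,
        "adjusted_p": adj_p,
        "reject": reject,
        "tested": testable,
    })


def global_comparison(
    msci_globals: pd.DataFrame, msni_globals: pd.DataFrame,
    directions: dict[str, str] | None = None, alpha: float = 0.05,
) -> pd.DataFrame:
    """One-tailed pooled t-test per global measure, Holm-Sidak across measures.

    ``directions`` maps measure name to ``'msni_greater'`` or
    ``'msci_greater'`` — the expected direction under the robustness
    hypothesis.  Measures without a stated direction raise (path-length
    style measures have no safe default).
    """
    directions = {**ROBUSTNESS_DIRECTIONS, **(directions or {})}
    measures = list(msci_globals.columns)
    if list(msni_globals.columns) != measures:
        raise ValidationError("cohort global tables have different measure sets")
    rows = []
    for m in measures:
        if m not in directions:
            raise ValidationError(
                f"no expected direction configured for global measure {m!r}"
            )
        d = directions[m]
        if d not in ("msni_greater", "msci_greater"):
            raise ValidationError(f"direction for {m!r} must be msni_greater/msci_greater")
        tail = "one_greater" if d == "msni_greater" else "one_less"
        a = np.asarray(msni_globals[m], float)
        b = np.asarray(msci_globals[m], float)
        row = {
            "measure_name": m, "direction_tested": d,
            "mean_msni": float(np.nanmean(a)), "mean_msci": float(np.nanmean(b)),
        }
        try:
            tr = pooled_t_test(a, b, tail=tail)
            row.update(t=tr.statistic, df=tr.df, raw_p=tr.p_value, tested=True)
        except ValidationError as exc:
            # e.g. zero pooled variance (identical topologies) or all-NaN
            logger.info("global_comparison: %s untestable (%s)", m, exc)
            row.update(t=np.nan, df=len(a) + len(b) - 2, raw_p=np.nan, tested=False)
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["tested"].to_numpy()
    reject = np.zeros(len(table), bool)
    adj = np.full(len(table), np.nan)
    if ok.any():
        reject[ok], adj[ok] = holm_sidak(table.loc[ok, "raw_p"].to_numpy(), alpha)
    table["adjusted_p"] = adj
    table["reject"] = reject
    return table


def correlate_with_ci(
    node_measure_values, ci_indices, node: int = 0, measure_name: str = "measure",
) -> CorrelationResult:
    """Pearson correlation of one node's measure with the CI index.

    Two-tailed p from the exact t transform r*sqrt((n-2)/(1-r^2));
    requires >= 3 pairs and nonzero variance in both variables.
    """
    x = np.asarray(node_measure_values, float)
    y = np.asarray(ci_indices, float)
    if x.size != y.size:
        raise ValidationError("paired samples have different lengths")
    if x.size < 3:
        raise ValidationError("need at least 3 paired observations")
    if x.var() == 0 or y.var() == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(node=node, measure_name=measure_name,
                             pearson_r=float(r), p_value=float(p), n=int(x.size))
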