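"""Blinded cross-protocol comparison of staining quality.

Samples are assigned random codes before analysis so the analyst is blind
to the clearing condition; per-condition replicate half-max depths are then
aggregated (mean ± SEM) and each condition is tested against the baseline
protocol with a two-tailed two-sample t-test, labeled * (p < 0.05),
** (p < 0.01) or ns. Comparisons are made only within a fluorophore group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlindingMap",
    "ConditionSummary",
    "blind_assign",
    "unblind",
    "summarize_condition",
    "ttest_vs_baseline",
    "compare_conditions",
    "significance_label",
    "export_heatmap_matrix",
]

P_STAR = 0.05
P_DOUBLE_STAR = 0.01


@dataclass
class BlindingMap:
    """Bijection between sample ids and random blind codes."""

    code_by_id: Dict[str, str]
    seed: int

    def __post_init__(self) -> None:
        ids = list(self.code_by_id)
        codes = list(self.code_by_id.values())
        if len(set(ids)) != len(ids) or len(set(codes)) != len(codes):
            raise ValueError("blinding map must be bijective")

    @property
    def id_by_code(self) -> Dict[str, str]:
        return {c: i for i, c in self.code_by_id.items()}

    @property
    def sample_ids(self) -> List[str]:
        return list(self.code_by_id)


def blind_assign(sample_ids: Sequence[str], seed: int) -> BlindingMap:
    """Assign each sample a random zero-padded numeric code.

    Codes are a seeded random permutation of 0..n-1, zero-padded to a
    common width, so file listings sorted by code shuffle the condition
    order. Deterministic for a given seed.
    """
    ids = list(sample_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    width = max(len(str(max(len(ids) - 1, 0))), 3)
    codes = [str(int(k)).zfill(width) for k in perm]
    return BlindingMap(code_by_id=dict(zip(ids, codes)), seed=int(seed))


def unblind(
    results_by_code: Dict[str, object], mapping: BlindingMap
) -> Tuple[Dict[str, object], List[str]]:
    """Re-key blinded results by sample id, restoring manifest order.

    Returns ``(results_by_id, missing_ids)``: results are ordered as in the
    blinding map; sample ids whose codes are absent from the results are
    listed in ``missing_ids`` rather than raising. Unknown codes raise.
    """
    known = mapping.id_by_code
    unknown = [c for c in results_by_code if c not in known]
    if unknown:
        raise KeyError(f"unknown blind codes: {sorted(unknown)}")
    out: Dict[str, object] = {}
    missing: List[str] = []
    for sid, code in mapping.code_by_id.items():
        if code in results_by_code:
            out[sid] = results_by_code[code]
        else:
            missing.append(sid)
    return out, missing


def summarize_condition(values: Sequence[float]) -> Tuple[float, float]:
    """Mean and standard error of the mean of replicate values.

    SEM uses the sample standard deviation (n−1 denominator) over sqrt(n);
    for a single replicate the SEM is undefined (NaN).
    """
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size == 0:
        raise ValueError("no replicate values")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, float("nan")
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return mean, sem


def significance_label(p: float) -> str:
    """Map a p-value to the ns / * / ** convention."""
    if not np.isfinite(p):
        return "ns"
    if p < P_DOUBLE_STAR:
        return "**"
    if p < P_STAR:
        return "*"
    return "ns"


def ttest_vs_baseline(
    cond_values: Sequence[float],
    baseline_values: Sequence[float],
    variant: str = "student",
) -> Tuple[float, float, float, str]:
    """Two-tailed two-sample t-test of a condition against baseline.

    Returns ``(t, df, p, label)`` with t positive when the condition mean
    exceeds the baseline mean. Default is Student's pooled-variance test;
    ``variant='welch'`` relaxes the equal-variance assumption. Two groups
    with zero variance and equal means yield p = 1 by convention.
    """
    a = np.asarray(list(cond_values), dtype=np.float64)
    b = np.asarray(list(baseline_values), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    equal_var = variant == "student"
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2 if equal_var else float("nan")
            return 0.0, float(df), 1.0, "ns"
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    return t, df, p, significance_label(p)


@dataclass
class ConditionSummary:
    """Aggregated half-max depths of one condition's replicates."""

    condition_id: str
    baseline_flag: bool
    replicate_values: List[float]
    mean_um: float
    sem_um: float
    t: float = float("nan")
    df: float = float("nan")
    p_vs_baseline: float = float("nan")
    sig_label: str = ""


def compare_conditions(
    values_by_condition: Dict[str, Sequence[float]],
    baseline: str,
    variant: str = "student",
    bonferroni: bool = False,
) -> List[ConditionSummary]:
    """Summarize every condition and t-test each against the baseline.

    The baseline's own p-value is left undefined. With ``bonferroni`` the
    p-values are multiplied by the number of non-baseline comparisons
    (capped at 1) before labeling.
    """
    if baseline not in values_by_condition:
        raise ValueError(f"baseline condition {baseline!r} not present")
    n_tests = max(len(values_by_condition) - 1, 1)
    out = []
    for cond, vals in values_by_condition.items():
        mean, sem = summarize_condition(vals)
        summary = ConditionSummary(
            condition_id=cond,
            baseline_flag=cond == baseline,
            replicate_values=[float(v) for v in vals],
            mean_um=mean,
            sem_um=sem,
        )
        if cond != baseline:
            t, df, p, _ = ttest_vs_baseline(vals, values_by_condition[baseline], variant)
            if bonferroni:
                p = min(p * n_tests, 1.0)
            summary.t, summary.df, summary.p_vs_baseline = t, df, p
            summary.sig_label = significance_label(p)
        out.append(summary)
    return out


def export_heatmap_matrix(scores: Iterable, path=None) -> pd.DataFrame:
    """Assemble normalized scores into a depth × condition matrix.

    Rows are depths (µm), one column per condition/replicate; profiles
    shorter than the longest depth grid are padded with NaN. Written as CSV
    when ``path`` is given. Inputs are NormalizedScore objects (or anything
    with depth_um / values / condition_id / replicate_id attributes).
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to export")
    grids = [np.asarray(s.depth_um) for s in scores]
    depth = max(grids, key=len)
    for g in grids:
        if not np.allclose(g, depth[: len(g)]):
            raise ValueError("conditions must share a common depth grid")
    columns = {}
    for s in scores:
        name = s.condition_id if s.condition_id else "sample"
        if s.replicate_id:
            name = f"{name}/{s.replicate_id}"
        col = np.full(len(depth), np.nan)
        col[: len(s.values)] = s.values
        columns[name] = col
    df = pd.DataFrame(columns, index=pd.Index(depth, name="depth_um"))
    if path is not None:
        df.to_csv(path)
    return df
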