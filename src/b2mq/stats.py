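"""Group-level statistics and caption-style reporting.

Values are expressed as mean +- SEM; two-group comparisons use two-tailed
t-tests (pooled-variance Student by default, Welch by flag) with p < 0.05
as the significance criterion.  Fold changes are reported both raw
(mean_a/mean_b) and rounded to the nearest integer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import Comparison, GroupSummary

ALPHA = 0.05


def summarize(values, label: str, unit: str = "") -> GroupSummary:
    """Mean and SEM (= sd/sqrt(n), ddof=1) of one group."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return GroupSummary(label=label, n=int(arr.size), mean=float(arr.mean()),
                        sem=sem, unit=unit)


def fold_change(mean_a: float, mean_b: float) -> tuple[float, int]:
    """(raw, rounded) ratio of group means."""
    if mean_b == 0:
        raise ValueError("cannot form a fold change with a zero denominator")
    f = mean_a / mean_b
    return f, int(round(f))


def compare(values_a, values_b, label_a: str = "a", label_b: str = "b",
            unit: str = "", variant: str = "student") -> Comparison:
    """Two-tailed two-sample t-test plus fold change of the means.

    ``variant``: "student" (pooled variance, the default) or "welch".
    Two zero-variance groups with equal means take p = 1 by convention.
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    ga = summarize(a, label_a, unit)
    gb = summarize(b, label_b, unit)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t, p = (0.0, 1.0) if ga.mean == gb.mean else (np.inf, 0.0)
        df = a.size + b.size - 2
    else:
        res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df) if hasattr(res, "df") else a.size + b.size - 2
    fold, fold_r = fold_change(ga.mean, gb.mean)
    return Comparison(group_a=ga, group_b=gb, t_statistic=t,
                      degrees_of_freedom=float(df), p_value=p,
                      significant=bool(p < ALPHA), fold_change=fold,
                      fold_rounded=fold_r, variant=variant)


def _summary_row(s: GroupSummary) -> dict:
    return {"group": s.label, "n": s.n, "mean": s.mean, "sem": s.sem, "unit": s.unit}


def build_report(stages: dict) -> dict:
    """Assemble caption-style tables from per-stage outputs.

    ``stages`` maps stage names (e.g. ``border_to_center``, ``expression_snr``,
    ``length_bins``, ``filopodia_counts``, ``branching_index``, ``activation``)
    to either a list of :class:`GroupSummary` or a dict with keys
    ``groups`` (list of GroupSummary) and optional ``comparisons``
    (list of Comparison).  Empty stages are recorded with a notice.

    Returns ``{"tables": {stage: DataFrame}, "notices": [...]}``; every row
    carries n and units, and fold columns come straight from ``compare``.
    """
    tables: dict[str, pd.DataFrame] = {}
    notices: list[str] = []
    for name, payload in stages.items():
        if payload is None or (isinstance(payload, (list, dict)) and not payload):
            notices.append(f"stage '{name}' produced no data; table omitted")
            continue
        if isinstance(payload, dict):
            groups = payload.get("groups", [])
            comps = payload.get("comparisons", [])
        else:
            groups, comps = list(payload), []
        rows = [_summary_row(g) for g in groups]
        for c in comps:
            rows.append({
                "group": f"{c.group_a.label} vs {c.group_b.label}",
                "n": f"{c.group_a.n}/{c.group_b.n}",
                "mean": np.nan, "sem": np.nan, "unit": c.group_a.unit,
                "t": c.t_statistic, "df": c.degrees_of_freedom,
                "p": c.p_value, "significant": c.significant,
                "fold": c.fold_change, "fold_rounded": c.fold_rounded,
            })
        if not rows:
            notices.append(f"stage '{name}' produced no data; table omitted")
            continue
        tables[name] = pd.DataFrame(rows)
    return {"tables": tables, "notices": notices}
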