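"""Strain-level (cohort) statistics over per-cell morphometrics records.

Group differences are tested with the two-sided Mann–Whitney U test, the
appropriate nonparametric choice for the skewed volume and sphericity
distributions of organelle morphometrics: the exact null distribution is
used for small tie-free samples (n_a + n_b ≤ 20), otherwise the normal
approximation with tie correction.  Reported p-values are raw by default
(no multiplicity adjustment); an optional Benjamini–Hochberg correction is
available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: Largest combined sample size for which the exact branch is used.
EXACT_MAX_N = 20


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of sample_a, p-value).

    Exact p for small tie-free samples, normal approximation with tie
    correction and continuity correction otherwise.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def summarize_groups(records: pd.DataFrame, metric: str,
                     group_key: str = "strain") -> pd.DataFrame:
    """Per-group n, median, quartiles and variance of one metric.

    Deterministic: rows are ordered by group name; invariant to row
    shuffling of the input.
    """
    if metric not in records.columns:
        raise KeyError(f"unknown metric {metric!r}")
    if group_key not in records.columns:
        raise KeyError(f"unknown group key {group_key!r}")
    rows = []
    for name, sub in sorted(records.groupby(group_key)):
        values = sub[metric].dropna().to_numpy(float)
        rows.append({
            group_key: name, "metric": metric, "n": values.size,
            "median": float(np.median(values)) if values.size else np.nan,
            "q1": float(np.percentile(values, 25)) if values.size else np.nan,
            "q3": float(np.percentile(values, 75)) if values.size else np.nan,
            "variance": float(values.var(ddof=1)) if values.size > 1
            else np.nan,
        })
    return pd.DataFrame(rows)


def compare_strains(records: pd.DataFrame, metrics: list[str],
                    group_key: str = "strain",
                    adjust: str | None = None,
                    out_dir: str | Path | None = None) -> dict:
    """Pairwise Mann–Whitney comparisons per metric plus summary tables.

    Returns ``{"summaries": DataFrame, "tests": DataFrame}``.  With a
    single group only summaries are produced.  ``adjust="bh"`` applies
    Benjamini–Hochberg across all reported tests (off by default; raw
    p-values match the field's reporting convention).  ``out_dir`` exports
    both tables as CSV plus the violin-plot data per metric.
    """
    groups = sorted(records[group_key].dropna().unique())
    summaries = pd.concat(
        [summarize_groups(records, m, group_key) for m in metrics],
        ignore_index=True)
    test_rows = []
    for metric in metrics:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                a = records.loc[records[group_key] == ga, metric] \
                    .dropna().to_numpy(float)
                b = records.loc[records[group_key] == gb, metric] \
                    .dropna().to_numpy(float)
                if a.size == 0 or b.size == 0:
                    continue
                u, p = mann_whitney_u(a, b)
                test_rows.append({"metric": metric, "group_a": ga,
                                  "group_b": gb, "n_a": a.size,
                                  "n_b": b.size, "U": u, "p": p})
    tests = pd.DataFrame(test_rows)
    if adjust == "bh" and len(tests):
        tests["p_adjusted"] = stats.false_discovery_control(
            tests["p"].to_numpy())
    report = {"summaries": summaries, "tests": tests}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(out_dir / "summaries.csv", index=False,
                         lineterminator="\n")
        tests.to_csv(out_dir / "tests.csv", index=False, lineterminator="\n")
        plot_data = {
            metric: {g: records.loc[records[group_key] == g, metric]
                     .dropna().tolist() for g in groups}
            for metric in metrics}
        (out_dir / "violin_data.json").write_text(
            json.dumps(plot_data, sort_keys=True))
    return report
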