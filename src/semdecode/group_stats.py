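"""Across-participant summaries and the worked-example report.

Summary accuracies are reported as mean +/- population SD (divisor N) —
the convention the packaged per-participant fixture reproduces — while
the inferential tests (paired t, Welch t, Pearson) use the standard
sample-variance formulas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .io_core import load_table2_fixture

__all__ = ["mean_sd", "pearson", "paired_t", "welch_t", "participant_summary",
           "build_report"]


def mean_sd(values):
    """(mean, population SD); SD uses divisor N, matching the +/- style
    of the per-participant accuracy summaries."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mean_sd of empty sequence")
    return float(v.mean()), float(v.std())


def pearson(x, y):
    """Pearson correlation with the two-sided p from the t-transform
    (n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length sequences of at least 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def paired_t(a, b):
    """Classical paired t-test (two-sided) on the differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need paired sequences of at least 2")
    d = a - b
    if d.std(ddof=1) == 0:
        raise ValueError("zero difference variance")
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p)


def welch_t(a, b):
    """Welch's unequal-variance t-test (two-sided, Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate groups")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def participant_summary(participant, full_result, targeted_result, electrodes,
                        channel_ids) -> dict:
    """One report row for a decoded session.

    Retained-feature counts per region group (IFG, SM1, other) are the
    across-fold means of the full-feature decoding, rounded to integer.
    """
    region_ix = electrodes.region_indices(channel_ids)
    ifg_ix = region_ix.get("IFG", np.empty(0, dtype=int))
    sm1_ix = region_ix.get("SM1", np.empty(0, dtype=int))
    per_fold = np.asarray([
        (f.mask.retained[ifg_ix].sum(), f.mask.retained[sm1_ix].sum(),
         f.mask.n_retained)
        for f in full_result.folds
    ], dtype=float)
    ifg, sm1, total = per_fold.mean(axis=0)
    return {
        "participant": participant,
        "full_accuracy": round(full_result.accuracy, 1),
        "targeted_accuracy": round(targeted_result.accuracy, 1),
        "reduction": round(full_result.accuracy - targeted_result.accuracy, 1),
        "ifg_features": int(round(ifg)),
        "sm1_features": int(round(sm1)),
        "other_features": int(round(total - ifg - sm1)),
        "all_features": int(round(total)),
    }


_COLUMNS = ["full_accuracy", "targeted_accuracy", "reduction",
            "ifg_features", "sm1_features", "other_features", "all_features"]


def build_report(per_participant: pd.DataFrame = None):
    """Tabular report plus group summary.

    ``per_participant`` needs columns participant, full_accuracy,
    targeted_accuracy, reduction, ifg_features, sm1_features,
    other_features, all_features; ``None`` loads the packaged fixture.
    Returns ``(report, summary)`` where ``report`` appends Average and SD
    (population) rows and ``summary`` holds the column means/SDs, the
    Pearson correlations of accuracy reduction against per-region
    retained-feature counts, and the paired t-test of full vs targeted
    accuracy.
    """
    df = load_table2_fixture() if per_participant is None else per_participant.copy()
    missing = [c for c in ["participant"] + _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"report table missing columns: {missing}")

    stats = {c: mean_sd(df[c]) for c in _COLUMNS}
    avg_row = {"participant": "Average", **{c: round(stats[c][0], 1) for c in _COLUMNS}}
    sd_row = {"participant": "SD", **{c: round(stats[c][1], 1) for c in _COLUMNS}}
    report = pd.concat([df, pd.DataFrame([avg_row, sd_row])], ignore_index=True)

    summary = {c: {"mean": stats[c][0], "sd": stats[c][1]} for c in _COLUMNS}
    for key, col in (("ifg", "ifg_features"), ("sm1", "sm1_features"),
                     ("other", "other_features")):
        try:
            r, p = pearson(df["reduction"], df[col])
            summary[f"pearson_reduction_vs_{key}"] = {"r": r, "p": p}
        except ValueError:
            summary[f"pearson_reduction_vs_{key}"] = None
    if len(df) >= 2:
        try:
            t, p = paired_t(df["full_accuracy"], df["targeted_accuracy"])
            summary["paired_t_full_vs_targeted"] = {"t": t, "p": p}
        except ValueError:
            summary["paired_t_full_vs_targeted"] = None
    return report, summary
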