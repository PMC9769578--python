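"""Assign assembly processes to sample pairs and aggregate fractions.

Decision rules (strict inequalities; boundary values fall to the
stochastic side):

* betaNRI < -2            -> homogeneous selection
* betaNRI > +2            -> heterogeneous selection
* else, RC_bray > +0.95   -> dispersal limitation
* else, RC_bray < -0.95   -> homogenizing dispersal
* otherwise               -> ecological drift
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROCESSES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

__all__ = ["PROCESSES", "ClassificationThresholds", "classify_pair",
           "classify_records", "summarize_processes"]


@dataclass(frozen=True)
class ClassificationThresholds:
    beta_nri_low: float = -2.0
    beta_nri_high: float = 2.0
    rc_low: float = -0.95
    rc_high: float = 0.95

    def __post_init__(self) -> None:
        if not (self.beta_nri_low < self.beta_nri_high and self.rc_low < self.rc_high):
            raise ValueError("thresholds must satisfy low < high")


def classify_pair(
    beta_nri: float,
    rc_bray: float,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> str | None:
    """Process label for one pair; None when either statistic is not finite."""
    if not (np.isfinite(beta_nri) and np.isfinite(rc_bray)):
        return None
    if beta_nri < thresholds.beta_nri_low:
        return "homogeneous_selection"
    if beta_nri > thresholds.beta_nri_high:
        return "heterogeneous_selection"
    if rc_bray > thresholds.rc_high:
        return "dispersal_limitation"
    if rc_bray < thresholds.rc_low:
        return "homogenizing_dispersal"
    return "drift"


def classify_records(
    records: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Add a ``process`` column to a pairwise-turnover table."""
    out = records.copy()
    out["process"] = [
        classify_pair(b, r, thresholds)
        for b, r in zip(out["beta_nri"], out["rc_bray"])
    ]
    return out


def _summary_row(group_label: str, labels: pd.Series, min_pairs: int) -> dict:
    classified = labels.dropna()
    n_pairs = len(labels)
    n_undef = int(labels.isna().sum())
    row: dict = {
        "group": group_label,
        "n_pairs": n_pairs,
        "n_classified": len(classified),
        "n_flagged_undefined": n_undef,
        "small_n_warning": len(classified) < min_pairs,
    }
    counts = classified.value_counts()
    for proc in PROCESSES:
        c = int(counts.get(proc, 0))
        row[f"count_{proc}"] = c
        row[f"frac_{proc}"] = c / len(classified) if len(classified) else np.nan
    if row["small_n_warning"]:
        logger.warning(
            "group %s has only %d classified pairs (< %d); fractions may "
            "not be interpretable", group_label, len(classified), min_pairs,
        )
    return row


def summarize_processes(
    records: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    grouping: str = "all",
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    min_samples: int = 4,
) -> pd.DataFrame:
    """Counts and fractions of the five processes, overall or per group.

    ``grouping="month"`` keeps only pairs whose two samples fall in the
    same calendar month (pooled across years and stations), so each
    month's fractions are independent of the others. Groups with fewer
    classified pairs than ``C(min_samples, 2)`` carry a small-n warning,
    mirroring the rule of thumb that a month sampled fewer than
    ``min_samples`` times is not interpretable.
    """
    if "process" not in records.columns:
        records = classify_records(records, thresholds)
    min_pairs = min_samples * (min_samples - 1) // 2
    if grouping == "all":
        rows = [_summary_row("ALL", records["process"], min_pairs)]
    elif grouping == "month":
        if metadata is None:
            raise ValueError("month grouping requires metadata")
        month_of = metadata.set_index(metadata["sample_id"].astype(str))["month"]
        ma = records["sample_a"].map(month_of)
        mb = records["sample_b"].map(month_of)
        if ma.isna().any() or mb.isna().any():
            bad = sorted(
                set(records.loc[ma.isna(), "sample_a"])
                | set(records.loc[mb.isna(), "sample_b"])
            )
            raise ValueError(f"samples without metadata: {bad[:10]}")
        within = records[ma == mb]
        months = ma[ma == mb]
        rows = []
        for m in range(1, 13):
            sel = within.loc[months == m, "process"]
            if len(sel) == 0:
                continue
            label = pd.Timestamp(2000, m, 1).strftime("%B")
            rows.append(_summary_row(label, sel, min_pairs))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    columns = [
        "group", "n_pairs", "n_classified", "n_flagged_undefined",
        "small_n_warning",
    ] + [c for p in PROCESSES for c in (f"count_{p}", f"frac_{p}")]
    if not rows:
        logger.warning("no within-group pairs under grouping=%s", grouping)
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    frac_cols = [f"frac_{p}" for p in PROCESSES]
    sums = df[frac_cols].sum(axis=1)
    ok = df["n_classified"] == 0
    assert np.all(ok | (np.abs(sums - 1.0) < 1e-12))
    return df
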