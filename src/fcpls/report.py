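"""Cohort bookkeeping and report formatting helpers.

Enrollment tables carry one row per enrolled participant with boolean
exclusion flags; `apply_exclusions` filters them and `cohort_summary`
produces the counts a methods section reports (enrolled, excluded by
reason, retained per group).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "build_enrollment_table",
    "apply_exclusions",
    "cohort_summary",
    "percent",
    "format_percent",
]

EXCLUSION_COLUMNS = ("motion_excluded", "clinical_excluded")


def build_enrollment_table(group_sizes, motion_excluded=None, clinical_excluded=None):
    """One row per enrolled participant with per-group exclusion counts.

    ``group_sizes`` maps group label -> n enrolled; the exclusion dicts
    map group label -> how many of that group are flagged (flags are
    assigned to the first unflagged rows, which is immaterial for
    counting).
    """
    motion_excluded = motion_excluded or {}
    clinical_excluded = clinical_excluded or {}
    rows = []
    for group, n in group_sizes.items():
        n_motion = motion_excluded.get(group, 0)
        n_clin = clinical_excluded.get(group, 0)
        if n_motion + n_clin > n:
            raise ValueError(f"more exclusions than enrollees in group {group}")
        for i in range(n):
            rows.append({
                "subject_id": f"{group}-{i + 1:03d}",
                "group": group,
                "motion_excluded": i < n_motion,
                "clinical_excluded": n_motion <= i < n_motion + n_clin,
            })
    return pd.DataFrame(rows)


def apply_exclusions(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows carrying any exclusion flag."""
    mask = pd.Series(False, index=table.index)
    for col in EXCLUSION_COLUMNS:
        if col in table:
            mask |= table[col].astype(bool)
    return table.loc[~mask].reset_index(drop=True)


def cohort_summary(table: pd.DataFrame) -> dict:
    """Counts before/after exclusion, total and per group."""
    retained = apply_exclusions(table)
    summary = {
        "enrolled": int(len(table)),
        "retained": int(len(retained)),
        "excluded_motion": int(table.get("motion_excluded", pd.Series(dtype=bool)).sum()),
        "excluded_clinical": int(table.get("clinical_excluded", pd.Series(dtype=bool)).sum()),
        "retained_by_group": retained["group"].value_counts().to_dict(),
    }
    return summary


def percent(count, total, decimals=1):
    """Share of ``count`` in ``total`` as a percentage rounded to ``decimals``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def format_percent(count, total, decimals=1):
    """E.g. ``format_percent(97, 115) == '84.3%'``."""
    return f"{percent(count, total, decimals):.{decimals}f}%"
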