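"""Reference summary tables from the motivating clinical cohort.

These are published-style frequency summaries of a 26-participant
severely obese NAFLD cohort (severity groups of 8 / 12 / 6 by NAFLD
activity score) encoded as long-format frequency tables; they let the
``filter_count`` machinery recompute headline participant counts
(NASH-positive total, fibrosis-stage totals, comorbidity totals) without
access to any per-participant raw data.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_histology_frequencies",
    "reference_comorbidity_counts",
    "GROUP_LABELS",
]

GROUP_LABELS = ["NAS0-1", "NAS2-3", "NAS4-6"]


def _freq(variable: str, rows: dict[str, tuple[int, int, int]]) -> list[dict]:
    return [
        {"variable": variable, "grade": grade, **dict(zip(GROUP_LABELS, counts))}
        for grade, counts in rows.items()
    ]


def reference_histology_frequencies() -> pd.DataFrame:
    """Histology frequency table: grade counts per severity group.

    Columns: ``variable, grade, NAS0-1, NAS2-3, NAS4-6``.  Group sizes
    are 8, 12 and 6; each variable's counts sum to the group sizes.
    """
    rows: list[dict] = []
    rows += _freq(
        "steatosis",
        {"0": (3, 0, 0), "1": (5, 6, 0), "2": (0, 5, 3), "3": (0, 1, 3)},
    )
    rows += _freq(
        "lobular_inflammation",
        {"0": (8, 4, 0), "1": (0, 8, 6), "2": (0, 0, 0), "3": (0, 0, 0)},
    )
    rows += _freq(
        "ballooning", {"0": (8, 9, 0), "1": (0, 3, 5), "2": (0, 0, 1)}
    )
    rows += _freq(
        "nas_total",
        {
            "0": (3, 0, 0),
            "1": (5, 0, 0),
            "2": (0, 6, 0),
            "3": (0, 6, 0),
            "4": (0, 0, 3),
            "5": (0, 0, 2),
            "6": (0, 0, 1),
            "7": (0, 0, 0),
            "8": (0, 0, 0),
        },
    )
    rows += _freq(
        "fibrosis_stage",
        {
            "0": (8, 9, 1),
            "1": (0, 3, 2),
            "2": (0, 0, 2),
            "3": (0, 0, 1),
            "4": (0, 0, 0),
        },
    )
    rows += _freq("nash", {"no": (8, 12, 1), "yes": (0, 0, 5)})
    return pd.DataFrame(rows)


def reference_comorbidity_counts() -> pd.DataFrame:
    """Comorbidity counts per severity group (participants affected)."""
    rows: list[dict] = []
    rows += _freq("type2_diabetes", {"yes": (4, 3, 3)})
    rows += _freq("hypertension", {"yes": (3, 5, 4)})
    rows += _freq("dyslipidemia", {"yes": (5, 2, 5)})
    return pd.DataFrame(rows)
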