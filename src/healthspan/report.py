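"""Descriptive baseline summaries of validated panels (Table-1-style)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .states import Gender, HealthState, SubjectPanel

__all__ = ["baseline_summary", "AGE_BAND_LABELS"]

AGE_BAND_LABELS = ("50-59", "60-69", "70-79", "80-89", ">=90")


def _age_band(age: float) -> str:
    if age >= 90:
        return AGE_BAND_LABELS[4]
    return AGE_BAND_LABELS[min(int((age - 50) // 10), 3)]


def baseline_summary(panels: list[SubjectPanel]) -> pd.DataFrame:
    """Counts and percentages by gender, baseline age band, baseline health
    state, and deaths during follow-up.

    Long format: one row per (section, category) with total / men / women
    counts and within-column percentages of the subject totals.
    """
    n = len(panels)
    men = [p for p in panels if p.gender is Gender.MAN]
    women = [p for p in panels if p.gender is Gender.WOMAN]

    def _count(section, category, pred):
        ct, cm, cw = (sum(pred(p) for p in grp) for grp in (panels, men, women))
        return {
            "section": section, "category": category,
            "n_total": ct, "pct_total": 100.0 * ct / max(n, 1),
            "n_men": cm, "pct_men": 100.0 * cm / max(len(men), 1),
            "n_women": cw, "pct_women": 100.0 * cw / max(len(women), 1),
        }

    rows = [
        _count("gender", "men", lambda p: p.gender is Gender.MAN),
        _count("gender", "women", lambda p: p.gender is Gender.WOMAN),
    ]
    for band in AGE_BAND_LABELS:
        rows.append(_count("age_band", band,
                           lambda p, b=band: _age_band(p.entry_age) == b))
    state_labels = {HealthState.ROBUST: "no_limitation",
                    HealthState.IADL: "iadl_disability",
                    HealthState.BADL: "badl_disability"}
    for state, label in state_labels.items():
        rows.append(_count("baseline_state", label,
                           lambda p, s=state: p.observations[0].state is s))
    rows.append(_count("follow_up", "deaths",
                       lambda p: p.observations[-1].state is HealthState.DEAD))
    return pd.DataFrame(rows)
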