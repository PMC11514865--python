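"""Published CLHLS 2008-2018 multistate HLE estimates, as reference inputs.

These are the printed population-based life-table results for lonely and
non-lonely Chinese older adults (ADL- and SRH-based health states): LE, HLE
and the HLE/LE ratio with 95% CIs at ages 65/75/85, and the gender-specific
HLE/LE schedules at ages 65-99 with the printed gender-difference (GD) and
age-decrement (AD) statistics.  They serve as inputs to the derived-statistic
operations in :mod:`healthexpect.reporting` (ratio, GD, AD) and as the shape
templates for the package's own report files; the printed GD/AD columns are
kept separately because some printed derived values reflect unrounded
internals rather than arithmetic on the rounded entries.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["expectancy_table", "gender_ratio_table"]

# age, LE, LE_lo, LE_hi, HLE, HLE_lo, HLE_hi, HLE/LE(%)
_TAB_LE = {
    ("adl", "lonely"): [
        (65, 19.5, 18.9, 20.0, 16.1, 15.6, 16.7, 82.8),
        (75, 13.0, 12.5, 13.4, 9.62, 9.2, 10.0, 74.0),
        (85, 8.4, 7.9, 8.8, 4.9, 4.5, 5.3, 59.0),
    ],
    ("adl", "non-lonely"): [
        (65, 23.0, 22.4, 23.6, 18.7, 18.3, 19.1, 81.2),
        (75, 16.1, 15.4, 16.7, 11.6, 11.2, 12.0, 72.4),
        (85, 10.9, 10.2, 11.7, 6.3, 5.8, 6.8, 57.6),
    ],
    ("srh", "lonely"): [
        (65, 19.9, 19.3, 20.5, 15.4, 14.8, 16.0, 77.4),
        (75, 13.5, 13.0, 14.0, 10.6, 10.09, 11.04, 78.4),
        (85, 8.6, 8.1, 9.0, 6.79, 6.36, 7.22, 79.4),
    ],
    ("srh", "non-lonely"): [
        (65, 22.2, 21.8, 22.6, 18.3, 17.8, 18.7, 82.3),
        (75, 15.3, 14.9, 15.8, 12.8, 12.3, 13.2, 83.1),
        (85, 10.0, 9.4, 10.4, 8.3, 7.9, 8.8, 84.0),
    ],
}

_AGES_3 = (65, 70, 75, 80, 85, 90, 95, 99)

# HLE/LE (%) by gender; printed GD per age and printed AD per column
_TAB_RATIO = {
    ("adl", "non-lonely"): {
        "men": (85.0, 81.7, 77.4, 71.5, 63.9, 54.2, 42.9, 33.4),
        "women": (78.0, 74.0, 68.9, 62.3, 54.2, 44.6, 34.3, 26.4),
        "gd_printed": (6.9, 7.7, 8.5, 9.2, 9.7, 9.6, 8.6, 7.1),
        "ad_printed": {"men": 51.5, "women": 51.7},
    },
    ("adl", "lonely"): {
        "men": (86.4, 83.2, 79.0, 73.3, 65.7, 56.2, 44.8, 35.0),
        "women": (80.4, 76.4, 71.2, 64.5, 56.2, 46.2, 35.3, 26.8),
        "gd_printed": (6.0, 6.8, 7.8, 8.7, 9.6, 10.0, 9.5, 8.2),
        "ad_printed": {"men": 51.4, "women": 53.6},
    },
    ("srh", "non-lonely"): {
        "men": (84.2, 84.6, 85.1, 85.6, 86.1, 86.6, 87.2, 87.6),
        "women": (80.6, 81.1, 81.6, 82.1, 82.7, 83.3, 83.9, 84.4),
        "gd_printed": (3.6, 3.5, 3.5, 3.5, 3.4, 3.4, 3.3, 3.3),
        "ad_printed": {"men": -3.4, "women": -3.7},
    },
    ("srh", "lonely"): {
        "men": (80.1, 80.6, 81.2, 81.8, 82.4, 83.1, 83.7, 84.3),
        "women": (75.8, 76.4, 76.9, 77.5, 78.2, 78.9, 79.6, 80.2),
        "gd_printed": (4.3, 4.2, 4.2, 4.2, 4.2, 4.2, 4.1, 4.1),
        "ad_printed": {"men": -4.2, "women": -4.4},
    },
}


def expectancy_table() -> pd.DataFrame:
    """Published LE/HLE/HLE-ratio by indicator and loneliness (ages 65/75/85)."""
    rows = []
    for (indicator, group), entries in _TAB_LE.items():
        for age, le, le_lo, le_hi, hle, hle_lo, hle_hi, pct in entries:
            rows.append(
                dict(
                    indicator=indicator,
                    loneliness=group,
                    age=age,
                    le=le,
                    le_lower=le_lo,
                    le_upper=le_hi,
                    hle=hle,
                    hle_lower=hle_lo,
                    hle_upper=hle_hi,
                    hle_pct=pct,
                )
            )
    return pd.DataFrame(rows)


def gender_ratio_table() -> pd.DataFrame:
    """Published gender-specific HLE/LE schedules with printed GD and AD."""
    rows = []
    for (indicator, group), block in _TAB_RATIO.items():
        for i, age in enumerate(_AGES_3):
            rows.append(
                dict(
                    indicator=indicator,
                    loneliness=group,
                    age=age,
                    men=block["men"][i],
                    women=block["women"][i],
                    gd_printed=block["gd_printed"][i],
                )
            )
    return pd.DataFrame(rows)


def printed_age_decrements() -> pd.DataFrame:
    """Published age-decrement (age-65 minus age-99 HLE/LE) values."""
    rows = []
    for (indicator, group), block in _TAB_RATIO.items():
        for gender in ("men", "women"):
            rows.append(
                dict(
                    indicator=indicator,
                    loneliness=group,
                    gender=gender,
                    ad_printed=block["ad_printed"][gender],
                )
            )
    return pd.DataFrame(rows)
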