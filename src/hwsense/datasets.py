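"""Reported summary values from the North Carolina heat-wave definition
comparison study (Coastal and Piedmont physiographic regions, five summer
seasons 2011-2016 excluding 2013).

These printed aggregates are the only public face of the restricted
weather/health record, and serve as worked-example inputs: the per-region
AIC columns for the 28 definitions, the monthly heat-wave-day and
emergency-department-visit table for the region-optimal definitions, and
the study/NWS overlap marginals.  The overlap ``both`` cells (24 and 17)
are not printed; they are reconstructed as the unique integers for which
the continuity-corrected McNemar statistic reproduces the reported values
(158.15 and 219.04) given the printed marginals.
"""

from __future__ import annotations

import pandas as pd

REGIONS = ("Coastal", "Piedmont")

STUDY_YEARS = (2011, 2012, 2014, 2015, 2016)
SUMMER_MONTHS = (5, 6, 7, 8, 9)

#: AIC per definition id, by region, for the 28-definition comparison.
PUBLISHED_AIC: dict[str, dict[str, float]] = {
    "Coastal": {
        "HW_01": 4475.7, "HW_02": 4480.7, "HW_03": 4362.9, "HW_04": 4396.7,
        "HW_05": 4287.3, "HW_06": 4293.5, "HW_07": 4216.2, "HW_08": 4211.8,
        "HW_09": 4475.4, "HW_10": 4479.7, "HW_11": 4413.7, "HW_12": 4435.3,
        "HW_13": 4283.5, "HW_14": 4318.0, "HW_15": 4192.6, "HW_16": 4234.4,
        "HW_17": 4423.1, "HW_18": 4488.1, "HW_19": 4479.1, "HW_20": 4401.1,
        "HW_21": 4433.5, "HW_22": 4352.0, "HW_23": 4353.0, "HW_24": 4305.5,
        "HW_25": 4303.0, "HW_26": 4254.0, "HW_27": 4319.9, "HW_28": 4415.7,
    },
    "Piedmont": {
        "HW_01": 4817.9, "HW_02": 4843.0, "HW_03": 4778.4, "HW_04": 4796.9,
        "HW_05": 4629.7, "HW_06": 4656.9, "HW_07": 4547.9, "HW_08": 4551.8,
        "HW_09": 4842.6, "HW_10": 4852.4, "HW_11": 4799.8, "HW_12": 4813.2,
        "HW_13": 4665.9, "HW_14": 4716.0, "HW_15": 4583.4, "HW_16": 4615.9,
        "HW_17": 4801.0, "HW_18": 4810.3, "HW_19": 4831.9, "HW_20": 4783.6,
        "HW_21": 4799.5, "HW_22": 4722.0, "HW_23": 4722.6, "HW_24": 4670.3,
        "HW_25": 4693.7, "HW_26": 4659.0, "HW_27": 4749.8, "HW_28": 4799.1,
    },
}

# Monthly heat-wave days (region-optimal definition, NWS-overlap days
# excluded) and HRI emergency-department visits on those days, May..Sep.
_HW_DAYS = {
    ("Coastal", 2011): (3, 21, 22, 10, 0),
    ("Coastal", 2012): (0, 5, 23, 0, 2),
    ("Coastal", 2014): (0, 6, 7, 0, 5),
    ("Coastal", 2015): (0, 15, 14, 5, 2),
    ("Coastal", 2016): (0, 5, 24, 19, 2),
    ("Piedmont", 2011): (1, 14, 25, 15, 0),
    ("Piedmont", 2012): (0, 6, 27, 8, 6),
    ("Piedmont", 2014): (0, 7, 11, 5, 6),
    ("Piedmont", 2015): (0, 16, 19, 9, 3),
    ("Piedmont", 2016): (0, 8, 26, 24, 5),
}
_ED_VISITS = {
    ("Coastal", 2011): (65, 309, 225, 195, 0),
    ("Coastal", 2012): (0, 45, 306, 0, 35),
    ("Coastal", 2014): (0, 101, 103, 0, 68),
    ("Coastal", 2015): (0, 817, 306, 117, 25),
    ("Coastal", 2016): (0, 80, 721, 366, 30),
    ("Piedmont", 2011): (37, 334, 417, 302, 0),
    ("Piedmont", 2012): (0, 95, 520, 112, 52),
    ("Piedmont", 2014): (0, 141, 149, 55, 92),
    ("Piedmont", 2015): (0, 897, 569, 177, 54),
    ("Piedmont", 2016): (0, 204, 950, 499, 106),
}


def monthly_heatwave_table() -> pd.DataFrame:
    """Tidy frame: region, year, month, hw_days, ed_visits."""
    rows = []
    for (region, year), hw in _HW_DAYS.items():
        ed = _ED_VISITS[(region, year)]
        for month, h, e in zip(SUMMER_MONTHS, hw, ed):
            rows.append(
                {"region": region, "year": year, "month": month, "hw_days": h, "ed_visits": e}
            )
    return pd.DataFrame(rows)


#: Study-flag / NWS-flag day marginals for the region-optimal definitions.
#: ``both`` is the reconstructed overlap (see module docstring).
REPORTED_OVERLAP: dict[str, dict[str, int]] = {
    "Coastal": {"study_days": 190, "nws_days": 26, "both": 24, "n_days": 704},
    "Piedmont": {"study_days": 241, "nws_days": 18, "both": 17, "n_days": 719},
}

#: Reported optimal definitions and their rate ratios (95% CI).
REPORTED_OPTIMA = {
    "Coastal": {"definition_id": "HW_15", "rr": 2.75, "ci": (2.40, 3.08)},
    "Piedmont": {"definition_id": "HW_07", "rr": 2.72, "ci": (2.46, 3.01)},
}
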