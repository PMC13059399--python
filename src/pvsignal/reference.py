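"""Published descriptive summary counts for the burosumab FAERS extract.

These are the printed case counts from the published burosumab
pharmacovigilance summary (primary-suspect reports, 2018Q1-2024Q3): 5,054
burosumab primary-suspect reports out of 7,480,032 reports retrieved in the
window.  They are inputs for self-contained arithmetic checks — the
percentage columns of a report-characteristics table are fully determined
by these counts, so :func:`pvsignal.descriptives.percent` can reproduce
them exactly.
"""

#: All reports retrieved in the quarter window (the screening background).
TOTAL_REPORTS = 7_480_032
#: Reports naming the drug as primary suspect.
PS_REPORTS = 5_054

#: Field -> category -> case count among the 5,054 primary-suspect reports.
#: Outcome categories are not mutually exclusive (multi-valued per report).
TABLE1_COUNTS: dict[str, dict[str, int]] = {
    "year": {
        "2018": 75, "2019": 576, "2020": 61, "2021": 1113,
        "2022": 1717, "2023": 924, "2024": 588,
    },
    "sex": {"female": 14, "male": 9, "unknown": 5031},
    "age_group": {"under18": 8, "18plus": 7, "unknown": 5039},
    "country": {
        "United States": 4723, "United Kingdom": 113, "Germany": 49,
        "France": 41, "Other": 128,
    },
    "outcome": {
        "death": 29, "life_threatening": 7, "hospitalization": 320,
        "disability": 10, "other": 606, "unknown": 4082,
    },
    "indication": {
        "hereditary hypophosphataemic rickets": 3960,
        "product used for unknown indication": 741,
        "hypophosphataemic osteomalacia": 96,
        "hypophosphataemia": 93,
        "phosphorus metabolism disorder": 87,
        "osteomalacia": 39,
        "rickets": 10,
    },
}

#: The printed percentage strings for spot categories, as published.
TABLE1_PERCENTS: dict[tuple[str, str], str] = {
    ("country", "United States"): "93.45",
    ("country", "United Kingdom"): "2.24",
    ("indication", "hereditary hypophosphataemic rickets"): "78.35",
    ("outcome", "death"): "0.57",
    ("outcome", "life_threatening"): "0.14",
    ("outcome", "hospitalization"): "6.33",
    ("sex", "unknown"): "99.54",
    ("age_group", "unknown"): "99.70",
    ("year", "2022"): "33.97",
}
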