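"""Published group-level NPS frequency data used by the contingency analyses.

The source multi-cohort study reports, per NPI-Q symptom and diagnostic
group, the number of participants with the symptom present and the
corresponding percentage; group denominators are not printed but are
recoverable as ``round(100 * count / percent)``.  Pairwise group contrasts
are reported as two-sided Fisher exact p-values.  These printed summaries
are the inputs to :mod:`npsmap.comparisons`; raw participant-level data are
not redistributable.
"""

from __future__ import annotations

DX_ORDER = ["ADMCI", "ALS", "FTD", "PD", "CVD"]

#: symptom -> {dx: (count_present, percent_present)}
NPS_FREQUENCIES = {
    "delusions": {"ADMCI": (10, 8.7), "ALS": (1, 2.5), "FTD": (7, 13.7),
                  "PD": (4, 2.9), "CVD": (11, 7.6)},
    "hallucinations": {"ADMCI": (5, 4.3), "ALS": (1, 2.5), "FTD": (2, 3.9),
                       "PD": (13, 9.5), "CVD": (3, 2.1)},
    "agitation": {"ADMCI": (33, 28.2), "ALS": (9, 22.5), "FTD": (20, 39.2),
                  "PD": (24, 17.4), "CVD": (37, 25.5)},
    "depression": {"ADMCI": (38, 32.5), "ALS": (15, 37.5), "FTD": (18, 36.0),
                   "PD": (52, 37.7), "CVD": (38, 26.2)},
    "anxiety": {"ADMCI": (30, 25.6), "ALS": (7, 17.5), "FTD": (24, 47.1),
                "PD": (30, 21.7), "CVD": (22, 15.2)},
    "euphoria": {"ADMCI": (6, 5.1), "ALS": (2, 5.0), "FTD": (8, 15.7),
                 "PD": (4, 2.9), "CVD": (5, 3.4)},
    "apathy": {"ADMCI": (44, 38.3), "ALS": (11, 27.5), "FTD": (28, 56.0),
               "PD": (32, 23.2), "CVD": (33, 22.8)},
    "disinhibition": {"ADMCI": (27, 23.1), "ALS": (3, 7.5), "FTD": (22, 44.0),
                      "PD": (17, 12.3), "CVD": (21, 14.5)},
    "irritability": {"ADMCI": (44, 37.9), "ALS": (9, 22.5), "FTD": (30, 58.8),
                     "PD": (38, 27.5), "CVD": (55, 38.2)},
    "aberrant_motor": {"ADMCI": (15, 12.8), "ALS": (5, 12.8), "FTD": (16, 31.4),
                       "PD": (7, 5.1), "CVD": (12, 8.3)},
    "appetite": {"ADMCI": (32, 28.1), "ALS": (16, 41.0), "FTD": (29, 56.9),
                 "PD": (38, 27.5), "CVD": (33, 22.8)},
    "nighttime": {"ADMCI": (26, 22.8), "ALS": (10, 26.3), "FTD": (28, 54.9),
                  "PD": (73, 52.9), "CVD": (49, 34.0)},
}

#: symptom -> published Pearson chi-square statistic (df = 4).
PUBLISHED_CHI2 = {
    "delusions": 9.12, "hallucinations": 9.33, "agitation": 10.54,
    "depression": 4.98, "anxiety": 22.94, "euphoria": 14.03,
    "apathy": 26.43, "disinhibition": 31.62, "irritability": 19.48,
    "aberrant_motor": 27.68, "appetite": 23.79, "nighttime": 33.38,
}

#: Pairwise group contrasts: (symptom, higher group, lower group,
#: published p, p is an upper bound "<p").
PAIRWISE_COMPARISONS = [
    ("agitation", "FTD", "PD", 0.003, False),
    ("anxiety", "FTD", "PD", 0.001, False),
    ("anxiety", "FTD", "ALS", 0.004, False),
    ("anxiety", "FTD", "CVD", 0.001, True),
    ("anxiety", "ADMCI", "CVD", 0.043, False),
    ("apathy", "FTD", "PD", 0.001, True),
    ("apathy", "FTD", "ALS", 0.001, False),
    ("apathy", "FTD", "CVD", 0.001, True),
    ("apathy", "ADMCI", "PD", 0.013, False),
    ("apathy", "ADMCI", "CVD", 0.009, False),
    ("appetite", "FTD", "ADMCI", 0.001, True),
    ("appetite", "FTD", "PD", 0.001, True),
    ("appetite", "FTD", "CVD", 0.001, True),
    ("appetite", "ALS", "CVD", 0.026, False),
    ("disinhibition", "FTD", "CVD", 0.001, True),
    ("disinhibition", "FTD", "PD", 0.001, True),
    ("disinhibition", "FTD", "ALS", 0.001, True),
    ("disinhibition", "ADMCI", "PD", 0.030, False),
    ("disinhibition", "ADMCI", "ALS", 0.036, False),
    ("euphoria", "FTD", "PD", 0.001, True),
    ("irritability", "FTD", "PD", 0.001, True),
    ("irritability", "FTD", "ALS", 0.001, True),
    ("aberrant_motor", "FTD", "CVD", 0.001, True),
    ("aberrant_motor", "FTD", "PD", 0.001, True),
    ("aberrant_motor", "ADMCI", "PD", 0.042, False),
    ("nighttime", "FTD", "ADMCI", 0.001, True),
    ("nighttime", "PD", "ADMCI", 0.001, True),
]
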