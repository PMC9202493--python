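"""Published population-level counts used in worked examples.

Demographic composition of the 75-million-patient EHR validation
population and its OUD/outcome cohorts, as released in aggregate form
(counts rounded to tens by the platform's de-identification step).  These
tables are *inputs*: the package recomputes the column percentages and the
crude odds ratios from the raw counts.  ``PRINTED_PERCENTS`` carries the
percentages as published, for cross-checking the arithmetic.

Category counts within a cohort need not sum to the cohort total because a
patient can report several values of one demographic at the same time.
"""

from __future__ import annotations

COHORTS = (
    "All",
    "OUD",
    "Hypothyroidism",
    "OUD+Hypothyroidism",
    "Hyperthyroidism",
    "OUD+Hyperthyroidism",
    "Type2Diabetes",
    "OUD+Type2Diabetes",
)

#: cohort -> {"total": N, "sex"/"age"/"race": {category: count}}
DEMOGRAPHIC_COUNTS: dict = {
    "All": {
        "total": 74_574_090,
        "sex": {"Female": 40_008_930, "Male": 34_047_620, "Unknown": 534_660},
        "age": {"Adult": 44_464_790, "Senior": 18_802_840, "Junior": 10_347_920},
        "race": {
            "White": 40_641_550,
            "African American": 7_705_410,
            "Asian": 1_201_360,
            "Hispanic/Latino": 1_051_630,
            "Unknown": 9_080_570,
        },
    },
    "OUD": {
        "total": 370_470,
        "sex": {"Female": 188_490, "Male": 180_670, "Unknown": 1_410},
        "age": {"Adult": 299_790, "Senior": 69_450, "Junior": 1_920},
        "race": {
            "White": 289_930,
            "African American": 47_220,
            "Asian": 1_610,
            "Hispanic/Latino": 2_200,
            "Unknown": 40_010,
        },
    },
    "Hypothyroidism": {
        "total": 3_739_290,
        "sex": {"Female": 2_817_360, "Male": 905_130, "Unknown": 19_610},
        "age": {"Adult": 1_656_970, "Senior": 2_020_550, "Junior": 23_830},
        "race": {
            "White": 2_972_760,
            "African American": 257_260,
            "Asian": 58_210,
            "Hispanic/Latino": 31_630,
            "Unknown": 490_390,
        },
    },
    "OUD+Hypothyroidism": {
        "total": 50_320,
        "sex": {"Female": 36_600, "Male": 13_450, "Unknown": 290},
        "age": {"Adult": 30_650, "Senior": 19_740, "Junior": 70},
        "race": {
            "White": 42_140,
            "African American": 4_720,
            "Asian": 220,
            "Hispanic/Latino": 250,
            "Unknown": 6_470,
        },
    },
    "Hyperthyroidism": {
        "total": 499_290,
        "sex": {"Female": 382_990, "Male": 114_460, "Unknown": 2_060},
        "age": {"Adult": 279_580, "Senior": 215_330, "Junior": 2_850},
        "race": {
            "White": 352_120,
            "African American": 77_830,
            "Asian": 13_260,
            "Hispanic/Latino": 4_820,
            "Unknown": 63_960,
        },
    },
    "OUD+Hyperthyroidism": {
        "total": 10_410,
        "sex": {"Female": 7_470, "Male": 2_930, "Unknown": 20},
        "age": {"Adult": 7_060, "Senior": 3_370, "Junior": 10},
        "race": {
            "White": 8_100,
            "African American": 1_800,
            "Asian": 60,
            "Hispanic/Latino": 60,
            "Unknown": 1_290,
        },
    },
    "Type2Diabetes": {
        "total": 5_051_290,
        "sex": {"Female": 2_590_240, "Male": 2_452_870, "Unknown": 12_930},
        "age": {"Adult": 2_080_090, "Senior": 2_941_860, "Junior": 13_680},
        "race": {
            "White": 3_446_160,
            "African American": 843_830,
            "Asian": 101_440,
            "Hispanic/Latino": 70_900,
            "Unknown": 630_950,
        },
    },
    "OUD+Type2Diabetes": {
        "total": 71_430,
        "sex": {"Female": 37_770, "Male": 33_420, "Unknown": 290},
        "age": {"Adult": 45_080, "Senior": 26_640, "Junior": 20},
        "race": {
            "White": 50_940,
            "African American": 15_830,
            "Asian": 350,
            "Hispanic/Latino": 520,
            "Unknown": 8_700,
        },
    },
}

#: percentages as published, same nesting (integer percent of cohort total)
PRINTED_PERCENTS: dict = {
    "All": {
        "sex": {"Female": 54, "Male": 46, "Unknown": 1},
        "age": {"Adult": 60, "Senior": 25, "Junior": 14},
        "race": {"White": 54, "African American": 10, "Asian": 2,
                 "Hispanic/Latino": 1, "Unknown": 12},
    },
    "OUD": {
        "sex": {"Female": 51, "Male": 49, "Unknown": 0},
        "age": {"Adult": 81, "Senior": 19, "Junior": 1},
        "race": {"White": 78, "African American": 13, "Asian": 0,
                 "Hispanic/Latino": 1, "Unknown": 11},
    },
    "Hypothyroidism": {
        "sex": {"Female": 75, "Male": 24, "Unknown": 1},
        "age": {"Adult": 44, "Senior": 54, "Junior": 1},
        "race": {"White": 79, "African American": 7, "Asian": 2,
                 "Hispanic/Latino": 1, "Unknown": 13},
    },
    "OUD+Hypothyroidism": {
        "sex": {"Female": 73, "Male": 27, "Unknown": 1},
        "age": {"Adult": 61, "Senior": 39, "Junior": 0},
        "race": {"White": 84, "African American": 9, "Asian": 0,
                 "Hispanic/Latino": 0, "Unknown": 13},
    },
    "Hyperthyroidism": {
        "sex": {"Female": 77, "Male": 23, "Unknown": 0},
        "age": {"Adult": 56, "Senior": 43, "Junior": 1},
        "race": {"White": 71, "African American": 16, "Asian": 3,
                 "Hispanic/Latino": 1, "Unknown": 13},
    },
    "OUD+Hyperthyroidism": {
        "sex": {"Female": 72, "Male": 28, "Unknown": 0},
        "age": {"Adult": 68, "Senior": 32, "Junior": 0},
        "race": {"White": 78, "African American": 17, "Asian": 1,
                 "Hispanic/Latino": 1, "Unknown": 12},
    },
    "Type2Diabetes": {
        "sex": {"Female": 51, "Male": 49, "Unknown": 0},
        "age": {"Adult": 41, "Senior": 58, "Junior": 0},
        "race": {"White": 68, "African American": 17, "Asian": 2,
                 "Hispanic/Latino": 1, "Unknown": 12},
    },
    "OUD+Type2Diabetes": {
        "sex": {"Female": 53, "Male": 47, "Unknown": 0},
        "age": {"Adult": 63, "Senior": 37, "Junior": 0},
        "race": {"White": 71, "African American": 22, "Asian": 0,
                 "Hispanic/Latino": 1, "Unknown": 12},
    },
}

#: headline cohort sizes for the crude odds-ratio worked examples
POPULATION_TOTAL = 74_574_090
OUD_TOTAL = 370_470
OUTCOME_TOTALS = {
    "Hypothyroidism": 3_739_290,
    "Hyperthyroidism": 499_290,
    "Type2Diabetes": 5_051_290,
}
OUD_OUTCOME_OVERLAP = {
    "Hypothyroidism": 50_320,
    "Hyperthyroidism": 10_410,
    "Type2Diabetes": 71_430,
}


def outcome_two_by_two(outcome: str):
    """Crude exposure/outcome 2x2 for one outcome from the headline totals."""
    from .case_control import TwoByTwo

    a = OUD_OUTCOME_OVERLAP[outcome]
    b = OUD_TOTAL - a
    c = OUTCOME_TOTALS[outcome] - a
    d = POPULATION_TOTAL - OUD_TOTAL - c
    return TwoByTwo(a, b, c, d)
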