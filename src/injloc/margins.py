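"""Published NEISS-FISS 1993-2015 sample margins used as reference inputs.

These are the printed unweighted counts from the public descriptive table
of the NEISS Firearm Injury Surveillance Study analysis sample (59 025
nonfatal gunshot injuries after BB-gun/non-GSW exclusion, of which 26 392
lack a coded injury location).  They serve two purposes: (1) arithmetic
identity checks — the printed percentages and the 70/30 split sizes must
be recomputable from the printed counts; (2) calibration targets for the
synthetic generator's covariate distributions.
"""

from __future__ import annotations

#: Header sizes of the four sample columns.
SAMPLE_SIZES = {
    "overall": 59_025,
    "missing": 26_392,
    "test": 9_790,
    "train": 22_843,
}

#: Unweighted counts in the "Overall" column, by characteristic.
OVERALL_COUNTS = {
    "sex": {"male": 52_630, "female": 6_378},
    "disposition": {
        "treated_released": 24_229,
        "transferred_released": 1_950,
        "transferred_hospital": 70,
        "hospitalized": 31_716,
        "observation": 674,
    },
    "race": {
        "not_stated": 11_353,
        "white": 11_642,
        "black": 29_304,
        "other": 6_726,
    },
    "age_group": {
        "0-14": 2_277, "15-24": 27_037, "25-34": 15_705, "35-44": 7_452,
        "45-54": 3_635, "55-64": 1_524, "65+": 1_073,
    },
    "body_part": {
        "head_neck": 8_410, "upper_trunk": 10_702, "lower_trunk": 9_741,
        "arm_hand": 9_052, "leg_foot": 20_228, "other": 578,
    },
    "stratum": {
        "small": 2_374, "medium": 3_862, "large": 8_535,
        "very_large": 42_314, "childrens": 1_940,
    },
    "intent": {
        "unknown": 6_396, "unintentional": 7_434,
        "assault": 42_099, "self_harm": 2_510,
    },
}

#: Counts in the "Missing location" column for the characteristics the
#: missingness model is calibrated against.
MISSING_COLUMN_COUNTS = {
    "disposition": {
        "treated_released": 10_240,
        "transferred_released": 753,
        "transferred_hospital": 32,
        "hospitalized": 14_944,
        "observation": 198,
    },
    "intent": {
        "unknown": 4_678, "unintentional": 2_602,
        "assault": 17_951, "self_harm": 930,
    },
}


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Percentage as printed in surveillance tables (rounded half-away-like
    ordinary float rounding to one decimal by default)."""
    return round(100.0 * count / total, decimals)
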