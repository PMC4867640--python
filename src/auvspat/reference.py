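"""Published summary statistics of the Porcupine Abyssal Plain AUV survey.

Effort and count summaries of the 2012 Autosub6000 photographic campaign
at the Porcupine Abyssal Plain (one 10 x 10 km broad grid over an abyssal
hill plus three 1 x 1 km fine grids) and the accompanying SHRIMP towed
video transect.  These printed values serve as worked-example inputs and
cross-checks for the estimators in this package; the underlying images
were never deposited.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "survey_summary",
    "fish_totals",
    "TOTAL_IMAGES",
    "shrimp_transect",
    "PLAIN_DENSITY_ALL_FISH",
    "TARGET_ALTITUDE_M",
    "VERTICAL_FOOTPRINT_M2",
    "OBLIQUE_FOOTPRINT_M2",
]

#: Per-sub-survey image counts and surveyed areas (km^2) by camera.
_SURVEY_SUMMARY_CSV = """\
survey_id,scale,depth_min_m,depth_max_m,oblique_images,oblique_area_km2,vertical_images,vertical_area_km2
B1,broad,4806,4852,44684,0.318,102072,0.150
F1,fine,4847,4851,0,0.0,13235,0.035
F2,fine,4768,4820,10488,0.072,47967,0.031
F3,fine,4846,4848,13910,0.092,27766,0.042
"""

#: Total individual fish recorded per camera across all sub-surveys.
_FISH_TOTALS = {"oblique": 203, "vertical": 194}

#: Published total image counts per camera.  Note: the per-sub-survey
#: image counts above do not sum exactly to these printed totals (69,082
#: and 191,040 respectively); the published percentages of fish-bearing
#: images derive from the totals given here.
TOTAL_IMAGES = {"oblique": 71_035, "vertical": 180_715}

#: Towed-video transect: all-fish count and track length.
_SHRIMP = {"n_fish": 11, "length_km": 3.4}

#: Reported all-fish density on the abyssal plain (>4840 m), individuals
#: km^-2, with its bootstrap 95% interval.
PLAIN_DENSITY_ALL_FISH = {"density": 723.0, "ci_low": 601.0, "ci_high": 844.0}

TARGET_ALTITUDE_M = 3.2
VERTICAL_FOOTPRINT_M2 = 2.4
OBLIQUE_FOOTPRINT_M2 = 16.5


def survey_summary() -> pd.DataFrame:
    """Effort summary per sub-survey (images and km^2 per camera)."""
    return pd.read_csv(io.StringIO(_SURVEY_SUMMARY_CSV))


def fish_totals() -> dict[str, int]:
    """Total fish individuals observed per camera."""
    return dict(_FISH_TOTALS)


def shrimp_transect() -> dict[str, float]:
    """All-fish count and length (km) of the towed video transect."""
    return dict(_SHRIMP)
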