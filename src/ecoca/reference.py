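"""Published land-use accounting tables for the Beijing study region.

These printed values (km²) are inputs for desk-scale reproduction of the
region's reported transition accounting and scenario area changes: the
2000→2005 inter-class transition matrix, the 2005 status areas, and the
three simulated 2020 outcomes. Cell size is 100 m; the landscape totals
16,385.72 km².
"""

import numpy as np
import pandas as pd

from .grid import DEFAULT_SCHEME

CLASS_NAMES = DEFAULT_SCHEME.names

#: 2000 (rows) → 2005 (columns) transition areas, km².
TRANSITION_2000_2005 = pd.DataFrame(
    np.array(
        [
            [3012.09, 618.74, 914.19, 8.83],
            [876.13, 8476.67, 305.07, 16.43],
            [342.40, 128.64, 1664.36, 5.29],
            [2.04, 13.10, 1.70, 0.04],
        ]
    ),
    index=CLASS_NAMES,
    columns=CLASS_NAMES,
)

#: Status and simulated 2020 class areas, km², by scenario.
AREAS = {
    "status_2000": pd.Series(
        {"cultivated": 4553.85, "ecological": 9674.30, "construction": 2140.69, "other": 16.88}
    ),
    "status_2005": pd.Series(
        {"cultivated": 4232.66, "ecological": 9237.15, "construction": 2885.32, "other": 30.59}
    ),
    "natural_development_2020": pd.Series(
        {"cultivated": 3798.57, "ecological": 8728.13, "construction": 3835.82, "other": 23.20}
    ),
    "object_orientation_2020": pd.Series(
        {"cultivated": 4003.17, "ecological": 9105.78, "construction": 3189.32, "other": 29.15}
    ),
    "ecosystem_priority_2020": pd.Series(
        {"cultivated": 3903.64, "ecological": 9266.64, "construction": 3189.32, "other": 25.72}
    ),
}

#: Planning caps (2006–2020): construction increment ≤ 304 km²; cultivated
#: decline controlled at 7.97% of the base area.
CONSTRUCTION_INCREMENT_CAP_KM2 = 304.0
CULTIVATED_DECLINE_CAP_PCT = 7.97


def area_frame(key: str) -> pd.DataFrame:
    """One published area vector as an AreaTable-style frame."""
    s = AREAS[key]
    return pd.DataFrame(
        {"area_km2": s, "proportion_pct": 100.0 * s / s.sum()}
    )
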