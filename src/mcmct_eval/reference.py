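"""Bundled reference inputs: three commercial study farms and the published
field-evaluation percentages for the monitoring system on those farms.

The farm descriptors (herd size, barn area, equipment, cameras) and the
per-task confusion-cell percentages are inputs for worked examples and for
desk-scale recomputation of the derived quantities (densities, ratios,
recall/precision/F1).  They are data, not code behaviour: nothing in the
package tunes itself to these numbers.
"""

from __future__ import annotations

from .farm_config import FarmConfig, validate_farm_config

#: Raw descriptors of the three study farms (western-France freestall barns,
#: Holstein herds, automatic milking).  Heights/spacings are stored metadata.
FARM_DESCRIPTORS = {
    "H1": {
        "farm_id": "H1",
        "n_cows": 70,
        "barn_area": 625.0,
        "n_cubicles": 66,
        "n_water_troughs": 2,
        "n_ams": 1,
        "n_cameras": 3,
        "camera_height": 4.9,
        "camera_spacing": 14.5,
    },
    "H2": {
        "farm_id": "H2",
        "n_cows": 140,
        "barn_area": 1225.0,
        "n_cubicles": 132,
        "n_water_troughs": 5,
        "n_ams": 2,
        "n_cameras": 8,
        "camera_height": 5.7,
        "camera_spacing": 13.4,
    },
    "H3": {
        "farm_id": "H3",
        "n_cows": 250,
        "barn_area": 1820.0,
        "n_cubicles": 218,
        "n_water_troughs": 8,
        "n_ams": 5,
        "n_cameras": 14,
        "camera_height": 6.0,
        "camera_spacing": 13.8,
    },
}


def reference_farms() -> dict[str, FarmConfig]:
    """The three study farms as validated :class:`FarmConfig` objects."""
    return {k: validate_farm_config(v) for k, v in FARM_DESCRIPTORS.items()}


#: Published per-task confusion-cell percentages and metrics, per farm:
#: (tp_pct, fn_pct, fp_pct, recall_pct, precision_pct, f1_pct).
#: TP + FN sums to ~100% of truly present evaluated cows; FP (detection-stage
#: spurious outputs) sits outside that sum and is shared across the three
#: tasks within a farm.
REFERENCE_PERFORMANCE = {
    "identification": {
        "H1": (69.01, 30.94, 6.57, 69.05, 91.31, 78.61),
        "H2": (78.05, 21.95, 12.76, 78.05, 85.95, 81.77),
        "H3": (75.36, 24.64, 15.22, 75.36, 83.22, 79.03),
    },
    "activity": {
        "H1": (84.78, 15.10, 6.57, 84.88, 92.80, 88.66),
        "H2": (87.86, 12.13, 12.76, 87.86, 87.33, 87.48),
        "H3": (99.01, 0.99, 15.22, 99.01, 86.68, 92.39),
    },
    "location": {
        "H1": (84.78, 15.10, 6.57, 84.88, 92.80, 88.66),
        "H2": (92.79, 7.21, 12.76, 92.79, 87.91, 90.31),
        "H3": (99.01, 0.99, 15.22, 99.01, 86.68, 92.39),
    },
}

#: Published daily detection performance (recall %, precision %) per farm,
#: from the 31-day AMS-list vs detection-list comparison.
REFERENCE_DETECTION = {
    "H1": (90.6, 93.2),
    "H2": (92.8, 87.9),
    "H3": (99.6, 86.7),
}

#: Published derived farm summaries: (stocking density m^2/cow, cows/camera).
REFERENCE_FARM_SUMMARIES = {
    "H1": (8.9, 23.3),
    "H2": (8.8, 17.5),
    "H3": (7.3, 17.9),
}
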