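"""Bundled reference data: the two-radiologist observer preference study.

A reading study on seven multi-phase cCTA cases produced 167 best/worst
branch pairs (102 LCA, 65 RCA).  Two experienced cardiothoracic radiologists
each chose the better-looking branch of every pair; the published per-case
pair counts, percent agreements, kappas, and Landis-Koch categories are
reproduced here so the aggregation arithmetic (pooled percent agreement,
average kappa, category binning) can be exercised and checked against the
published overall figures.

Comparisons: "rad1_computer" = radiologist 1 vs the automated VQM selection,
"rad2_computer" = radiologist 2 vs the automated selection, "rad1_rad2" =
the two radiologists against each other.
"""

from __future__ import annotations

COMPARISONS = ("rad1_computer", "rad2_computer", "rad1_rad2")

OBSERVER_STUDY = {
    "cases": [1, 2, 3, 4, 5, 6, 7],
    # total / LCA / RCA pairs per case
    "n_pairs": [31, 14, 25, 38, 18, 26, 15],
    "n_pairs_lca": [17, 11, 12, 23, 13, 16, 10],
    "n_pairs_rca": [14, 3, 13, 15, 5, 10, 5],
    "percent_agreement": {
        "rad1_computer": [90, 93, 84, 79, 61, 62, 53],
        "rad2_computer": [90, 93, 76, 74, 67, 77, 47],
        "rad1_rad2": [94, 86, 84, 82, 83, 62, 80],
    },
    "kappa": {
        "rad1_computer": [0.87, 0.81, 0.68, 0.56, 0.24, 0.21, 0.04],
        "rad2_computer": [0.80, 0.81, 0.51, 0.50, 0.33, 0.32, -0.13],
        "rad1_rad2": [0.87, 0.65, 0.68, 0.61, 0.67, 0.18, 0.33],
    },
    "kappa_category": {
        "rad1_computer": [
            "Almost perfect", "Almost perfect", "Substantial", "Moderate",
            "Fair", "Fair", "Slight",
        ],
        "rad2_computer": [
            "Substantial", "Almost perfect", "Moderate", "Moderate",
            "Fair", "Fair", "Less than chance",
        ],
        "rad1_rad2": [
            "Almost perfect", "Substantial", "Substantial", "Substantial",
            "Substantial", "Slight", "Fair",
        ],
    },
}

# Published overall figures, for cross-checking the aggregation arithmetic.
REPORTED_OVERALL = {
    "n_pairs": 167,
    "percent_agreement": {"rad1_computer": 76, "rad2_computer": 76, "rad1_rad2": 81},
    "kappa": {"rad1_computer": 0.49, "rad2_computer": 0.45, "rad1_rad2": 0.57},
    "kappa_category": {
        "rad1_computer": "Moderate",
        "rad2_computer": "Moderate",
        "rad1_rad2": "Moderate",
    },
}
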