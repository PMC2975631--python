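"""Reference summary tables from a high-risk preterm (ELBW) newborn cohort.

These are published cohort-level summary statistics — per-structure
within-subject SDs, repeatability values and ICCs from repeated manual
segmentations, and mean tissue volumes under the automated, semi-automated
and manual approaches — used by the worked examples, the report-format
checks, and the acceptance script. They are inputs (printed numbers), not
quantities this package computes; the package's own statistics are checked
for consistency against them (e.g. the repeatability column must equal
2.77x the SD column).

All volumes in mm^3.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "INTRA_RATER_RELIABILITY",
    "INTER_RATER_RELIABILITY",
    "WMSA_RELIABILITY",
    "STRUCTURE_MEAN_VOLUMES",
    "TISSUE_MEAN_VOLUMES",
]

# Intra-rater reliability of repeated manual segmentation (20 infants):
# region -> (within-subject SD, repeatability, ICC, ICC 95% CI low, high)
INTRA_RATER_RELIABILITY: dict[str, tuple[float, float, float, float, float]] = {
    "cerebellum":          (261.9, 725.4, 0.998, 0.994, 0.999),
    "brain_stem":          (82.7, 229.0, 0.990, 0.975, 0.996),
    "amygdalae":           (20.8, 57.6, 0.970, 0.925, 0.988),
    "hippocampi":          (37.6, 104.1, 0.981, 0.952, 0.992),
    "accumbens":           (17.4, 48.3, 0.984, 0.960, 0.994),
    "caudate":             (97.1, 269.0, 0.975, 0.937, 0.990),
    "lenticular":          (133.9, 370.9, 0.985, 0.962, 0.994),
    "thalamus":            (134.7, 373.0, 0.970, 0.925, 0.998),
    "corpus_callosum":     (25.0, 69.3, 0.990, 0.974, 0.996),
    "cerebral_gm":         (2674.6, 7408.5, 0.997, 0.988, 0.999),
    "cerebral_wm":         (2633.9, 7295.9, 0.995, 0.979, 0.999),
    "csf":                 (1249.4, 3460.9, 0.997, 0.988, 0.999),
}

# Inter-rater reliability (two raters, same cohort), same column layout.
INTER_RATER_RELIABILITY: dict[str, tuple[float, float, float, float, float]] = {
    "cerebellum":          (393.1, 1089.0, 0.996, 0.983, 0.999),
    "brain_stem":          (154.5, 427.8, 0.974, 0.934, 0.990),
    "amygdalae":           (51.7, 143.2, 0.942, 0.854, 0.977),
    "hippocampi":          (81.7, 226.4, 0.970, 0.924, 0.988),
    "accumbens":           (23.2, 64.1, 0.984, 0.939, 0.996),
    "caudate":             (163.0, 451.4, 0.975, 0.907, 0.993),
    "lenticular":          (246.8, 683.5, 0.993, 0.975, 0.998),
    "thalamus":            (166.7, 461.8, 0.992, 0.972, 0.998),
    "corpus_callosum":     (73.7, 204.1, 0.963, 0.908, 0.986),
    "cerebral_gm":         (7453.6, 20646.3, 0.933, 0.732, 0.984),
    "cerebral_wm":         (8402.6, 23275.2, 0.977, 0.905, 0.994),
    "csf":                 (1927.3, 5338.7, 0.998, 0.990, 0.999),
}

# WMSA relabeling intra-rater reliability (10 infants):
# (mean volume, within-subject SD, repeatability, ICC)
WMSA_RELIABILITY = {"mean_volume": 5524.2, "within_subject_sd": 42.7,
                    "repeatability": 118.3, "icc": 0.999}

# Mean manually segmented structure volumes (20 infants), mm^3.
STRUCTURE_MEAN_VOLUMES: dict[str, float] = {
    "cerebellum": 15800.9,
    "brain_stem": 5603.9,
    "amygdalae": 485.1,
    "hippocampi": 1211.8,
    "accumbens": 389.2,
    "caudate": 2597.0,
    "lenticular": 5253.1,
    "thalamus": 7248.7,
    "corpus_callosum": 803.0,
}

# Mean tissue volumes (10 infants) under the three approaches, mm^3.
TISSUE_MEAN_VOLUMES: dict[str, dict[str, float]] = {
    "automated":      {"cerebral_gm": 94279, "cerebral_wm": 113326,
                       "csf": 62233, "total": 269838},
    "semi_automated": {"cerebral_gm": 92973, "cerebral_wm": 111753,
                       "csf": 65239, "total": 269965},
    "manual":         {"cerebral_gm": 91918, "cerebral_wm": 113444,
                       "csf": 65095, "total": 270457},
}


def intra_rater_table() -> pd.DataFrame:
    """Intra-rater reliability as a DataFrame in standard column order."""
    return pd.DataFrame(
        [(k, *v) for k, v in INTRA_RATER_RELIABILITY.items()],
        columns=["region", "within_subject_sd_mm3", "repeatability_mm3",
                 "icc", "icc_ci_low", "icc_ci_high"])


def tissue_volume_percent_differences() -> dict[str, float]:
    """Percent |semi-automated - manual| difference per tissue, of manual."""
    semi = TISSUE_MEAN_VOLUMES["semi_automated"]
    manual = TISSUE_MEAN_VOLUMES["manual"]
    return {k: 100.0 * abs(semi[k] - manual[k]) / manual[k] for k in manual}
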