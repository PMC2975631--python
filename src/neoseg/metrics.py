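"""Segmentation accuracy indices and rater-reliability statistics.

Accuracy of an automated map against a reference map is summarized per class
from voxel confusion counts (TP, FP, FN):

    SI  = 2 TP / (2 TP + FP + FN)      (Dice similarity index)
    CEI = TP / (TP + FN)               (correct estimation index)
    OEI = FP / (TP + FN)               (over-estimation index)
    UEI = FN / (TP + FN)               (under-estimation index)

CEI + UEI = 1 by construction; SI is symmetric in reference/automated while
the estimation indices are reference-relative.

Reliability of repeated volume measurements uses

* within-subject SD: square root of the one-way ANOVA residual (within-
  subject) mean square; for paired repeats this equals sqrt(sum d_i^2 / 2n);
* repeatability: 2.77 x within-subject SD (the 95% limit for the absolute
  difference of two repeated measurements on the same subject);
* ICC: intraclass correlation from ANOVA mean squares — one-way random
  ICC(1,1) for intra-rater designs, two-way random single-measure absolute-
  agreement ICC(2,1) for inter-rater designs — with F-based 95% CIs.

Undefined statistics (empty reference, zero variance) are reported as NaN
with an explicit flag, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volumes_io import GeometryError, LabelMap

__all__ = [
    "ConfusionCounts",
    "confusion",
    "similarity_index",
    "estimation_indices",
    "accuracy_report",
    "within_subject_sd",
    "repeatability",
    "icc",
    "ICCResult",
    "reliability_report",
    "DesignError",
]

REPEATABILITY_FACTOR = 2.77


class DesignError(ValueError):
    """Measurement table does not satisfy the design the statistic needs."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel counts for one class: reference vs automated segmentation."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def ref_size(self) -> int:
        return self.tp + self.fn

    @property
    def auto_size(self) -> int:
        return self.tp + self.fp


def confusion(ref: LabelMap | np.ndarray, auto: LabelMap | np.ndarray,
              class_code: int) -> ConfusionCounts:
    """Voxelwise TP/FP/FN of ``auto`` against ``ref`` for one class."""
    r = ref.labels if isinstance(ref, LabelMap) else np.asarray(ref)
    a = auto.labels if isinstance(auto, LabelMap) else np.asarray(auto)
    if r.shape != a.shape:
        raise GeometryError(f"shape mismatch: {r.shape} vs {a.shape}")
    rin = r == class_code
    ain = a == class_code
    return ConfusionCounts(tp=int(np.count_nonzero(rin & ain)),
                           fp=int(np.count_nonzero(~rin & ain)),
                           fn=int(np.count_nonzero(rin & ~ain)))


def similarity_index(counts: ConfusionCounts) -> float:
    """Dice SI = 2 TP / (2 TP + FP + FN); NaN when both maps are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return float("nan")
    return 2.0 * counts.tp / denom


def estimation_indices(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(CEI, OEI, UEI) relative to the reference size; NaN triple if empty."""
    ref = counts.ref_size
    if ref == 0:
        return (float("nan"),) * 3
    return counts.tp / ref, counts.fp / ref, counts.fn / ref


def accuracy_report(ref: LabelMap, auto: LabelMap,
                    classes: list[int]) -> pd.DataFrame:
    """Per-class table with columns class, code, SI, CEI, OEI, UEI."""
    rows = []
    for code in classes:
        c = confusion(ref, auto, code)
        cei, oei, uei = estimation_indices(c)
        rows.append({
            "class": ref.scheme.name(code), "code": int(code),
            "SI": similarity_index(c), "CEI": cei, "OEI": oei, "UEI": uei,
            "ref_voxels": c.ref_size, "auto_voxels": c.auto_size,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

def _grouped(measures: pd.DataFrame, value_col: str = "volume",
             subject_col: str = "subject") -> list[np.ndarray]:
    if subject_col not in measures or value_col not in measures:
        raise DesignError(f"need columns {subject_col!r} and {value_col!r}")
    groups = [np.asarray(g[value_col], dtype=np.float64)
              for _, g in measures.groupby(subject_col)]
    for g in groups:
        if g.size < 2:
            raise DesignError("every subject needs >= 2 observations")
    return groups


def within_subject_sd(measures: pd.DataFrame, value_col: str = "volume",
                      subject_col: str = "subject") -> float:
    """sqrt of the one-way ANOVA within-subject mean square.

    ``measures`` is long-form with one row per observation. For a duplicate
    design this reduces to sqrt(sum of squared differences / 2n).
    """
    groups = _grouped(measures, value_col, subject_col)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    dfw = sum(g.size - 1 for g in groups)
    return float(np.sqrt(ssw / dfw))


def repeatability(sd: float) -> float:
    """95% limit for the difference of two repeats: 2.77 x within-subject SD."""
    if sd < 0:
        raise ValueError("within-subject SD cannot be negative")
    return REPEATABILITY_FACTOR * sd


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str

    @property
    def defined(self) -> bool:
        return np.isfinite(self.estimate)


def _measure_matrix(measures: pd.DataFrame, value_col: str,
                    subject_col: str, within_col: str | None) -> np.ndarray:
    """Subjects x repeats matrix; raises DesignError if unbalanced."""
    if within_col is not None and within_col in measures:
        wide = measures.pivot_table(index=subject_col, columns=within_col,
                                    values=value_col, aggfunc="first")
        if wide.isna().any().any():
            raise DesignError("unbalanced design: missing cells")
        return wide.to_numpy(dtype=np.float64)
    groups = _grouped(measures, value_col, subject_col)
    k = groups[0].size
    if any(g.size != k for g in groups):
        raise DesignError("unbalanced design: unequal repeats per subject")
    return np.vstack(groups)


def icc(measures: pd.DataFrame, model: str = "icc1",
        value_col: str = "volume", subject_col: str = "subject",
        within_col: str | None = "repeat", alpha: float = 0.05) -> ICCResult:
    """Intraclass correlation with F-based 95% CI from ANOVA mean squares.

    ``model`` is ``"icc1"`` (one-way random, single measure — intra-rater
    repeats) or ``"icc2"`` (two-way random, single measure, absolute
    agreement — inter-rater). Returns NaN estimate when both between- and
    within-subject variance vanish.
    """
    x = _measure_matrix(measures, value_col, subject_col, within_col)
    n, k = x.shape
    if n < 2:
        raise DesignError("need >= 2 subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ssb = k * float(((row_means - grand) ** 2).sum())          # between subjects
    ssw = float(((x - row_means[:, None]) ** 2).sum())         # within subjects
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))

    if model == "icc1":
        if msb == 0 and msw == 0:
            return ICCResult(float("nan"), float("nan"), float("nan"), "ICC(1,1)")
        est = (msb - msw) / (msb + (k - 1) * msw) if (msb + (k - 1) * msw) else float("nan")
        if msw == 0:
            return ICCResult(1.0, 1.0, 1.0, "ICC(1,1)")
        fobs = msb / msw
        fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        fu = fobs * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return ICCResult(float(est), float(lo), float(hi), "ICC(1,1)")

    if model == "icc2":
        ssc = n * float(((col_means - grand) ** 2).sum())      # between raters
        sse = ssw - ssc
        msc = ssc / (k - 1)
        mse = sse / ((n - 1) * (k - 1))
        denom = msb + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            return ICCResult(float("nan"), float("nan"), float("nan"), "ICC(2,1)")
        est = (msb - mse) / denom
        if mse == 0 and msc == 0:
            return ICCResult(1.0, 1.0, 1.0, "ICC(2,1)")
        # McGraw & Wong CI for ICC(A,1)
        a = k * est / (n * (1 - est)) if est < 1 else np.inf
        b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
        v = ((a * msc + b * mse) ** 2 /
             ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
        f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
        lo = (n * (msb - f_star * mse) /
              (f_star * (k * msc + (k * n - k - n) * mse) + n * msb))
        f_star2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        hi = (n * (f_star2 * msb - mse) /
              (k * msc + (k * n - k - n) * mse + n * f_star2 * msb))
        return ICCResult(float(est), float(lo), float(hi), "ICC(2,1)")

    raise ValueError(f"unknown ICC model {model!r}")


def reliability_report(measures: pd.DataFrame, model: str = "icc1",
                       value_col: str = "volume", subject_col: str = "subject",
                       region_col: str | None = "region",
                       within_col: str | None = "repeat") -> pd.DataFrame:
    """Per-region reliability table: within-subject SD, repeatability, ICC.

    Columns mirror the standard presentation (SD and repeatability in mm^3 to
    one decimal, ICC with 95% CI to three decimals); the ``repeatability``
    column is exactly 2.77 x the SD column before rounding.
    """
    if region_col is not None and region_col in measures:
        regions = [(name, grp) for name, grp in measures.groupby(region_col)]
    else:
        regions = [("all", measures)]
    rows = []
    for name, grp in regions:
        sd = round(within_subject_sd(grp, value_col, subject_col), 1)
        res = icc(grp, model=model, value_col=value_col,
                  subject_col=subject_col, within_col=within_col)
        rows.append({
            "region": name,
            "within_subject_sd_mm3": sd,
            "repeatability_mm3": round(repeatability(sd), 1),
            "icc": round(res.estimate, 3) if res.defined else float("nan"),
            "icc_ci_low": round(res.ci_low, 3) if res.defined else float("nan"),
            "icc_ci_high": round(res.ci_high, 3) if res.defined else float("nan"),
            "icc_model": res.model,
        })
    return pd.DataFrame(rows)
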