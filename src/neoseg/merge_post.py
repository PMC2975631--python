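"""Post-EM correction, structural-map merging, WMSA relabeling, full pipeline.

After the HMRF-EM stage three label-editing operations complete the map:

* **Surface relabel** — partial-volume voxels at the brain surface are often
  called WM although they are CSF; WM within 2-3 voxels of the mask surface
  (per axial slice, 3x3 erosion) is relabeled CSF.
* **Structural merge** — a manually produced map of nine subcortical /
  posterior-fossa structures (codes 10-18) is pasted onto the tissue map:
  structural codes win wherever present.
* **WMSA relabel** — periventricular white matter signal abnormality mimics
  CSF intensity and is consistently mislabeled CSF; a rater-approved
  correction mask turns those CSF voxels into WMSA (code 4). The package
  never relabels WMSA without a mask, but can propose candidate regions
  (interior CSF components near the ventricles) for human review.

Each edit is monotone and auditable: surface relabel only turns WM into CSF,
merge only overwrites with structural codes, WMSA relabel only turns CSF into
WMSA, and the total in-mask voxel count never changes.

``run_pipeline`` chains everything: brain mask -> diffusion -> normalization
-> Parzen initial labels -> HMRF-EM -> surface relabel -> merge -> WMSA.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes_io import (BACKGROUND, CSF, WM, WMSA, STRUCTURE_CODES,
                         GeometryError, LabelMap, MultiChannelVolume,
                         volume_report)
from .preprocess import (BrainMask, NormalizationModel, anisotropic_diffusion,
                         apply_normalization, extract_brain_mask)
from .parzen import FeatureMap, TrainingSample, build_feature_map, classify_initial
from .hmrf_em import BiasField, MRFConfig, em_fit

__all__ = [
    "MergePolicy",
    "relabel_surface_wm",
    "merge_structural",
    "relabel_wmsa",
    "suggest_wmsa_candidates",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger("neoseg")

_KERNEL_3X3 = np.ones((3, 3), dtype=bool)


@dataclass
class MergePolicy:
    """Structural-overwrites-tissue precedence plus post-correction knobs."""

    surface_depth: int = 2          # voxels of surface WM relabeled to CSF
    wmsa_max_distance_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.surface_depth not in (2, 3):
            raise ValueError("surface relabel depth must be 2 or 3")
        if self.wmsa_max_distance_mm <= 0:
            raise ValueError("candidate distance must be positive")


def relabel_surface_wm(labels: LabelMap, mask: BrainMask | np.ndarray,
                       depth: int = 2) -> LabelMap:
    """Relabel surface WM as CSF per axial slice.

    The brain mask is eroded ``depth`` times with a 3x3 in-plane kernel; WM
    voxels inside the mask but outside the eroded mask become CSF. No other
    code is touched. Empty mask slices are skipped with a warning.
    """
    if depth not in (2, 3):
        raise ValueError("depth must be 2 or 3")
    m = mask.mask if isinstance(mask, BrainMask) else np.asarray(mask).astype(bool)
    if m.shape != labels.shape:
        raise GeometryError("mask/labels shape mismatch")
    out = labels.labels.copy()
    for z in range(m.shape[2]):
        sl = m[:, :, z]
        if not sl.any():
            logger.warning("surface relabel: empty mask slice %d skipped", z)
            continue
        eroded = ndimage.binary_erosion(sl, structure=_KERNEL_3X3,
                                        iterations=depth)
        rim = sl & ~eroded
        sel = rim & (out[:, :, z] == WM)
        out[:, :, z][sel] = CSF
    return labels.with_labels(out)


def merge_structural(tissue_labels: LabelMap,
                     structural_labels: LabelMap) -> LabelMap:
    """Paste the structural map onto the tissue map (structural codes win)."""
    tissue_labels.check_geometry(structural_labels)
    s = structural_labels.labels
    bad = np.setdiff1d(np.unique(s), np.array([BACKGROUND, *STRUCTURE_CODES]))
    if bad.size:
        raise ValueError(f"structural map carries non-structural codes {bad.tolist()}")
    out = np.where(s != BACKGROUND, s, tissue_labels.labels)
    return tissue_labels.with_labels(out)


def relabel_wmsa(labels: LabelMap, correction_mask: np.ndarray) -> LabelMap:
    """Turn CSF voxels inside a rater-approved mask into WMSA.

    Mask voxels not labeled CSF are counted and reported (logged), never
    relabeled: the operation is strictly CSF -> WMSA.
    """
    cm = np.asarray(correction_mask).astype(bool)
    if cm.shape != labels.shape:
        raise GeometryError("correction mask shape mismatch")
    out = labels.labels.copy()
    target = cm & (out == CSF)
    skipped = int(cm.sum() - target.sum())
    if skipped:
        logger.info("WMSA relabel: %d masked voxels were not CSF and were left "
                    "untouched", skipped)
    out[target] = WMSA
    return labels.with_labels(out)


def suggest_wmsa_candidates(
    labels: LabelMap,
    reference_region: np.ndarray,
    max_distance_mm: float = 10.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Propose interior CSF components near the ventricles for human review.

    Returns a boolean mask of CSF-labeled connected components (3-D,
    6-connectivity) that do NOT touch the subarachnoid surface (the brain-mask
    boundary) and lie within ``max_distance_mm`` of ``reference_region``
    (a ventricle or periventricular structure mask). May be empty.
    """
    ref = np.asarray(reference_region).astype(bool)
    if ref.shape != labels.shape:
        raise GeometryError("reference region shape mismatch")
    if mask is None:
        mask = labels.labels != BACKGROUND
    mask = np.asarray(mask).astype(bool)

    csf = labels.labels == CSF
    comp, n = ndimage.label(csf)
    if n == 0:
        return np.zeros(labels.shape, dtype=bool)

    # surface shell of the brain mask: voxels with an out-of-mask face neighbor
    interior = ndimage.binary_erosion(mask)
    shell = mask & ~interior
    surface_ids = np.unique(comp[shell & csf])
    surface_ids = surface_ids[surface_ids > 0]

    if ref.any():
        dist = ndimage.distance_transform_edt(~ref, sampling=labels.spacing)
    else:
        dist = np.full(labels.shape, np.inf)

    out = np.zeros(labels.shape, dtype=bool)
    for cid in range(1, n + 1):
        if cid in surface_ids:
            continue  # surface-connected subarachnoid CSF is never a candidate
        sel = comp == cid
        if dist[sel].min() <= max_distance_mm:
            out |= sel
    return out


@dataclass
class PipelineResult:
    """Bundle of everything the one-command pipeline produces."""

    labels: LabelMap
    bias: BiasField
    mask: BrainMask
    normalized: MultiChannelVolume
    initial_labels: LabelMap
    em_labels: LabelMap
    report: pd.DataFrame
    timings: dict[str, float] = field(default_factory=dict)


def _stage(timings: dict[str, float], name: str):
    class _Timer:
        def __enter__(self_inner):
            self_inner.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self_inner

        def __exit__(self_inner, exc_type, exc, tb):
            dt = time.perf_counter() - self_inner.t0
            timings[name] = dt
            if exc is not None:
                logger.error("stage %s: FAILED after %.2fs (%s)", name, dt, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False
    return _Timer()


def run_pipeline(
    volume: MultiChannelVolume,
    *,
    seed_voxel: tuple[int, int, int] | None = None,
    seed_band: tuple[float, float] | None = None,
    brain_mask: BrainMask | None = None,
    feature_map: FeatureMap | None = None,
    training_samples: list[TrainingSample] | None = None,
    structural_labels: LabelMap | None = None,
    wmsa_mask: np.ndarray | None = None,
    mrf_config: MRFConfig | None = None,
    policy: MergePolicy | None = None,
    diffusion_iter: int = 10,
    norm_model: "NormalizationModel | None" = None,
) -> PipelineResult:
    """Full semi-automated segmentation: one call, deterministic.

    Either ``brain_mask`` or a region-growing ``seed_voxel`` + ``seed_band``
    must be given; likewise either a prebuilt ``feature_map`` or raw
    ``training_samples``. When ``norm_model`` is given the scan is mapped
    onto its standard scale before classification — the feature map /
    training samples must then live on that same scale (i.e. be built from
    normalized training scans); without a model, raw intensities are used and
    the training set must share the scan's intensity scale. Structural
    merging and WMSA relabeling run only when their inputs are supplied (the
    human-in-the-loop steps).
    """
    policy = policy or MergePolicy()
    timings: dict[str, float] = {}

    with _stage(timings, "mask"):
        if brain_mask is None:
            if seed_voxel is None or seed_band is None:
                raise ValueError("need brain_mask or seed_voxel + seed_band")
            brain_mask = extract_brain_mask(volume, seed_voxel,
                                            seed_band[0], seed_band[1])

    with _stage(timings, "diffusion"):
        vol = MultiChannelVolume(
            pd=anisotropic_diffusion(volume.pd, n_iter=diffusion_iter),
            t2=anisotropic_diffusion(volume.t2, n_iter=diffusion_iter),
            spacing=volume.spacing, affine=volume.affine)

    if norm_model is not None:
        with _stage(timings, "normalize"):
            vol = apply_normalization(vol, brain_mask.mask, norm_model)

    with _stage(timings, "train"):
        if feature_map is None:
            if not training_samples:
                raise ValueError("need feature_map or training_samples")
            feature_map = build_feature_map(training_samples)

    with _stage(timings, "parzen"):
        initial = classify_initial(vol, brain_mask, feature_map)

    with _stage(timings, "hmrf_em"):
        params, bias, em_labels = em_fit(vol, brain_mask, initial,
                                         mrf_config or MRFConfig())

    with _stage(timings, "surface_relabel"):
        labels = relabel_surface_wm(em_labels, brain_mask,
                                    depth=policy.surface_depth)

    if structural_labels is not None:
        with _stage(timings, "merge"):
            labels = merge_structural(labels, structural_labels)

    if wmsa_mask is not None:
        with _stage(timings, "wmsa"):
            labels = relabel_wmsa(labels, wmsa_mask)

    with _stage(timings, "report"):
        report = volume_report(labels)

    return PipelineResult(labels=labels, bias=bias, mask=brain_mask,
                          normalized=vol, initial_labels=initial,
                          em_labels=em_labels, report=report, timings=timings)
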