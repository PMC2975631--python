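"""Parzen-window feature map and initial tissue classification in PD-T2 space.

A nonparametric per-class density is estimated from labeled training samples
with an isotropic 2-D Gaussian kernel,

    p_c(x) = (1/n_c) sum_i  (1 / (2 pi h_c^2)) exp(-||x - xi_i||^2 / (2 h_c^2)),

where xi_i are the n_c training samples of class c and h_c its bandwidth.
The three class densities (CSF, GM, WM) are tabulated on a regular grid over
the standardized PD-T2 plane ("feature map"); each in-brain voxel receives the
class whose density is highest at the voxel's (PD, T2) position. A parametric
HMRF-EM stage then refines these initial labels.

The bandwidth rule is a 2-D Silverman-type shrinkage: the per-class pooled
standard deviation times n^(-1/6); overridable per class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BrainMask
from .volumes_io import BACKGROUND, CSF, GM, MultiChannelVolume, LabelMap, WM

__all__ = [
    "TrainingSample",
    "FeatureMap",
    "BandwidthError",
    "CoverageError",
    "TISSUE_ORDER",
    "estimate_bandwidth",
    "build_feature_map",
    "classify_initial",
    "classify_direct",
    "samples_from_dataframe",
]

# fixed class order; also the tie-break priority (CSF > GM > WM)
TISSUE_ORDER = (CSF, GM, WM)

DEFAULT_GRID_BINS = 256


class BandwidthError(ValueError):
    """Too few samples or zero variance: bandwidth undefined."""


class CoverageError(ValueError):
    """Feature-map grid does not cover the data it is asked to classify."""


@dataclass(frozen=True)
class TrainingSample:
    """One labeled (PD, T2) intensity pair."""

    pd: float
    t2: float
    label: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pd) and np.isfinite(self.t2)):
            raise ValueError("non-finite training intensities")
        if self.label not in TISSUE_ORDER:
            raise ValueError(f"label {self.label} is not a trainable tissue code")


def samples_from_dataframe(df: pd.DataFrame) -> list[TrainingSample]:
    """Build samples from a table with columns pd, t2, label."""
    return [TrainingSample(float(r.pd), float(r.t2), int(r.label))
            for r in df.itertuples(index=False)]


def _per_class_arrays(samples: list[TrainingSample]) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    for code in TISSUE_ORDER:
        pts = np.array([[s.pd, s.t2] for s in samples if s.label == code])
        if pts.size:
            out[code] = pts
    return out


def estimate_bandwidth(samples: list[TrainingSample]) -> dict[int, float]:
    """Per-class kernel bandwidth: pooled per-axis SD x n^(-1/6).

    The pooled SD is sqrt of the mean of the two per-axis variances, so the
    rule is equivariant under a common rescaling of both channels. Requires
    at least 2 samples and nonzero variance per class present.
    """
    by_class = _per_class_arrays(samples)
    if not by_class:
        raise BandwidthError("no training samples")
    bw: dict[int, float] = {}
    for code, pts in by_class.items():
        n = pts.shape[0]
        if n < 2:
            raise BandwidthError(f"class {code}: need >= 2 samples, got {n}")
        var = pts.var(axis=0, ddof=1)
        pooled_sd = float(np.sqrt(var.mean()))
        if pooled_sd <= 0:
            raise BandwidthError(f"class {code}: zero variance")
        bw[code] = pooled_sd * n ** (-1.0 / 6.0)
    return bw


@dataclass
class FeatureMap:
    """Per-class Parzen density grids over the (PD, T2) plane.

    ``densities`` maps tissue code -> 2-D array indexed (pd_bin, t2_bin);
    ``pd_edges``/``t2_edges`` are the bin edges; ``bandwidths`` and
    ``n_samples`` record the kernel used per class. Voxel lookup is by
    nearest bin (bin centers are the evaluation points).
    """

    densities: dict[int, np.ndarray]
    pd_edges: np.ndarray
    t2_edges: np.ndarray
    bandwidths: dict[int, float]
    n_samples: dict[int, int]
    training: dict[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for code, grid in self.densities.items():
            if np.any(grid < 0):
                raise ValueError(f"negative density for class {code}")

    @property
    def pd_centers(self) -> np.ndarray:
        return 0.5 * (self.pd_edges[:-1] + self.pd_edges[1:])

    @property
    def t2_centers(self) -> np.ndarray:
        return 0.5 * (self.t2_edges[:-1] + self.t2_edges[1:])

    def mass(self, code: int) -> float:
        """Integral of one class density over the grid (should be ~1)."""
        area = np.diff(self.pd_edges)[:, None] * np.diff(self.t2_edges)[None, :]
        return float((self.densities[code] * area).sum())

    def to_files(self, density_path: str | Path, meta_path: str | Path) -> None:
        """Serialize densities (.npy stack in class order) + JSON metadata."""
        codes = sorted(self.densities)
        np.save(str(density_path), np.stack([self.densities[c] for c in codes]))
        Path(meta_path).write_text(json.dumps({
            "codes": codes,
            "pd_edges": self.pd_edges.tolist(),
            "t2_edges": self.t2_edges.tolist(),
            "bandwidths": {str(c): self.bandwidths[c] for c in codes},
            "n_samples": {str(c): self.n_samples[c] for c in codes},
        }, indent=2))

    @classmethod
    def from_files(cls, density_path: str | Path, meta_path: str | Path) -> "FeatureMap":
        meta = json.loads(Path(meta_path).read_text())
        stack = np.load(str(density_path))
        codes = meta["codes"]
        return cls(
            densities={c: stack[i] for i, c in enumerate(codes)},
            pd_edges=np.asarray(meta["pd_edges"]),
            t2_edges=np.asarray(meta["t2_edges"]),
            bandwidths={int(k): v for k, v in meta["bandwidths"].items()},
            n_samples={int(k): v for k, v in meta["n_samples"].items()},
        )


def _kernel_density(points: np.ndarray, h: float, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gaussian kernel-sum density at grid points (x[:,None], y[None,:])."""
    norm = 1.0 / (2.0 * np.pi * h * h * points.shape[0])
    dx = x[:, None, None] - points[None, None, :, 0]
    dy = y[None, :, None] - points[None, None, :, 1]
    return norm * np.exp(-(dx * dx + dy * dy) / (2.0 * h * h)).sum(axis=2)


def build_feature_map(
    samples: list[TrainingSample],
    grid_range: tuple[tuple[float, float], tuple[float, float]] | None = None,
    bandwidths: dict[int, float] | None = None,
    bins: int = DEFAULT_GRID_BINS,
) -> FeatureMap:
    """Tabulate each class's kernel density on a regular PD-T2 grid.

    ``grid_range`` is ((pd_min, pd_max), (t2_min, t2_max)); the default spans
    the samples padded by 4 bandwidths so the kernels' mass is captured.
    Raises :class:`CoverageError` when a class's density mass on the grid is
    below 0.99 (grid does not cover the samples).
    """
    by_class = _per_class_arrays(samples)
    if not by_class:
        raise ValueError("no training samples")
    if bandwidths is None:
        bandwidths = estimate_bandwidth(samples)
    hmax = max(bandwidths.values())
    pts_all = np.vstack(list(by_class.values()))
    if grid_range is None:
        lo = pts_all.min(axis=0) - 4.0 * hmax
        hi = pts_all.max(axis=0) + 4.0 * hmax
        grid_range = ((lo[0], hi[0]), (lo[1], hi[1]))
    (pd_lo, pd_hi), (t2_lo, t2_hi) = grid_range
    pd_edges = np.linspace(pd_lo, pd_hi, bins + 1)
    t2_edges = np.linspace(t2_lo, t2_hi, bins + 1)
    xc = 0.5 * (pd_edges[:-1] + pd_edges[1:])
    yc = 0.5 * (t2_edges[:-1] + t2_edges[1:])

    densities: dict[int, np.ndarray] = {}
    n_samples: dict[int, int] = {}
    for code, pts in by_class.items():
        densities[code] = _kernel_density(pts, bandwidths[code], xc, yc)
        n_samples[code] = pts.shape[0]

    fmap = FeatureMap(densities=densities, pd_edges=pd_edges, t2_edges=t2_edges,
                      bandwidths={c: bandwidths[c] for c in by_class},
                      n_samples=n_samples, training=by_class)
    for code in densities:
        if fmap.mass(code) < 0.99:
            raise CoverageError(
                f"class {code}: density mass {fmap.mass(code):.3f} < 0.99; "
                "grid does not cover the training samples"
            )
    return fmap


def _density_argmax(density_cols: list[np.ndarray]) -> np.ndarray:
    """Index of the winning class with fixed priority on exact ties.

    Columns are ordered by TISSUE_ORDER, so taking the FIRST argmax implements
    the CSF > GM > WM tie-break.
    """
    stack = np.stack(density_cols, axis=0)
    return stack.argmax(axis=0)  # np.argmax returns the first maximum


def classify_direct(
    pd_vals: np.ndarray,
    t2_vals: np.ndarray,
    training: dict[int, np.ndarray],
    bandwidths: dict[int, float],
) -> np.ndarray:
    """Ungridded kernel-sum classification (reference path; O(n_voxels x n)).

    Evaluates the Parzen density sum exactly at each (PD, T2) point and takes
    the per-point argmax with the same CSF > GM > WM tie-break as the gridded
    path. Points with zero density under every class fall back to the nearest
    training sample's class.
    """
    pts = np.column_stack([np.ravel(pd_vals), np.ravel(t2_vals)])
    codes = [c for c in TISSUE_ORDER if c in training]
    dens = []
    for code in codes:
        tr = training[code]
        h = bandwidths[code]
        d2 = ((pts[:, None, :] - tr[None, :, :]) ** 2).sum(axis=2)
        dens.append(np.exp(-d2 / (2 * h * h)).sum(axis=1) / (2 * np.pi * h * h * tr.shape[0]))
    winner = _density_argmax(dens)
    labels = np.array(codes)[winner]

    allzero = np.max(dens, axis=0) == 0
    if allzero.any():
        tr_all = np.vstack([training[c] for c in codes])
        tr_lab = np.concatenate([np.full(training[c].shape[0], c) for c in codes])
        d2 = ((pts[allzero][:, None, :] - tr_all[None, :, :]) ** 2).sum(axis=2)
        labels[allzero] = tr_lab[d2.argmin(axis=1)]
    return labels.reshape(np.shape(pd_vals))


def classify_initial(
    volume: MultiChannelVolume,
    mask: BrainMask | np.ndarray,
    feature_map: FeatureMap,
    max_offgrid_fraction: float = 0.05,
) -> LabelMap:
    """Assign each in-mask voxel the argmax-density tissue class.

    Voxel (PD, T2) values are looked up in the feature map by nearest bin;
    out-of-mask voxels become background. If more than
    ``max_offgrid_fraction`` of in-mask voxels fall outside the grid the
    volume is presumed unnormalized and a :class:`CoverageError` is raised
    (off-grid voxels inside the tolerance are clamped to the border bin).
    Voxels where every class density underflows to zero are assigned by the
    nearest training sample when the map retains its samples, else by the
    tie-break priority.
    """
    m = mask.mask if isinstance(mask, BrainMask) else np.asarray(mask).astype(bool)
    if m.shape != volume.shape:
        raise ValueError(f"mask shape {m.shape} != volume shape {volume.shape}")
    pd_vals = volume.pd[m]
    t2_vals = volume.t2[m]

    pd_e, t2_e = feature_map.pd_edges, feature_map.t2_edges
    off = ((pd_vals < pd_e[0]) | (pd_vals > pd_e[-1]) |
           (t2_vals < t2_e[0]) | (t2_vals > t2_e[-1]))
    if off.mean() > max_offgrid_fraction:
        raise CoverageError(
            f"{off.mean():.1%} of in-mask voxels fall off the feature-map grid; "
            "normalize the volume to the training scale first"
        )

    nb_pd = pd_e.size - 1
    nb_t2 = t2_e.size - 1
    ii = np.clip(np.searchsorted(pd_e, pd_vals, side="right") - 1, 0, nb_pd - 1)
    jj = np.clip(np.searchsorted(t2_e, t2_vals, side="right") - 1, 0, nb_t2 - 1)

    codes = [c for c in TISSUE_ORDER if c in feature_map.densities]
    dens = [feature_map.densities[c][ii, jj] for c in codes]
    winner = _density_argmax(dens)
    vox_labels = np.array(codes)[winner]

    allzero = np.max(dens, axis=0) == 0
    if allzero.any() and feature_map.training is not None:
        vox_labels[allzero] = classify_direct(
            pd_vals[allzero], t2_vals[allzero],
            feature_map.training, feature_map.bandwidths,
        )

    labels = np.full(volume.shape, BACKGROUND, dtype=np.int16)
    labels[m] = vox_labels
    return LabelMap(labels=labels, spacing=volume.spacing, affine=volume.affine)
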