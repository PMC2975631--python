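"""Hidden-Markov-random-field EM refinement of the initial tissue labels.

The three tissue classes are modeled as 2-D Gaussians in (PD, T2) feature
space coupled by a Potts prior over a spatial neighborhood: the energy of
assigning class k to voxel i is

    U_i(k) = -log N(y_i; mu_k, Sigma_k) + beta * #{j in N_i : x_j != k}.

Starting from the Parzen labels, the algorithm alternates

* E-step: class posteriors proportional to exp(-U_i(k)) given the current
  labels' neighborhood configuration;
* M-step: closed-form weighted mean / covariance / mixing-proportion updates
  from the posteriors;
* optional bias update: per-channel multiplicative gain estimated by smoothing
  the log-residual (log intensity minus log fitted class mean) at a large
  spatial scale, gauge-fixed to mean 1 over the mask;
* ICM: raster-order sweeps setting each voxel to the class minimizing U_i,

until the fraction of labels changed in an EM iteration drops below tolerance
or the iteration cap is reached. Everything is deterministic given the
initialization.

The default neighborhood is the 8 in-plane neighbors within each axial slice
(the through-plane voxel size is ~5.5x the in-plane size, so axial coupling
is the natural choice); a 3-D 6-neighborhood is available by config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from numba import njit
from scipy import ndimage

from .preprocess import BrainMask
from .volumes_io import BACKGROUND, MultiChannelVolume, LabelMap
from .parzen import TISSUE_ORDER

__all__ = [
    "ClassParams",
    "MRFConfig",
    "BiasField",
    "ClassCollapseError",
    "BiasError",
    "em_fit",
    "icm_sweep",
    "estimate_bias",
    "negative_log_likelihood",
]


class ClassCollapseError(RuntimeError):
    """A tissue class lost all its voxels during EM."""


class BiasError(ValueError):
    """Bias-field estimation impossible (non-positive intensities in mask)."""


@dataclass
class ClassParams:
    """Gaussian emission parameters for one tissue class in (PD, T2) space."""

    mean: np.ndarray           # shape (2,)
    cov: np.ndarray            # shape (2, 2), symmetric positive-definite
    proportion: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(2)
        self.cov = np.asarray(self.cov, dtype=np.float64).reshape(2, 2)
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov)[0] <= 0:
            raise ValueError("covariance must be positive-definite")
        if not 0 <= self.proportion <= 1:
            raise ValueError("proportion must be in [0, 1]")


@dataclass
class MRFConfig:
    """Knobs for the HMRF-EM stage.

    beta >= 0 is the Potts coupling (0 disables spatial smoothing and reduces
    the model to an independent Gaussian mixture); neighborhood is
    "2d8" (8 in-plane neighbors, default) or "3d6" (6-face 3-D);
    bias_correction requires strictly positive in-mask intensities.
    """

    beta: float = 1.0
    neighborhood: str = "2d8"
    max_em_iter: int = 20
    max_icm_sweeps: int = 5
    tolerance: float = 1e-4
    bias_correction: bool = False
    bias_smoothing_mm: float = 25.0
    cov_regularization: float = 1e-6
    cov_max_condition: float = 1e8
    cov_floor: float = 0.0          # eigenvalue floor against variance collapse

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.neighborhood not in ("2d8", "3d6"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.max_em_iter <= 0 or self.max_icm_sweeps <= 0:
            raise ValueError("iteration caps must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class BiasField:
    """Smooth multiplicative per-channel gain on the volume grid."""

    gain_pd: np.ndarray
    gain_t2: np.ndarray

    def __post_init__(self) -> None:
        for g in (self.gain_pd, self.gain_t2):
            if np.any(g <= 0):
                raise ValueError("gain must be strictly positive")

    def correct(self, volume: MultiChannelVolume) -> MultiChannelVolume:
        """Divide out the gain."""
        return MultiChannelVolume(pd=volume.pd / self.gain_pd,
                                  t2=volume.t2 / self.gain_t2,
                                  spacing=volume.spacing, affine=volume.affine)

    @classmethod
    def identity(cls, shape: tuple[int, int, int]) -> "BiasField":
        return cls(gain_pd=np.ones(shape), gain_t2=np.ones(shape))


# ---------------------------------------------------------------------------
# Emission likelihood
# ---------------------------------------------------------------------------

def _regularize(cov: np.ndarray, config: MRFConfig) -> np.ndarray:
    w = np.linalg.eigvalsh(cov)
    if w[0] <= 0 or w[-1] / max(w[0], 1e-300) > config.cov_max_condition:
        warnings.warn("singular/ill-conditioned covariance regularized",
                      RuntimeWarning, stacklevel=3)
        cov = cov + config.cov_regularization * max(np.trace(cov), 1.0) * np.eye(2)
    if config.cov_floor > 0:
        # guard against variance collapse in heavily denoised homogeneous
        # regions, which skews the decision boundary toward the narrow class
        w, v = np.linalg.eigh(cov)
        cov = (v * np.maximum(w, config.cov_floor)) @ v.T
    return cov


def negative_log_likelihood(features: np.ndarray,
                            params: list[ClassParams]) -> np.ndarray:
    """-log N(y; mu_k, Sigma_k) for each point and class; shape (K, n)."""
    feats = np.asarray(features, dtype=np.float64).reshape(-1, 2)
    out = np.empty((len(params), feats.shape[0]))
    for k, p in enumerate(params):
        diff = feats - p.mean
        inv = np.linalg.inv(p.cov)
        maha = np.einsum("ni,ij,nj->n", diff, inv, diff)
        _, logdet = np.linalg.slogdet(p.cov)
        out[k] = 0.5 * (maha + logdet + 2.0 * np.log(2.0 * np.pi))
    return out


# ---------------------------------------------------------------------------
# ICM (raster-order sequential sweep; numba for speed)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _icm_kernel(labels, mask, nll, beta, use_3d):  # pragma: no cover - numba
    nx, ny, nz = labels.shape
    K = nll.shape[0]
    changed = 0
    for z in range(nz):
        for x in range(nx):
            for y in range(ny):
                if not mask[x, y, z]:
                    continue
                best_k = -1
                best_e = 1e300
                for k in range(K):
                    e = nll[k, x, y, z]
                    if use_3d:
                        for dx, dy, dz in ((-1, 0, 0), (1, 0, 0), (0, -1, 0),
                                           (0, 1, 0), (0, 0, -1), (0, 0, 1)):
                            xx, yy, zz = x + dx, y + dy, z + dz
                            if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                                if mask[xx, yy, zz] and labels[xx, yy, zz] != k:
                                    e += beta
                    else:
                        for dx in (-1, 0, 1):
                            for dy in (-1, 0, 1):
                                if dx == 0 and dy == 0:
                                    continue
                                xx, yy = x + dx, y + dy
                                if 0 <= xx < nx and 0 <= yy < ny:
                                    if mask[xx, yy, z] and labels[xx, yy, z] != k:
                                        e += beta
                    if e < best_e:  # strict: first (lowest index) wins ties
                        best_e = e
                        best_k = k
                if best_k != labels[x, y, z]:
                    labels[x, y, z] = best_k
                    changed += 1
    return changed


def _neighbor_disagreement(labels_k: np.ndarray, mask: np.ndarray,
                           k: int, neighborhood: str) -> np.ndarray:
    """Count of in-mask neighbors whose label differs from k, per voxel."""
    if neighborhood == "2d8":
        foot = np.ones((3, 3, 1), dtype=bool)
        foot[1, 1, 0] = False
    else:
        foot = np.zeros((3, 3, 3), dtype=bool)
        foot[0, 1, 1] = foot[2, 1, 1] = foot[1, 0, 1] = True
        foot[1, 2, 1] = foot[1, 1, 0] = foot[1, 1, 2] = True
    in_mask_neighbors = ndimage.convolve(mask.astype(np.float64), foot.astype(np.float64),
                                         mode="constant")
    same = ((labels_k == k) & mask).astype(np.float64)
    agreeing = ndimage.convolve(same, foot.astype(np.float64), mode="constant")
    return in_mask_neighbors - agreeing


def icm_sweep(
    labels: LabelMap,
    volume: MultiChannelVolume,
    params: dict[int, ClassParams],
    beta: float,
    neighborhood: str = "2d8",
    mask: np.ndarray | None = None,
    n_sweeps: int = 1,
) -> LabelMap:
    """Raster-order ICM pass(es): each voxel takes the class minimizing
    emission negative log-likelihood + beta x (disagreeing in-mask neighbors).

    The sweep is sequential (updates are visible to later voxels in the same
    pass) and idempotent at a local energy minimum. Ties go to the class
    earliest in the CSF > GM > WM priority.
    """
    codes = [c for c in TISSUE_ORDER if c in params]
    if mask is None:
        mask = labels.labels != BACKGROUND
    mask = np.ascontiguousarray(mask.astype(np.bool_))
    nll_flat = negative_log_likelihood(
        np.stack([volume.pd, volume.t2], axis=-1).reshape(-1, 2),
        [params[c] for c in codes])
    nll = np.ascontiguousarray(nll_flat.reshape(len(codes), *volume.shape))

    code_to_idx = {c: i for i, c in enumerate(codes)}
    lab_idx = np.zeros(labels.shape, dtype=np.int64)
    for c, i in code_to_idx.items():
        lab_idx[labels.labels == c] = i
    lab_idx = np.ascontiguousarray(lab_idx)

    for _ in range(n_sweeps):
        changed = _icm_kernel(lab_idx, mask, nll, float(beta),
                              neighborhood == "3d6")
        if changed == 0:
            break

    out = np.full(labels.shape, BACKGROUND, dtype=np.int16)
    for c, i in code_to_idx.items():
        out[mask & (lab_idx == i)] = c
    return labels.with_labels(out)


# ---------------------------------------------------------------------------
# Bias field
# ---------------------------------------------------------------------------

def estimate_bias(
    volume: MultiChannelVolume,
    mask: np.ndarray,
    labels: LabelMap,
    params: dict[int, ClassParams],
    smoothing_mm: float = 25.0,
) -> BiasField:
    """Per-channel multiplicative gain from the smoothed log-residual field.

    gain = exp(smooth(log intensity - log fitted class mean)), smoothed with a
    Gaussian of ``smoothing_mm`` (mask-normalized so edges are unbiased), then
    rescaled so the mean gain over the mask is exactly 1.
    """
    mask = np.asarray(mask).astype(bool)
    gains = []
    for ch, chan in enumerate((volume.pd, volume.t2)):
        if np.any(chan[mask] <= 0):
            raise BiasError("non-positive in-mask intensities; bias needs a "
                            "positive intensity scale")
        mu = np.ones(volume.shape)
        for code, p in params.items():
            sel = mask & (labels.labels == code)
            mu[sel] = max(p.mean[ch], 1e-12)
        resid = np.zeros(volume.shape)
        resid[mask] = np.log(chan[mask]) - np.log(mu[mask])

        sigma_vox = [smoothing_mm / s for s in volume.spacing]
        num = ndimage.gaussian_filter(resid * mask, sigma=sigma_vox)
        den = ndimage.gaussian_filter(mask.astype(np.float64), sigma=sigma_vox)
        smooth = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
        gain = np.exp(smooth)
        gain /= gain[mask].mean()  # gauge: mean gain over mask = 1
        gains.append(gain)
    return BiasField(gain_pd=gains[0], gain_t2=gains[1])


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

def _m_step(feats: np.ndarray, post: np.ndarray, config: MRFConfig,
            codes: list[int]) -> dict[int, ClassParams]:
    params: dict[int, ClassParams] = {}
    weights = post.sum(axis=1)
    total = feats.shape[0]
    for k, code in enumerate(codes):
        w = weights[k]
        if w <= 0:
            raise ClassCollapseError(f"class {code} emptied during EM")
        mean = (post[k][:, None] * feats).sum(axis=0) / w
        diff = feats - mean
        cov = (post[k][:, None, None] * np.einsum("ni,nj->nij", diff, diff)).sum(axis=0) / w
        cov = _regularize(cov, config)
        params[code] = ClassParams(mean=mean, cov=cov, proportion=float(w / total))
    return params


def em_fit(
    volume: MultiChannelVolume,
    mask: BrainMask | np.ndarray,
    initial_labels: LabelMap,
    config: MRFConfig | None = None,
) -> tuple[dict[int, ClassParams], BiasField, LabelMap]:
    """HMRF-EM refinement of the initial classification.

    Returns the fitted per-class Gaussian parameters, the estimated bias field
    (identity when ``config.bias_correction`` is off), and the final crisp
    label map. Raises :class:`ClassCollapseError` if a tissue class empties.
    """
    config = config or MRFConfig()
    m = mask.mask if isinstance(mask, BrainMask) else np.asarray(mask).astype(bool)
    codes = [c for c in TISSUE_ORDER if np.any(initial_labels.labels[m] == c)]
    if len(codes) < 3:
        raise ValueError(
            f"initialization must contain all 3 tissue classes, found {codes}")

    work = volume
    labels = initial_labels.with_labels(
        np.where(m, initial_labels.labels, BACKGROUND))
    bias = BiasField.identity(volume.shape)

    # initial parameters from the crisp initialization
    feats_full = np.stack([work.pd, work.t2], axis=-1)
    params: dict[int, ClassParams] = {}
    n_in = int(m.sum())
    for code in codes:
        sel = m & (labels.labels == code)
        pts = feats_full[sel]
        cov = _regularize(np.cov(pts.T, ddof=1), MRFConfig())
        params[code] = ClassParams(mean=pts.mean(axis=0), cov=cov,
                                   proportion=pts.shape[0] / n_in)

    for _ in range(config.max_em_iter):
        feats_in = feats_full[m]
        nll = negative_log_likelihood(feats_in, [params[c] for c in codes])

        # E-step: posterior under emission + Potts prior given current labels
        energy = nll.copy()
        if config.beta > 0:
            for k, code in enumerate(codes):
                dis = _neighbor_disagreement(labels.labels, m, code,
                                             config.neighborhood)
                energy[k] += config.beta * dis[m]
        energy -= energy.min(axis=0, keepdims=True)
        post = np.exp(-energy)
        post /= post.sum(axis=0, keepdims=True)

        # M-step
        params = _m_step(feats_in, post, config, codes)

        # bias update on the crisp labels, then re-correct the working volume
        if config.bias_correction:
            bias = estimate_bias(volume, m, labels, params,
                                 smoothing_mm=config.bias_smoothing_mm)
            work = bias.correct(volume)
            feats_full = np.stack([work.pd, work.t2], axis=-1)

        # ICM label update
        prev = labels.labels.copy()
        labels = icm_sweep(labels, work, params, config.beta,
                           neighborhood=config.neighborhood, mask=m,
                           n_sweeps=config.max_icm_sweeps)
        change = np.count_nonzero(labels.labels[m] != prev[m]) / max(n_in, 1)
        for code in codes:
            if not np.any(labels.labels[m] == code):
                raise ClassCollapseError(f"class {code} emptied during EM")
        if change < config.tolerance:
            break

    return params, bias, labels
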