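"""Image volumes, label maps, and the shared label-code scheme.

All stages of the pipeline exchange two containers: a :class:`MultiChannelVolume`
holding the co-registered dual-echo PD- and T2-weighted intensity grids, and a
:class:`LabelMap` holding integer tissue/structural codes on the same grid.
Volumes and label maps are stored as NIfTI-1 (``.nii``/``.nii.gz``) via nibabel;
the label scheme travels as a JSON sidecar.

Label codes are this package's own convention::

    0  background            10 brain stem       14 corpus callosum
    1  CSF                   11 cerebellum       15 accumbens
    2  gray matter           12 amygdalae        16 caudate
    3  white matter          13 hippocampi       17 thalamus
    4  WMSA                  18 lenticular

Left/right counterparts of a structure share a single code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "SchemeError",
    "LabelScheme",
    "DEFAULT_SCHEME",
    "MultiChannelVolume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "volume_mm3",
    "volume_report",
]

# Tissue codes (1-4) are disjoint from structural codes (10-18) so that the
# structural map can be pasted onto the tissue map without ambiguity.
BACKGROUND = 0
CSF = 1
GM = 2
WM = 3
WMSA = 4

TISSUE_CODES = (CSF, GM, WM, WMSA)
STRUCTURE_CODES = tuple(range(10, 19))

_CORE_NAMES = {
    0: "background",
    1: "csf",
    2: "gray_matter",
    3: "white_matter",
    4: "wmsa",
    10: "brain_stem",
    11: "cerebellum",
    12: "amygdalae",
    13: "hippocampi",
    14: "corpus_callosum",
    15: "accumbens",
    16: "caudate",
    17: "thalamus",
    18: "lenticular",
}


class GeometryError(ValueError):
    """Raised when two grids that must share geometry do not."""


class SchemeError(ValueError):
    """Raised when a label map contains a code the scheme does not register."""


@dataclass(frozen=True)
class LabelScheme:
    """Mapping from integer codes to region names.

    The core codes above are fixed; additional codes may be registered but must
    not collide. Tissue codes (1-4) and structural codes (10-18) are disjoint
    by construction.
    """

    names: dict[int, str] = field(default_factory=lambda: dict(_CORE_NAMES))

    def __post_init__(self) -> None:
        if len(set(self.names.values())) != len(self.names):
            raise SchemeError("duplicate names in label scheme")
        for code, name in _CORE_NAMES.items():
            if code in self.names and self.names[code] != name:
                raise SchemeError(f"core code {code} renamed to {self.names[code]!r}")

    def __contains__(self, code: int) -> bool:
        return int(code) in self.names

    def name(self, code: int) -> str:
        try:
            return self.names[int(code)]
        except KeyError:
            raise SchemeError(f"code {code} not registered") from None

    def validate_codes(self, labels: np.ndarray) -> None:
        present = np.unique(labels)
        unknown = [int(c) for c in present if int(c) not in self.names]
        if unknown:
            raise SchemeError(f"unregistered label codes: {unknown}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({str(k): v for k, v in sorted(self.names.items())}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelScheme":
        raw = json.loads(Path(path).read_text())
        return cls(names={int(k): v for k, v in raw.items()})


DEFAULT_SCHEME = LabelScheme()


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite values")


@dataclass
class MultiChannelVolume:
    """Co-registered PD- and T2-weighted intensity volumes.

    ``pd`` and ``t2`` are 3-D float arrays on an identical grid; ``spacing`` is
    the voxel size in mm per axis (i, j, k); ``affine`` carries the NIfTI
    voxel-to-world transform shared by both channels.
    """

    pd: np.ndarray
    t2: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pd = np.asarray(self.pd, dtype=np.float64)
        self.t2 = np.asarray(self.t2, dtype=np.float64)
        if self.pd.ndim != 3 or self.t2.ndim != 3:
            raise GeometryError("channels must be 3-D")
        if self.pd.shape != self.t2.shape:
            raise GeometryError(
                f"channel shape mismatch: PD {self.pd.shape} vs T2 {self.t2.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive values, got {self.spacing}")
        _check_finite(self.pd, "PD channel")
        _check_finite(self.t2, "T2 channel")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pd.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def stacked(self) -> np.ndarray:
        """Feature array of shape (*grid, 2) with channels ordered (PD, T2)."""
        return np.stack([self.pd, self.t2], axis=-1)


@dataclass
class LabelMap:
    """Integer-coded segmentation sharing geometry with its source volume."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    scheme: LabelScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError("label grid must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(np.asarray(self.labels, dtype=np.float64))
            if not np.array_equal(rounded, self.labels):
                raise SchemeError("label values must be integers")
            self.labels = rounded.astype(np.int16)
        else:
            self.labels = self.labels.astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive values, got {self.spacing}")
        self.scheme.validate_codes(self.labels)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def check_geometry(self, other: "MultiChannelVolume | LabelMap") -> None:
        if self.shape != other.shape:
            raise GeometryError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise GeometryError(f"spacing mismatch: {self.spacing} vs {other.spacing}")

    def with_labels(self, labels: np.ndarray) -> "LabelMap":
        return LabelMap(labels=labels, spacing=self.spacing, scheme=self.scheme,
                        affine=self.affine)


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read {path}: {exc}") from exc
    data = np.asarray(img.get_fdata())
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def read_volume(path_pd: str | Path, path_t2: str | Path) -> MultiChannelVolume:
    """Read a co-registered PD/T2 pair, validating shared geometry.

    Raises :class:`GeometryError` if the two channels differ in dimensions or
    voxel spacing, ``IOError`` if either file is unreadable.
    """
    pd_data, pd_spacing, pd_affine = _load_nifti(path_pd)
    t2_data, t2_spacing, _ = _load_nifti(path_t2)
    if pd_data.shape != t2_data.shape:
        raise GeometryError(
            f"PD shape {pd_data.shape} != T2 shape {t2_data.shape}"
        )
    if not np.allclose(pd_spacing, t2_spacing):
        raise GeometryError(f"PD spacing {pd_spacing} != T2 spacing {t2_spacing}")
    return MultiChannelVolume(pd=pd_data, t2=t2_data, spacing=pd_spacing,
                              affine=pd_affine)


def write_volume(vol: MultiChannelVolume, path_pd: str | Path, path_t2: str | Path) -> None:
    """Write the two channels as separate NIfTI files (float32)."""
    for data, path in ((vol.pd, path_pd), (vol.t2, path_t2)):
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), vol.affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))


def write_labelmap(labelmap: LabelMap, path: str | Path,
                   scheme_sidecar: str | Path | None = None) -> None:
    """Write a label map as int16 NIfTI plus an optional JSON scheme sidecar."""
    labelmap.scheme.validate_codes(labelmap.labels)
    img = nib.Nifti1Image(labelmap.labels.astype(np.int16), labelmap.affine)
    img.header.set_zooms(labelmap.spacing)
    nib.save(img, str(path))
    if scheme_sidecar is not None:
        labelmap.scheme.to_json(scheme_sidecar)


def read_labelmap(path: str | Path, scheme: LabelScheme | None = None) -> LabelMap:
    """Read an integer label map; every code must be registered in ``scheme``."""
    data, spacing, affine = _load_nifti(path)
    labels = np.rint(data).astype(np.int16)
    return LabelMap(labels=labels, spacing=spacing,
                    scheme=scheme or DEFAULT_SCHEME, affine=affine)


def volume_mm3(labelmap: LabelMap, code: int) -> float:
    """Volume of one region in mm^3: voxel count x voxel volume (0 if absent)."""
    if code not in labelmap.scheme:
        raise SchemeError(f"code {code} not registered")
    count = int(np.count_nonzero(labelmap.labels == code))
    return count * labelmap.voxel_volume_mm3


def volume_report(labelmap: LabelMap, codes: list[int] | None = None) -> pd.DataFrame:
    """Per-region volume table (structure, code, voxels, mm^3).

    Defaults to every code present in the map (background excluded).
    """
    if codes is None:
        codes = [int(c) for c in np.unique(labelmap.labels) if c != BACKGROUND]
    rows = []
    for code in codes:
        count = int(np.count_nonzero(labelmap.labels == code))
        rows.append({
            "structure": labelmap.scheme.name(code),
            "code": int(code),
            "voxels": count,
            "mm3": count * labelmap.voxel_volume_mm3,
        })
    return pd.DataFrame(rows, columns=["structure", "code", "voxels", "mm3"])
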