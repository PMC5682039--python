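"""Volume I/O, smoothing, probability masking, and matrix assembly.

A scan cohort enters the analysis as a stack of 3-D parametric volumes
(BP_ND-like scalar images). This module turns those volumes into the two
matrices the PLS stage consumes: the scans × voxels data matrix ``X``
(one masked, flattened volume per row) and the scans × 4 indicator design
matrix ``Y`` coding the group × season cell of each scan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

GROUPS = ("nonSAD", "SAD")
SEASONS = ("summer", "winter")
#: Fixed column order of the design matrix: group × season cells.
DESIGN_CELLS = (
    ("nonSAD", "summer"),
    ("nonSAD", "winter"),
    ("SAD", "summer"),
    ("SAD", "winter"),
)

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D scalar grid with an isotropic voxel size in mm.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities (e.g. BP_ND).
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    meta : dict
        Free-form header passthrough (e.g. the NIfTI affine).
    """

    values: np.ndarray
    voxel_size_mm: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "VoxelVolume":
        return dataclasses.replace(self, values=values)


@dataclass(frozen=True)
class CohortDesign:
    """Ordered scan records; record order is the canonical matrix row order.

    Each record is ``(subject_id, group, season)``. Every subject appears
    exactly twice, once per season (a paired longitudinal design).
    """

    records: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        records = tuple((str(s), str(g), str(c)) for s, g, c in self.records)
        for sid, group, season in records:
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r} for subject {sid!r}")
            if season not in SEASONS:
                raise ValueError(f"unknown season {season!r} for subject {sid!r}")
        seen: dict[str, set[str]] = {}
        groups: dict[str, str] = {}
        for sid, group, season in records:
            seen.setdefault(sid, set())
            if season in seen[sid]:
                raise ValueError(f"subject {sid!r} scanned twice in {season}")
            seen[sid].add(season)
            if groups.setdefault(sid, group) != group:
                raise ValueError(f"subject {sid!r} assigned to two groups")
        for sid, seasons in seen.items():
            if seasons != set(SEASONS):
                raise ValueError(f"subject {sid!r} lacks one season: has {sorted(seasons)}")
        object.__setattr__(self, "records", records)

    @property
    def n_scans(self) -> int:
        return len(self.records)

    @property
    def subjects(self) -> tuple[str, ...]:
        out: list[str] = []
        for sid, _, _ in self.records:
            if sid not in out:
                out.append(sid)
        return tuple(out)

    def subjects_in_group(self, group: str) -> tuple[str, ...]:
        return tuple(s for s in self.subjects if self.group_of(s) == group)

    def group_of(self, subject_id: str) -> str:
        for sid, group, _ in self.records:
            if sid == subject_id:
                return group
        raise KeyError(subject_id)

    def scan_indices_of(self, subject_id: str) -> tuple[int, ...]:
        return tuple(i for i, (sid, _, _) in enumerate(self.records) if sid == subject_id)

    def subset(self, indices: Sequence[int]) -> "CohortDesign":
        """Sub-design over the given scan indices (order preserved).

        Split planning moves whole subjects, so any half re-validates as a
        complete paired design.
        """
        return CohortDesign(tuple(self.records[i] for i in indices))


@dataclass(frozen=True)
class AnalysisMask:
    """Boolean inclusion grid plus the fixed, ordered list of kept voxels."""

    include: np.ndarray
    voxel_index: np.ndarray  # (n_voxels, 3) int array, C-order of included voxels

    @classmethod
    def from_include(cls, include: np.ndarray) -> "AnalysisMask":
        include = np.asarray(include, dtype=bool)
        idx = np.argwhere(include)
        if idx.shape[0] < 1:
            raise ValueError("mask is empty: no voxel passes the thresholds")
        return cls(include=include, voxel_index=idx)

    @property
    def n_voxels(self) -> int:
        return self.voxel_index.shape[0]

    def extract(self, volume: VoxelVolume) -> np.ndarray:
        """Flatten a volume to the masked 1-D vector (mask voxel order)."""
        if volume.shape != self.include.shape:
            raise ValueError(f"volume shape {volume.shape} != mask shape {self.include.shape}")
        return volume.values[self.include]

    def scatter(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a masked 1-D vector back into a full 3-D grid."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_voxels,):
            raise ValueError(f"vector length {vector.shape} != mask size {self.n_voxels}")
        out = np.full(self.include.shape, fill, dtype=float)
        out[self.include] = vector
        return out


@dataclass(frozen=True)
class DataMatrix:
    """Scans × voxels matrix, with the design and mask that fix its axes."""

    X: np.ndarray
    row_design: CohortDesign
    mask: AnalysisMask


@dataclass(frozen=True)
class DesignMatrix:
    """Scans × 4 one-hot matrix over the group × season cells."""

    Y: np.ndarray
    column_labels: tuple[str, ...]


def gaussian_smooth(v: VoxelVolume, fwhm_mm: float, mode: str = "reflect") -> VoxelVolume:
    """Isotropic 3-D Gaussian smoothing with the kernel width given as FWHM.

    sigma_voxels = (fwhm_mm / (2 sqrt(2 ln 2))) / voxel_size_mm. A FWHM of 0
    returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return v
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / v.voxel_size_mm
    return v.with_values(ndimage.gaussian_filter(v.values, sigma=sigma_vox, mode=mode))


def build_mask(
    gm: VoxelVolume,
    csf: VoxelVolume,
    gm_thresh: float = 0.1,
    csf_thresh: float = 0.3,
) -> AnalysisMask:
    """Mask of voxels with gray-matter probability above ``gm_thresh`` and
    CSF probability below ``csf_thresh`` (both comparisons strict)."""
    if gm.shape != csf.shape:
        raise ValueError("gray-matter and CSF volumes differ in shape")
    for name, vol in (("gray-matter", gm), ("CSF", csf)):
        if vol.values.min() < 0 or vol.values.max() > 1:
            raise ValueError(f"{name} probabilities must lie in [0, 1]")
    include = (gm.values > gm_thresh) & (csf.values < csf_thresh)
    return AnalysisMask.from_include(include)


def assemble_data_matrix(
    volumes: Sequence[VoxelVolume], design: CohortDesign, mask: AnalysisMask
) -> DataMatrix:
    """Stack masked volumes into the scans × voxels matrix, rows in design order."""
    if len(volumes) != design.n_scans:
        raise ValueError(f"{len(volumes)} volumes for {design.n_scans} design records")
    X = np.stack([mask.extract(v) for v in volumes], axis=0)
    return DataMatrix(X=X, row_design=design, mask=mask)


def encode_design(design: CohortDesign) -> DesignMatrix:
    """One-hot group × season cell coding, scans × 4, fixed column order."""
    labels = tuple(f"{g}-{s}" for g, s in DESIGN_CELLS)
    cell_of = {cell: j for j, cell in enumerate(DESIGN_CELLS)}
    Y = np.zeros((design.n_scans, 4), dtype=float)
    for i, (_, group, season) in enumerate(design.records):
        Y[i, cell_of[(group, season)]] = 1.0
    return DesignMatrix(Y=Y, column_labels=labels)


def standardize_columns(M: np.ndarray) -> np.ndarray:
    """Columnwise standardization: mean 0, sample SD 1 (ddof=1).

    Zero-variance columns are set to all-zero rather than dropped, so voxel
    indexing is preserved and maps stay reconstructible.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if M.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    centered = M - M.mean(axis=0, keepdims=True)
    sd = M.std(axis=0, ddof=1, keepdims=True)
    out = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_nifti(path: str | Path) -> VoxelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(f"anisotropic voxels {zooms} are not supported; resample first")
    return VoxelVolume(values=data, voxel_size_mm=float(zooms[0]), meta={"affine": img.affine})


def write_nifti(volume: VoxelVolume, path: str | Path) -> None:
    affine = volume.meta.get("affine")
    if affine is None:
        affine = np.diag([volume.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms((volume.voxel_size_mm,) * 3)
    nib.save(img, str(path))
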