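"""Synthetic PET-cohort generator.

Emulates a paired longitudinal design — two groups (nonSAD, SAD), each
subject scanned once per season (summer, winter) — by planting a spatially
distributed group × season covariance pattern on a constant-baseline
phantom, with subject-level random intercepts and i.i.d. Gaussian voxel
noise:

    volume(subject, group, season)
        = baseline + c(group, season) * effect_map + subject_offset + noise

The default contrast ``c`` gives +1 to nonSAD-winter, -1 to SAD-winter and
0 to both summer cells, mirroring a winter-selective group dissociation.
Everything downstream (masking, PLS, NPAIRS, reporting) is testable on
these cohorts with no external data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .images import CohortDesign, VoxelVolume, write_nifti

#: Default group × season coefficients of the planted pattern.
DEFAULT_CONTRAST: Mapping[tuple[str, str], float] = {
    ("nonSAD", "summer"): 0.0,
    ("nonSAD", "winter"): +1.0,
    ("SAD", "summer"): 0.0,
    ("SAD", "winter"): -1.0,
}


@dataclass(frozen=True)
class Region:
    """A spherical effect region: voxels whose centers lie strictly within
    ``radius_mm`` of ``center`` (a 0-based voxel triple) get
    ``effect_sign * effect_size`` added; overlapping regions sum."""

    center: tuple[int, int, int]
    radius_mm: float
    effect_sign: int = +1
    effect_size: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.effect_sign not in (+1, -1):
            raise ValueError("effect_sign must be +1 or -1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic cohort.

    Defaults reproduce the study conditions the pipeline targets: 13 + 6
    subjects scanned in two seasons (38 scans) on a 16 voxel cube at 2 mm,
    baseline 2.0 BP_ND, one positive and one negative planted 5 mm sphere
    of 0.3 BP_ND, whole-volume subject intercepts of SD 0.15 and voxel
    noise of SD 0.25.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 2.0
    baseline_level: float = 2.0
    regions: tuple[Region, ...] = (
        Region(center=(5, 5, 6), radius_mm=5.0, effect_sign=+1, effect_size=0.3),
        Region(center=(11, 10, 9), radius_mm=5.0, effect_sign=-1, effect_size=0.3),
    )
    n_subjects_per_group: tuple[int, int] = (13, 6)
    subject_sd: float = 0.15
    noise_sd: float = 0.25
    seed: int = 0
    contrast: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST)
    )

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise ValueError("grid_shape must be three integers >= 1")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("subject_sd and noise_sd must be >= 0")
        if any(n < 1 for n in self.n_subjects_per_group):
            raise ValueError("need at least one subject per group")
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "regions", tuple(self.regions))


def default_design(n_per_group: tuple[int, int] = (13, 6)) -> CohortDesign:
    """Paired two-season design: one summer and one winter scan per subject.

    Scan order is subject-major (summer then winter within subject), nonSAD
    subjects first.
    """
    records = []
    for group, n in zip(("nonSAD", "SAD"), n_per_group):
        for i in range(n):
            sid = f"{group}{i + 1:02d}"
            records.append((sid, group, "summer"))
            records.append((sid, group, "winter"))
    return CohortDesign(tuple(records))


def build_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, VoxelVolume]:
    """Rasterize the baseline and the additive effect map.

    Returns ``(baseline, effect_map)``. The effect map is zero outside all
    region spheres; inside a sphere it equals ``effect_sign * effect_size``,
    and overlapping spheres sum.
    """
    shape = spec.grid_shape
    effect = np.zeros(shape, dtype=float)
    grid = np.indices(shape, dtype=float)
    for r, region in enumerate(spec.regions):
        center = np.asarray(region.center, dtype=float)
        if np.any(center < 0) or np.any(center >= np.asarray(shape)):
            raise ValueError(
                f"region {r} center {region.center} lies outside grid {shape}"
            )
        dist_mm = (
            np.sqrt(((grid - center.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
            * spec.voxel_size_mm
        )
        inside = dist_mm < region.radius_mm  # strict: center within radius
        effect[inside] += region.effect_sign * region.effect_size
    baseline = np.full(shape, spec.baseline_level, dtype=float)
    return (
        VoxelVolume(baseline, spec.voxel_size_mm),
        VoxelVolume(effect, spec.voxel_size_mm),
    )


def simulate_cohort(
    spec: PhantomSpec, design: CohortDesign | None = None
) -> tuple[list[VoxelVolume], CohortDesign]:
    """Simulate one volume per design record.

    volume = baseline + c(group, season) * effect_map + subject_offset + noise.
    A single RNG stream is seeded from ``spec.seed``; all subject offsets are
    drawn before any noise field, so adding scans never perturbs offsets.
    Identical specs give bit-identical cohorts.
    """
    if design is None:
        design = default_design(spec.n_subjects_per_group)
    counts = tuple(len(design.subjects_in_group(g)) for g in ("nonSAD", "SAD"))
    if counts != tuple(spec.n_subjects_per_group):
        raise ValueError(
            f"design has {counts} subjects per group, spec expects "
            f"{tuple(spec.n_subjects_per_group)}"
        )
    baseline, effect = build_phantom(spec)
    rng = np.random.default_rng(spec.seed)
    subjects = design.subjects
    offsets = dict(zip(subjects, rng.normal(0.0, spec.subject_sd, size=len(subjects))))
    volumes = []
    for sid, group, season in design.records:
        c = spec.contrast.get((group, season), 0.0)
        values = baseline.values + c * effect.values + offsets[sid]
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        volumes.append(VoxelVolume(values, spec.voxel_size_mm))
    return volumes, design


def brain_ellipsoid_probabilities(
    spec: PhantomSpec, semiaxis_fraction: float = 0.45
) -> tuple[VoxelVolume, VoxelVolume]:
    """GM/CSF probability volumes for default masking of the phantom.

    Gray-matter probability is 1 inside a centered ellipsoid with semi-axes
    ``semiaxis_fraction`` of each grid dimension and 0 outside; CSF
    probability is 0 everywhere, so the default thresholds (GM > 0.1,
    CSF < 0.3) keep exactly the ellipsoid.
    """
    shape = np.asarray(spec.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = semiaxis_fraction * shape
    grid = np.indices(spec.grid_shape, dtype=float)
    normalized = (grid - center.reshape(3, 1, 1, 1)) / semi.reshape(3, 1, 1, 1)
    gm = ((normalized**2).sum(axis=0) <= 1.0).astype(float)
    csf = np.zeros(spec.grid_shape)
    return (
        VoxelVolume(gm, spec.voxel_size_mm),
        VoxelVolume(csf, spec.voxel_size_mm),
    )


def write_cohort(
    volumes: Sequence[VoxelVolume],
    design: CohortDesign,
    out_dir: str | Path,
    gm: VoxelVolume | None = None,
    csf: VoxelVolume | None = None,
) -> Path:
    """Write one .nii.gz per scan plus a design CSV; returns the CSV path.

    CSV columns: subject,group,season,filename. Optional GM/CSF probability
    volumes are written as gm_prob.nii.gz / csf_prob.nii.gz.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ((sid, group, season), vol) in enumerate(zip(design.records, volumes)):
        fname = f"scan_{i:03d}_{sid}_{season}.nii.gz"
        write_nifti(vol, out_dir / fname)
        rows.append((sid, group, season, fname))
    csv_path = out_dir / "design.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "group", "season", "filename"])
        writer.writerows(rows)
    if gm is not None:
        write_nifti(gm, out_dir / "gm_prob.nii.gz")
    if csf is not None:
        write_nifti(csf, out_dir / "csf_prob.nii.gz")
    return csv_path


def read_cohort(csv_path: str | Path) -> tuple[list[VoxelVolume], CohortDesign]:
    """Read a cohort written by :func:`write_cohort` (or hand-built to the
    same CSV contract)."""
    from .images import read_nifti

    csv_path = Path(csv_path)
    base = csv_path.parent
    records, volumes = [], []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append((row["subject"], row["group"], row["season"]))
            volumes.append(read_nifti(base / row["filename"]))
    return volumes, CohortDesign(tuple(records))
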