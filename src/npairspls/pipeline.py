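"""End-to-end orchestration: simulate/read → mask → PLS → NPAIRS →
subspace selection → cluster and contrast reporting, from a single config.

Every stage is driven by one :class:`RunConfig`, with protocol defaults
(1,000 splits, Z threshold ±2.8, 640 mm³ extent, 95% bootstrap CIs) and a
single master seed controlling all randomness, so a run is reproducible
end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .images import (
    VoxelVolume,
    assemble_data_matrix,
    build_mask,
    encode_design,
    gaussian_smooth,
    read_nifti,
)
from .phantom import (
    PhantomSpec,
    brain_ellipsoid_probabilities,
    read_cohort,
    simulate_cohort,
    write_cohort,
)
from .pls import brain_scores, fit_pls
from .reporting import condition_brain_scores, contrast_tests, threshold_clusters
from .subspace import plot_curve, select_optimal_k


@dataclass(frozen=True)
class RunConfig:
    """Single document of pipeline settings.

    ``mode`` is "simulate" (generate a phantom cohort) or "read" (load a
    design CSV referencing NIfTI scans plus GM/CSF probability volumes).
    """

    mode: str = "simulate"
    output_dir: str = "npairspls_run"
    seed: int = 0
    # simulate mode
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    # read mode
    design_csv: str | None = None
    gm_path: str | None = None
    csf_path: str | None = None
    # preprocessing
    fwhm_mm: float = 0.0
    gm_thresh: float = 0.1
    csf_thresh: float = 0.3
    # NPAIRS / subspace
    n_splits: int = 1000
    k_max: int | None = None
    # reporting
    z_thresh: float = 2.8
    extent_mm3: float = 640.0
    connectivity: int = 26
    n_boot: int = 1000
    make_plot: bool = True

    def validate(self) -> None:
        if self.mode not in ("simulate", "read"):
            raise ValueError(f"mode must be 'simulate' or 'read', got {self.mode!r}")
        if self.mode == "read":
            for name in ("design_csv", "gm_path", "csf_path"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"read mode requires {name}")
                if not Path(path).exists():
                    raise ValueError(f"{name} does not exist: {path}")
        for name, lo in (
            ("fwhm_mm", 0.0), ("z_thresh", None), ("extent_mm3", None),
            ("n_boot", 1),
        ):
            value = getattr(self, name)
            if lo is None and value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
            if lo is not None and value < lo:
                raise ValueError(f"{name} must be >= {lo}, got {value}")
        if self.n_splits < 2:
            raise ValueError(f"n_splits must be >= 2, got {self.n_splits}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if not 0 <= self.gm_thresh < 1 or not 0 < self.csf_thresh <= 1:
            raise ValueError("gm_thresh must be in [0, 1) and csf_thresh in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "phantom" in raw and isinstance(raw["phantom"], dict):
            pr = dict(raw["phantom"])
            if "regions" in pr:
                from .phantom import Region

                pr["regions"] = tuple(
                    Region(
                        center=tuple(r["center"]),
                        radius_mm=r["radius_mm"],
                        effect_sign=r.get("effect_sign", 1),
                        effect_size=r.get("effect_size", 0.0),
                    )
                    for r in pr["regions"]
                )
            for key in ("grid_shape", "n_subjects_per_group"):
                if key in pr:
                    pr[key] = tuple(pr[key])
            raw = dict(raw, phantom=PhantomSpec(**pr))
        return cls(**raw)


def _load_inputs(config: RunConfig):
    if config.mode == "simulate":
        spec = dataclasses.replace(config.phantom, seed=config.seed)
        volumes, design = simulate_cohort(spec)
        gm, csf = brain_ellipsoid_probabilities(spec)
    else:
        volumes, design = read_cohort(config.design_csv)
        gm = read_nifti(config.gm_path)
        csf = read_nifti(config.csf_path)
    return volumes, design, gm, csf


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write every declared output.

    Returns the run report (also written as report.json): seeds, versions,
    data dimensions, k*, the per-k curve summary, LV-1 covariance fraction,
    and the prediction/reproducibility p-values at k*.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    volumes, design, gm, csf = _load_inputs(config)
    if config.mode == "simulate":
        write_cohort(volumes, design, out / "cohort", gm=gm, csf=csf)
    if config.fwhm_mm > 0:
        volumes = [gaussian_smooth(v, config.fwhm_mm) for v in volumes]
    mask = build_mask(gm, csf, config.gm_thresh, config.csf_thresh)
    X = assemble_data_matrix(volumes, design, mask)
    Y = encode_design(design)

    model = fit_pls(X, Y)
    curve = select_optimal_k(
        X, Y, k_max=config.k_max, n_splits=config.n_splits, seed=config.seed
    )
    result = curve.result_at_star

    voxel_size = volumes[0].voxel_size_mm
    for name, vec in (
        ("zmap", result.zmap),
        ("salience_mean", result.salience_mean),
        ("salience_se", result.salience_se),
    ):
        vol = VoxelVolume(
            np.nan_to_num(mask.scatter(vec), nan=0.0), voxel_size
        )
        from .images import write_nifti

        write_nifti(vol, out / f"{name}.nii.gz")

    zvol = VoxelVolume(mask.scatter(np.nan_to_num(result.zmap, nan=0.0)), voxel_size)
    clusters = threshold_clusters(
        zvol, config.z_thresh, config.extent_mm3, config.connectivity
    )
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)

    scores = brain_scores(X, model)
    cond = condition_brain_scores(scores, n_boot=config.n_boot, seed=config.seed)
    cond.to_frame().to_csv(out / "condition_scores.tsv", sep="\t", index=False)
    contrasts = contrast_tests(cond)
    contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False)

    curve.to_frame().to_csv(out / "subspace_curve.csv", index=False)
    result.metrics_frame().to_csv(out / "npairs_metrics.csv", index=False)
    if config.make_plot:
        plot_curve(curve, str(out / "subspace_curve.png"))

    ref_rt, ref_rs, ref_d = curve.reference_metrics
    report = {
        "npairspls_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "n_scans": design.n_scans,
        "n_voxels": mask.n_voxels,
        "n_splits": config.n_splits,
        "connectivity": config.connectivity,
        "k_star": curve.k_star,
        "D_at_k_star": float(curve.D[curve.k_star - 1]),
        "D_reference_no_pca": ref_d,
        "mean_r_test_at_k_star": float(curve.mean_r_test[curve.k_star - 1]),
        "mean_r_spatial_at_k_star": float(curve.mean_r_spatial[curve.k_star - 1]),
        "p_test": result.p_test,
        "p_spatial": result.p_spatial,
        "lv1_cov_fraction": float(model.cov_fraction[0]),
        "n_clusters": int(len(clusters)),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
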