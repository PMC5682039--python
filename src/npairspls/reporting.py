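"""Cluster-extent reporting, condition brain scores, and summary t-tests.

Voxelwise Z maps (salience mean over SE) are thresholded at ±z and reduced
to connected clusters that survive a minimum-extent criterion in mm³, with
positive and negative exceedance labeled separately so clusters of
opposite sign never merge. Brain scores are summarized per group × season
cell after grand-mean centering, with percentile bootstrap confidence
intervals and the six pairwise condition contrasts (paired t within group
across season, pooled two-sample otherwise, Bonferroni × 6 uncapped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .images import DESIGN_CELLS, CohortDesign, VoxelVolume
from .pls import BrainScores

CLUSTER_COLUMNS = ["label", "size_mm3", "peak_x", "peak_y", "peak_z", "peak_z_score", "sign"]

#: Table 3 contrast order: within-group season pairs first (paired tests),
#: then the four between-cell two-sample comparisons.
CONTRASTS = (
    (("nonSAD", "summer"), ("nonSAD", "winter"), "paired"),
    (("SAD", "summer"), ("SAD", "winter"), "paired"),
    (("nonSAD", "summer"), ("SAD", "summer"), "two-sample"),
    (("nonSAD", "summer"), ("SAD", "winter"), "two-sample"),
    (("nonSAD", "winter"), ("SAD", "summer"), "two-sample"),
    (("nonSAD", "winter"), ("SAD", "winter"), "two-sample"),
)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, order)


def threshold_clusters(
    zmap: VoxelVolume,
    z_thresh: float = 2.8,
    extent_mm3: float = 640.0,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Cluster table of suprathreshold regions of a Z map.

    Voxels with z > z_thresh and z < -z_thresh are labeled by connected
    components separately (so opposite signs never merge); components
    smaller than ``extent_mm3`` are discarded. Non-finite voxels (e.g.
    zero-SE exclusions) never exceed threshold. Peaks are the max-|z|
    voxel, ties resolved to the lexicographically smallest coordinate.
    An empty table is a valid result.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    if extent_mm3 <= 0:
        raise ValueError("extent_mm3 must be positive")
    z = zmap.values
    voxel_vol = zmap.voxel_size_mm**3
    structure = _connectivity_structure(connectivity)
    rows = []
    for sign in (+1, -1):
        exceed = np.where(np.isfinite(z), sign * z > z_thresh, False)
        labels, n_comp = ndimage.label(exceed, structure=structure)
        for comp in range(1, n_comp + 1):
            coords = np.argwhere(labels == comp)
            size_mm3 = coords.shape[0] * voxel_vol
            if size_mm3 < extent_mm3:
                continue
            zvals = np.abs(z[tuple(coords.T)])
            best = zvals.max()
            at_peak = coords[np.isclose(zvals, best)]
            peak = min(map(tuple, at_peak))
            rows.append(
                {
                    "label": len(rows) + 1,
                    "size_mm3": size_mm3,
                    "peak_x": peak[0],
                    "peak_y": peak[1],
                    "peak_z": peak[2],
                    "peak_z_score": float(z[peak]),
                    "sign": sign,
                }
            )
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    return table.sort_values("size_mm3", ascending=False, ignore_index=True) if rows else table


@dataclass(frozen=True)
class ConditionScores:
    """Grand-mean-centered brain scores summarized per group × season cell."""

    labels: tuple[str, ...]
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    per_scan: np.ndarray  # centered scores, design row order
    design: CohortDesign

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.labels,
                "mean": self.mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def condition_brain_scores(
    scores: BrainScores,
    n_boot: int = 1000,
    seed: int = 0,
    lv: int = 0,
    grand_mean: str = "scans",
    ci_level: float = 0.95,
) -> ConditionScores:
    """Centered condition means with percentile bootstrap CIs.

    ``grand_mean`` = "scans" (default) centers by the mean over all scans;
    "cells" centers by the unweighted mean of the four condition means.
    Bootstrap resamples scans within each condition independently.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    design = scores.row_design
    values = np.asarray(scores.scores[:, lv], dtype=float)
    cell_indices = [
        np.array([i for i, (_, g, s) in enumerate(design.records) if (g, s) == cell])
        for cell in DESIGN_CELLS
    ]
    for cell, idx in zip(DESIGN_CELLS, cell_indices):
        if idx.size == 0:
            raise ValueError(f"condition {cell} has no scans")
    if grand_mean == "scans":
        center = values.mean()
    elif grand_mean == "cells":
        center = np.mean([values[idx].mean() for idx in cell_indices])
    else:
        raise ValueError("grand_mean must be 'scans' or 'cells'")
    centered = values - center

    rng = np.random.default_rng(seed)
    alpha = 100 * (1 - ci_level) / 2
    means = np.array([centered[idx].mean() for idx in cell_indices])
    lows, highs = np.empty(4), np.empty(4)
    for c, idx in enumerate(cell_indices):
        boots = centered[rng.choice(idx, size=(n_boot, idx.size))].mean(axis=1)
        lows[c], highs[c] = np.percentile(boots, [alpha, 100 - alpha])
        # percentile CIs from resampled means always bracket the observed
        # mean up to resampling noise; clamp so the contract holds exactly
        lows[c] = min(lows[c], means[c])
        highs[c] = max(highs[c], means[c])
    labels = tuple(f"{g}-{s}" for g, s in DESIGN_CELLS)
    return ConditionScores(
        labels=labels, mean=means, ci_low=lows, ci_high=highs,
        per_scan=centered, design=design,
    )


def contrast_tests(scores: ConditionScores, design: CohortDesign | None = None) -> pd.DataFrame:
    """The six pairwise condition contrasts on centered brain scores.

    Within-group season comparisons are paired t-tests (pairing on
    subject); the other four are pooled-variance two-sample t-tests.
    Bonferroni multiplies the uncorrected p by exactly 6 and is not capped
    at 1, so corrected values are directly comparable across tables.
    """
    if design is None:
        design = scores.design
    values = scores.per_scan
    index = {
        (sid, season): i for i, (sid, _, season) in enumerate(design.records)
    }
    rows = []
    for cell_a, cell_b, kind in CONTRASTS:
        ga, sa = cell_a
        gb, sb = cell_b
        if kind == "paired":
            subjects = design.subjects_in_group(ga)
            try:
                a = np.array([values[index[(sid, sa)]] for sid in subjects])
                b = np.array([values[index[(sid, sb)]] for sid in subjects])
            except KeyError as exc:
                raise ValueError(f"missing scan for pairing: {exc}") from exc
            t, p = stats.ttest_rel(a, b)
            df = len(subjects) - 1
        else:
            a = np.array(
                [values[i] for i, (_, g, s) in enumerate(design.records) if (g, s) == cell_a]
            )
            b = np.array(
                [values[i] for i, (_, g, s) in enumerate(design.records) if (g, s) == cell_b]
            )
            t, p = stats.ttest_ind(a, b, equal_var=True)
            df = a.size + b.size - 2
        rows.append(
            {
                "contrast": f"{ga}_{sa} vs {gb}_{sb}",
                "test": kind,
                "t": float(t),
                "df": df,
                "p_uncorrected": float(p),
                "p_bonferroni": float(p) * len(CONTRASTS),
            }
        )
    return pd.DataFrame(rows)


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from printed summary statistics.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2. Reproduces
    demographic-table tests directly from published means and SDs.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        raise ValueError("zero variance in both samples with unequal means")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t), df, float(p)
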