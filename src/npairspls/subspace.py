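"""Adaptive PC-subspace selection for NPAIRS-validated PLS.

Restricting each training half to its top-k principal components acts as a
denoising regularizer. The subspace dimension k is chosen by running the
same split-half schedule at every k and scoring each k by its distance
from the ideal point (prediction = 1, reproducibility = 1):

    D(k) = (1 - mean r_spatial(k))^2 + (1 - mean r_test(k))^2

The selected k* minimizes D (ties break toward the smallest k). A
no-reduction reference run quantifies what the optimization buys, and the
correlation of every k's mean salience map with the k* map measures how
robust the identified pattern is to the choice of k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .images import DataMatrix, DesignMatrix, standardize_columns
from .npairs import (
    NpairsResult,
    SplitPlan,
    make_split_schedule,
    run_npairs,
    _pearson,
)
from .pls import fit_pls


@dataclass(frozen=True)
class SubspaceCurve:
    """Per-k NPAIRS summary plus the no-PCA reference.

    ``reference_metrics`` is the (mean_r_test, mean_r_spatial, D) triple
    with no PC reduction; ``reference_pattern_corr`` is the correlation of
    the no-PCA mean salience map with the k* map.
    """

    k_values: np.ndarray
    mean_r_test: np.ndarray
    mean_r_spatial: np.ndarray
    D: np.ndarray
    k_star: int
    pattern_corr_to_star: np.ndarray
    reference_metrics: tuple[float, float, float]
    reference_pattern_corr: float
    saliences: np.ndarray  # (n_k, voxels) mean salience map per k
    result_at_star: NpairsResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "mean_r_test": self.mean_r_test,
                "mean_r_spatial": self.mean_r_spatial,
                "D": self.D,
                "pattern_corr_to_star": self.pattern_corr_to_star,
            }
        )


def reduce_to_pcs(
    X_half: np.ndarray, k: int, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of one (standardized) half, retaining the top-k components.

    Returns ``(T, W)`` where ``T`` (scans × k) holds the component scores
    and ``W`` (voxels × k) the orthonormal loadings; ``T @ W.T``
    reconstructs the standardized half exactly when k reaches its rank.
    Column-centering removes one degree of freedom, hence the ``rows - 1``
    bound.
    """
    X_half = np.asarray(X_half, dtype=float)
    bound = min(X_half.shape[0] - 1, X_half.shape[1])
    if not 1 <= k <= bound:
        raise ValueError(
            f"k={k} out of range; need 1 <= k <= {bound} "
            f"(= min(rows - 1, columns) for a {X_half.shape} half)"
        )
    if standardize:
        X_half = standardize_columns(X_half)
    U, s, Vt = np.linalg.svd(X_half, full_matrices=False)
    T = U[:, :k] * s[:k]
    W = Vt[:k].T
    return T, W


def distance_D(mean_r_spatial: float, mean_r_test: float) -> float:
    """D = (1 - r_spatial)^2 + (1 - r_test)^2.

    A sum of squares (the squared Euclidean distance from the ideal point
    (1, 1)); the argmin over k is identical to that of the Euclidean
    distance itself.
    """
    return (1.0 - mean_r_spatial) ** 2 + (1.0 - mean_r_test) ** 2


def pattern_stability_across_k(
    saliences: np.ndarray, k_star_index: int
) -> np.ndarray:
    """Pearson correlation of each row's sign-aligned salience map with the
    k*-row map; exactly 1 at the k* row itself."""
    saliences = np.asarray(saliences, dtype=float)
    star = saliences[k_star_index]
    out = np.empty(saliences.shape[0])
    for i, sal in enumerate(saliences):
        if float(np.dot(sal, star)) < 0:
            sal = -sal
        out[i] = 1.0 if i == k_star_index else _pearson(sal, star)
    return out


def select_optimal_k(
    X: DataMatrix,
    Y: DesignMatrix,
    k_max: int | None = None,
    n_splits: int = 1000,
    seed: int = 0,
    metric_mode: str = "matrix",
    global_standardize: bool = False,
) -> SubspaceCurve:
    """Scan k = 1..k_max over a shared split schedule and select k* = argmin D.

    The same split plans are reused for every k (and for the no-PCA
    reference run), so the per-k curves differ only in the subspace
    dimension. ``k_max`` defaults to the largest admissible value,
    min(half size) - 1 capped at the voxel count.
    """
    plans = make_split_schedule(X.row_design, n_splits, seed)
    min_half = min(min(len(p.half_A), len(p.half_B)) for p in plans)
    bound = min(min_half - 1, X.X.shape[1])
    if k_max is None:
        k_max = bound
    if not 1 <= k_max <= bound:
        raise ValueError(f"k_max={k_max} out of range; need 1 <= k_max <= {bound}")
    reference_salience = fit_pls(X, Y).V[:, 0]

    def one_run(k: int | None) -> NpairsResult:
        return run_npairs(
            X, Y, k,
            plans=plans,
            reference_salience=reference_salience,
            metric_mode=metric_mode,
            global_standardize=global_standardize,
        )

    k_values = np.arange(1, k_max + 1)
    results = [one_run(int(k)) for k in k_values]
    mean_r_test = np.array([r.r_test.mean() for r in results])
    mean_r_spatial = np.array([r.r_spatial.mean() for r in results])
    D = np.array(
        [distance_D(rs, rt) for rs, rt in zip(mean_r_spatial, mean_r_test)]
    )
    star_index = int(np.argmin(D))  # first minimum -> smallest k on ties
    k_star = int(k_values[star_index])
    saliences = np.stack([r.salience_mean for r in results])
    pattern_corr = pattern_stability_across_k(saliences, star_index)

    ref = one_run(None)
    ref_rt, ref_rs = float(ref.r_test.mean()), float(ref.r_spatial.mean())
    ref_sal = ref.salience_mean
    if float(np.dot(ref_sal, saliences[star_index])) < 0:
        ref_sal = -ref_sal
    return SubspaceCurve(
        k_values=k_values,
        mean_r_test=mean_r_test,
        mean_r_spatial=mean_r_spatial,
        D=D,
        k_star=k_star,
        pattern_corr_to_star=pattern_corr,
        reference_metrics=(ref_rt, ref_rs, distance_D(ref_rs, ref_rt)),
        reference_pattern_corr=_pearson(ref_sal, saliences[star_index]),
        saliences=saliences,
        result_at_star=results[star_index],
    )


def plot_curve(curve: SubspaceCurve, path: str) -> None:
    """Two-panel figure: per-k metric scatter with the no-PCA reference
    point, and the pattern-robustness curve with the reference line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    sc = ax1.scatter(
        curve.mean_r_spatial, curve.mean_r_test, c=curve.k_values, cmap="viridis"
    )
    star = curve.k_values == curve.k_star
    ax1.scatter(
        curve.mean_r_spatial[star], curve.mean_r_test[star],
        facecolors="none", edgecolors="black", s=160, label=f"k* = {curve.k_star}",
    )
    ref_rt, ref_rs, _ = curve.reference_metrics
    ax1.scatter([ref_rs], [ref_rt], color="red", marker="o", label="no PCA")
    ax1.set_xlabel("mean $r_{spatial}$")
    ax1.set_ylabel("mean $r_{test}$")
    ax1.legend()
    fig.colorbar(sc, ax=ax1, label="k")
    ax2.plot(curve.k_values, curve.pattern_corr_to_star, "o-")
    ax2.axhline(curve.reference_pattern_corr, color="red", linestyle=":",
                label="no-PCA reference")
    ax2.set_xlabel("k (PC #)")
    ax2.set_ylabel(f"pattern correlation to k* = {curve.k_star}")
    ax2.set_ylim(-1.05, 1.05)
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
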