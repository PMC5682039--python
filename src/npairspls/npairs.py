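"""NPAIRS split-half cross-validation for contrast-based PLS.

Subjects are repeatedly assigned to two halves under matched (stratified)
sampling, so each half carries both groups and both seasons and a
subject's two scans travel together. Each half is standardized on its own,
optionally reduced to a top-k principal-component subspace, and PLS-fit;
per split the framework scores

* prediction on the training half, r_train_i = rho(Y_i, X_i E_iᵀ),
* prediction on the held-out half, r_test_i = rho(Y_j, X_j E_iᵀ) (j != i),
* spatial reproducibility, r_spatial = rho of the two halves' retained
  voxel salience patterns,

with rho the Pearson correlation of the vectorized arguments. Aggregating
over splits gives empirical p-values for prediction and reproducibility,
and voxelwise salience mean / SE / Z maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .images import CohortDesign, DataMatrix, DesignMatrix, standardize_columns
from .pls import fit_pls

MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SplitPlan:
    """One split-half assignment: scan indices of the two halves.

    Plans built by :func:`split_half_partition` satisfy the matched-sampling
    contract (disjoint halves covering all scans; whole subjects; at least
    one subject per group and scans of both seasons in each half); the
    container itself does not re-validate, so degenerate plans can be
    constructed for diagnostics.
    """

    half_A: tuple[int, ...]
    half_B: tuple[int, ...]
    seed: int | None = None


@dataclass(frozen=True)
class SplitMetrics:
    """Per-split scalars: train/test correlations for each half and the
    spatial reproducibility of the retained LV pattern."""

    r_train: tuple[float, float]
    r_test: tuple[float, float]
    r_spatial: float


@dataclass(frozen=True)
class NpairsResult:
    """Aggregate over splits.

    ``r_train`` and ``r_test`` are (n_splits, 2) arrays (one value per
    half); ``r_spatial`` is (n_splits,). ``salience_mean``/``salience_se``
    are across the per-split averaged, sign-aligned salience maps, and
    ``zmap`` is their elementwise ratio (NaN where the SE is zero).
    """

    r_train: np.ndarray
    r_test: np.ndarray
    r_spatial: np.ndarray
    p_test: float
    p_spatial: float
    salience_mean: np.ndarray
    salience_se: np.ndarray
    zmap: np.ndarray
    n_splits: int
    k: int | None

    def metrics_frame(self) -> pd.DataFrame:
        """Metric distributions as a tidy table, one row per split."""
        return pd.DataFrame(
            {
                "split_id": np.arange(self.n_splits),
                "r_train_A": self.r_train[:, 0],
                "r_train_B": self.r_train[:, 1],
                "r_test_A": self.r_test[:, 0],
                "r_test_B": self.r_test[:, 1],
                "r_spatial": self.r_spatial,
            }
        )


def empirical_pvalue(samples: np.ndarray) -> float:
    """One-sided empirical p-value against 0 with add-one smoothing.

    p = (1 + #{samples <= 0}) / (1 + n): the probability, under the
    resampling distribution, that the metric fails to exceed zero. Never
    returns 0, so downstream -log10 transforms stay finite.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("empirical_pvalue needs at least one sample")
    return float((1 + np.sum(samples <= 0)) / (1 + samples.size))


def split_half_partition(design: CohortDesign, rng: np.random.Generator) -> SplitPlan:
    """Random matched-sampling split: within each group, subjects divide as
    evenly as possible between the halves (odd counts put the extra subject
    on a random side); both scans of a subject follow the subject."""
    half_subjects: tuple[list[str], list[str]] = ([], [])
    for group in ("nonSAD", "SAD"):
        subjects = list(design.subjects_in_group(group))
        if len(subjects) < 2:
            raise ValueError(
                f"group {group!r} has {len(subjects)} subject(s); "
                "matched splitting needs at least 2 per group"
            )
        order = rng.permutation(len(subjects))
        n_a = len(subjects) // 2
        if len(subjects) % 2 == 1 and rng.integers(2) == 1:
            n_a += 1
        for pos, j in enumerate(order):
            half_subjects[0 if pos < n_a else 1].append(subjects[j])
    halves = []
    for members in half_subjects:
        idx: list[int] = []
        for sid in members:
            idx.extend(design.scan_indices_of(sid))
        halves.append(tuple(sorted(idx)))
    return SplitPlan(half_A=halves[0], half_B=halves[1])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return float("nan")
    return float(np.dot(a, b) / denom)


def _retained_salience(
    E: np.ndarray, W: np.ndarray | None, reference: np.ndarray | None
) -> np.ndarray:
    """Voxel salience of the retained LV of one half.

    The SVD of the (possibly subspace) cross-product gives candidate LVs;
    the retained one is LV-1 unless a reference pattern is supplied, in
    which case it is the LV whose back-projected salience correlates most
    strongly (in absolute value) with the reference — guarding against LV
    order swaps between halves.
    """
    _, _, Vt = np.linalg.svd(E, full_matrices=False)
    V = Vt.T if W is None else W @ Vt.T
    if reference is None or V.shape[1] == 1:
        return V[:, 0]
    corrs = [abs(_pearson(V[:, l], reference)) for l in range(V.shape[1])]
    return V[:, int(np.argmax(corrs))]


def evaluate_split(
    X: DataMatrix,
    Y: DesignMatrix,
    plan: SplitPlan,
    k: int | None,
    reference_salience: np.ndarray | None = None,
    metric_mode: str = "matrix",
    global_standardize: bool = False,
) -> tuple[SplitMetrics, tuple[np.ndarray, np.ndarray]]:
    """Fit PLS independently on each half and score the split.

    Parameters
    ----------
    k : int or None
        PC-subspace dimension per half; None skips the PCA reduction.
    reference_salience : array, optional
        Full-data LV-1 voxel pattern used to track the retained LV and to
        fix the overall sign of the returned salience pair.
    metric_mode : {"matrix", "per_lv"}
        "matrix" (default) correlates the vectorized standardized design
        matrix with the vectorized projection X Eᵀ over all four columns
        jointly; "per_lv" correlates the retained LV's design and brain
        scores instead.
    global_standardize : bool
        If True, halves reuse the full-cohort column statistics instead of
        standardizing themselves.

    Returns the split metrics and the sign-aligned voxel salience pair
    (half A first).
    """
    if metric_mode not in ("matrix", "per_lv"):
        raise ValueError(f"unknown metric_mode {metric_mode!r}")
    from .subspace import reduce_to_pcs  # local import: subspace builds on npairs

    halves = (np.asarray(plan.half_A, dtype=int), np.asarray(plan.half_B, dtype=int))
    if global_standardize:
        Xg, Yg = standardize_columns(X.X), standardize_columns(Y.Y)
        Xs = [Xg[h] for h in halves]
        Ys = [Yg[h] for h in halves]
    else:
        Xs = [standardize_columns(X.X[h]) for h in halves]
        Ys = [standardize_columns(Y.Y[h]) for h in halves]
    if k is not None:
        bound = min(min(len(h) for h in halves) - 1, X.X.shape[1])
        if not 1 <= k <= bound:
            raise ValueError(f"k={k} out of range; need 1 <= k <= {bound} "
                             "(min half size - 1, capped at the voxel count)")
        reduced = [reduce_to_pcs(Xh, k, standardize=False) for Xh in Xs]
        T = [t for t, _ in reduced]
        W: list[np.ndarray | None] = [w for _, w in reduced]
    else:
        T = Xs
        W = [None, None]
    E = [Ys[i].T @ T[i] for i in (0, 1)]

    saliences = [
        _retained_salience(E[i], W[i], reference_salience) for i in (0, 1)
    ]
    if reference_salience is not None and _pearson(saliences[0], reference_salience) < 0:
        saliences[0] = -saliences[0]
    if float(np.dot(saliences[1], saliences[0])) < 0:
        saliences[1] = -saliences[1]

    r_train, r_test = [], []
    for i, j in ((0, 1), (1, 0)):
        if metric_mode == "matrix":
            r_train.append(_pearson(Ys[i], T[i] @ E[i].T))
            Tj_on_i = Xs[j] if W[i] is None else Xs[j] @ W[i]
            r_test.append(_pearson(Ys[j], Tj_on_i @ E[i].T))
        else:
            Ui, si, Vti = np.linalg.svd(E[i], full_matrices=False)
            u, v = Ui[:, 0], Vti[0]
            r_train.append(_pearson(Ys[i] @ u, T[i] @ v))
            Tj_on_i = Xs[j] if W[i] is None else Xs[j] @ W[i]
            r_test.append(_pearson(Ys[j] @ u, Tj_on_i @ v))
    metrics = SplitMetrics(
        r_train=(r_train[0], r_train[1]),
        r_test=(r_test[0], r_test[1]),
        r_spatial=_pearson(saliences[0], saliences[1]),
    )
    return metrics, (saliences[0], saliences[1])


def make_split_schedule(
    design: CohortDesign, n_splits: int, seed: int
) -> list[SplitPlan]:
    """Reproducible schedule of split plans: a master seed spawns one child
    seed per split, so schedules are identical across k values and runs."""
    master = np.random.default_rng(seed)
    plans = []
    for _ in range(n_splits):
        child = int(master.integers(MAX_SEED))
        plan = split_half_partition(design, np.random.default_rng(child))
        plans.append(SplitPlan(plan.half_A, plan.half_B, seed=child))
    return plans


def run_npairs(
    X: DataMatrix,
    Y: DesignMatrix,
    k: int | None,
    n_splits: int = 1000,
    seed: int = 0,
    plans: list[SplitPlan] | None = None,
    reference_salience: np.ndarray | None = None,
    metric_mode: str = "matrix",
    global_standardize: bool = False,
) -> NpairsResult:
    """Aggregate evaluate_split over ``n_splits`` resamples.

    The default 1,000 splits match the protocol this pipeline implements.
    Per split the sign-aligned salience pair is averaged into one
    split-map; mean and SE maps are taken across split-maps, the Z map is
    their ratio, and p_test / p_spatial are empirical p-values of the
    pooled r_test samples and the r_spatial samples against zero.
    """
    if n_splits < 2 and plans is None:
        raise ValueError("n_splits must be >= 2")
    if plans is None:
        plans = make_split_schedule(X.row_design, n_splits, seed)
    n_splits = len(plans)
    if reference_salience is None:
        reference_salience = fit_pls(X, Y).V[:, 0]
    r_train = np.empty((n_splits, 2))
    r_test = np.empty((n_splits, 2))
    r_spatial = np.empty(n_splits)
    split_maps = np.empty((n_splits, X.X.shape[1]))
    for s, plan in enumerate(plans):
        metrics, (sal_a, sal_b) = evaluate_split(
            X, Y, plan, k,
            reference_salience=reference_salience,
            metric_mode=metric_mode,
            global_standardize=global_standardize,
        )
        r_train[s] = metrics.r_train
        r_test[s] = metrics.r_test
        r_spatial[s] = metrics.r_spatial
        split_maps[s] = 0.5 * (sal_a + sal_b)
    salience_mean = split_maps.mean(axis=0)
    salience_se = split_maps.std(axis=0, ddof=1)
    # saliences are unit-norm maps, so an SE at the 1e-12 scale is floating-
    # point jitter of identical split patterns, not a real error estimate
    se_floor = 1e-12 * max(1.0, float(np.max(np.abs(salience_mean), initial=0.0)))
    zmap = np.divide(
        salience_mean,
        salience_se,
        out=np.full_like(salience_mean, np.nan),
        where=salience_se > se_floor,
    )
    return NpairsResult(
        r_train=r_train,
        r_test=r_test,
        r_spatial=r_spatial,
        p_test=empirical_pvalue(r_test),
        p_spatial=empirical_pvalue(r_spatial),
        salience_mean=salience_mean,
        salience_se=salience_se,
        zmap=zmap,
        n_splits=n_splits,
        k=k,
    )
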