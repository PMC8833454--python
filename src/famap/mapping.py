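"""Multivariate SVR-based topographical mapping with permutation inference.

The method regresses a behavioural score on voxel-wise features (skeletonized
FA values, or binary lesion indicators) with an epsilon-SVR:

1. the regularization constant C is tuned over a power-of-two grid to jointly
   maximize out-of-sample model fit (squared Pearson correlation between
   held-out predictions and observed scores, five times 5-fold CV) and
   feature-weight reproducibility (mean pairwise Pearson correlation of the
   weight vectors over all training-subset models);
2. the full-cohort linear model's per-voxel feature weights are assigned
   permutation p-values by refitting under random relabelings of the score
   vector, followed by Benjamini-Hochberg FDR selection and removal of
   significant clusters smaller than a minimum extent.

Because the features never change across permutations, the permutation engine
precomputes the linear Gram matrix once and recovers primal weights from the
dual coefficients of each refit, which makes tens of thousands of refits
cheap at cohort-scale sample sizes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.model_selection import RepeatedKFold
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DataError,
    DegenerateInputError,
    DimensionError,
    ParameterError,
)
from .io import SkeletonDataset, Volume, project_map

__all__ = [
    "SVRModel",
    "HyperparameterTrace",
    "CovariateControl",
    "MappingConfig",
    "MappingResult",
    "default_c_grid",
    "fit_svr",
    "evaluate_c",
    "optimize_c",
    "permutation_pmap",
    "fdr_select",
    "filter_clusters",
    "apply_covariate_control",
    "run_mapping",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def default_c_grid(low: int = -20, high: int = 20) -> np.ndarray:
    """The power-of-two C grid, 2**low .. 2**high inclusive."""
    return 2.0 ** np.arange(low, high + 1)


def _as_matrix(dataset) -> np.ndarray:
    if isinstance(dataset, SkeletonDataset):
        return dataset.features
    return np.asarray(dataset, dtype=float)


def _check_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim != 2:
        raise DimensionError("features must be 2D (subjects x voxels)")
    if len(y) != x.shape[0]:
        raise DimensionError("scores length != number of subjects")
    if not np.isfinite(x).all():
        raise DataError("features contain non-finite values")
    if not np.isfinite(y).all():
        raise DataError("scores contain non-finite values")
    if np.ptp(y) < 1e-12:
        raise DegenerateInputError("score vector is constant")
    return x, y


@dataclass(frozen=True)
class SVRModel:
    """A fitted epsilon-SVR; ``weights`` is the primal vector (linear only)."""

    estimator: SVR
    weights: np.ndarray | None
    intercept: float
    kernel: str

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class HyperparameterTrace:
    """Per-C cross-validation fit and weight-reproducibility record."""

    c_grid: np.ndarray
    fit_r2: np.ndarray
    reproducibility_r: np.ndarray
    chosen_c: float
    folds: int
    repeats: int
    cv_seed: int

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "c": self.c_grid,
                "fit_r2": self.fit_r2,
                "reproducibility_r": self.reproducibility_r,
                "chosen": np.isclose(self.c_grid, self.chosen_c),
            }
        )


@dataclass(frozen=True)
class CovariateControl:
    """How a nuisance covariate is handled before mapping.

    ``residualize_behaviour`` replaces the scores by their OLS residuals on
    the covariate; ``covary_in_model`` additionally residualizes every
    feature column (toolbox-style covarying).
    """

    strategy: str = "none"
    covariate: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.strategy not in ("none", "residualize_behaviour", "covary_in_model"):
            raise ParameterError(f"unknown covariate strategy {self.strategy!r}")
        if self.strategy != "none":
            if self.covariate is None:
                raise ParameterError("covariate values required for this strategy")
            cov = np.asarray(self.covariate, dtype=float).ravel()
            if not np.isfinite(cov).all():
                raise DataError("covariate contains non-finite values")
            object.__setattr__(self, "covariate", cov)


@dataclass(frozen=True)
class MappingConfig:
    """All knobs of the mapping chain, with study-style defaults."""

    c: float | None = None
    c_grid: Sequence[float] = field(default_factory=default_c_grid)
    folds: int = 5
    repeats: int = 5
    n_permutations: int = 25000
    q: float = 0.05
    min_cluster: int = 20
    connectivity: int = 26
    tail: str = "negative"
    kernel: str = "linear"
    epsilon: float = 0.1
    zscore_features: bool = False
    covariate_strategy: str = "none"
    cv_seed: int = 0
    perm_seed: int = 0

    def manifest(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["c_grid"] = [float(c) for c in self.c_grid]
        return d


@dataclass(frozen=True)
class MappingResult:
    """Feature weights, permutation p-values and thresholded topographies."""

    weights: np.ndarray
    p_values: np.ndarray
    fdr_q: float
    p_threshold: float
    sig_mask_raw: Volume
    sig_mask_filtered: Volume
    min_cluster: int
    n_permutations: int
    tail: str
    perm_seed: int
    chosen_c: float
    trace: HyperparameterTrace | None
    degenerate_voxels: np.ndarray

    @property
    def n_significant_raw(self) -> int:
        return int(self.sig_mask_raw.data.sum())

    @property
    def n_significant(self) -> int:
        return int(self.sig_mask_filtered.data.sum())


# ---------------------------------------------------------------------------
# model fitting


def fit_svr(
    dataset,
    scores: np.ndarray,
    c: float = 1.0,
    kernel: str = "linear",
    epsilon: float = 0.1,
) -> SVRModel:
    """Fit an epsilon-SVR of scores on voxel features.

    For the linear kernel the primal weight vector w and bias b are exposed
    (prediction = w.x + b); for the rbf kernel only predictions are defined.
    """
    x = _as_matrix(dataset)
    x, y = _check_xy(x, scores)
    if x.shape[0] < 3:
        raise DegenerateInputError("need at least 3 subjects")
    if c <= 0:
        raise ParameterError("C must be positive")
    if kernel not in ("linear", "rbf"):
        raise ParameterError(f"unsupported kernel {kernel!r}")
    return _fit_svr_unchecked(x, y, c, kernel, epsilon)


def _fit_svr_unchecked(
    x: np.ndarray, y: np.ndarray, c: float, kernel: str, epsilon: float
) -> SVRModel:
    """Fit without the public-facing size checks (CV folds may be tiny)."""
    est = SVR(kernel=kernel, C=c, epsilon=epsilon)
    est.fit(x, y)
    weights = est.coef_.ravel().copy() if kernel == "linear" else None
    return SVRModel(
        estimator=est,
        weights=weights,
        intercept=float(est.intercept_[0]),
        kernel=kernel,
    )


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, defined as 0 when either vector is constant."""
    if np.ptp(a) < 1e-15 or np.ptp(b) < 1e-15:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_c(
    dataset,
    scores: np.ndarray,
    c: float,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    kernel: str = "linear",
    epsilon: float = 0.1,
) -> tuple[float, float]:
    """Cross-validated model fit and feature-weight reproducibility at one C.

    ``fit_r2`` is the mean over all folds x repeats of the squared Pearson
    correlation between held-out predictions and observed scores.
    ``reproducibility_r`` is the mean Pearson correlation of the linear
    weight vectors over all unordered pairs of training-subset models.
    Folds are drawn reproducibly from ``seed``.
    """
    x = _as_matrix(dataset)
    x, y = _check_xy(x, scores)
    if x.shape[0] < folds:
        raise DegenerateInputError("fewer subjects than folds")
    splitter = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    r2s: list[float] = []
    weight_stack: list[np.ndarray] = []
    for train, test in splitter.split(x):
        if np.ptp(y[train]) < 1e-12:
            warnings.warn("training fold has constant scores; fold skipped")
            continue
        model = _fit_svr_unchecked(x[train], y[train], c, kernel, epsilon)
        if model.weights is not None:
            weight_stack.append(model.weights)
        if np.ptp(y[test]) < 1e-12:
            warnings.warn("held-out fold has constant scores; fold skipped")
            continue
        pred = model.predict(x[test])
        r2s.append(_safe_pearson(pred, y[test]) ** 2)
    fit_r2 = float(np.mean(r2s)) if r2s else 0.0
    if len(weight_stack) >= 2:
        pair_rs = [
            _safe_pearson(wa, wb)
            for wa, wb in itertools.combinations(weight_stack, 2)
        ]
        reproducibility_r = float(np.mean(pair_rs))
    else:
        reproducibility_r = float("nan")
    return fit_r2, reproducibility_r


def _select_c(
    c_grid: np.ndarray, fit_r2: np.ndarray, reproducibility_r: np.ndarray
) -> int:
    """Index of the chosen C: max of the summed min-max-normalized criteria.

    Ties go to the smaller C. A criterion that is constant across the grid
    contributes zero everywhere.
    """

    def norm(v: np.ndarray) -> np.ndarray:
        v = np.nan_to_num(np.asarray(v, dtype=float), nan=0.0)
        span = v.max() - v.min()
        if span < 1e-15:
            return np.zeros_like(v)
        return (v - v.min()) / span

    score = norm(fit_r2) + norm(reproducibility_r)
    best = score.max()
    candidates = np.flatnonzero(score >= best - 1e-12)
    return int(candidates[np.argmin(np.asarray(c_grid)[candidates])])


def optimize_c(
    dataset,
    scores: np.ndarray,
    c_grid: Sequence[float] | None = None,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    kernel: str = "linear",
    epsilon: float = 0.1,
) -> HyperparameterTrace:
    """Evaluate every C on the grid and pick the jointly best one.

    The selection rule sums the min-max-normalized fit and reproducibility
    curves; ties resolve to the smaller C.
    """
    grid = np.asarray(
        default_c_grid() if c_grid is None else list(c_grid), dtype=float
    )
    if grid.size == 0:
        raise ParameterError("c_grid is empty")
    fit = np.empty(grid.size)
    rep = np.empty(grid.size)
    for i, c in enumerate(grid):
        fit[i], rep[i] = evaluate_c(
            dataset, scores, c, folds=folds, repeats=repeats, seed=seed,
            kernel=kernel, epsilon=epsilon,
        )
    chosen = _select_c(grid, fit, rep)
    return HyperparameterTrace(
        c_grid=grid,
        fit_r2=fit,
        reproducibility_r=rep,
        chosen_c=float(grid[chosen]),
        folds=folds,
        repeats=repeats,
        cv_seed=seed,
    )


# ---------------------------------------------------------------------------
# permutation inference


def _dual_weights(est: SVR, x: np.ndarray) -> np.ndarray:
    """Primal weight vector from a precomputed-kernel SVR fit."""
    return est.dual_coef_.ravel() @ x[est.support_]


def _count_extreme(
    perm_w: np.ndarray, obs_w: np.ndarray, tail: str
) -> np.ndarray:
    if tail == "negative":
        return (perm_w <= obs_w).astype(np.int64)
    if tail == "positive":
        return (perm_w >= obs_w).astype(np.int64)
    if tail == "two_sided":
        return (np.abs(perm_w) >= np.abs(obs_w)).astype(np.int64)
    raise ParameterError(f"unknown tail {tail!r}")


def permutation_pmap(
    dataset,
    scores: np.ndarray,
    c: float,
    n_permutations: int = 25000,
    seed: int = 0,
    tail: str = "negative",
    epsilon: float = 0.1,
    exhaustive: bool = False,
) -> np.ndarray:
    """Per-voxel permutation p-values for linear SVR feature weights.

    The observed weights are computed once on the real labels; each
    permutation refits the model with the score vector shuffled (without
    replacement) and the voxel-wise weights recomputed. With sampled
    permutations p = (1 + #extreme) / (n_permutations + 1); with
    ``exhaustive=True`` all n! distinct orderings (including the identity)
    are enumerated and p is the exact rank-based fraction.

    Zero-variance feature columns carry no information about the score; their
    p-value is reported as 1.
    """
    x = _as_matrix(dataset)
    x, y = _check_xy(x, scores)
    if tail not in ("negative", "positive", "two_sided"):
        raise ParameterError(f"unknown tail {tail!r}")
    if not exhaustive and n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    n = x.shape[0]
    gram = x @ x.T
    est = SVR(kernel="precomputed", C=c, epsilon=epsilon)
    est.fit(gram, y)
    obs_w = _dual_weights(est, x)

    counts = np.zeros(x.shape[1], dtype=np.int64)
    if exhaustive:
        if math.factorial(n) > 50000:
            raise ParameterError("exhaustive enumeration only feasible for tiny n")
        total = 0
        for perm in itertools.permutations(range(n)):
            est_k = SVR(kernel="precomputed", C=c, epsilon=epsilon)
            est_k.fit(gram, y[list(perm)])
            counts += _count_extreme(_dual_weights(est_k, x), obs_w, tail)
            total += 1
        p = counts / total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            est_k = SVR(kernel="precomputed", C=c, epsilon=epsilon)
            est_k.fit(gram, y[rng.permutation(n)])
            counts += _count_extreme(_dual_weights(est_k, x), obs_w, tail)
        p = (1 + counts) / (n_permutations + 1)
    p = np.asarray(p, dtype=float)
    p[x.std(axis=0) < 1e-15] = 1.0
    return p


def fdr_select(p_values: np.ndarray, q: float = 0.05) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up selection.

    Returns the largest p-value declared significant (0.0 when nothing is)
    and the boolean significance flags.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise DegenerateInputError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise DataError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ParameterError("q must lie in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    k = int(reject.sum())
    if k == 0:
        return 0.0, np.zeros_like(p, dtype=bool)
    threshold = float(np.sort(p)[k - 1])
    return threshold, p <= threshold


def filter_clusters(
    sig_volume: Volume, min_cluster: int = 20, connectivity: int = 26
) -> Volume:
    """Remove connected components smaller than ``min_cluster`` voxels.

    Components are defined under 6-, 18- or 26-connectivity (default 26);
    components with at least ``min_cluster`` voxels are preserved unchanged.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ParameterError("connectivity must be one of 6, 18, 26")
    if min_cluster < 0:
        raise ParameterError("min_cluster must be non-negative")
    if not sig_volume.is_binary():
        raise DataError("cluster filtering expects a binary volume")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_comp = ndimage.label(sig_volume.data > 0, structure=structure)
    if n_comp == 0:
        return Volume(np.zeros(sig_volume.shape, dtype=np.int16), sig_volume.affine)
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_cluster)
    keep = keep[keep > 0]
    out = np.isin(labels, keep).astype(np.int16)
    return Volume(out, sig_volume.affine)


def _residualize(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(covariate), covariate])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def apply_covariate_control(
    scores: np.ndarray, features: np.ndarray, control: CovariateControl
) -> tuple[np.ndarray, np.ndarray]:
    """Adjust scores (and optionally features) for a nuisance covariate."""
    scores = np.asarray(scores, dtype=float).ravel()
    features = np.asarray(features, dtype=float)
    if control.strategy == "none":
        return scores, features
    cov = control.covariate
    if len(cov) != len(scores):
        raise DimensionError("covariate length != scores length")
    if np.ptp(cov) < 1e-12:
        raise DegenerateInputError("covariate is constant")
    adj_scores = _residualize(scores, cov)
    if control.strategy == "residualize_behaviour":
        return adj_scores, features
    adj_features = _residualize(features, cov)
    return adj_scores, adj_features


# ---------------------------------------------------------------------------
# full chain


def run_mapping(
    dataset: SkeletonDataset,
    scores: np.ndarray,
    config: MappingConfig = MappingConfig(),
    covariate: np.ndarray | None = None,
) -> MappingResult:
    """Run the full chain: covariate control, C selection, full-cohort fit,
    permutation p-values, FDR selection and cluster-extent filtering.

    The binary-lesion variant is obtained by passing a 0/1 feature matrix in
    ``dataset``; nothing else changes. The permutation step requires the
    linear kernel (feature weights are undefined otherwise).
    """
    if config.n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    if config.kernel != "linear":
        raise ParameterError("permutation inference requires the linear kernel")
    x = dataset.features
    y = np.asarray(scores, dtype=float).ravel()
    if config.zscore_features:
        sd = x.std(axis=0)
        x = (x - x.mean(axis=0)) / np.where(sd < 1e-15, 1.0, sd)
    control = CovariateControl(strategy=config.covariate_strategy, covariate=covariate)
    y, x = apply_covariate_control(y, x, control)
    if np.ptp(y) < 1e-12:
        raise DegenerateInputError("scores are constant after covariate control")

    trace = None
    if config.c is not None:
        chosen_c = float(config.c)
    else:
        trace = optimize_c(
            x, y,
            c_grid=config.c_grid,
            folds=config.folds,
            repeats=config.repeats,
            seed=config.cv_seed,
            epsilon=config.epsilon,
        )
        chosen_c = trace.chosen_c

    model = fit_svr(x, y, c=chosen_c, kernel="linear", epsilon=config.epsilon)
    p = permutation_pmap(
        x, y,
        c=chosen_c,
        n_permutations=config.n_permutations,
        seed=config.perm_seed,
        tail=config.tail,
        epsilon=config.epsilon,
    )
    p_threshold, flags = fdr_select(p, q=config.q)
    sig_raw = project_map(
        flags.astype(np.int16), dataset.voxel_index, fill=0
    )
    sig_filtered = filter_clusters(
        sig_raw, min_cluster=config.min_cluster, connectivity=config.connectivity
    )
    return MappingResult(
        weights=model.weights,
        p_values=p,
        fdr_q=config.q,
        p_threshold=p_threshold,
        sig_mask_raw=sig_raw,
        sig_mask_filtered=sig_filtered,
        min_cluster=config.min_cluster,
        n_permutations=config.n_permutations,
        tail=config.tail,
        perm_seed=config.perm_seed,
        chosen_c=chosen_c,
        trace=trace,
        degenerate_voxels=x.std(axis=0) < 1e-15,
    )
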