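"""Site-grouped evaluation protocol for spectral trait prediction.

Acquisition sites (batches) are never split across cross-validation folds:
when the subjects of a site are being predicted, no subject from that site
was part of the training data.  Hyperparameters are selected by nested
cross-validation, with the inner folds built from the outer-training sites
only.  On top of the fold machinery this module provides pooled scoring
(R^2 and MAE in years), the brain-age delta (predicted minus chronological
age), log-space prediction, the post-hoc bias correction of the residual's
age dependence, paired sign-flip permutation tests across channels, and
subgroup (sex / site) breakdowns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .embedding import DistanceCache, InnerKernelSpec, distance_matrix
from .regress import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_GAMMA_GRID,
    fit_dual_ridge,
    fit_rr,
    predict_dual,
    predict_rr,
    rbf_from_squared_distance,
    squared_euclidean,
)
from .spectra import Cohort, bin_variance_scales

__all__ = [
    "Fold",
    "FoldPlan",
    "EvaluationResult",
    "PermutationResult",
    "make_site_folds",
    "nested_cv_fit_predict",
    "score",
    "bias_correct",
    "compute_delta",
    "delta_summary",
    "permutation_test_paired",
    "subgroup_eval",
]

METHODS = ("kmer", "krr", "rr")


@dataclass(frozen=True)
class Fold:
    train_idx: np.ndarray
    test_idx: np.ndarray
    test_sites: tuple[str, ...] = ()


@dataclass(frozen=True)
class FoldPlan:
    mode: str
    folds: tuple[Fold, ...]

    def __iter__(self):
        return iter(self.folds)

    def __len__(self) -> int:
        return len(self.folds)


def make_site_folds(
    cohort: Cohort,
    mode: str = "leave-site-out",
    k: int = 5,
    seed: int = 0,
    site: str | None = None,
) -> FoldPlan:
    """Build grouped cross-validation folds.

    ``leave-site-out``: one fold per site (whole site held out).
    ``grouped-k-fold``: whole sites packed into ``k`` folds, balancing
    subject counts greedily (largest site first into the currently smallest
    fold).  ``within-site-k-fold``: subjects of a single ``site`` shuffled
    with ``seed`` and split into ``k`` folds; training is restricted to
    that site.
    """
    sites = cohort.meta["site"].to_numpy()
    site_order = cohort.sites

    if mode == "leave-site-out":
        if len(site_order) < 2:
            raise ValueError("leave-site-out needs at least 2 sites")
        folds = []
        for s in site_order:
            test = np.flatnonzero(sites == s)
            train = np.flatnonzero(sites != s)
            folds.append(Fold(train, test, (s,)))
        return FoldPlan(mode, tuple(folds))

    if mode == "grouped-k-fold":
        if len(site_order) < 2:
            raise ValueError("grouped folds need at least 2 sites")
        if k > len(site_order):
            raise ValueError(f"k={k} exceeds the number of sites ({len(site_order)})")
        counts = {s: int((sites == s).sum()) for s in site_order}
        by_size = sorted(site_order, key=lambda s: (-counts[s], s))
        assignment: list[list[str]] = [[] for _ in range(k)]
        load = np.zeros(k, dtype=int)
        for s in by_size:
            j = int(np.argmin(load))
            assignment[j].append(s)
            load[j] += counts[s]
        folds = []
        for group in assignment:
            test = np.flatnonzero(np.isin(sites, group))
            train = np.flatnonzero(~np.isin(sites, group))
            folds.append(Fold(train, test, tuple(group)))
        return FoldPlan(mode, tuple(folds))

    if mode == "within-site-k-fold":
        if site is None:
            if len(site_order) != 1:
                raise ValueError("within-site mode needs an explicit site")
            site = site_order[0]
        members = np.flatnonzero(sites == site)
        if members.size < k:
            raise ValueError(f"site {site!r} has fewer subjects than k={k}")
        rng = np.random.default_rng(seed)
        shuffled = rng.permutation(members)
        folds = []
        for chunk in np.array_split(shuffled, k):
            test = np.sort(chunk)
            train = np.setdiff1d(members, chunk)
            folds.append(Fold(train, test, (site,)))
        return FoldPlan(mode, tuple(folds))

    raise ValueError(f"unknown fold mode {mode!r}")


def _subject_kfold(idx: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(idx)
    out = []
    for chunk in np.array_split(shuffled, k):
        out.append((np.setdiff1d(idx, chunk), np.sort(chunk)))
    return out


def score(y: np.ndarray, y_hat: np.ndarray) -> dict[str, float]:
    """Pooled explained variance R^2 = 1 - SSE/SST and MAE (years)."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.size != y_hat.size or y.size < 2:
        raise ValueError("score needs equal-length vectors with >= 2 entries")
    sst = float(((y - y.mean()) ** 2).sum())
    mae = float(np.abs(y - y_hat).mean())
    if sst == 0:
        warnings.warn("target has zero variance; R^2 undefined", stacklevel=2)
        return {"r2": float("nan"), "mae": mae}
    r2 = 1.0 - float(((y - y_hat) ** 2).sum()) / sst
    return {"r2": r2, "mae": mae}


def compute_delta(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """Brain-age delta: predicted minus chronological age, per subject."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.size != y_hat.size:
        raise ValueError("length mismatch")
    return y_hat - y


def delta_summary(df: pd.DataFrame, by: str = "site") -> pd.DataFrame:
    """Mean/sd/quartiles of delta per group (site, sex, ...)."""
    g = df.groupby(by)["delta"]
    out = g.agg(["count", "mean", "std"])
    out["q25"] = g.quantile(0.25)
    out["median"] = g.quantile(0.5)
    out["q75"] = g.quantile(0.75)
    return out


def bias_correct(
    train_y: np.ndarray,
    train_y_hat: np.ndarray,
    test_y: np.ndarray,
    test_y_hat: np.ndarray,
) -> np.ndarray:
    """Post-hoc correction of the residual's dependence on chronological age.

    A line r = a + b*y is fitted to the training residuals r = y - y_hat
    against chronological age y; corrected test predictions are
    y_hat + a + b*y_test.  On the training pairs this makes the corrected
    residual orthogonal to age.  Note the correction uses the test
    subject's chronological age: it is a correction of the brain-age delta,
    not a blind predictor.
    """
    train_y = np.asarray(train_y, float)
    train_y_hat = np.asarray(train_y_hat, float)
    test_y = np.asarray(test_y, float)
    test_y_hat = np.asarray(test_y_hat, float)
    if train_y.size < 3:
        raise ValueError("bias correction needs at least 3 training subjects")
    if np.ptp(train_y) == 0:
        raise ValueError("training age is constant; cannot fit the bias line")
    resid = train_y - train_y_hat
    A = np.column_stack([np.ones_like(train_y), train_y])
    (a, b), *_ = np.linalg.lstsq(A, resid, rcond=None)
    return test_y_hat + a + b * test_y


@dataclass
class PermutationResult:
    statistic: float
    n_perm: int
    p_value: float


def permutation_test_paired(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Paired sign-flip permutation test on per-channel score differences.

    The statistic is the mean paired difference; the null is built by
    flipping the sign of each channel's difference independently, and the
    two-sided p-value is (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm).
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must be 1-d and equal length")
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    d = a - b
    t_obs = float(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
    t_perm = (signs * d).mean(axis=1)
    p = (1 + int((np.abs(t_perm) >= abs(t_obs)).sum())) / (1 + n_perm)
    return PermutationResult(statistic=t_obs, n_perm=n_perm, p_value=p)


@dataclass
class EvaluationResult:
    """Out-of-sample predictions and scores for one (channel, method) run.

    ``predictions`` has one row per subject: subject_id, site, sex, age,
    fold, y_pred, optional y_pred_corrected, delta.  Scores are pooled over
    all out-of-sample predictions; ``per_fold`` holds the fold-level
    breakdown and selected hyperparameters.
    """

    method: str
    channel: str
    predictions: pd.DataFrame
    r2: float
    mae: float
    r2_corrected: float | None = None
    mae_corrected: float | None = None
    r2_log: float | None = None
    mae_log: float | None = None
    per_fold: list[dict] = field(default_factory=list)
    options: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        out = {
            "method": self.method,
            "channel": self.channel,
            "n_subjects": int(len(self.predictions)),
            "r2": self.r2,
            "mae": self.mae,
            "per_fold": self.per_fold,
            "options": self.options,
        }
        for key in ("r2_corrected", "mae_corrected", "r2_log", "mae_log"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out


def _inner_splits(
    cohort: Cohort, train_idx: np.ndarray, outer_mode: str, inner_k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Inner folds drawn from the outer-training subjects only."""
    train_sites = pd.unique(cohort.meta["site"].to_numpy()[train_idx])
    if outer_mode in ("leave-site-out", "grouped-k-fold") and len(train_sites) >= 2:
        sites = cohort.meta["site"].to_numpy()
        splits = []
        if outer_mode == "leave-site-out" or len(train_sites) <= inner_k:
            groups = [[s] for s in train_sites]
        else:
            counts = {s: int(np.sum(sites[train_idx] == s)) for s in train_sites}
            by_size = sorted(train_sites, key=lambda s: (-counts[s], s))
            groups = [[] for _ in range(inner_k)]
            load = np.zeros(inner_k, dtype=int)
            for s in by_size:
                j = int(np.argmin(load))
                groups[j].append(s)
                load[j] += counts[s]
        for group in groups:
            mask = np.isin(sites[train_idx], group)
            splits.append((train_idx[~mask], train_idx[mask]))
        return splits
    if outer_mode in ("leave-site-out", "grouped-k-fold"):
        warnings.warn(
            "fewer than 2 sites in the outer-training set; falling back to "
            "subject-level k-fold for inner model selection",
            stacklevel=2,
        )
    k = min(inner_k, train_idx.size)
    return _subject_kfold(train_idx, k, seed)


class _MethodEngine:
    """Shared fit/predict plumbing over a squared-distance or feature matrix.

    For the kernel methods (kmer, krr) everything reduces to slicing a full
    subject-by-subject squared-distance matrix and exponentiating it with
    the outer bandwidth gamma; for rr it is a plain feature-matrix ridge.
    """

    def __init__(self, method: str, X: np.ndarray | None, SQ: np.ndarray | None):
        self.method = method
        self.X = X
        self.SQ = SQ

    def fit_predict(
        self,
        train_idx: np.ndarray,
        test_idx: np.ndarray,
        y_train: np.ndarray,
        alpha: float,
        gamma: float,
    ) -> np.ndarray:
        if self.method == "rr":
            model = fit_rr(self.X[train_idx], y_train, alpha)
            return predict_rr(model, self.X[test_idx])
        K = rbf_from_squared_distance(self.SQ[np.ix_(train_idx, train_idx)], gamma)
        Kx = rbf_from_squared_distance(self.SQ[np.ix_(test_idx, train_idx)], gamma)
        model = fit_dual_ridge(K, y_train, alpha, kind=self.method)
        return predict_dual(model, Kx)


def nested_cv_fit_predict(
    cohort: Cohort,
    channel: str,
    method: str,
    fold_plan: FoldPlan | None = None,
    *,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    gammas: Sequence[float] = DEFAULT_GAMMA_GRID,
    inner_kernel: InnerKernelSpec | None = None,
    mmd_mode: str = "weighted",
    n_samples: int = 1000,
    unbiased: bool = False,
    log_space: bool = False,
    do_bias_correct: bool = False,
    normalize_bins: bool = False,
    gamma_scale: str = "median",
    inner_k: int = 5,
    seed: int = 0,
    cache: DistanceCache | None = None,
) -> EvaluationResult:
    """Nested site-grouped cross-validation for one channel and method.

    For each outer fold, every (alpha, gamma) pair on the grids is scored
    by mean MAE over inner folds built from the outer-training sites; the
    best pair (ties: smaller alpha, then smaller gamma) is refit on the
    full outer-training set and applied once to the outer test set, so
    every subject receives exactly one out-of-sample prediction.

    With ``gamma_scale="median"`` (default) the outer-kernel grid values act
    as multipliers of 1/median(d^2) over the outer-training distances — the
    median heuristic — so the bandwidth grid tracks the scale of the
    distances, which for unit-mass spectra is far below 1.  Pass
    ``gamma_scale="none"`` to use the grid values as absolute bandwidths.

    ``log_space`` trains on log(age) and back-transforms before scoring
    (scores are reported in both domains).  ``do_bias_correct`` additionally
    regresses the training residual on chronological age — using
    out-of-sample training predictions from the inner folds at the selected
    hyperparameters — and reports corrected predictions and scores.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if len(alphas) == 0 or len(gammas) == 0:
        raise ValueError("hyperparameter grids must be non-empty")
    if fold_plan is None:
        fold_plan = make_site_folds(cohort, seed=seed)

    y = cohort.ages()
    if np.any(~np.isfinite(y)):
        raise ValueError("all subjects need a recorded age (filter first)")
    if log_space:
        if np.any(y <= 0):
            raise ValueError("log-space prediction needs positive ages")
        y_fit = np.log(y)
    else:
        y_fit = y.copy()

    X = cohort.spectra[channel]
    if normalize_bins and method == "kmer":
        warnings.warn(
            "per-bin normalization applies to the feature view only; the "
            "embedding distance is unaffected",
            stacklevel=2,
        )

    # Distance backbone: MMD distances for kmer, Euclidean feature distances
    # for krr; both are y-independent so precomputing them leaks nothing.
    SQ = None
    if method == "kmer":
        D = distance_matrix(
            cohort, channel, inner_kernel or InnerKernelSpec(),
            mode=mmd_mode, n=n_samples, unbiased=unbiased, cache=cache,
        )
        SQ = D.values**2
    gamma_grid = list(gammas) if method != "rr" else [0.0]

    preds = np.full(cohort.n_subjects, np.nan)
    preds_corr = np.full(cohort.n_subjects, np.nan) if do_bias_correct else None
    fold_labels = np.full(cohort.n_subjects, -1)
    per_fold: list[dict] = []

    back = np.exp if log_space else (lambda v: v)

    for f_num, fold in enumerate(fold_plan):
        tr, te = fold.train_idx, fold.test_idx
        Xf = X
        if method != "kmer" and normalize_bins:
            Xf = X * bin_variance_scales(X[tr])[None, :]
        if method == "krr":
            SQ_f = squared_euclidean(Xf, Xf)
        else:
            SQ_f = SQ
        engine = _MethodEngine(method, Xf, SQ_f)

        if method == "rr" or gamma_scale == "none":
            fold_gammas = gamma_grid
        elif gamma_scale == "median":
            block = SQ_f[np.ix_(tr, tr)]
            med = float(np.median(block[block > 0])) if np.any(block > 0) else 1.0
            fold_gammas = [g / med for g in gamma_grid]
        else:
            raise ValueError(f"unknown gamma_scale {gamma_scale!r}")

        splits = _inner_splits(cohort, tr, fold_plan.mode, inner_k, seed + f_num)
        best = None  # (mae, alpha, gamma)
        for alpha in alphas:
            for gamma in fold_gammas:
                maes = []
                for itr, ite in splits:
                    p = engine.fit_predict(itr, ite, y_fit[itr], alpha, gamma)
                    maes.append(float(np.abs(back(p) - y[ite]).mean()))
                mean_mae = float(np.mean(maes))
                if best is None or mean_mae < best[0]:
                    best = (mean_mae, alpha, gamma)
        _, alpha_sel, gamma_sel = best

        p_test = back(engine.fit_predict(tr, te, y_fit[tr], alpha_sel, gamma_sel))
        preds[te] = p_test
        fold_labels[te] = f_num

        if do_bias_correct:
            # Out-of-sample training predictions at the selected pair.
            train_oos = np.full(cohort.n_subjects, np.nan)
            for itr, ite in splits:
                train_oos[ite] = back(
                    engine.fit_predict(itr, ite, y_fit[itr], alpha_sel, gamma_sel)
                )
            have = tr[np.isfinite(train_oos[tr])]
            preds_corr[te] = bias_correct(y[have], train_oos[have], y[te], p_test)

        fold_scores = score(y[te], p_test) if te.size >= 2 else {"r2": float("nan"),
                                                                 "mae": float(np.abs(y[te] - p_test).mean())}
        per_fold.append(
            {
                "fold": f_num,
                "test_sites": list(fold.test_sites),
                "n_test": int(te.size),
                "alpha": float(alpha_sel),
                "gamma": float(gamma_sel),
                "inner_mae": best[0],
                **fold_scores,
            }
        )

    covered = fold_labels >= 0
    df = cohort.meta.loc[covered, ["subject_id", "site", "sex", "age"]].copy()
    df["fold"] = fold_labels[covered]
    df["y_pred"] = preds[covered]
    if do_bias_correct:
        df["y_pred_corrected"] = preds_corr[covered]
    df["delta"] = compute_delta(df["age"].to_numpy(), df["y_pred"].to_numpy())

    pooled = score(df["age"].to_numpy(), df["y_pred"].to_numpy())
    result = EvaluationResult(
        method=method,
        channel=channel,
        predictions=df.reset_index(drop=True),
        r2=pooled["r2"],
        mae=pooled["mae"],
        per_fold=per_fold,
        options={
            "fold_mode": fold_plan.mode,
            "log_space": log_space,
            "bias_correct": do_bias_correct,
            "normalize_bins": normalize_bins,
            "mmd_mode": mmd_mode,
            "seed": seed,
        },
    )
    if do_bias_correct:
        sc = score(df["age"].to_numpy(), df["y_pred_corrected"].to_numpy())
        result.r2_corrected, result.mae_corrected = sc["r2"], sc["mae"]
    if log_space:
        sc = score(np.log(df["age"].to_numpy()), np.log(df["y_pred"].to_numpy()))
        result.r2_log, result.mae_log = sc["r2"], sc["mae"]
    return result


def subgroup_eval(
    result: EvaluationResult, grouping: str
) -> dict[str, dict[str, float]]:
    """Recompute pooled scores within each subgroup (sex or site).

    Uses the same out-of-sample predictions — no refitting.  Groups with
    fewer than 3 subjects are skipped with a warning.
    """
    if grouping not in ("sex", "site"):
        raise KeyError(f"unknown grouping {grouping!r} (use 'sex' or 'site')")
    out: dict[str, dict[str, float]] = {}
    for label, sub in result.predictions.groupby(grouping, sort=False):
        if len(sub) < 3:
            warnings.warn(
                f"{grouping}={label!r} has {len(sub)} subject(s); skipped",
                stacklevel=2,
            )
            continue
        sc = score(sub["age"].to_numpy(), sub["y_pred"].to_numpy())
        sc["n"] = int(len(sub))
        out[str(label)] = sc
    return out
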