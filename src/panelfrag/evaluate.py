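"""Penalized multinomial classification with repeated nested cross-validation.

The evaluation protocol, applied identically to every feature table so their
scores are directly comparable:

* stratified 10-fold outer cross-validation, repeated 25 times with
  different seeds; for a given repeat the fold assignment is computed once
  and shared across all metrics;
* per outer training fold, hyperparameters (elastic-net mixing alpha in
  [0, 1] and penalty strength lambda on a log scale) are chosen from a
  Latin-hypercube sample of 10 candidate pairs by nested 5-fold inner CV,
  maximizing mean one-vs-rest AUROC (macro-averaged over classes; ties break
  toward smaller lambda, then smaller alpha);
* minority classes are up-sampled with replacement to the majority count,
  inside training data only;
* the winning candidate is refit on the whole outer training fold and scored
  on the held-out fold; out-of-fold class probabilities are pooled per repeat
  and reduced to a one-vs-rest AUROC per phenotype.

The classifier minimizes the glmnet objective
``-(1/N) log-likelihood + lambda * ((1-alpha)/2 * ||b||^2 + alpha * ||b||_1)``
with unpenalized intercepts, via scikit-learn's saga solver with
``C = 1 / (N * lambda)``.  Feature medians (imputation) and z-scoring
statistics are estimated on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .fragments import ConfigError
from .metrics import FeatureTable
from .mixing import assign_fraction_bin

import warnings

__all__ = [
    "CVConfig",
    "HyperParams",
    "make_folds",
    "latin_hypercube_hyperparams",
    "upsample_classes",
    "fit_penalized_multinomial",
    "nested_cv_select",
    "one_vs_rest_auroc",
    "macro_ovr_auroc",
    "run_repeated_cv",
    "run_mixture_evaluation",
    "summarize",
    "median_delta",
]


@dataclass
class CVConfig:
    """Protocol parameters for the repeated nested-CV evaluation."""

    outer_folds: int = 10
    inner_folds: int = 5
    n_hyper: int = 10
    n_repeats: int = 25
    upsample: bool = True
    alpha_range: tuple[float, float] = (0.0, 1.0)
    lambda_range: tuple[float, float] = (1e-4, 10.0)
    master_seed: int = 0
    max_iter: int = 200
    tol: float = 1e-3
    # coarser solver settings while ranking candidates in the inner CV; the
    # winning candidate is refit at full precision
    select_max_iter: int = 80
    select_tol: float = 1e-2

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ConfigError("fold counts must be >= 2")
        if self.n_hyper < 1 or self.n_repeats < 1:
            raise ConfigError("n_hyper and n_repeats must be >= 1")
        if not (0.0 <= self.alpha_range[0] < self.alpha_range[1] <= 1.0):
            raise ConfigError("alpha_range must be an interval within [0, 1]")
        if not (0.0 < self.lambda_range[0] < self.lambda_range[1]):
            raise ConfigError("lambda_range must be a positive interval")


@dataclass(frozen=True)
class HyperParams:
    """Elastic-net mixing (alpha: 0=ridge, 1=lasso) and strength (lambda)."""

    alpha: float
    lambda_: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha {self.alpha} outside [0, 1]")
        if self.lambda_ <= 0:
            raise ConfigError(f"lambda {self.lambda_} must be positive")


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0]) % (2**31)


def make_folds(labels: Sequence, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (array of fold indices), deterministic.

    When a class has fewer members than ``k`` stratification degrades
    gracefully to a plain shuffled partition (with a warning) rather than
    failing.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ConfigError(f"need at least 2 folds, got {k}")
    if k > len(y):
        raise ConfigError(f"{k} folds for {len(y)} samples")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        warnings.warn(
            f"class with {counts.min()} members < {k} folds; "
            "falling back to unstratified folds"
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=np.int64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for f, (_, test_idx) in enumerate(splitter.split(np.zeros((len(y), 1)), y)):
            folds[test_idx] = f
    return folds


def latin_hypercube_hyperparams(
    n: int,
    alpha_range: tuple[float, float] = (0.0, 1.0),
    lambda_range: tuple[float, float] = (1e-4, 10.0),
    seed: int = 0,
) -> list[HyperParams]:
    """Latin-hypercube sample of (alpha, lambda) candidate pairs.

    Each axis is split into ``n`` equal-probability strata holding exactly one
    point; lambda is stratified on the log scale.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if not (0.0 <= alpha_range[0] <= alpha_range[1] <= 1.0):
        raise ConfigError("invalid alpha_range")
    if not (0.0 < lambda_range[0] <= lambda_range[1]):
        raise ConfigError("invalid lambda_range")
    sampler = qmc.LatinHypercube(d=2, rng=np.random.default_rng(seed))
    u = sampler.random(n)
    alpha = alpha_range[0] + u[:, 0] * (alpha_range[1] - alpha_range[0])
    log_lo, log_hi = np.log(lambda_range[0]), np.log(lambda_range[1])
    lam = np.exp(log_lo + u[:, 1] * (log_hi - log_lo))
    return [HyperParams(float(a), float(l)) for a, l in zip(alpha, lam)]


def upsample_classes(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Resample every minority class with replacement to the majority count.

    Original rows are always kept; only the deficit is drawn.  Applied to
    training folds only — never to held-out data.
    """
    idx = _upsample_indices(np.asarray(y), seed)
    return np.asarray(X)[idx], np.asarray(y)[idx]


def _upsample_indices(y: np.ndarray, seed: int) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    if (counts == 0).any() or len(classes) == 0:
        raise ConfigError("empty class in training data")
    target = counts.max()
    rng = np.random.default_rng(seed)
    parts = [np.arange(len(y))]
    for cls, cnt in zip(classes, counts):
        if cnt < target:
            members = np.flatnonzero(y == cls)
            parts.append(rng.choice(members, size=target - cnt, replace=True))
    return np.concatenate(parts)


def fit_penalized_multinomial(
    X: np.ndarray,
    y: np.ndarray,
    params: HyperParams,
    max_iter: int = 200,
    tol: float = 1e-3,
    seed: int = 0,
) -> LogisticRegression:
    """Fit the elastic-net multinomial model on standardized features.

    ``X`` must already be standardized per feature (training statistics
    only).  Returns a fitted scikit-learn estimator exposing
    ``predict_proba``; intercepts are unpenalized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ConfigError("non-finite values in feature matrix")
    if len(np.unique(y)) < 2:
        raise ConfigError("need at least two classes")
    # elastic net via saga: l1_ratio mixes L1/L2, C scales the whole penalty
    model = LogisticRegression(
        solver="saga",
        l1_ratio=params.alpha,
        C=1.0 / (len(y) * params.lambda_),
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def one_vs_rest_auroc(scores: Sequence[float], positives: Sequence[bool]) -> float:
    """Probability that a random positive outscores a random negative.

    Mann-Whitney form with ties counting one half.  Returns NaN when either
    class is absent (undefined AUROC, reported as missing).
    """
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(positives, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def macro_ovr_auroc(
    proba: np.ndarray, y: np.ndarray, classes: Sequence
) -> float:
    """Mean one-vs-rest AUROC over the classes present in ``y``."""
    vals = []
    for ci, cls in enumerate(classes):
        a = one_vs_rest_auroc(proba[:, ci], np.asarray(y) == cls)
        if not np.isnan(a):
            vals.append(a)
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# fold-level machinery
# ---------------------------------------------------------------------------

class _FoldModel:
    """Imputation + standardization + classifier fit on one training fold.

    All statistics come from the training rows passed to :meth:`fit`; the
    transform is then applied unchanged to any rows it scores.
    """

    def __init__(
        self, params: HyperParams, config: CVConfig, seed: int, coarse: bool = False
    ):
        self.params = params
        self.config = config
        self.seed = seed
        self.coarse = coarse

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_FoldModel":
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            med = np.nanmedian(X, axis=0)
        self.medians_ = np.nan_to_num(med, nan=0.0)
        Xf = np.where(np.isnan(X), self.medians_, X)
        self.means_ = Xf.mean(axis=0)
        sd = Xf.std(axis=0)
        sd[sd == 0] = 1.0
        self.sds_ = sd
        Z = (Xf - self.means_) / self.sds_
        yt = np.asarray(y)
        if self.config.upsample:
            Z, yt = upsample_classes(Z, yt, seed=self.seed)
        self.model_ = fit_penalized_multinomial(
            Z,
            yt,
            self.params,
            max_iter=self.config.select_max_iter if self.coarse else self.config.max_iter,
            tol=self.config.select_tol if self.coarse else self.config.tol,
            seed=self.seed,
        )
        self.classes_ = self.model_.classes_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xf = np.where(np.isnan(X), self.medians_, X)
        return (Xf - self.means_) / self.sds_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict_proba(self.transform(X))


def nested_cv_select(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[HyperParams],
    inner_k: int = 5,
    seed: int = 0,
    config: CVConfig | None = None,
) -> HyperParams:
    """Choose the candidate maximizing mean inner-fold macro OVR AUROC.

    Ties break deterministically toward smaller lambda, then smaller alpha.
    A single candidate is returned unconditionally.
    """
    if not candidates:
        raise ConfigError("no hyperparameter candidates")
    if len(candidates) == 1:
        return candidates[0]
    config = config or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = make_folds(y, min(inner_k, len(y)), seed)
    classes = np.unique(y)
    scores = []
    for ci, params in enumerate(candidates):
        fold_scores = []
        for f in np.unique(folds):
            tr, te = folds != f, folds == f
            if len(np.unique(y[tr])) < 2:
                continue
            fm = _FoldModel(params, config, seed=_derive_seed(seed, ci, int(f)), coarse=True)
            fm.fit(X[tr], y[tr])
            proba = fm.predict_proba(X[te])
            aligned = np.zeros((int(te.sum()), len(classes)))
            for k, cls in enumerate(classes):
                hit = np.flatnonzero(fm.classes_ == cls)
                if hit.size:
                    aligned[:, k] = proba[:, hit[0]]
            a = macro_ovr_auroc(aligned, y[te], classes)
            if not np.isnan(a):
                fold_scores.append(a)
        scores.append(np.mean(fold_scores) if fold_scores else float("-inf"))
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-scores[i], candidates[i].lambda_, candidates[i].alpha),
    )
    return candidates[order[0]]


def _train_one_fold(
    X: np.ndarray,
    y: np.ndarray,
    train_mask: np.ndarray,
    candidates: Sequence[HyperParams],
    config: CVConfig,
    seed: int,
) -> _FoldModel:
    """Hyperparameter selection + refit using only the training rows."""
    Xtr, ytr = X[train_mask], np.asarray(y)[train_mask]
    params = nested_cv_select(
        Xtr, ytr, candidates, inner_k=config.inner_folds, seed=seed, config=config
    )
    return _FoldModel(params, config, seed=_derive_seed(seed, 999)).fit(Xtr, ytr)


# ---------------------------------------------------------------------------
# repeated CV over metric tables
# ---------------------------------------------------------------------------

def _check_alignment(tables: Mapping[str, FeatureTable]) -> pd.Series:
    labels = None
    for name, t in tables.items():
        if labels is None:
            labels = t.labels
        elif not t.labels.index.equals(labels.index) or not (
            t.labels.values == labels.values
        ).all():
            raise ConfigError(f"table {name} misaligned with the others")
    if labels is None:
        raise ConfigError("no feature tables given")
    return labels


def run_repeated_cv(
    tables: Mapping[str, FeatureTable], config: CVConfig | None = None
) -> pd.DataFrame:
    """Repeated nested-CV evaluation of every feature table.

    Returns one row per (metric, phenotype, repeat) with the pooled
    out-of-fold one-vs-rest AUROC.  Within a repeat the outer fold assignment
    is shared by all tables, so metrics are compared on identical splits.
    """
    config = config or CVConfig()
    labels = _check_alignment(tables)
    y = labels.to_numpy()
    classes = np.unique(y)
    metric_order = sorted(tables)
    rows = []
    for r in range(config.n_repeats):
        fold_seed = _derive_seed(config.master_seed, r, 1)
        lhs_seed = _derive_seed(config.master_seed, r, 2)
        fit_seed = _derive_seed(config.master_seed, r, 3)
        folds = make_folds(y, config.outer_folds, fold_seed)
        candidates = latin_hypercube_hyperparams(
            config.n_hyper, config.alpha_range, config.lambda_range, lhs_seed
        )
        for mi, metric in enumerate(metric_order):
            X = tables[metric].values.to_numpy(dtype=float)
            oof = np.full((len(y), len(classes)), np.nan)
            for f in np.unique(folds):
                tr = folds != f
                fm = _train_one_fold(
                    X, y, tr, candidates, config, seed=_derive_seed(fit_seed, mi, int(f))
                )
                proba = fm.predict_proba(X[~tr])
                for k, cls in enumerate(classes):
                    hit = np.flatnonzero(fm.classes_ == cls)
                    oof[~tr, k] = proba[:, hit[0]] if hit.size else 0.0
            for k, cls in enumerate(classes):
                rows.append(
                    {
                        "metric": metric,
                        "phenotype": cls,
                        "repeat": r,
                        "auroc": one_vs_rest_auroc(oof[:, k], y == cls),
                    }
                )
    return pd.DataFrame(rows)


def run_mixture_evaluation(
    train_table: FeatureTable,
    val_table: FeatureTable,
    val_fractions: pd.Series,
    config: CVConfig | None = None,
    positive_label: str = "cancer",
) -> pd.DataFrame:
    """Train on mixed training samples, score held-out validation mixtures,
    and report healthy-vs-cancer AUROC per calculated-fraction bin.

    ``val_fractions`` maps validation sample id to its calculated ctDNA
    fraction (0 for healthy-healthy controls).  Per bin, positives are the
    cancer mixtures falling in the bin and negatives are all validation
    controls; ``bin == "all"`` pools every validation mixture.  Repeated
    ``n_repeats`` times with fresh hyperparameter draws and fit seeds.
    """
    config = config or CVConfig()
    Xtr = train_table.values.to_numpy(dtype=float)
    ytr = train_table.labels.to_numpy()
    if set(val_table.values.columns) != set(train_table.values.columns):
        raise ConfigError("train/validation feature columns differ")
    Xval = val_table.values[train_table.values.columns].to_numpy(dtype=float)
    yval = val_table.labels.to_numpy()
    frac = val_fractions.reindex(val_table.values.index)
    if frac.isna().any():
        raise ConfigError("missing calculated fractions for validation samples")
    frac = frac.to_numpy(dtype=float)
    is_cancer = yval == positive_label
    bins = np.array(
        [
            assign_fraction_bin(f) if f > 0 else ""
            for f in frac
        ]
    )
    rows = []
    for r in range(config.n_repeats):
        lhs_seed = _derive_seed(config.master_seed, r, 12)
        fit_seed = _derive_seed(config.master_seed, r, 13)
        candidates = latin_hypercube_hyperparams(
            config.n_hyper, config.alpha_range, config.lambda_range, lhs_seed
        )
        fm = _train_one_fold(
            Xtr, ytr, np.ones(len(ytr), dtype=bool), candidates, config, seed=fit_seed
        )
        proba = fm.predict_proba(Xval)
        pi = np.flatnonzero(fm.classes_ == positive_label)[0]
        scores = proba[:, pi]
        rows.append(
            {
                "repeat": r,
                "fraction_bin": "all",
                "auroc": one_vs_rest_auroc(scores, is_cancer),
                "n_pos": int(is_cancer.sum()),
            }
        )
        for label in _present_bins(bins):
            in_bin = is_cancer & (bins == label)
            use = in_bin | ~is_cancer
            rows.append(
                {
                    "repeat": r,
                    "fraction_bin": label,
                    "auroc": one_vs_rest_auroc(scores[use], in_bin[use]),
                    "n_pos": int(in_bin.sum()),
                }
            )
    return pd.DataFrame(rows)


def _present_bins(bins: np.ndarray) -> list[str]:
    from .mixing import FRACTION_BIN_LABELS

    return [b for b in FRACTION_BIN_LABELS if (bins == b).any()]


def summarize(
    results: pd.DataFrame, by: Sequence[str] = ("metric", "phenotype")
) -> pd.DataFrame:
    """Median AUROC over repeats, grouped by the given keys."""
    by = [c for c in by if c in results.columns]
    return (
        results.groupby(list(by), observed=True)["auroc"]
        .median()
        .rename("median_auroc")
        .reset_index()
    )


def median_delta(
    full: pd.DataFrame,
    subset: pd.DataFrame,
    by: Sequence[str] = ("metric", "phenotype"),
) -> pd.DataFrame:
    """Median AUROC difference (subset minus full panel) per group."""
    a = summarize(full, by).rename(columns={"median_auroc": "full"})
    b = summarize(subset, by).rename(columns={"median_auroc": "subset"})
    out = a.merge(b, on=list(by), how="inner")
    out["delta"] = out["subset"] - out["full"]
    return out
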