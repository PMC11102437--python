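"""Nested cross-validated decoding and descriptive feature statistics.

The harness evaluates how well trial-wise features (sDM variants, Gram
matrices, or band powers) predict trial labels or continuous targets.
Hyperparameters — the SVM cost or the ridge penalty, and the DMD rank —
are tuned strictly inside each outer training fold by an inner
cross-validation, so reported scores are free of selection leakage.
Classification is scored by balanced accuracy (mean per-class recall)
with deterministic oversampling of minority classes at training time;
regression by Fisher-z-averaged Pearson correlations per target
dimension.

Descriptive statistics mirror the standard characterizations of a new
feature type: one-way ANOVA F maps (class selectivity per feature
component), trial-to-trial reproducibility (Fisher-z mean correlation
across same-class trial pairs), and the correlation profile between
per-channel features and the PSD at each frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .data import TrialSet
from .dmd import DMD
from .exceptions import InvalidInputError
from .features import (BandSpec, band_filtered_sdm, band_power,
                       projection_kernel, psd, sdm_features)

__all__ = [
    "CVScheme",
    "ModelSpec",
    "FeaturePipeline",
    "DecodingResult",
    "oversample_balance",
    "balanced_accuracy",
    "nested_cv_classify",
    "nested_cv_regress",
    "reproducibility",
    "anova_f_map",
    "feature_psd_correlation",
    "fisher_z",
    "kfold_splits",
    "FEATURE_KINDS",
    "MODEL_KINDS",
]

FEATURE_KINDS = ("sndm", "sedm", "sndm+sedm", "sdm", "band-sndm",
                 "band-sedm", "band-filtered", "high-gamma-power")
MODEL_KINDS = ("kernel-svm", "linear-svm", "logistic-l1", "ridge")

DEFAULT_COST_GRID = tuple(10.0 ** k for k in range(-1, 9))      # 10^-1 .. 10^8
DEFAULT_LAMBDA_GRID = tuple(10.0 ** k for k in range(-8, 9))    # 10^-8 .. 10^8


@dataclass(frozen=True)
class CVScheme:
    """Nested cross-validation layout.

    Defaults: 10-fold outer CV repeated 10 times, each outer training set
    tuned by 10-fold inner CV repeated 10 times, stratified random splits
    that minimize per-fold class imbalance.  ``split_mode='sequential-blocks'``
    divides the trial sequence into contiguous blocks instead (for
    time-series targets); block splits are deterministic, so repeats
    collapse to one.
    """

    n_outer: int = 10
    outer_repeats: int = 10
    n_inner: int = 10
    inner_repeats: int = 10
    stratified: bool = True
    split_mode: str = "stratified"
    seed: int = 0

    def __post_init__(self):
        if self.n_outer < 2 or self.n_inner < 2:
            raise InvalidInputError("need at least 2 folds")
        if self.outer_repeats < 1 or self.inner_repeats < 1:
            raise InvalidInputError("repeats must be positive")
        if self.split_mode not in ("stratified", "sequential-blocks"):
            raise InvalidInputError(f"unknown split mode {self.split_mode!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Decoder family and hyperparameter grids.

    ``cost_grid`` follows the conventional 10^-1..10^8 ladder for SVM /
    logistic cost C; ``lambda_grid`` the 10^-8..10^8 ladder (17 values)
    for the ridge penalty; ``rank_grid`` defaults to
    {25, 50, 100, 200, 300} clipped to the data plus the maximum
    available rank.
    """

    kind: str = "linear-svm"
    cost_grid: tuple = DEFAULT_COST_GRID
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    rank_grid: tuple = None

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise InvalidInputError(
                f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}"
            )
        for name in ("cost_grid", "lambda_grid"):
            g = tuple(float(v) for v in getattr(self, name))
            if len(g) == 0 or list(g) != sorted(g):
                raise InvalidInputError(f"{name} must be nonempty and ascending")
            object.__setattr__(self, name, g)
        if self.rank_grid is not None:
            g = tuple(int(v) for v in self.rank_grid)
            if len(g) == 0 or list(g) != sorted(g) or g[0] < 1:
                raise InvalidInputError("rank_grid must be nonempty, ascending, positive")
            object.__setattr__(self, "rank_grid", g)


def default_rank_grid(max_rank: int) -> tuple:
    grid = [r for r in (25, 50, 100, 200, 300) if r < max_rank]
    grid.append(max_rank)
    return tuple(grid)


class FeaturePipeline:
    """Per-trial DMD feature extraction with rank as a tunable parameter.

    DMD (stacking + SVD) is fitted once per trial and cached; features for
    any requested rank are then derived cheaply, which is what makes
    rank a practical inner-CV hyperparameter.  All features are computed
    per trial with no cross-trial fitting, so precomputing them for the
    whole set introduces no train/test leakage.
    """

    def __init__(self, trialset: TrialSet, feature: str = "sndm",
                 bands: BandSpec | None = None,
                 high_gamma_band: tuple = (80.0, 150.0)):
        if feature not in FEATURE_KINDS:
            raise InvalidInputError(
                f"unknown feature kind {feature!r}; choose from {FEATURE_KINDS}"
            )
        self.trialset = trialset
        self.feature = feature
        self.bands = bands if isinstance(bands, BandSpec) else (
            BandSpec(tuple(bands)) if bands is not None else BandSpec())
        self.high_gamma_band = tuple(high_gamma_band)
        self._models = [DMD(t) for t in trialset.trials]
        self._results_cache: dict = {}
        self._feature_cache: dict = {}
        self._gram_cache: dict = {}
        self._power = None

    @property
    def n_trials(self) -> int:
        return self.trialset.n_trials

    @property
    def max_rank(self) -> int:
        return min(m.max_rank for m in self._models)

    def results(self, rank: int) -> list:
        """Normalized DMD results per trial at the given rank (cached)."""
        if rank not in self._results_cache:
            self._results_cache[rank] = [
                m.fit(rank=rank).normalize_modes() for m in self._models
            ]
        return self._results_cache[rank]

    def modes(self, rank: int) -> list:
        return [r.modes for r in self.results(rank)]

    def _trial_vector(self, res) -> np.ndarray:
        if self.feature in ("sndm", "sedm", "sndm+sedm", "sdm"):
            f = sdm_features(res.modes)
            if self.feature == "sndm":
                return f.sndm
            if self.feature == "sedm":
                return f.sedm
            if self.feature == "sndm+sedm":
                return np.concatenate([f.sndm, f.sedm])
            return f.vector
        # band-filtered variants
        parts = []
        for f in band_filtered_sdm(res, self.bands):
            if self.feature == "band-sndm":
                parts.append(f.sndm)
            elif self.feature == "band-sedm":
                parts.append(f.sedm)
            else:  # band-filtered: snDM + seDM per band, concatenated
                parts.append(np.concatenate([f.sndm, f.sedm]))
        return np.concatenate(parts)

    def features(self, rank: int) -> np.ndarray:
        """(N, D) feature matrix at the given rank (cached per rank)."""
        if self.feature == "high-gamma-power":
            if self._power is None:
                self._power = np.stack([
                    band_power(psd(t), self.high_gamma_band)
                    for t in self.trialset.trials
                ])
            return self._power
        if rank not in self._feature_cache:
            self._feature_cache[rank] = np.stack(
                [self._trial_vector(r) for r in self.results(rank)]
            )
        return self._feature_cache[rank]

    def gram(self, rank: int) -> np.ndarray:
        """(N, N) projection-kernel Gram matrix at the given rank."""
        if rank not in self._gram_cache:
            mats = self.modes(rank)
            n = len(mats)
            G = np.empty((n, n))
            for i in range(n):
                for j in range(i, n):
                    G[i, j] = G[j, i] = projection_kernel(mats[i], mats[j])
            self._gram_cache[rank] = G
        return self._gram_cache[rank]

    def data_for(self, model_kind: str, rank: int) -> np.ndarray:
        return self.gram(rank) if model_kind == "kernel-svm" else self.features(rank)


def oversample_balance(labels) -> np.ndarray:
    """Index multiset that balances class counts by deterministic cycling.

    All original indices are retained (in order); each minority class's
    indices are then repeated cyclically until every class reaches the
    count of the largest class.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InvalidInputError("labels are empty")
    classes, counts = np.unique(labels, return_counts=True)
    n_max = counts.max()
    extras = []
    for c, n_c in zip(classes, counts):
        if n_c < n_max:
            idx = np.flatnonzero(labels == c)
            extras.append(idx[np.arange(n_max - n_c) % n_c])
    if not extras:
        return np.arange(labels.size)
    return np.concatenate([np.arange(labels.size)] + extras)


def balanced_accuracy(truth, predicted) -> float:
    """Mean per-class recall."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise InvalidInputError("truth and predictions must have equal length")
    t_classes = set(np.unique(truth).tolist())
    if not set(np.unique(predicted).tolist()) <= t_classes:
        raise InvalidInputError("prediction contains a class unseen in truth")
    recalls = [
        np.mean(predicted[truth == c] == c) for c in sorted(t_classes)
    ]
    return float(np.mean(recalls))


def kfold_splits(labels, n_splits: int, stratified: bool = True,
                 mode: str = "stratified", seed: int = 0):
    """One repeat of k-fold splits over ``len(labels)`` trials.

    Returns a list of (train_idx, test_idx) pairs.  ``sequential-blocks``
    splits the trial order into contiguous blocks (deterministic,
    seed-free); otherwise shuffled (Stratified)KFold seeded by ``seed``.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if mode == "sequential-blocks":
        blocks = np.array_split(np.arange(n), n_splits)
        return [
            (np.concatenate([b for j, b in enumerate(blocks) if j != i]), blocks[i])
            for i in range(n_splits)
        ]
    if stratified:
        kf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        try:
            return [(tr, te) for tr, te in kf.split(np.zeros(n), labels)]
        except ValueError as exc:
            raise InvalidInputError(
                f"cannot build {n_splits} stratified folds: {exc}"
            ) from exc
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(np.zeros(n))]


@dataclass
class DecodingResult:
    """Nested-CV decoding outcome.

    ``scores`` holds one balanced accuracy (classification) or one mean
    Fisher-z correlation (regression) per (outer repeat, outer fold);
    ``mean_score`` averages them.  ``fold_params`` records the
    hyperparameters selected in each outer fold; ``fold_predictions``
    the test indices and predicted values per fold.
    """

    kind: str
    scores: np.ndarray
    fold_params: list
    fold_predictions: list = field(default_factory=list, repr=False)
    mean_correlation: float = None
    model: ModelSpec = None
    scheme: CVScheme = None

    @property
    def mean_score(self) -> float:
        return float(np.nanmean(self.scores))

    def selected(self, param: str) -> list:
        return [p[param] for p in self.fold_params if param in p]

    def summary(self) -> str:
        lines = [
            f"Nested-CV {self.kind} result",
            f"  outer repeats x folds: {self.scores.shape[0]} x {self.scores.shape[1]}",
        ]
        if self.kind == "classification":
            lines.append(f"  mean balanced accuracy: {self.mean_score:.4f}")
        else:
            lines.append(f"  mean Fisher-z correlation: {self.mean_score:.4f}")
            lines.append(f"  mean correlation (tanh of mean z): {self.mean_correlation:.4f}")
        sel = pd.DataFrame(self.fold_params)
        if not sel.empty:
            counts = {
                c: sel[c].value_counts().to_dict()
                for c in sel.columns if c not in ("repeat", "fold")
            }
            lines.append(f"  selected hyperparameters (fold counts): {counts}")
        return "\n".join(lines)


# libsvm can spin near-indefinitely at very large costs on non-separable
# data; a generous iteration cap bounds the worst case without touching
# fits that converge (they stop far earlier).
_SVC_MAX_ITER = 100_000


def _make_classifier(kind: str, cost: float):
    if kind == "kernel-svm":
        return SVC(C=cost, kernel="precomputed", max_iter=_SVC_MAX_ITER)
    if kind == "linear-svm":
        return SVC(C=cost, kernel="linear", max_iter=_SVC_MAX_ITER)
    if kind == "logistic-l1":
        # liblinear is binary-only; one-vs-rest reproduces its classic
        # multiclass behaviour
        return OneVsRestClassifier(
            LogisticRegression(l1_ratio=1.0, C=cost, solver="liblinear")
        )
    raise InvalidInputError(f"{kind!r} is not a classification model")


def _fit_predict_clf(kind, data, labels, tr_idx, te_idx, cost):
    os_idx = tr_idx[oversample_balance(labels[tr_idx])]
    clf = _make_classifier(kind, cost)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        if kind == "kernel-svm":
            clf.fit(data[np.ix_(os_idx, os_idx)], labels[os_idx])
            return clf.predict(data[np.ix_(te_idx, os_idx)])
        clf.fit(data[os_idx], labels[os_idx])
        return clf.predict(data[te_idx])


def _check_folds(labels, splits):
    for tr, te in splits:
        if len(np.unique(labels[tr])) < len(np.unique(labels)):
            raise InvalidInputError(
                "degenerate fold: a class is absent from a training split; "
                "use fewer folds or more trials"
            )


def nested_cv_classify(pipeline: FeaturePipeline, model: ModelSpec = None,
                       scheme: CVScheme = None) -> DecodingResult:
    """Nested cross-validated classification.

    For every outer fold, the inner (repeated) CV scores each
    (rank, cost) pair by mean balanced accuracy on the inner validation
    folds; the best pair (ties to the smallest rank, then smallest cost)
    is refit on the full outer training set with minority oversampling
    and scored on the held-out outer fold.
    """
    model = model or ModelSpec()
    scheme = scheme or CVScheme()
    labels = pipeline.trialset.labels
    if labels is None:
        raise InvalidInputError("trial set has no labels")
    if model.kind == "ridge":
        raise InvalidInputError("ridge is a regression model; use nested_cv_regress")
    rank_grid = model.rank_grid or default_rank_grid(pipeline.max_rank)
    if max(rank_grid) > pipeline.max_rank:
        raise InvalidInputError(
            f"rank grid exceeds available rank {pipeline.max_rank}"
        )

    scores = np.zeros((scheme.outer_repeats, scheme.n_outer))
    fold_params, fold_predictions = [], []
    for rep in range(scheme.outer_repeats):
        outer = kfold_splits(labels, scheme.n_outer, scheme.stratified,
                             scheme.split_mode, seed=scheme.seed + rep)
        _check_folds(labels, outer)
        for fold, (tr, te) in enumerate(outer):
            best = None  # (acc, rank, cost)
            for rank in rank_grid:
                data = pipeline.data_for(model.kind, rank)
                for cost in model.cost_grid:
                    accs = []
                    for irep in range(scheme.inner_repeats):
                        inner_seed = scheme.seed + 9973 * (rep + 1) + 101 * fold + irep
                        inner = kfold_splits(labels[tr], scheme.n_inner,
                                             scheme.stratified, scheme.split_mode,
                                             seed=inner_seed)
                        for itr, ite in inner:
                            pred = _fit_predict_clf(model.kind, data, labels,
                                                    tr[itr], tr[ite], cost)
                            accs.append(balanced_accuracy(labels[tr[ite]], pred))
                    acc = float(np.mean(accs))
                    if best is None or acc > best[0]:
                        best = (acc, rank, cost)
            _, rank, cost = best
            data = pipeline.data_for(model.kind, rank)
            pred = _fit_predict_clf(model.kind, data, labels, tr, te, cost)
            scores[rep, fold] = balanced_accuracy(labels[te], pred)
            fold_params.append({"repeat": rep, "fold": fold, "rank": rank, "cost": cost})
            fold_predictions.append({"repeat": rep, "fold": fold,
                                     "test_idx": te, "predicted": pred})
    return DecodingResult(kind="classification", scores=scores,
                          fold_params=fold_params,
                          fold_predictions=fold_predictions,
                          model=model, scheme=scheme)


def nested_cv_regress(pipeline: FeaturePipeline, model: ModelSpec = None,
                      scheme: CVScheme = None) -> DecodingResult:
    """Nested cross-validated ridge regression.

    Per outer fold and per target dimension, the inner CV selects
    (rank, lambda) minimizing mean squared error; predictions on the
    outer test fold are scored by the Pearson correlation with the true
    values, Fisher-z transformed, then averaged over folds and
    dimensions.  Constant target dimensions are skipped with a warning.
    """
    model = model or ModelSpec(kind="ridge")
    scheme = scheme or CVScheme()
    if model.kind != "ridge":
        raise InvalidInputError("nested_cv_regress supports the ridge model")
    targets = pipeline.trialset.targets
    if targets is None:
        raise InvalidInputError("trial set has no continuous targets")
    n, D = targets.shape
    rank_grid = model.rank_grid or default_rank_grid(pipeline.max_rank)

    repeats = 1 if scheme.split_mode == "sequential-blocks" else scheme.outer_repeats
    inner_repeats = 1 if scheme.split_mode == "sequential-blocks" else scheme.inner_repeats
    scores = np.full((repeats, scheme.n_outer), np.nan)
    fold_params, fold_predictions = [], []
    for rep in range(repeats):
        outer = kfold_splits(np.zeros(n), scheme.n_outer, stratified=False,
                             mode=scheme.split_mode, seed=scheme.seed + rep)
        for fold, (tr, te) in enumerate(outer):
            zs = []
            for d in range(D):
                y = targets[:, d]
                if np.ptp(y[tr]) == 0:
                    warnings.warn(f"target dimension {d} is constant on a "
                                  "training fold; skipped", RuntimeWarning)
                    continue
                best = None  # (mse, rank, lam)
                for rank in rank_grid:
                    F = pipeline.features(rank)
                    for lam in model.lambda_grid:
                        errs = []
                        for irep in range(inner_repeats):
                            inner_seed = scheme.seed + 9973 * (rep + 1) + 101 * fold + irep
                            inner = kfold_splits(np.zeros(len(tr)), scheme.n_inner,
                                                 stratified=False,
                                                 mode=scheme.split_mode,
                                                 seed=inner_seed)
                            for itr, ite in inner:
                                reg = Ridge(alpha=lam)
                                reg.fit(F[tr[itr]], y[tr[itr]])
                                err = np.mean((reg.predict(F[tr[ite]]) - y[tr[ite]]) ** 2)
                                errs.append(err)
                        mse = float(np.mean(errs))
                        if best is None or mse < best[0]:
                            best = (mse, rank, lam)
                _, rank, lam = best
                F = pipeline.features(rank)
                reg = Ridge(alpha=lam)
                reg.fit(F[tr], y[tr])
                pred = reg.predict(F[te])
                if np.ptp(pred) == 0 or np.ptp(y[te]) == 0:
                    warnings.warn(f"correlation undefined for dimension {d} on a "
                                  "test fold; skipped", RuntimeWarning)
                    continue
                r = float(np.corrcoef(y[te], pred)[0, 1])
                zs.append(fisher_z(r))
                fold_params.append({"repeat": rep, "fold": fold, "dim": d,
                                    "rank": rank, "lambda": lam})
                fold_predictions.append({"repeat": rep, "fold": fold, "dim": d,
                                         "test_idx": te, "predicted": pred})
            if zs:
                scores[rep, fold] = float(np.mean(zs))
    mean_z = float(np.nanmean(scores))
    return DecodingResult(kind="regression", scores=scores,
                          fold_params=fold_params,
                          fold_predictions=fold_predictions,
                          mean_correlation=float(np.tanh(mean_z)),
                          model=model, scheme=scheme)


def fisher_z(r, clip: float = 1.0 - 1e-12):
    """atanh with |r| clipped just below 1 to keep the transform finite."""
    return np.arctanh(np.clip(r, -clip, clip))


def reproducibility(features, labels) -> float:
    """Trial-to-trial reproducibility of a feature vector.

    Pearson correlation over feature components for every pair of trials
    sharing a label, Fisher-z transformed and averaged.  Pairs involving a
    zero-variance feature vector are skipped with a warning.
    """
    F = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if F.ndim != 2:
        raise InvalidInputError("features must be (n_trials, n_features)")
    if F.shape[0] != labels.shape[0]:
        raise InvalidInputError("labels length must match the trial count")
    centered = F - F.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zs = []
    n_skipped = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                if norms[i] == 0 or norms[j] == 0:
                    n_skipped += 1
                    continue
                r = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
                zs.append(fisher_z(r))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} pair(s) with zero-variance "
                      "features", RuntimeWarning)
    if not zs:
        raise InvalidInputError("no valid same-label trial pair")
    return float(np.mean(zs))


def anova_f_map(features, labels) -> np.ndarray:
    """One-way ANOVA F statistic per feature component.

    Classical between-/within-group mean-square ratio, vectorized over
    columns.  Components with zero within-group variance map to +inf
    (with a warning) when the group means differ, and to 0 when they do
    not.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    counts = np.array([np.count_nonzero(labels == g) for g in groups])
    if counts.min() < 2:
        raise InvalidInputError("need at least 2 samples per group")
    grand = F.mean(axis=0)
    ssb = np.zeros(F.shape[1])
    ssw = np.zeros(F.shape[1])
    for g, n_g in zip(groups, counts):
        block = F[labels == g]
        m = block.mean(axis=0)
        ssb += n_g * (m - grand) ** 2
        ssw += ((block - m) ** 2).sum(axis=0)
    msb = ssb / (len(groups) - 1)
    msw = ssw / (F.shape[0] - len(groups))
    out = np.empty(F.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = msb / msw
    degenerate = msw == 0
    if np.any(degenerate):
        out[degenerate & (msb > 0)] = np.inf
        out[degenerate & (msb == 0)] = 0.0
        if np.any(degenerate & (msb > 0)):
            warnings.warn("zero within-group variance: F reported as +inf",
                          RuntimeWarning)
    return out


def feature_psd_correlation(sndm, psd_values) -> np.ndarray:
    """Correlation profile between per-channel features and the PSD.

    ``sndm`` is (n_trials, P); ``psd_values`` is (n_trials, P, F).  For
    every frequency bin, the Pearson correlation between the concatenated
    (trial, channel) feature values and PSD values is computed and
    Fisher-z transformed.  Bins with constant PSD are returned as NaN
    with a warning.
    """
    x = np.asarray(sndm, dtype=float).ravel()
    S = np.asarray(psd_values, dtype=float)
    if S.ndim != 3:
        raise InvalidInputError("psd_values must be (n_trials, P, F)")
    if S.shape[0] * S.shape[1] != x.size:
        raise InvalidInputError("snDM and PSD trial/channel layout mismatch")
    Y = S.reshape(-1, S.shape[2])
    xc = x - x.mean()
    xn = np.linalg.norm(xc)
    if xn == 0:
        raise InvalidInputError("snDM features are constant")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    yn = np.linalg.norm(Yc, axis=0)
    ok = yn > 0
    if not np.all(ok):
        warnings.warn(f"{np.count_nonzero(~ok)} constant PSD bin(s) skipped",
                      RuntimeWarning)
    z = np.full(Y.shape[1], np.nan)
    z[ok] = fisher_z((xc @ Yc[:, ok]) / (xn * yn[ok]))
    return z
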