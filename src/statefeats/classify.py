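"""Feature-table assembly, partition schemes, leakage-free preprocessing and
kernel classification with balanced accuracy.

Three cross-validation partition schemes are supported:

* ``within`` — one classifier per subject, k-fold over contiguous epoch
  blocks inside that subject;
* ``between`` — leave-one-subject-out (or grouped k-fold when fewer folds
  than subjects are requested); whole subjects are never split;
* ``across`` — every subject contributes a contiguous hold-out block to the
  test set of every fold (default: 10 rotations of a 90/10 split; a
  single-split 85/15 mode is available via ``holdout_fraction``).

Per fold, preprocessing is fitted on the training rows only and frozen:
(1) NaN -> train column mean; (2) robust scaling by train median/IQR;
(3) elementwise tanh; (4) PCA keeping the smallest number of components
reaching 90% cumulative explained variance (either one global PCA, or one
PCA per feature across its spatial-unit columns). The classifier is a
soft-margin SVM (RBF kernel, C = 10) with one-vs-one voting, ties broken by
summed decision values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import balanced_accuracy_score
from sklearn.svm import SVC

from . import aperiodic as ap
from .spectral import (
    FREQBANDS_NAMES,
    FULLFFT_NAMES,
    BandDefinition,
    average_spectrum,
    band_power_features,
    fullfft_features,
    power_spectrum,
)
from .synth import EpochedRecording
from .timefeats import TIMEFEATS_NAMES, compute_timefeats, compute_timefeats_banded

__all__ = [
    "FeatureTable",
    "FoldPlan",
    "PreprocessParams",
    "ClassifierConfig",
    "ClassificationResult",
    "assemble_feature_table",
    "build_folds",
    "fit_preprocessor",
    "apply_preprocessor",
    "balanced_accuracy",
    "run_classification",
]

FEATURE_SETS = ("TimeFeats", "FreqBands", "fullFFT")


@dataclass
class FeatureTable:
    """Observations x (feature x spatial-unit) matrix with annotations."""

    X: np.ndarray
    y: np.ndarray
    subject: np.ndarray
    epoch_order: np.ndarray
    column_meta: list[tuple[str, str]]  # (feature_name, spatial_unit)

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.subject) == len(self.epoch_order) == n):
            raise ValueError("X, y, subject, epoch_order must align on observations")
        if len(self.column_meta) != self.X.shape[1]:
            raise ValueError("column_meta must have one entry per column")

    @property
    def feature_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for f, _ in self.column_meta:
            seen.setdefault(f)
        return list(seen)

    def feature_blocks(self) -> dict[str, np.ndarray]:
        """Column indices per feature name (spatial-unit columns grouped)."""
        blocks: dict[str, list[int]] = {}
        for j, (f, _) in enumerate(self.column_meta):
            blocks.setdefault(f, []).append(j)
        return {f: np.asarray(ix) for f, ix in blocks.items()}

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{f}__{u}" for f, u in self.column_meta]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "epoch_order", self.epoch_order)
        df.insert(0, "state", self.y)
        df.insert(0, "subject", self.subject)
        return df


def assemble_feature_table(
    cohort: list[EpochedRecording],
    feature_set: str = "TimeFeats",
    band: BandDefinition | None = None,
    peak_cfg: ap.PeakDetectConfig = ap.PeakDetectConfig(),
) -> FeatureTable:
    """One row per epoch; columns ordered feature-major, spatial-unit-minor.

    For TimeFeats, oscillatory peaks are detected once per (subject, unit)
    on the spectrum averaged over all that unit's epochs, and reused for
    every epoch's masked aperiodic fit. NaNs from degenerate features are
    preserved for the imputation stage.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    fs = cohort[0].fs
    units = cohort[0].unit_names
    for rec in cohort:
        if rec.fs != fs or rec.unit_names != units:
            raise ValueError("all recordings must share fs and spatial units")

    if feature_set == "TimeFeats":
        feat_names = list(TIMEFEATS_NAMES)
    elif feature_set == "FreqBands":
        feat_names = list(FREQBANDS_NAMES)
    else:
        feat_names = list(FULLFFT_NAMES)

    rows, ys, subs, orders = [], [], [], []
    for rec in cohort:
        n_ep = rec.n_epochs
        per_unit: list[np.ndarray] = []
        for ui in range(len(units)):
            unit_epochs = rec.epochs[:, ui, :]
            if feature_set == "TimeFeats":
                avg = average_spectrum(unit_epochs, fs).restrict(*peak_cfg.fit_range)
                peaks = ap.detect_spectral_peaks(avg, peak_cfg)
                if band is None:
                    vals = np.stack(
                        [
                            compute_timefeats(e, fs, avg_peaks=peaks).as_array()
                            for e in unit_epochs
                        ]
                    )
                else:
                    vals = np.stack(
                        [
                            compute_timefeats_banded(e, fs, band, avg_peaks=peaks).as_array()
                            for e in unit_epochs
                        ]
                    )
            else:
                specs = [power_spectrum(e, fs) for e in unit_epochs]
                if feature_set == "FreqBands":
                    vals = np.stack([band_power_features(s) for s in specs])
                else:
                    vals = np.stack([fullfft_features(s) for s in specs])
            per_unit.append(vals)  # [n_ep, n_feat]
        # feature-major, unit-minor column order
        stacked = np.stack(per_unit, axis=2)  # [n_ep, n_feat, n_unit]
        rows.append(stacked.reshape(n_ep, -1))
        ys.append(rec.state_labels)
        subs.append(np.repeat(rec.subject_id, n_ep))
        orders.append(np.arange(n_ep))

    meta = [(f, u) for f in feat_names for u in units]
    return FeatureTable(
        X=np.concatenate(rows),
        y=np.concatenate(ys),
        subject=np.concatenate(subs),
        epoch_order=np.concatenate(orders),
        column_meta=meta,
    )


def select_classes(table: FeatureTable, classes: tuple[str, ...]) -> FeatureTable:
    """Restrict a table to a subset of states (e.g. EC/EO two-class runs)."""
    m = np.isin(table.y, classes)
    return FeatureTable(
        table.X[m], table.y[m], table.subject[m], table.epoch_order[m], table.column_meta
    )


# ------------------------------------------------------------------- folds


@dataclass
class FoldPlan:
    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train rows, test rows)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def _state_blocks(table: FeatureTable, subject) -> list[np.ndarray]:
    """Contiguous runs of identical state labels within one subject, in time order."""
    idx = np.flatnonzero(table.subject == subject)
    idx = idx[np.argsort(table.epoch_order[idx], kind="stable")]
    blocks: list[np.ndarray] = []
    start = 0
    y = table.y[idx]
    for i in range(1, len(idx) + 1):
        if i == len(idx) or y[i] != y[start]:
            blocks.append(idx[start:i])
            start = i
    return blocks


def _fold_chunks(blocks: list[np.ndarray], n_folds: int) -> list[np.ndarray]:
    """Test rows per fold: the k-th contiguous chunk of every state block.

    Chunking each condition block separately keeps test segments contiguous
    in recording time (the filter-leakage rationale) while guaranteeing that
    every fold's training set still contains every state.
    """
    per_block = [np.array_split(b, n_folds) for b in blocks]
    folds = []
    for k in range(n_folds):
        parts = [c[k] for c in per_block if c[k].size]
        if parts:
            folds.append(np.sort(np.concatenate(parts)))
    return folds


def build_folds(
    table: FeatureTable,
    scheme: str,
    n_folds: int = 10,
    holdout_fraction: float | None = None,
    seed: int = 0,
) -> FoldPlan:
    """Train/test partitions under the named scheme.

    within : one classifier per subject; k-fold where each fold's test set
        is a contiguous chunk of each of that subject's state blocks (one
        fold entry per subject x fold).
    between : leave-one-subject-out when ``n_folds >= n_subjects``, else a
        grouped k-fold in which subjects are never split.
    across : ``n_folds`` rotations; in each, every subject contributes the
        k-th contiguous chunk (~1/n_folds) of each of its state blocks to
        the test set (or the last ``holdout_fraction`` of each block for a
        single split, e.g. 0.15 for the 85/15 mode).
    """
    subjects = list(pd.unique(table.subject))
    all_rows = np.arange(table.X.shape[0])

    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if scheme == "within":
        for s in subjects:
            blocks = _state_blocks(table, s)
            rows = np.sort(np.concatenate(blocks))
            for test in _fold_chunks(blocks, n_folds):
                folds.append((np.setdiff1d(rows, test), test))
    elif scheme == "between":
        if len(subjects) < 2:
            raise ValueError("between scheme needs at least 2 subjects")
        if n_folds >= len(subjects):
            groups = [[s] for s in subjects]
        else:
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(subjects))
            groups = [[subjects[i] for i in g] for g in np.array_split(perm, n_folds)]
        for grp in groups:
            test = np.sort(np.flatnonzero(np.isin(table.subject, grp)))
            train = np.setdiff1d(all_rows, test)
            folds.append((train, test))
    elif scheme == "across":
        if len(subjects) < 2:
            raise ValueError("across scheme needs at least 2 subjects")
        if holdout_fraction is not None:
            # single split: last fraction of every (subject, state) block
            test_parts = []
            for s in subjects:
                for b in _state_blocks(table, s):
                    n_test = max(int(round(holdout_fraction * b.size)), 1)
                    if n_test >= b.size:
                        raise ValueError("holdout leaves an empty training set")
                    test_parts.append(b[-n_test:])
            test = np.sort(np.concatenate(test_parts))
            folds.append((np.setdiff1d(all_rows, test), test))
        else:
            per_subject = {s: _fold_chunks(_state_blocks(table, s), n_folds) for s in subjects}
            for k in range(n_folds):
                parts = [per_subject[s][k] for s in subjects if k < len(per_subject[s])]
                if not parts:  # fewer epochs per block than folds
                    continue
                test = np.sort(np.concatenate(parts))
                folds.append((np.setdiff1d(all_rows, test), test))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    for train, test in folds:
        if train.size == 0 or test.size == 0:
            raise ValueError("a fold has an empty train or test set")
    return FoldPlan(scheme, folds)


# --------------------------------------------------------------- preprocess


@dataclass
class PreprocessParams:
    """Frozen, train-only preprocessing parameters (pure function of train rows)."""

    col_means: np.ndarray
    medians: np.ndarray
    iqrs: np.ndarray
    kept_cols: np.ndarray  # all-NaN train columns are dropped
    pca: PCA | None
    per_feature_pcas: list[tuple[np.ndarray, PCA]] | None
    fitted_on: str = ""


def _impute_scale_tanh(
    X: np.ndarray, params: PreprocessParams
) -> np.ndarray:
    X = X[:, params.kept_cols].copy()
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = params.col_means[nan_c]
    X = (X - params.medians) / params.iqrs
    return np.tanh(X)


def fit_preprocessor(
    train_X: np.ndarray,
    variance_target: float = 0.90,
    pca_mode: str = "global",
    feature_blocks: dict[str, np.ndarray] | None = None,
    fitted_on: str = "",
) -> PreprocessParams:
    """Fit the imputation/robust-scaling/tanh/PCA chain on training rows only."""
    train_X = np.asarray(train_X, dtype=float)
    if train_X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")

    all_nan = np.all(np.isnan(train_X), axis=0)
    if all_nan.any():
        warnings.warn(
            f"dropping {int(all_nan.sum())} all-NaN training columns",
            RuntimeWarning,
            stacklevel=2,
        )
    kept = np.flatnonzero(~all_nan)
    Xk = train_X[:, kept]
    col_means = np.nanmean(Xk, axis=0)
    imputed = np.where(np.isnan(Xk), col_means, Xk)
    medians = np.median(imputed, axis=0)
    q75, q25 = np.percentile(imputed, [75, 25], axis=0)
    iqrs = q75 - q25
    iqrs[iqrs == 0] = 1.0  # constant columns: centered to zero, scale 1

    params = PreprocessParams(col_means, medians, iqrs, kept, None, None, fitted_on)
    Xt = _impute_scale_tanh(train_X, params)

    if pca_mode == "global":
        pca = PCA(n_components=_pca_ncomp(Xt, variance_target), svd_solver="full")
        pca.fit(Xt)
        params.pca = pca
    elif pca_mode == "per_feature":
        if feature_blocks is None:
            raise ValueError("per_feature mode needs feature_blocks")
        per = []
        # map original column indices to kept-column positions
        pos = {c: i for i, c in enumerate(kept)}
        for fname, cols in feature_blocks.items():
            cols_kept = np.asarray([pos[c] for c in cols if c in pos])
            if cols_kept.size == 0:
                continue
            block = Xt[:, cols_kept]
            pca = PCA(n_components=_pca_ncomp(block, variance_target), svd_solver="full")
            pca.fit(block)
            per.append((cols_kept, pca))
        params.per_feature_pcas = per
    else:
        raise ValueError(f"unknown pca_mode {pca_mode!r}")
    return params


def _pca_ncomp(X: np.ndarray, variance_target: float) -> int:
    """Smallest k whose cumulative explained-variance ratio reaches target."""
    max_k = min(X.shape[0], X.shape[1])
    probe = PCA(n_components=max_k, svd_solver="full").fit(X)
    csum = np.cumsum(probe.explained_variance_ratio_)
    return int(np.searchsorted(csum, variance_target - 1e-12) + 1)


def apply_preprocessor(params: PreprocessParams, X: np.ndarray) -> np.ndarray:
    """Apply the frozen chain to any row set (train or test)."""
    Xt = _impute_scale_tanh(np.asarray(X, dtype=float), params)
    if params.pca is not None:
        return params.pca.transform(Xt)
    assert params.per_feature_pcas is not None
    blocks = [pca.transform(Xt[:, cols]) for cols, pca in params.per_feature_pcas]
    return np.concatenate(blocks, axis=1)


# ------------------------------------------------------------- classifier


@dataclass(frozen=True)
class ClassifierConfig:
    kernel: str = "rbf"
    C: float = 10.0
    variance_target: float = 0.90
    pca_mode: str = "global"  # "global" (within/between) or "per_feature" (across sets)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be rbf or linear")


def kernel_gamma(X: np.ndarray) -> float:
    """RBF width rule: gamma = 1 / (n_columns * mean column variance)."""
    v = float(np.mean(np.var(X, axis=0)))
    if v <= 0:
        v = 1.0
    return 1.0 / (X.shape[1] * v)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Unweighted mean of per-class recall over classes present in y_true."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("labels must be non-empty and of equal length")
    with warnings.catch_warnings():
        # predictions of classes absent from y_true are legal here (e.g. a
        # between-subjects fold whose test subject lacks a state)
        warnings.filterwarnings("ignore", message="y_pred contains classes not in y_true")
        return float(balanced_accuracy_score(y_true, y_pred))


def _ovo_predict(clf: SVC, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """One-vs-one majority vote; ties broken by summed decision values."""
    if len(classes) == 2:
        return clf.predict(X)
    dec = clf.decision_function(X)  # ovo pairwise columns
    n_cls = len(classes)
    votes = np.zeros((X.shape[0], n_cls))
    sums = np.zeros((X.shape[0], n_cls))
    for k, (i, j) in enumerate(combinations(range(n_cls), 2)):
        d = dec[:, k]
        votes[:, i] += d > 0
        votes[:, j] += d <= 0
        sums[:, i] += d
        sums[:, j] -= d
    # lexicographic argmax: votes first, summed decision values as tie-break
    rank = votes + 1e-9 * np.tanh(sums)
    winner = np.argmax(rank, axis=1)
    return classes[winner]


@dataclass
class ClassificationResult:
    scheme: str
    fold_accuracies: list[float]
    pooled_accuracy: float
    per_fold_sizes: list[int]
    config: ClassifierConfig
    seed: int
    skipped_folds: int = 0
    y_true_pooled: np.ndarray | None = None
    y_pred_pooled: np.ndarray | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scheme": self.scheme,
                "fold": np.arange(len(self.fold_accuracies)),
                "balanced_accuracy": self.fold_accuracies,
                "n_test": self.per_fold_sizes,
            }
        )


def run_classification(
    table: FeatureTable,
    plan: FoldPlan,
    cfg: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
) -> ClassificationResult:
    """Cross-validated SVM evaluation with leakage-free preprocessing.

    Per fold: preprocessing is fitted on the training rows, both sides are
    transformed with frozen parameters, the SVM is trained and the fold's
    balanced accuracy recorded. The pooled accuracy is the balanced accuracy
    over all test predictions concatenated across folds.
    """
    feature_blocks = table.feature_blocks() if cfg.pca_mode == "per_feature" else None
    fold_accs: list[float] = []
    sizes: list[int] = []
    all_true: list[np.ndarray] = []
    all_pred: list[np.ndarray] = []
    skipped = 0

    for fi, (train, test) in enumerate(plan.folds):
        y_train = table.y[train]
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {fi}: single-class training set, skipped", RuntimeWarning)
            skipped += 1
            continue
        params = fit_preprocessor(
            table.X[train],
            variance_target=cfg.variance_target,
            pca_mode=cfg.pca_mode,
            feature_blocks=feature_blocks,
            fitted_on=f"{plan.scheme}/fold{fi}",
        )
        Xtr = apply_preprocessor(params, table.X[train])
        Xte = apply_preprocessor(params, table.X[test])
        gamma = kernel_gamma(Xtr) if cfg.kernel == "rbf" else "scale"
        clf = SVC(
            kernel=cfg.kernel,
            C=cfg.C,
            gamma=gamma,
            decision_function_shape="ovo",
            random_state=seed,
        )
        clf.fit(Xtr, y_train)
        y_pred = _ovo_predict(clf, Xte, clf.classes_)
        y_true = table.y[test]
        fold_accs.append(balanced_accuracy(y_true, y_pred))
        sizes.append(int(test.size))
        all_true.append(y_true)
        all_pred.append(y_pred)

    if not fold_accs:
        raise ValueError("no usable folds")
    y_true_pooled = np.concatenate(all_true)
    y_pred_pooled = np.concatenate(all_pred)
    pooled = balanced_accuracy(y_true_pooled, y_pred_pooled)
    return ClassificationResult(
        plan.scheme, fold_accs, pooled, sizes, cfg, seed, skipped,
        y_true_pooled, y_pred_pooled,
    )


def permutation_null(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of balanced accuracy under label permutation.

    Permuting the true labels against fixed predictions realizes the null
    hypothesis of no association between states and classifier output.
    """
    rng = np.random.default_rng(seed)
    y_true = np.asarray(y_true)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        out[i] = balanced_accuracy(rng.permutation(y_true), y_pred)
    return out
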