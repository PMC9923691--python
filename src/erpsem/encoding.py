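"""Cross-validated per-timepoint ridge encoding of ERP patterns.

An encoding model asks how well a word's position in some feature space
(embedding vectors, taxonomy similarities, covariate-augmented variants)
linearly predicts the ERP pattern it evokes.  Within a k-fold
cross-validation loop an independent ridge regression is fitted per
timepoint, mapping standardized features to the vector of sensor
amplitudes; held-out predictions are scored with the signed squared
correlation across items, aggregated over sensors, and summarized in the
analysis window with fold-bootstrap confidence intervals and a Wilcoxon
signed-rank test against chance (0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .simulate import Covariates
from .stats import TestResult, bootstrap_ci_rows, wilcoxon_signed_rank, wilcoxon_rank_sum

__all__ = [
    "ERPDataset",
    "FoldScheme",
    "EncoderModel",
    "EncodingResult",
    "ModelComparison",
    "make_folds",
    "signed_r2",
    "fit_encoder",
    "encode_cv",
    "window_average",
    "compare_models",
    "augment_features",
]

DEFAULT_PENALTY = 1.0  # ridge L2 penalty on standardized features
DEFAULT_WINDOW_MS = (300.0, 500.0)  # N400 analysis window


@dataclass
class ERPDataset:
    """Item-level ERPs: one subject-averaged epoch per word.

    ``data`` is items x sensors x timepoints in microvolts on a uniform
    time axis starting at ``t_start_ms`` with step ``1000/rate_hz``.
    """

    words: list[str]
    data: np.ndarray
    rate_hz: float
    t_start_ms: float
    sensor_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.words = list(self.words)
        if len(set(self.words)) != len(self.words):
            raise ValueError("duplicate words in ERP dataset")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ERP data must be items x sensors x timepoints")
        if self.data.shape[0] != len(self.words):
            raise ValueError("ERP item count does not match word count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ERP data contains non-finite values")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not self.sensor_labels:
            self.sensor_labels = [f"E{i+1:03d}" for i in range(self.data.shape[1])]
        if len(self.sensor_labels) != self.data.shape[1]:
            raise ValueError("sensor_labels length does not match sensor axis")

    @property
    def n_items(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.rate_hz
        return self.t_start_ms + step * np.arange(self.n_times)

    def window_mask(self, t0_ms: float, t1_ms: float) -> np.ndarray:
        """Boolean mask of timepoints with t0 <= t <= t1 (inclusive)."""
        t = self.times_ms
        mask = (t >= t0_ms - 1e-9) & (t <= t1_ms + 1e-9)
        if not mask.any():
            raise ValueError(f"window [{t0_ms}, {t1_ms}] ms contains no timepoints")
        return mask


@dataclass(frozen=True)
class FoldScheme:
    """A partition of items into cross-validation folds (sizes differ <= 1)."""

    n_folds: int
    assignments: np.ndarray  # item index -> fold index
    seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.assignments, minlength=self.n_folds)
        if counts.size != self.n_folds or counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    @property
    def n_items(self) -> int:
        return self.assignments.size

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test

    def same_partition(self, other: "FoldScheme") -> bool:
        return self.n_folds == other.n_folds and np.array_equal(
            self.assignments, other.assignments
        )


@dataclass
class EncoderModel:
    """Per-timepoint ridge coefficients with the training-fold scaling.

    ``coefficients`` is timepoints x features x sensors; feature means/sds
    come from the training items only and are applied before prediction.
    """

    coefficients: np.ndarray
    intercepts: np.ndarray  # timepoints x sensors
    penalty: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predicted ERPs (items x sensors x timepoints) for new feature rows."""
        Xs = (features - self.feature_mean) / self.feature_sd
        # (T,p,s) x (n,p) -> (n,s,T)
        pred = np.einsum("np,tps->nst", Xs, self.coefficients)
        return pred + self.intercepts.T[None, :, :]


@dataclass
class EncodingResult:
    """Per-fold, per-timepoint encoding scores plus window summaries."""

    scores: np.ndarray  # folds x timepoints, mean over sensors
    sensor_scores: np.ndarray  # folds x sensors x timepoints
    time_ms: np.ndarray
    window_ms: tuple[float, float]
    window_means: np.ndarray  # per fold
    ci: np.ndarray  # timepoints x 2 (lo, hi)
    ci_level: float
    test: TestResult
    folds: FoldScheme
    penalty: float
    aggregate: str

    @property
    def mean_window_score(self) -> float:
        return float(self.window_means.mean())

    def electrode_window_scores(self) -> np.ndarray:
        """Encoding performance aggregated over window time and folds, per sensor."""
        mask = (self.time_ms >= self.window_ms[0] - 1e-9) & (
            self.time_ms <= self.window_ms[1] + 1e-9
        )
        return self.sensor_scores[:, :, mask].mean(axis=(0, 2))


def make_folds(words: list[str], n_folds: int, seed: int) -> FoldScheme:
    """Seeded shuffle of the items followed by contiguous equal blocks."""
    n = len(words)
    if not (2 <= n_folds <= n):
        raise ValueError(f"n_folds must be in [2, {n}], got {n_folds}")
    order = np.random.default_rng(seed).permutation(n)
    assignments = np.empty(n, dtype=int)
    for fold, block in enumerate(np.array_split(order, n_folds)):
        assignments[block] = fold
    return FoldScheme(n_folds, assignments, seed)


def signed_r2(predicted, observed) -> float:
    """Signed squared Pearson correlation, ``sign(r) * r**2``.

    Keeps the direction of the fit: anti-correlated predictions score
    negatively rather than being rewarded.  Constant vectors (undefined
    correlation) score 0.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size != o.size:
        raise ValueError(f"length mismatch: {p.size} vs {o.size}")
    if p.size < 3:
        raise ValueError("need at least 3 paired values")
    pc = p - p.mean()
    oc = o - o.mean()
    denom = np.sqrt((pc @ pc) * (oc @ oc))
    if denom == 0.0:
        return 0.0
    r = float((pc @ oc) / denom)
    r = max(-1.0, min(1.0, r))
    return float(np.sign(r) * r * r)


def _signed_r2_items(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Vectorized signed r^2 across the item axis of (items, ...) arrays."""
    pc = pred - pred.mean(axis=0)
    oc = obs - obs.mean(axis=0)
    num = (pc * oc).sum(axis=0)
    denom = np.sqrt((pc * pc).sum(axis=0) * (oc * oc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    return np.sign(r) * r * r


def standardize_train(
    features: np.ndarray, train: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature mean/sd from the training rows; zero sd maps to 1.

    A zero-variance feature then becomes an all-zero column, which the
    ridge penalty sends to a zero coefficient — so degenerate covariates
    cannot influence predictions.
    """
    mean = features[train].mean(axis=0)
    sd = features[train].std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (features - mean) / sd, mean, sd


def ridge_solve(Xtr: np.ndarray, Yc: np.ndarray, penalty: float) -> np.ndarray:
    """Primal ridge coefficients ``(X'X + lam I)^-1 X'Y`` via Cholesky."""
    p = Xtr.shape[1]
    G = Xtr.T @ Xtr + penalty * np.eye(p)
    return cho_solve(cho_factor(G), Xtr.T @ Yc)


def fit_encoder(
    erp: ERPDataset,
    features: np.ndarray,
    train: np.ndarray,
    penalty: float = DEFAULT_PENALTY,
) -> EncoderModel:
    """Fit the per-timepoint ridge encoder on a set of training items.

    The returned model carries one features x sensors coefficient block
    per timepoint plus the training-fold feature scaling, and predicts
    full ERPs for unseen feature rows via :meth:`EncoderModel.predict`.
    """
    features = np.asarray(features, dtype=float)
    train = np.asarray(train, dtype=int)
    if train.size < 2:
        raise ValueError("need at least 2 training items")
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    n, s, T = erp.data.shape
    Xs, mean, sd = standardize_train(features, train)
    flatY = erp.data.reshape(n, s * T)
    Ym = flatY[train].mean(axis=0)
    W = ridge_solve(Xs[train], flatY[train] - Ym, penalty)  # p x (s*T)
    p = features.shape[1]
    coefficients = W.reshape(p, s, T).transpose(2, 0, 1)  # T x p x s
    intercepts = Ym.reshape(s, T).T  # T x s
    return EncoderModel(coefficients, intercepts, penalty, mean, sd)


def encode_cv(
    erp: ERPDataset,
    features: np.ndarray,
    folds: FoldScheme,
    penalty: float = DEFAULT_PENALTY,
    *,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    aggregate: str = "per_sensor",
    solver: str = "primal",
    ci_level: float = 0.95,
    n_boot: int = 10_000,
    ci_seed: int | None = None,
    return_predictions: bool = False,
):
    """Cross-validated per-timepoint ridge encoding of an ERP dataset.

    Per fold and timepoint a ridge regression maps standardized features to
    the sensor vector; held-out items are scored per sensor with signed r^2
    across items, then averaged over sensors (``aggregate='per_sensor'``,
    default) or correlated on the flattened item x sensor pattern
    (``aggregate='flatten'``).  ``solver='dual'`` fits the identical model
    through the item x item Gram matrix of the standardized features
    (kernel ridge); by the representer theorem the predictions coincide
    with the primal ones, which is what lets similarity matrices act as
    feature spaces of their own.

    Returns an :class:`EncodingResult`; with ``return_predictions=True``
    returns ``(result, predictions)`` where predictions is the full
    items x sensors x timepoints array of held-out predictions.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] != erp.n_items:
        raise ValueError(
            f"features must be ({erp.n_items}, p), got {features.shape}"
        )
    if folds.n_items != erp.n_items:
        raise ValueError("fold scheme does not match ERP item count")
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    if aggregate not in ("per_sensor", "flatten"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    if solver not in ("primal", "dual"):
        raise ValueError(f"unknown solver {solver!r}")

    n, s, T = erp.data.shape
    flatY = erp.data.reshape(n, s * T)
    sensor_scores = np.zeros((folds.n_folds, s, T))
    flat_scores = np.zeros((folds.n_folds, T))
    predictions = np.zeros_like(erp.data) if return_predictions else None

    for fold in range(folds.n_folds):
        train, test = folds.split(fold)
        if train.size < 2:
            raise ValueError(f"fold {fold} leaves fewer than 2 training items")
        Xs, _, _ = standardize_train(features, train)
        Ym = flatY[train].mean(axis=0)
        Yc = flatY[train] - Ym
        if solver == "primal":
            W = ridge_solve(Xs[train], Yc, penalty)
            pred = Xs[test] @ W + Ym
        else:
            K = Xs @ Xs.T
            A = cho_solve(
                cho_factor(K[np.ix_(train, train)] + penalty * np.eye(train.size)),
                Yc,
            )
            pred = K[np.ix_(test, train)] @ A + Ym
        pred3 = pred.reshape(test.size, s, T)
        obs3 = erp.data[test]
        if predictions is not None:
            predictions[test] = pred3
        sensor_scores[fold] = _signed_r2_items(pred3, obs3)
        if aggregate == "flatten":
            flat_scores[fold] = _signed_r2_items(
                pred3.reshape(-1, T), obs3.reshape(-1, T)
            )

    scores = sensor_scores.mean(axis=1) if aggregate == "per_sensor" else flat_scores

    times = erp.times_ms
    mask = erp.window_mask(*window_ms)
    window_means = scores[:, mask].mean(axis=1)
    if ci_seed is None:
        ci_seed = folds.seed + 1
    ci = bootstrap_ci_rows(scores, ci_level, n_boot, ci_seed)
    test_res = wilcoxon_signed_rank(window_means, 0.0)

    result = EncodingResult(
        scores=scores,
        sensor_scores=sensor_scores,
        time_ms=times,
        window_ms=tuple(window_ms),
        window_means=window_means,
        ci=ci,
        ci_level=ci_level,
        test=test_res,
        folds=folds,
        penalty=penalty,
        aggregate=aggregate,
    )
    if return_predictions:
        return result, predictions
    return result


def window_average(result: EncodingResult, t0_ms: float, t1_ms: float) -> np.ndarray:
    """Per-fold mean score over timepoints with t0 <= t <= t1 (inclusive)."""
    mask = (result.time_ms >= t0_ms - 1e-9) & (result.time_ms <= t1_ms + 1e-9)
    if not mask.any():
        raise ValueError(f"window [{t0_ms}, {t1_ms}] ms contains no timepoints")
    return result.scores[:, mask].mean(axis=1)


@dataclass
class ModelComparison:
    """Fold-paired comparison of two encoding models (a minus b)."""

    fold_differences: np.ndarray  # per-fold window-mean differences
    diff_timecourse: np.ndarray  # fold-mean score difference per timepoint
    test: TestResult
    folds_a_better: int

    @property
    def mean_difference(self) -> float:
        return float(self.fold_differences.mean())


def compare_models(
    result_a: EncodingResult, result_b: EncodingResult, test: str = "signed_rank"
) -> ModelComparison:
    """Which of two encoding models predicts held-out ERPs better?

    Both results must come from the identical fold partition and time axis.
    Differences are a - b, per fold (window means) and per timepoint.  The
    default test is the Wilcoxon signed-rank on the per-fold window-mean
    differences against 0; ``test='rank_sum'`` instead ranks the two sets
    of per-fold window means against each other (an unpaired variant).
    """
    if not result_a.folds.same_partition(result_b.folds):
        raise ValueError("fold schemes differ between the two results")
    if not np.array_equal(result_a.time_ms, result_b.time_ms):
        raise ValueError("time axes differ between the two results")
    fold_diff = result_a.window_means - result_b.window_means
    diff_tc = (result_a.scores - result_b.scores).mean(axis=0)
    if test == "signed_rank":
        res = wilcoxon_signed_rank(fold_diff, 0.0)
    elif test == "rank_sum":
        res = wilcoxon_rank_sum(result_a.window_means, result_b.window_means)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ModelComparison(
        fold_differences=fold_diff,
        diff_timecourse=diff_tc,
        test=res,
        folds_a_better=int((fold_diff > 0).sum()),
    )


def augment_features(
    features: np.ndarray, words: list[str], covariates: Covariates
) -> np.ndarray:
    """Append log-frequency and concreteness columns to a feature matrix.

    Lets the encoding model test whether the embedding carries information
    beyond such lexical covariates; the word lists must align row-for-row.
    """
    features = np.asarray(features, dtype=float)
    if list(words) != list(covariates.words):
        raise ValueError("covariate word list does not match feature rows")
    extra = np.column_stack([covariates.log_frequency, covariates.concreteness])
    return np.hstack([features, extra])
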