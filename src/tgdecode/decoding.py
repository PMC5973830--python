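"""Shrinkage-LDA decoding over time: diagonal, temporal and cross-condition
generalization.

At every time point the two stimulus classes are separated with a linear
discriminant on the sensor vector (data smoothed with a centred 30 ms boxcar
first). The pooled within-class covariance is shrunk toward the scaled
identity, ``(1-g) C + g (tr C / p) I``, with the Ledoit-Wolf intensity when
``shrinkage="auto"`` — with ~270 sensors and ~170 training trials the raw
covariance is ill-conditioned and plain LDA is unusable.

Cross-validation uses a single stratified trial partition for the whole
time x time matrix, so diagonal and off-diagonal cells are estimated from
identical folds and their comparison (the specificity index) is paired.
Cross-condition decoding reuses that partition on the paired segment: the
classifier is trained on the training trials of one condition and tested on
the held-out trials of the other, which avoids optimistic transfer estimates
driven by shared trial noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .epochs import EpochsArray, sliding_average

__all__ = [
    "LDAModel",
    "DecodingTimecourse",
    "GeneralizationMatrix",
    "fit_lda",
    "balance_classes",
    "decode_diagonal",
    "decode_generalization",
    "decode_eyetrack",
    "TemporalDecoder",
]

CHANCE = 0.5


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Two-class linear discriminant: decision = sign(w'x + b), 1 if positive."""

    weights: np.ndarray
    bias: float
    classes: tuple[int, int] = (0, 1)
    shrinkage: float = 0.0

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision(X) > 0).astype(np.int64)


def _ledoit_wolf_intensity(resid: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage intensity for class-centered residuals.

    ``resid`` is (n, p) or (n, p, T); the intensity is computed per time
    slice. Follows the scaled-identity-target estimator: the ratio of the
    estimation variance of the sample covariance to its squared distance
    from the target, clipped to [0, 1].
    """
    if resid.ndim == 2:
        resid = resid[:, :, None]
    n = resid.shape[0]
    rT = np.ascontiguousarray(np.moveaxis(resid, 2, 0))  # (T, n, p)
    S = rT.transpose(0, 2, 1) @ rT / n
    return _lw_gamma_from_s(S, resid, n)


def _lw_gamma_from_s(S: np.ndarray, resid: np.ndarray, n: int) -> np.ndarray:
    p = S.shape[1]
    m = np.trace(S, axis1=1, axis2=2) / p
    S_fro2 = np.einsum("tpq,tpq->t", S, S)
    d2 = S_fro2 - p * m**2  # ||S - m I||_F^2
    norms2 = np.einsum("ipt,ipt->it", resid, resid)
    b2 = (np.sum(norms2**2, axis=0) - n * S_fro2) / n**2
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(d2 > 0, np.minimum(b2, d2) / d2, 1.0)
    return np.clip(gamma, 0.0, 1.0)


def _fit_lda_stack(X: np.ndarray, y: np.ndarray,
                   shrinkage: float | str = "auto") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit shrinkage LDA at every time slice of ``X`` (n, p, T).

    Returns (W, b, gamma) with W of shape (T, p).
    """
    if X.ndim == 2:
        X = X[:, :, None]
    y = np.asarray(y)
    n, p, T = X.shape
    mask1 = y == 1
    mask0 = y == 0
    if not (mask0.any() and mask1.any()):
        raise ValueError("both classes must be present to fit LDA")
    if mask0.sum() < 2 or mask1.sum() < 2:
        raise ValueError("need at least 2 trials per class to estimate covariance")
    mu0 = X[mask0].mean(axis=0)  # (p, T)
    mu1 = X[mask1].mean(axis=0)
    resid = X.copy()
    resid[mask0] -= mu0
    resid[mask1] -= mu1
    rT = np.ascontiguousarray(np.moveaxis(resid, 2, 0))  # (T, n, p)
    C = rT.transpose(0, 2, 1) @ rT / (n - 2)
    tr = np.trace(C, axis1=1, axis2=2)
    if np.any(tr <= 0):
        raise ValueError("all features have zero variance; cannot fit LDA")
    if shrinkage == "auto":
        gamma = _lw_gamma_from_s(C * ((n - 2) / n), resid, n)
    else:
        gamma = np.full(T, float(shrinkage))
        if np.any((gamma < 0) | (gamma > 1)):
            raise ValueError("shrinkage must be in [0, 1]")
    target = (tr / p)[:, None, None] * np.eye(p)[None]
    C_shrunk = (1.0 - gamma)[:, None, None] * C + gamma[:, None, None] * target
    dmu = (mu1 - mu0).T  # (T, p)
    W = np.linalg.solve(C_shrunk, dmu[:, :, None])[:, :, 0]
    b = -np.einsum("tp,pt->t", W, (mu0 + mu1) / 2.0)
    return W, b, gamma


def fit_lda(X: np.ndarray, y: np.ndarray, shrinkage: float | str = "auto") -> LDAModel:
    """Fit a two-class shrinkage LDA on trials x features data."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be trials x features")
    W, b, gamma = _fit_lda_stack(X[:, :, None], y, shrinkage)
    return LDAModel(weights=W[0], bias=float(b[0]), shrinkage=float(gamma[0]))


def balance_classes(y: np.ndarray, seed) -> np.ndarray:
    """Indices keeping equal class counts; excess majority trials dropped at random."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise ValueError("both classes must be present")
    n_keep = min(idx0.size, idx1.size)
    keep0 = np.sort(rng.choice(idx0, size=n_keep, replace=False))
    keep1 = np.sort(rng.choice(idx1, size=n_keep, replace=False))
    return np.sort(np.concatenate([keep0, keep1]))


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class DecodingTimecourse:
    """Cross-validated accuracy over time for one subject and condition."""

    times: np.ndarray
    accuracy: np.ndarray
    n_folds: int
    chance: float = CHANCE
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.accuracy.shape != self.times.shape:
            raise ValueError("accuracy and times must align")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracy must be within [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "accuracy": self.accuracy})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def summary(self) -> str:
        peak = int(np.argmax(self.accuracy))
        lines = [
            f"Decoding timecourse  subject={self.subject_id}  condition={self.condition}",
            f"  folds: {self.n_folds}   chance: {self.chance}",
            f"  time span: [{self.times[0]:.3f}, {self.times[-1]:.3f}] s, {self.times.size} points",
            f"  mean accuracy: {self.accuracy.mean():.3f}",
            f"  peak accuracy: {self.accuracy[peak]:.3f} at {self.times[peak]*1000:.0f} ms",
        ]
        return "\n".join(lines)


@dataclass
class GeneralizationMatrix:
    """Accuracy A(train_time, test_time), cross-validated on one trial partition."""

    train_times: np.ndarray
    test_times: np.ndarray
    accuracy: np.ndarray
    train_condition: str = ""
    test_condition: str = ""
    cross_validated: bool = True
    n_folds: int = 5
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.accuracy.shape != (self.train_times.size, self.test_times.size):
            raise ValueError("accuracy must be train_times x test_times")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracy must be within [0, 1]")

    def diagonal(self) -> np.ndarray:
        if self.train_times.size != self.test_times.size:
            raise ValueError("diagonal undefined for unequal time axes")
        return np.diag(self.accuracy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.accuracy,
            index=pd.Index(self.train_times, name="train_time_s"),
            columns=[f"{t:.6g}" for t in self.test_times],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    def summary(self) -> str:
        i, j = np.unravel_index(np.argmax(self.accuracy), self.accuracy.shape)
        return "\n".join(
            [
                f"Temporal generalization  subject={self.subject_id}  "
                f"train={self.train_condition} -> test={self.test_condition}",
                f"  matrix: {self.accuracy.shape[0]} x {self.accuracy.shape[1]}"
                f"   cross-validated: {self.cross_validated}   folds: {self.n_folds}",
                f"  mean accuracy: {self.accuracy.mean():.3f}",
                f"  peak accuracy: {self.accuracy[i, j]:.3f} at train "
                f"{self.train_times[i]*1000:.0f} ms / test {self.test_times[j]*1000:.0f} ms",
            ]
        )


# ---------------------------------------------------------------------------
# cross-validated decoders
# ---------------------------------------------------------------------------

def _stratified_folds(labels: np.ndarray, k_folds: int, seed: int):
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if labels.size < 2 * k_folds:
        raise ValueError(f"need at least {2*k_folds} trials for {k_folds} folds")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed % (2**32))
    return list(skf.split(np.zeros((labels.size, 1)), labels))


def _fold_accuracy_counts(train: EpochsArray, test: EpochsArray, folds, seed: int,
                          shrinkage: float | str, diagonal_only: bool,
                          time_block: int = 64):
    """Pooled correct/total counts per (train_time, test_time) cell across folds."""
    n_train_t = train.n_samples
    n_test_t = test.n_samples
    if diagonal_only:
        correct = np.zeros(n_train_t)
    else:
        correct = np.zeros((n_train_t, n_test_t))
    total = 0
    for fold_i, (tr_idx, te_idx) in enumerate(folds):
        rng_seed = [int(seed) & 0x7FFFFFFF, fold_i]
        y_tr_all = train.labels[tr_idx]
        kept = balance_classes(y_tr_all, rng_seed)
        sel = tr_idx[kept]
        y_tr = train.labels[sel]
        if (y_tr == 0).sum() < 2 or (y_tr == 1).sum() < 2:
            raise ValueError(
                f"fewer than 2 trials of a class in training fold {fold_i} after balancing"
            )
        X_tr = train.data[sel]  # (n, p, T)
        X_te = test.data[te_idx]  # (m, p, T')
        y_te = test.labels[te_idx]
        total += y_te.size
        for start in range(0, n_train_t, time_block):
            stop = min(start + time_block, n_train_t)
            W, b, _ = _fit_lda_stack(X_tr[:, :, start:stop], y_tr, shrinkage)
            if diagonal_only:
                scores = np.einsum("tp,mpt->tm", W, X_te[:, :, start:stop]) + b[:, None]
                pred = (scores > 0).astype(np.int64)
                correct[start:stop] += (pred == y_te[None, :]).sum(axis=1)
            else:
                scores = np.einsum("tp,mps->tms", W, X_te) + b[:, None, None]
                pred = (scores > 0).astype(np.int64)
                correct[start:stop] += (pred == y_te[None, :, None]).sum(axis=1)
    return correct, total


def decode_diagonal(epochs: EpochsArray, k_folds: int = 5, window_ms: float = 30.0,
                    seed: int = 0, shrinkage: float | str = "auto") -> DecodingTimecourse:
    """Train and test at the same time points with stratified k-fold CV.

    Training folds are class-balanced by random removal; test folds are
    scored as-is and accuracy is the pooled proportion correct.
    """
    epochs.require_both_classes()
    smoothed = sliding_average(epochs, window_ms)
    folds = _stratified_folds(smoothed.labels, k_folds, seed)
    correct, total = _fold_accuracy_counts(
        smoothed, smoothed, folds, seed, shrinkage, diagonal_only=True
    )
    return DecodingTimecourse(
        times=smoothed.times.copy(),
        accuracy=correct / total,
        n_folds=k_folds,
        subject_id=epochs.subject_id,
        condition=epochs.condition,
    )


def decode_generalization(train: EpochsArray, test: EpochsArray | None = None,
                          k_folds: int = 5, window_ms: float = 30.0, seed: int = 0,
                          shrinkage: float | str = "auto") -> GeneralizationMatrix:
    """Temporal generalization matrix, within or across conditions.

    A single stratified trial partition drives both segments: per fold the
    classifier is trained at every train time on the training trials of
    ``train`` and scored at every test time on the held-out trials of
    ``test``. With ``test=None`` (or the same object) this is within-
    condition temporal generalization; its diagonal equals
    :func:`decode_diagonal` for identical settings and seed.
    """
    train.require_both_classes()
    within = test is None or test is train
    if within:
        test = train
    else:
        if test.n_trials != train.n_trials:
            raise ValueError(
                f"segments are not trial-paired: {train.n_trials} vs {test.n_trials} trials"
            )
        if not np.array_equal(train.labels, test.labels):
            raise ValueError(
                "segments are not trial-paired: label sequences differ "
                f"({train.condition} vs {test.condition})"
            )
    train_s = sliding_average(train, window_ms)
    test_s = train_s if within else sliding_average(test, window_ms)
    folds = _stratified_folds(train_s.labels, k_folds, seed)
    correct, total = _fold_accuracy_counts(
        train_s, test_s, folds, seed, shrinkage, diagonal_only=False
    )
    return GeneralizationMatrix(
        train_times=train_s.times.copy(),
        test_times=test_s.times.copy(),
        accuracy=correct / total,
        train_condition=train.condition,
        test_condition=test.condition,
        cross_validated=True,
        n_folds=k_folds,
        subject_id=train.subject_id,
    )


def decode_eyetrack(subject, k_folds: int = 5, window_ms: float = 30.0,
                    seed: int = 0, shrinkage: float | str = "auto") -> DecodingTimecourse:
    """Stimulus decoding from the 2 eye-position channels (control analysis)."""
    eye = subject.eyetrack if hasattr(subject, "eyetrack") else subject
    if eye.n_sensors != 2:
        raise ValueError(f"eye tracker segment must have exactly 2 channels, got {eye.n_sensors}")
    return decode_diagonal(eye, k_folds=k_folds, window_ms=window_ms, seed=seed,
                           shrinkage=shrinkage)


# ---------------------------------------------------------------------------
# model front end
# ---------------------------------------------------------------------------

class TemporalDecoder:
    """Time-resolved decoding model for one subject.

    Parameters
    ----------
    train : EpochsArray
        Segment providing the training trials.
    test : EpochsArray, optional
        Paired segment for cross-condition generalization; omit for
        within-condition analysis.
    k_folds, window_ms, shrinkage
        Cross-validation folds (default 5), smoothing window (default
        30 ms) and LDA shrinkage ("auto" = Ledoit-Wolf).
    """

    def __init__(self, train: EpochsArray, test: EpochsArray | None = None,
                 k_folds: int = 5, window_ms: float = 30.0,
                 shrinkage: float | str = "auto"):
        self.train = train
        self.test = test
        self.k_folds = k_folds
        self.window_ms = window_ms
        self.shrinkage = shrinkage

    def fit(self, seed: int = 0) -> GeneralizationMatrix:
        """Fit the full temporal generalization matrix."""
        return decode_generalization(
            self.train, self.test, k_folds=self.k_folds,
            window_ms=self.window_ms, seed=seed, shrinkage=self.shrinkage,
        )

    def fit_diagonal(self, seed: int = 0) -> DecodingTimecourse:
        """Fit only the matched train/test time points (accuracy timecourse)."""
        if self.test is not None and self.test is not self.train:
            raise ValueError("diagonal decoding is a within-condition analysis")
        return decode_diagonal(
            self.train, k_folds=self.k_folds, window_ms=self.window_ms,
            seed=seed, shrinkage=self.shrinkage,
        )
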