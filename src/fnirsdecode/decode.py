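"""From-scratch shrinkage linear discriminant decoding.

Implements the two-class LDA with fold-wise feature normalization,
the three cross-validation configurations of the experiment
(intra-block leave-one-trial-out, inter-block cross-validation,
inter-block leave-one-trial-out), per-class and balanced accuracy,
and aggregation of classifier weights into channel-level maps.

Model
-----
Both classes are assumed Gaussian with a shared covariance.  With
class means ``muA``, ``muB`` and pooled within-class covariance
``S`` (n - 2 denominator), the discriminant direction is::

    w = Sg^-1 (muB - muA),   Sg = (1 - g) S + g (tr S / p) I

where ``g`` is the shrinkage intensity (Ledoit-Wolf analytic estimate
by default; with p = 64 features and at most 19 training trials the
unshrunk pooled covariance is singular, so some regularization is a
necessity, not an option).  The decision value is ``d(x) = w.x + b``
with the threshold placed at the projected grand mean of the training
set, ``b = -w . mu_grand``; after fold normalization the grand mean is
zero, so effectively ``b = 0``.  This threshold is the one choice that
is unbiased under an exchangeable null in leave-one-out designs: the
conventional midpoint between the class means is systematically pushed
toward the majority class by small-sample mean estimation and yields
below-chance null accuracy (see docs/methods.md).  ``d > 0`` predicts
the second-listed class; an exact tie goes to the first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import TrialMatrix

logger = logging.getLogger("fnirsdecode")

#: Cross-validation scheme identifiers.
SCHEMES = ("intra-LOTO", "inter-cross", "inter-LOTO")


# --------------------------------------------------------------------------
# Fold normalization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature training mean and standard deviation (sample, n-1).

    Zero-variance features have their sd replaced by 1 and are
    recorded in ``degenerate``; a constant feature carries no
    information and must not produce division errors.
    """

    mean: np.ndarray
    sd: np.ndarray
    degenerate: tuple[int, ...] = ()


def normalize_fold(T: np.ndarray, t: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray, NormalizationStats]:
    """Standardize training and test features with *training* statistics.

    The mean and sd are computed from the training rows only and
    applied to both sets; test rows never influence them.
    """
    T = np.asarray(T, dtype=float)
    t = np.asarray(t, dtype=float)
    if T.shape[0] < 2:
        raise ValueError("training set needs at least 2 rows")
    mu = T.mean(axis=0)
    sd = T.std(axis=0, ddof=1)
    degenerate = tuple(int(i) for i in np.flatnonzero(sd == 0))
    if degenerate:
        sd = sd.copy()
        sd[list(degenerate)] = 1.0
        logger.debug("constant training features %s; sd set to 1", degenerate)
    stats = NormalizationStats(mean=mu, sd=sd, degenerate=degenerate)
    return (T - mu) / sd, (t - mu) / sd, stats


# --------------------------------------------------------------------------
# LDA
# --------------------------------------------------------------------------

def ledoit_wolf_gamma(X_centered: np.ndarray) -> float:
    """Analytic shrinkage intensity from within-class centered rows.

    Standard Ledoit-Wolf estimator toward the scaled identity
    ``(tr S / p) I``, computed on the pooled within-class residuals.
    """
    X = np.asarray(X_centered, dtype=float)
    n, p = X.shape
    S = X.T @ X / n
    mu = np.trace(S) / p
    d2 = np.sum((S - mu * np.eye(p)) ** 2)
    if d2 <= 0:
        return 1.0
    xsq = X ** 2
    # (1/n^2) sum_i ||x_i x_i' - S||_F^2 without materializing outer products
    b2 = (np.einsum("ij,ik->", xsq, xsq) / n - np.sum(S ** 2)) / n
    b2 = min(max(b2, 0.0), d2)
    return float(b2 / d2)


@dataclass(frozen=True)
class LDAModel:
    """Fitted discriminant: ``d(x) = w.x + b``; d > 0 predicts class B."""

    w: np.ndarray
    b: float
    gamma: float
    classes: tuple[str, str]

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b

    def predict(self, X: np.ndarray) -> list[str]:
        d = self.decision_values(np.atleast_2d(X))
        return [self.classes[1] if v > 0 else self.classes[0] for v in d]


def fit_lda(X: np.ndarray, labels, classes: tuple[str, str],
            gamma: float | None = None) -> LDAModel:
    """Fit the shrinkage LDA on (already normalized) training data.

    Parameters
    ----------
    X, labels
        Training rows and their class labels.
    classes
        The (A, B) pair; ``w`` points from A toward B.
    gamma
        Shrinkage intensity in [0, 1]; ``None`` selects the
        Ledoit-Wolf analytic value.  ``gamma = 0`` requires a
        non-singular pooled covariance (n - 2 >= p).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    a, b_ = classes
    maskA, maskB = y == a, y == b_
    nA, nB = int(maskA.sum()), int(maskB.sum())
    if nA == 0 or nB == 0:
        raise ValueError(f"both classes {classes} must be present")
    if nA + nB < 4:
        raise ValueError("need at least 4 training samples")
    n, p = X.shape
    muA = X[maskA].mean(axis=0)
    muB = X[maskB].mean(axis=0)
    Xc = np.vstack([X[maskA] - muA, X[maskB] - muB])
    if gamma is None:
        gamma = ledoit_wolf_gamma(Xc)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    S = Xc.T @ Xc / (n - 2)
    if gamma == 0.0 and np.linalg.matrix_rank(S) < p:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular at gamma = 0; use a nonzero "
            "shrinkage (gamma > 0 or gamma = None for Ledoit-Wolf)")
    Sg = (1.0 - gamma) * S + gamma * (np.trace(S) / p) * np.eye(p)
    w = np.linalg.solve(Sg, muB - muA)
    grand = (nA * muA + nB * muB) / n
    b = -float(w @ grand)
    return LDAModel(w=w, b=b, gamma=float(gamma), classes=(a, b_))


# --------------------------------------------------------------------------
# Accuracy
# --------------------------------------------------------------------------

def balanced_accuracy(true, predicted, class_a: str, class_b: str,
                      ) -> tuple[float, float, float]:
    """Per-class and balanced accuracy on the 0-100 scale.

    Balanced accuracy is the mean of the two per-class percentages of
    correctly classified trials, which compensates for the 5-vs-10
    class imbalance of the valence-vs-neutral designs.
    """
    true = np.asarray(true)
    pred = np.asarray(predicted)
    bad = set(true) - {class_a, class_b}
    if bad:
        raise ValueError(f"labels outside ({class_a}, {class_b}): {bad}")
    mA, mB = true == class_a, true == class_b
    if not mA.any() or not mB.any():
        raise ValueError("need at least one trial of each class")
    acc_a = 100.0 * float((pred[mA] == class_a).mean())
    acc_b = 100.0 * float((pred[mB] == class_b).mean())
    return acc_a, acc_b, (acc_a + acc_b) / 2.0


# --------------------------------------------------------------------------
# Cross-validation schemes
# --------------------------------------------------------------------------

@dataclass
class DecodingResult:
    """Predictions, accuracies and fold-wise weights for one comparison."""

    comparison: str
    scheme: str
    classes: tuple[str, str]
    y_true: list[str]
    y_pred: list[str]
    accuracy_a: float
    accuracy_b: float
    balanced: float
    fold_weights: np.ndarray  # (n_folds, p)
    feature_names: list[str] = field(default_factory=list)

    @property
    def weight_map(self) -> "WeightMap":
        return aggregate_weights(self.fold_weights, self.feature_names)


def _loto(values: np.ndarray, y: list[str], classes: tuple[str, str],
          gamma: float | None, comparison: str, scheme: str,
          feature_names: list[str]) -> DecodingResult:
    m = len(y)
    if m < 4:
        raise ValueError(f"need at least 4 trials for LOTO, got {m}")
    preds: list[str] = []
    weights = []
    for i in range(m):
        train = np.ones(m, dtype=bool)
        train[i] = False
        yT = [y[j] for j in range(m) if train[j]]
        Tn, tn, _ = normalize_fold(values[train], values[~train])
        model = fit_lda(Tn, yT, classes, gamma)
        preds.append(model.predict(tn)[0])
        weights.append(model.w)
    acc_a, acc_b, bal = balanced_accuracy(y, preds, *classes)
    return DecodingResult(comparison=comparison, scheme=scheme,
                          classes=classes, y_true=list(y), y_pred=preds,
                          accuracy_a=acc_a, accuracy_b=acc_b, balanced=bal,
                          fold_weights=np.array(weights),
                          feature_names=feature_names)


def intra_block_loto(matrix: TrialMatrix, pair: tuple[str, str],
                     gamma: float | None = None) -> DecodingResult:
    """Leave-one-trial-out decoding of a label pair within one block.

    The classifier is trained on m - 1 trials and tested on the held-out
    trial, m times; each fold is normalized with its own training
    statistics before fitting.
    """
    sub = matrix.select(labels=set(pair))
    return _loto(sub.values, sub.labels, pair, gamma,
                 comparison=f"{pair[0]}-vs-{pair[1]}", scheme="intra-LOTO",
                 feature_names=sub.feature_names)


def inter_block_cross(train_matrix: TrialMatrix, test_matrix: TrialMatrix,
                      pair: tuple[str, str], gamma: float | None = None,
                      ) -> DecodingResult:
    """Train on one elicitation condition, test on the other (single fold)."""
    if train_matrix.feature_names != test_matrix.feature_names:
        raise ValueError("train and test matrices have different feature spaces")
    tr = train_matrix.select(labels=set(pair))
    te = test_matrix.select(labels=set(pair))
    Tn, tn, _ = normalize_fold(tr.values, te.values)
    model = fit_lda(Tn, tr.labels, pair, gamma)
    preds = model.predict(tn)
    acc_a, acc_b, bal = balanced_accuracy(te.labels, preds, *pair)
    cond_tr = train_matrix.conditions[0] if train_matrix.conditions else "?"
    cond_te = test_matrix.conditions[0] if test_matrix.conditions else "?"
    return DecodingResult(
        comparison=f"{pair[0]}-vs-{pair[1]} ({cond_tr}->{cond_te})",
        scheme="inter-cross", classes=pair, y_true=list(te.labels),
        y_pred=preds, accuracy_a=acc_a, accuracy_b=acc_b, balanced=bal,
        fold_weights=model.w[None, :], feature_names=tr.feature_names)


def inter_block_loto(combined_matrix: TrialMatrix, valence: str,
                     gamma: float | None = None) -> DecodingResult:
    """Decode elicitation condition (passive vs active) within one valence.

    The combined matrix must hold that valence's trials from both
    blocks; the condition tag is the class label and the fold
    mechanics are the same leave-one-trial-out procedure.
    """
    sub = combined_matrix.select(labels={valence})
    conds = sorted(set(sub.conditions),
                   key=lambda c: {"passive": 0, "active": 1}.get(c, 2))
    if len(conds) != 2:
        raise ValueError(f"both conditions required for valence {valence!r}, "
                         f"got {conds}")
    classes = (conds[0], conds[1])
    return _loto(sub.values, sub.conditions, classes, gamma,
                 comparison=f"{valence}: {classes[0]}-vs-{classes[1]}",
                 scheme="inter-LOTO", feature_names=sub.feature_names)


#: The three pairwise valence comparisons.
PAIRS = (("positive", "neutral"), ("negative", "neutral"),
         ("positive", "negative"))


def decode_participant(passive: TrialMatrix, active: TrialMatrix,
                       gamma: float | None = None) -> list[DecodingResult]:
    """Run all 15 comparisons of the full design for one participant.

    Six intra-block LOTO comparisons (three valence pairs per
    condition), six inter-block cross-validations (each pair, trained
    on either condition and tested on the other), and three inter-block
    LOTO condition decodings (one per valence).
    """
    results = []
    for cond, tm in (("passive", passive), ("active", active)):
        for pair in PAIRS:
            r = intra_block_loto(tm, pair, gamma)
            r.comparison = f"{cond}: {r.comparison}"
            results.append(r)
    for pair in PAIRS:
        results.append(inter_block_cross(passive, active, pair, gamma))
        results.append(inter_block_cross(active, passive, pair, gamma))
    combined = TrialMatrix.concatenate([passive, active])
    for valence in ("neutral", "negative", "positive"):
        results.append(inter_block_loto(combined, valence, gamma))
    return results


# --------------------------------------------------------------------------
# Weight maps
# --------------------------------------------------------------------------

@dataclass
class WeightMap:
    """Mean signed and mean absolute classifier weights across folds."""

    mean_signed: np.ndarray
    mean_abs: np.ndarray
    feature_names: list[str]

    def by_channel(self, chromophore: str) -> pd.Series:
        """Channel-level mean-absolute map for one chromophore."""
        suffix = f"_{chromophore}"
        idx = [i for i, n in enumerate(self.feature_names)
               if n.endswith(suffix)]
        if not idx:
            raise KeyError(f"no features for chromophore {chromophore!r}")
        names = [self.feature_names[i].removesuffix(suffix) for i in idx]
        return pd.Series(self.mean_abs[idx], index=names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_names,
                             "mean_signed": self.mean_signed,
                             "mean_abs": self.mean_abs})


def aggregate_weights(fold_weights: np.ndarray,
                      feature_names: list[str] | None = None) -> WeightMap:
    """Average fold-wise weight vectors into a weight map."""
    W = np.atleast_2d(np.asarray(fold_weights, dtype=float))
    if W.shape[0] < 1:
        raise ValueError("need at least one fold")
    if feature_names is None or not list(feature_names):
        feature_names = [f"f{i}" for i in range(W.shape[1])]
    if len(feature_names) != W.shape[1]:
        raise ValueError("inconsistent weight vector lengths")
    return WeightMap(mean_signed=W.mean(axis=0), mean_abs=np.abs(W).mean(axis=0),
                     feature_names=list(feature_names))
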