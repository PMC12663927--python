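"""Sequence-to-rate models and the identity-thresholded LOO benchmark.

Four models map an aligned rubisco sequence to a carboxylation rate,
always working on natural-log rates (rates are roughly log-normal within
a form):

* ``nn`` — the ln-rate of the most similar training sequence (ties
  average);
* ``mean`` — the unweighted mean ln-rate of the training set;
* ``weighted_mean`` — identity-weighted mean with exponential weights
  ``w_i = exp(-lam * (1 - s_i))``, where ``s_i`` is the identity between
  training sequence i and the query;
* ``svr_rbf`` — support-vector regression on one-hot encoded alignment
  columns with an RBF kernel at library-default parameters
  (C = 1, epsilon = 0.1, gamma = 1 / (n_features * Var(X))).

Model quality is assessed by leave-one-out cross-validation in which the
training set for each held-out variant is restricted to characterized
variants sharing at least identity X with it; sweeping X measures how
much nearby sequences improve prediction.  Errors are reported as
ln-space RMSE and as the equivalent fold-change error ``exp(rmse)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .seqspace import AMBIGUOUS, AMINO_ACIDS, GAP, AlignedSeqSet, identity_matrix

#: one-hot state alphabet: the 20 amino acids plus the gap character.
#: ``X`` (ambiguity) encodes as an all-zero block, contributing no
#: similarity at its position.
STATE_ALPHABET = AMINO_ACIDS + GAP
N_STATES = len(STATE_ALPHABET)
_STATE_INDEX = {ch: k for k, ch in enumerate(STATE_ALPHABET)}


@dataclass
class EncodedMatrix:
    """One-hot encoded alignment: rows are sequences, columns are
    (position, state) indicator features in position-major order."""

    X: np.ndarray
    feature_index: list[tuple[int, str]]
    ids: list[str]
    n_positions: int

    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.feature_index])


def one_hot_encode(aln: AlignedSeqSet) -> EncodedMatrix:
    """Encode an alignment as a binary (n, L*21) matrix.

    Column ordering is deterministic: position-major, states in the
    fixed order ``ACDEFGHIKLMNPQRSTVWY-``.  Rows containing ambiguity
    codes have all-zero blocks at the ambiguous positions, so their row
    sum falls short of the alignment length by the number of ``X``s.
    """
    n, L = len(aln), aln.length
    X = np.zeros((n, L * N_STATES), dtype=np.float64)
    for i, row in enumerate(aln.rows):
        for p, ch in enumerate(row):
            if ch == AMBIGUOUS:
                continue
            X[i, p * N_STATES + _STATE_INDEX[ch]] = 1.0
    feature_index = [(p, s) for p in range(L) for s in STATE_ALPHABET]
    return EncodedMatrix(X=X, feature_index=feature_index, ids=list(aln.ids), n_positions=L)


def decode(enc: EncodedMatrix) -> list[str]:
    """Inverse of :func:`one_hot_encode` (ambiguous positions decode to X)."""
    rows = []
    for i in range(enc.X.shape[0]):
        chars = []
        for p in range(enc.n_positions):
            block = enc.X[i, p * N_STATES : (p + 1) * N_STATES]
            hits = np.flatnonzero(block)
            chars.append(STATE_ALPHABET[hits[0]] if hits.size else AMBIGUOUS)
        rows.append("".join(chars))
    return rows


@dataclass
class ModelSpec:
    """Model kind plus the hyperparameters that matter.

    ``lam`` controls the weighted-mean decay: at the default 14 a
    5-point identity drop roughly halves a training sequence's weight;
    lam = 0 recovers the unweighted mean and large lam approaches the
    nearest-neighbour model.
    """

    kind: str = "svr_rbf"
    lam: float = 14.0
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    svr_gamma: str | float = "scale"  # 1 / (n_features * Var(X))

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.lam < 0 or self.svr_c <= 0 or self.svr_epsilon < 0:
            raise ValueError("hyperparameters must be non-negative (C positive)")


MODEL_KINDS = ("nn", "mean", "weighted_mean", "svr_rbf")


# ---------------------------------------------------------------------------
# The four predictors
# ---------------------------------------------------------------------------

def predict_nn(identities: np.ndarray, y: np.ndarray) -> float:
    """ln-rate of the most similar training sequence; ties average."""
    identities = np.asarray(identities, float)
    y = np.asarray(y, float)
    if identities.size == 0:
        raise ValueError("empty training set")
    best = identities.max()
    return float(y[identities == best].mean())


def predict_mean(y: np.ndarray) -> float:
    y = np.asarray(y, float)
    if y.size == 0:
        raise ValueError("empty training set")
    return float(y.mean())


def predict_weighted_mean(identities: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Identity-weighted mean with weights exp(-lam * (1 - identity))."""
    identities = np.asarray(identities, float)
    y = np.asarray(y, float)
    if identities.size == 0:
        raise ValueError("empty training set")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    w = np.exp(-lam * (1.0 - identities))
    return float(np.sum(w * y) / np.sum(w))


def fit_svr(X: np.ndarray, y: np.ndarray, spec: ModelSpec | None = None) -> SVR:
    """Fit epsilon-insensitive RBF-kernel SVR at the pinned defaults."""
    spec = spec or ModelSpec(kind="svr_rbf")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("SVR needs at least 2 training rows")
    model = SVR(
        kernel="rbf", C=spec.svr_c, epsilon=spec.svr_epsilon, gamma=spec.svr_gamma
    )
    model.fit(X, y)
    return model


def _predict_one(
    spec: ModelSpec,
    train_idx: np.ndarray,
    query_idx: int,
    sim: np.ndarray,
    y: np.ndarray,
    enc: EncodedMatrix | None,
) -> float:
    s = sim[query_idx, train_idx]
    yt = y[train_idx]
    if spec.kind == "nn":
        return predict_nn(s, yt)
    if spec.kind == "mean":
        return predict_mean(yt)
    if spec.kind == "weighted_mean":
        return predict_weighted_mean(s, yt, spec.lam)
    # svr_rbf; a single-sequence training set cannot support a fit and
    # degenerates to its mean (= that sequence's value)
    if train_idx.size < 2:
        return predict_mean(yt)
    assert enc is not None
    model = fit_svr(enc.X[train_idx], yt, spec)
    return float(model.predict(enc.X[query_idx : query_idx + 1])[0])


# ---------------------------------------------------------------------------
# Identity-thresholded leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-threshold LOO error of one model.

    ``rmse_ln`` is the root-mean-square error of ln-rate predictions
    over the evaluable targets (those with at least one training
    sequence above the identity threshold); ``fold_error = exp(rmse_ln)``
    expresses the same error as a typical fold change (1 = perfect).
    """

    model: str
    thresholds: list[float]
    rmse_ln: list[float]
    fold_error: list[float]
    n_evaluable: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "rmse_ln": self.rmse_ln,
                "fold_error": self.fold_error,
                "n_evaluable": self.n_evaluable,
                "model": self.model,
            }
        )

    def at(self, threshold: float) -> tuple[float, float, int]:
        k = self.thresholds.index(threshold)
        return self.rmse_ln[k], self.fold_error[k], self.n_evaluable[k]


DEFAULT_CV_THRESHOLDS = [round(0.5 + 0.05 * k, 2) for k in range(9)]


def loo_crossval(
    aln: AlignedSeqSet,
    ln_rates: Mapping[str, float] | Sequence[float],
    spec: ModelSpec,
    thresholds: Sequence[float] | None = None,
    scope_forms: bool = False,
    sim: np.ndarray | None = None,
) -> CVResult:
    """Leave-one-out benchmark with identity-restricted training sets.

    For each held-out variant v and threshold X, the training set is
    every other characterized variant with identity(., v) >= X (and of
    the same form when ``scope_forms``).  Targets with an empty training
    set at X are skipped and excluded from that threshold's RMSE;
    ``n_evaluable`` records how many remained.  Deterministic: none of
    the four models is stochastic.
    """
    if len(aln) < 3:
        raise ValueError("cross-validation needs at least 3 sequences")
    thresholds = list(DEFAULT_CV_THRESHOLDS if thresholds is None else thresholds)
    if isinstance(ln_rates, Mapping):
        y = np.array([ln_rates[v] for v in aln.ids], float)
    else:
        y = np.asarray(ln_rates, float)
        if y.size != len(aln):
            raise ValueError("ln_rates length mismatch")
    if not np.isfinite(y).all():
        raise ValueError("ln_rates must be finite")
    if sim is None:
        sim = identity_matrix(aln)
    enc = one_hot_encode(aln) if spec.kind == "svr_rbf" else None
    forms = np.array(aln.form)
    n = len(aln)
    rmses, folds, counts = [], [], []
    for x in thresholds:
        errs = []
        for v in range(n):
            mask = sim[v] >= x
            mask[v] = False
            if scope_forms:
                mask &= forms == forms[v]
            train_idx = np.flatnonzero(mask)
            if train_idx.size == 0:
                continue
            pred = _predict_one(spec, train_idx, v, sim, y, enc)
            errs.append(pred - y[v])
        if errs:
            rmse = float(np.sqrt(np.mean(np.square(errs))))
        else:
            rmse = float("nan")
        rmses.append(rmse)
        folds.append(float(np.exp(rmse)))
        counts.append(len(errs))
    if all(c == 0 for c in counts):
        raise ValueError("no evaluable targets at any threshold")
    return CVResult(
        model=spec.kind,
        thresholds=thresholds,
        rmse_ln=rmses,
        fold_error=folds,
        n_evaluable=counts,
    )


# ---------------------------------------------------------------------------
# Per-form prediction of uncharacterized variants
# ---------------------------------------------------------------------------

@dataclass
class PredictionSet:
    """Back-transformed rate predictions for uncharacterized variants."""

    predictions: pd.DataFrame  # variant_id, form, predicted_kcat_c, fold_error, model
    skipped: pd.DataFrame      # variant_id, form, reason

    def to_frame(self) -> pd.DataFrame:
        return self.predictions


def predict_all(
    aln: AlignedSeqSet,
    ln_rates: Mapping[str, float],
    spec: ModelSpec,
    min_train: int = 3,
    fold_errors: Mapping[str, float] | None = None,
    cv_threshold: float = 0.0,
) -> PredictionSet:
    """Predict rates for every uncharacterized variant, one model per form.

    Training uses only characterized variants of the same form; forms
    with fewer than ``min_train`` characterized members (or an unknown
    label) are refused rather than extrapolated.  Each prediction
    carries the fold-change error of its form's LOO cross-validation
    (at ``cv_threshold``) unless explicit ``fold_errors`` are supplied.
    Predicted rates are returned in s^-1 (exp of the modelled ln-rate).
    """
    char_idx = [i for i, c in enumerate(aln.characterized) if c]
    unchar_idx = [i for i, c in enumerate(aln.characterized) if not c]
    if not char_idx:
        raise ValueError("no characterized variants to train on")
    sim = identity_matrix(aln)
    y_by_id = dict(ln_rates)
    rows, skipped = [], []
    forms_present = sorted({aln.form[i] for i in unchar_idx})
    for form in forms_present:
        train = [i for i in char_idx if aln.form[i] == form]
        targets = [i for i in unchar_idx if aln.form[i] == form]
        if form == "unknown" or len(train) < min_train:
            reason = (
                "unknown form" if form == "unknown" else f"fewer than {min_train} characterized"
            )
            skipped.extend((aln.ids[i], form, reason) for i in targets)
            continue
        train_idx = np.array(train)
        y_train = np.array([y_by_id[aln.ids[i]] for i in train_idx])
        if fold_errors is not None and form in fold_errors:
            fe = float(fold_errors[form])
        else:
            sub = aln.subset(train)
            cv = loo_crossval(
                sub,
                {aln.ids[i]: y_by_id[aln.ids[i]] for i in train},
                spec,
                thresholds=[cv_threshold],
            )
            fe = cv.fold_error[0]
        enc = one_hot_encode(aln) if spec.kind == "svr_rbf" else None
        if spec.kind == "svr_rbf" and len(train) >= 2:
            model = fit_svr(enc.X[train_idx], y_train, spec)
            preds = model.predict(enc.X[np.array(targets)])
            for i, p in zip(targets, preds):
                rows.append((aln.ids[i], form, float(np.exp(p)), fe, spec.kind))
        else:
            y_full = np.array(
                [y_by_id.get(aln.ids[i], np.nan) for i in range(len(aln))]
            )
            for i in targets:
                p = _predict_one(spec, train_idx, i, sim, y_full, enc)
                rows.append((aln.ids[i], form, float(np.exp(p)), fe, spec.kind))
    predictions = pd.DataFrame(
        rows, columns=["variant_id", "form", "predicted_kcat_c", "fold_error", "model"]
    )
    skipped_df = pd.DataFrame(skipped, columns=["variant_id", "form", "reason"])
    return PredictionSet(predictions=predictions, skipped=skipped_df)
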