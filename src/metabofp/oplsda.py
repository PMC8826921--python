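"""Two-class OPLS-DA: one predictive latent component plus orthogonal filtering.

For a two-class problem the discriminant needs a single predictive component;
systematic variation uncorrelated with class membership is removed first as a
sequence of orthogonal components (NIPALS-style single-response algorithm).
With ``n_ortho = 0`` the model coincides exactly with one-component PLS1, and
with ``n_ortho = k`` its predictions equal those of a (k+1)-component PLS1
model — a classical equivalence used as an oracle in the test suite.

Columns are centered and unit-variance scaled inside the model (state stored
and reapplied at prediction time); rows are never normalised. Class coding is
control=-1 / case=+1 with decision threshold 0; a tied score is assigned to
the control class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class LabelError(ValueError):
    pass


class RankError(ValueError):
    pass


class DimensionError(ValueError):
    pass


@dataclass
class OplsModel:
    """Fitted OPLS-DA discriminant.

    Attributes mirror the algorithm: predictive weights ``w`` (unit norm),
    predictive loadings ``p``, scalar y-loading ``q``; per-orthogonal-component
    weights ``W_o`` and loadings ``P_o`` (rows); fit-time column means/sds and
    the mask of retained (non-constant) columns.
    """

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray
    w: np.ndarray
    p: np.ndarray
    q: float
    W_o: np.ndarray  # (n_ortho, p)
    P_o: np.ndarray  # (n_ortho, p)
    n_ortho: int
    control_label: object
    case_label: object
    threshold: float = 0.0
    scores_train: np.ndarray = field(default=None, repr=False)
    ortho_scores_train: np.ndarray = field(default=None, repr=False)

    @property
    def class_codes(self) -> dict:
        return {self.control_label: -1.0, self.case_label: 1.0}


def _encode_labels(y, positive_class=None):
    y = np.asarray(y)
    classes = sorted(map(str, set(y.tolist())))
    if len(classes) != 2:
        raise LabelError(f"need exactly two classes, got {classes}")
    if positive_class is None:
        control, case = classes[0], classes[1]
    else:
        positive_class = str(positive_class)
        if positive_class not in classes:
            raise LabelError(f"positive class {positive_class!r} not in {classes}")
        case = positive_class
        control = [c for c in classes if c != case][0]
    coded = np.where(np.asarray(y).astype(str) == case, 1.0, -1.0)
    return coded, control, case


def fit_oplsda(X: np.ndarray, y, n_ortho: int = 0, positive_class=None) -> OplsModel:
    """Fit OPLS-DA on samples x features ``X`` and two-class labels ``y``.

    ``n_ortho`` orthogonal components are extracted and deflated before the
    single predictive component. ``positive_class`` selects which label is
    coded +1 (default: lexicographically larger label).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionError("X must be 2-D")
    n, p = X.shape
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if n <= n_ortho + 1:
        raise RankError(f"{n} rows cannot support {n_ortho} orthogonal components")
    coded, control, case = _encode_labels(y, positive_class)
    if len(coded) != n:
        raise DimensionError("y length must match X rows")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    kept = sd > 0
    Xs = (X[:, kept] - mean[kept]) / sd[kept]
    yv = coded.copy()

    W_o, P_o, T_o = [], [], []
    Xd = Xs
    for _ in range(int(n_ortho)):
        wy = Xd.T @ yv
        nw = np.linalg.norm(wy)
        if nw < 1e-12:
            raise RankError("class covariance vanished; n_ortho too large for this data")
        w = wy / nw
        t = Xd @ w
        pl = Xd.T @ t / (t @ t)
        w_o = pl - (w @ pl) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            raise RankError("no orthogonal variation left; reduce n_ortho")
        w_o = w_o / n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    wy = Xd.T @ yv
    nw = np.linalg.norm(wy)
    if nw < 1e-12:
        raise RankError("predictive weight vanished")
    w = wy / nw
    t = Xd @ w
    pl = Xd.T @ t / (t @ t)
    q = float(yv @ t / (t @ t))

    return OplsModel(
        mean=mean,
        sd=sd,
        kept=kept,
        w=w,
        p=pl,
        q=q,
        W_o=np.array(W_o) if W_o else np.zeros((0, int(kept.sum()))),
        P_o=np.array(P_o) if P_o else np.zeros((0, int(kept.sum()))),
        n_ortho=int(n_ortho),
        control_label=control,
        case_label=case,
        scores_train=t,
        ortho_scores_train=np.array(T_o).T if T_o else np.zeros((n, 0)),
    )


def _filtered_scores(model: OplsModel, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply stored scaling, strip orthogonal variation, return (t, T_o)."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim == 1:
        Xnew = Xnew[None, :]
    if Xnew.shape[1] != model.mean.size:
        raise DimensionError(
            f"feature count {Xnew.shape[1]} does not match fit ({model.mean.size})"
        )
    k = model.kept
    Xd = (Xnew[:, k] - model.mean[k]) / model.sd[k]
    T_o = np.zeros((Xd.shape[0], model.n_ortho))
    for i in range(model.n_ortho):
        t_o = Xd @ model.W_o[i]
        Xd = Xd - np.outer(t_o, model.P_o[i])
        T_o[:, i] = t_o
    return Xd @ model.w, T_o


def predict_oplsda(model: OplsModel, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted scores yhat and class labels for new samples.

    yhat = t * q after orthogonal filtering; label = case if yhat > threshold
    else control (ties to control).
    """
    t, _ = _filtered_scores(model, Xnew)
    yhat = t * model.q
    labels = np.where(yhat > model.threshold, model.case_label, model.control_label)
    return yhat, labels


def project(model: OplsModel, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score-plot coordinates (t, t_o1) for external samples.

    ``t`` is identical to the score underlying :func:`predict_oplsda`. With
    ``n_ortho = 0`` there is no orthogonal axis; zeros are returned with a
    warning.
    """
    t, T_o = _filtered_scores(model, Xnew)
    if model.n_ortho == 0:
        warnings.warn("model has no orthogonal component; t_o1 reported as zeros", stacklevel=2)
        return t, np.zeros_like(t)
    return t, T_o[:, 0]
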