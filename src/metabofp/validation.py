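"""Monte-Carlo repeated twofold cross-validation (2CV) for OPLS-DA models.

Two nested resampling loops: the inner loop (CV1) picks the number of
orthogonal components by repeated stratified 80/20 splits of the training
part; the outer loop (CV2) repeatedly holds out a stratified 10% test split,
fits the selected model on the remaining 90% and records accuracy,
sensitivity and specificity. Summaries are the mean and the percentile 95%
interval (2.5th/97.5th) across outer repetitions.

For unbalanced group sizes, :func:`balanced_subsample_cv` first equalises the
groups by random subsampling of the larger group, repeating the whole outer
step over many balanced draws and averaging.

All randomness flows from a single master seed; each repetition draws its
own child generator deterministically, so identical configuration and seed
give identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .oplsda import OplsModel, fit_oplsda, predict_oplsda

logger = logging.getLogger(__name__)


class StratificationError(ValueError):
    pass


@dataclass(frozen=True)
class CvConfig:
    outer_repetitions: int = 100
    outer_test_fraction: float = 0.10
    inner_repetitions: int = 50
    inner_validation_fraction: float = 0.20
    max_ortho: int = 5
    seed: int = 0
    positive_class: str = "dn2PD"

    def __post_init__(self) -> None:
        if not (0 < self.outer_test_fraction < 1 and 0 < self.inner_validation_fraction < 1):
            raise ValueError("fractions must be in (0, 1)")
        if self.outer_repetitions < 1 or self.inner_repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.max_ortho < 0:
            raise ValueError("max_ortho must be >= 0")


@dataclass
class CvResult:
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    chosen_n_ortho: np.ndarray
    summary: dict = field(default_factory=dict)

    @staticmethod
    def _ci(v: np.ndarray) -> tuple[float, float, float]:
        return float(np.mean(v)), float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))

    def summarize(self) -> dict:
        out = {}
        for name, v in (
            ("accuracy", self.accuracy),
            ("sensitivity", self.sensitivity),
            ("specificity", self.specificity),
        ):
            mean, lo, hi = self._ci(v)
            out[name] = {"mean": mean, "ci95_low": lo, "ci95_high": hi}
        out["n_repetitions"] = int(self.accuracy.size)
        out["median_n_ortho"] = float(np.median(self.chosen_n_ortho))
        self.summary = out
        return out


def classification_metrics(true_labels, predicted_labels, positive_class) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) by the standard definitions.

    Sensitivity is recall on the positive class, specificity recall on the
    negative class.
    """
    t = np.asarray(true_labels).astype(str)
    p = np.asarray(predicted_labels).astype(str)
    if t.size == 0 or t.size != p.size:
        raise ValueError("labels must be nonempty and equally long")
    pos = str(positive_class)
    if not np.any(t == pos):
        raise StratificationError(f"positive class {pos!r} absent; sensitivity undefined")
    correct = t == p
    accuracy = float(np.mean(correct))
    sensitivity = float(np.mean(correct[t == pos]))
    neg = t != pos
    specificity = float(np.mean(correct[neg])) if np.any(neg) else float("nan")
    return accuracy, sensitivity, specificity


def _stratified_split(y: np.ndarray, test_fraction: float, rng: np.random.Generator):
    """Indices (train, test) of a stratified random split; every class keeps
    presence in both parts (>= 1 test member, >= 2 train members)."""
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 3:
            raise StratificationError(f"class {cls!r} has fewer than 3 members")
        perm = rng.permutation(idx)
        n_test = max(1, int(round(test_fraction * idx.size)))
        n_test = min(n_test, idx.size - 2)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def inner_component_selection(X: np.ndarray, y, cfg: CvConfig, rng: np.random.Generator) -> int:
    """CV1: pick n_ortho in 0..max_ortho by mean accuracy over repeated
    stratified inner splits; ties go to the smallest n_ortho."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise StratificationError(f"need two classes, got {classes.tolist()}")
    if counts.min() < 2:
        raise StratificationError("each class needs >= 2 members for stratified splits")
    candidates = list(range(cfg.max_ortho + 1))
    acc = np.zeros((len(candidates), cfg.inner_repetitions))
    for r in range(cfg.inner_repetitions):
        tr, va = _stratified_split(y, cfg.inner_validation_fraction, rng)
        for ci, k in enumerate(candidates):
            if X[tr].shape[0] <= k + 1:
                acc[ci, r] = 0.0
                continue
            try:
                model = fit_oplsda(X[tr], y[tr], n_ortho=k, positive_class=cfg.positive_class)
            except Exception:
                acc[ci, r] = 0.0
                continue
            _, pred = predict_oplsda(model, X[va])
            acc[ci, r] = float(np.mean(pred.astype(str) == y[va]))
    mean_acc = acc.mean(axis=1)
    return int(candidates[int(np.argmax(mean_acc))])  # argmax takes first max: smallest k


def _one_outer_repetition(X, y, cfg: CvConfig, rng) -> tuple[float, float, float, int]:
    for _ in range(100):
        tr, te = _stratified_split(y, cfg.outer_test_fraction, rng)
        if np.unique(y[te]).size == 2 and np.unique(y[tr]).size == 2:
            break
        logger.info("resampling split that left a class empty")
    else:  # pragma: no cover - stratified splits always keep both classes
        raise StratificationError("could not produce a valid split")
    k = inner_component_selection(X[tr], y[tr], cfg, rng)
    model = fit_oplsda(X[tr], y[tr], n_ortho=k, positive_class=cfg.positive_class)
    _, pred = predict_oplsda(model, X[te])
    a, se, sp = classification_metrics(y[te], pred, cfg.positive_class)
    return a, se, sp, k


def mc_2cv(X: np.ndarray, y, cfg: CvConfig | None = None) -> CvResult:
    """CV2: repeated stratified 90/10 outer splits around CV1 model selection.

    Returns per-repetition metric vectors and their mean / percentile 95% CI.
    """
    cfg = cfg or CvConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise StratificationError(f"need two classes, got {classes.tolist()}")
    ss = np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 303])
    children = ss.spawn(cfg.outer_repetitions)
    acc = np.zeros(cfg.outer_repetitions)
    sen = np.zeros(cfg.outer_repetitions)
    spe = np.zeros(cfg.outer_repetitions)
    cho = np.zeros(cfg.outer_repetitions, dtype=int)
    for r in range(cfg.outer_repetitions):
        rng = np.random.default_rng(children[r])
        acc[r], sen[r], spe[r], cho[r] = _one_outer_repetition(X, y, cfg, rng)
    res = CvResult(accuracy=acc, sensitivity=sen, specificity=spe, chosen_n_ortho=cho)
    res.summarize()
    return res


def balanced_subsample_cv(X: np.ndarray, y, cfg: CvConfig | None = None, n_models: int = 100) -> CvResult:
    """Equal-size modelling of unequal groups.

    Each of ``n_models`` draws subsamples the larger group (without
    replacement) down to the smaller group's size, then runs one outer 2CV
    repetition (inner selection + fit + held-out test) on the balanced
    subset; metrics are averaged across the models.
    """
    cfg = cfg or CvConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise StratificationError(f"need two classes, got {classes.tolist()}")
    n_small = int(counts.min())
    if n_small < 4:
        raise StratificationError("smaller group has fewer than 4 members")
    ss = np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 404])
    children = ss.spawn(n_models)
    acc = np.zeros(n_models)
    sen = np.zeros(n_models)
    spe = np.zeros(n_models)
    cho = np.zeros(n_models, dtype=int)
    for r in range(n_models):
        rng = np.random.default_rng(children[r])
        keep = []
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            keep.append(rng.choice(idx, size=n_small, replace=False) if idx.size > n_small else idx)
        keep = np.sort(np.concatenate(keep))
        acc[r], sen[r], spe[r], cho[r] = _one_outer_repetition(X[keep], y[keep], cfg, rng)
    res = CvResult(accuracy=acc, sensitivity=sen, specificity=spe, chosen_n_ortho=cho)
    res.summarize()
    return res


def external_validation(model: OplsModel, X_test: np.ndarray, y_test, positive_class) -> dict:
    """Blind projection of an external cohort onto a fitted model.

    No refitting: predictions use the frozen scaling and components; the test
    labels enter only after prediction, for scoring.
    """
    _, pred = predict_oplsda(model, np.asarray(X_test, dtype=float))
    a, se, sp = classification_metrics(y_test, pred, positive_class)
    return {"accuracy": a, "sensitivity": se, "specificity": sp, "n": int(len(pred))}
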