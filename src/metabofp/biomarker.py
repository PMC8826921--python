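"""Single-analyte biomarker assessment.

Each candidate analyte is standardised by centering and dividing by two
standard deviations (so its logistic coefficient is comparable to that of a
binary predictor), used as the sole predictor of disease status in a
binomial logistic regression, and scored by ROC AUC on the training fit and
on blind predictions for a validation cohort. Standardisation parameters and
regression coefficients are frozen on the training cohort before any
validation sample is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import ConcentrationTable
from .univariate import bh_adjust


class DegeneratePredictorError(ValueError):
    pass


class SeparationError(RuntimeError):
    """Perfect separation: the ML estimate diverges."""


def rescale_2sd(x) -> tuple[np.ndarray, float, float]:
    """(x - mean) / (2 * sd); returns the standardized vector and the
    training (mean, sd) for reuse on new data."""
    x = np.asarray(x, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd <= 0:
        raise DegeneratePredictorError("constant predictor cannot be standardized")
    return (x - mean) / (2.0 * sd), mean, sd


def fit_logistic(x, y) -> dict:
    """ML fit of logit P(case) = b0 + b1*x by IRLS.

    Returns coefficients, Wald standard error and p-value for b1, the odds
    ratio exp(b1) and its 95% Wald CI. Perfect separation (coefficient norm
    exploding on the 2-SD scale) raises :class:`SeparationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=50, tol=1e-10)
    b0, b1 = res.params
    if abs(b1) > 20.0 or not np.all(np.isfinite(res.bse)):
        raise SeparationError("perfect separation detected (|b1| > 20 on the 2-SD scale)")
    se = float(res.bse[1])
    return {
        "beta0": float(b0),
        "beta1": float(b1),
        "se": se,
        "p_value": float(res.pvalues[1]),
        "odds_ratio": float(np.exp(b1)),
        "or_ci_low": float(np.exp(b1 - 1.96 * se)),
        "or_ci_high": float(np.exp(b1 + 1.96 * se)),
    }


def predict_probability(fit: dict, x_std: np.ndarray) -> np.ndarray:
    z = fit["beta0"] + fit["beta1"] * np.asarray(x_std, dtype=float)
    return 1.0 / (1.0 + np.exp(-z))


def roc_auc(scores, labels) -> float:
    """AUC = P(score_case > score_control) + 0.5 * P(tie), via the rank
    (Mann-Whitney U) statistic."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined with a single class")
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = pd.Series(s).rank(method="average").to_numpy()
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class BiomarkerResult:
    table: pd.DataFrame
    case_group: str
    control_group: str


def biomarker_panel(
    train: ConcentrationTable,
    test: ConcentrationTable | None,
    analytes: list[str],
    case_group: str,
    control_group: str,
    sex_filter: str | None = None,
    freeze_standardization: bool = True,
) -> BiomarkerResult:
    """Fit one logistic model per analyte on the training stratum and score
    training and validation AUCs; BH-adjust the panel's p-values.

    ``freeze_standardization`` (default) reuses the training (mean, sd) for
    the validation cohort, keeping the prediction fully blind; per-cohort
    re-standardisation is available for sensitivity analysis.
    """
    def _stratum(tab: ConcentrationTable):
        groups = np.array([m.group for m in tab.meta])
        sexes = np.array([m.sex for m in tab.meta])
        mask = np.isin(groups, [case_group, control_group])
        if sex_filter is not None:
            mask &= sexes == sex_filter
        y = (groups[mask] == case_group).astype(float)
        return tab.values[mask], y

    for name in analytes:
        if name not in train.analyte_names:
            raise KeyError(f"analyte {name!r} missing from training table")
        if test is not None and name not in test.analyte_names:
            raise KeyError(f"analyte {name!r} missing from validation table")

    Xtr, ytr = _stratum(train)
    if np.unique(ytr).size < 2:
        raise ValueError("training stratum must contain both groups")
    Xte, yte = _stratum(test) if test is not None else (None, None)

    rows = []
    for name in analytes:
        j = train.analyte_names.index(name)
        x_std, mean, sd = rescale_2sd(Xtr[:, j])
        try:
            fit = fit_logistic(x_std, ytr)
            separated = False
        except SeparationError:
            rows.append(
                {"analyte": name, "odds_ratio": np.nan, "or_ci_low": np.nan,
                 "or_ci_high": np.nan, "p_value": np.nan, "auc_training": np.nan,
                 "auc_test": np.nan, "mean": mean, "sd": sd, "separation": True}
            )
            continue
        p_tr = predict_probability(fit, x_std)
        auc_tr = roc_auc(p_tr, ytr)
        auc_te = np.nan
        if Xte is not None:
            jt = test.analyte_names.index(name)
            if freeze_standardization:
                x_te = (Xte[:, jt] - mean) / (2.0 * sd)
            else:
                x_te, _, _ = rescale_2sd(Xte[:, jt])
            auc_te = roc_auc(predict_probability(fit, x_te), yte)
        rows.append(
            {"analyte": name, "odds_ratio": fit["odds_ratio"],
             "or_ci_low": fit["or_ci_low"], "or_ci_high": fit["or_ci_high"],
             "p_value": fit["p_value"], "auc_training": auc_tr, "auc_test": auc_te,
             "mean": mean, "sd": sd, "separation": separated}
        )
    df = pd.DataFrame(rows)
    ok = df["p_value"].notna()
    fdr = np.full(len(df), np.nan)
    if ok.any():
        fdr[ok.to_numpy()] = bh_adjust(df.loc[ok, "p_value"].to_numpy())
    df["fdr"] = fdr
    df = df[
        ["analyte", "odds_ratio", "or_ci_low", "or_ci_high", "p_value", "fdr",
         "auc_training", "auc_test", "mean", "sd", "separation"]
    ]
    return BiomarkerResult(table=df, case_group=case_group, control_group=control_group)
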