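"""End-to-end study replica.

One call runs the whole analysis on a synthetic study population:

1. simulate training and validation cohorts (concentrations + spectra);
2. bucket the spectra (0.02 ppm, water window excluded) and run exploratory
   PCA on unit-variance-scaled buckets;
3. fingerprint dn2PD vs CTR by OPLS-DA with Monte-Carlo 2CV — overall,
   male-only and female-only strata, using balanced subsampling whenever the
   two groups differ in size;
4. blindly project the validation cohort onto each stratum's training model
   and score it; project the advPD samples (never used for fitting) onto the
   overall model;
5. univariate profiling of the training males and females;
6. single-analyte biomarker panel (training males -> validation males) on the
   analytes flagged by the univariate stage;
7. top-30 Ward/Pearson heatmap over the combined cohorts.

Every stage draws its seed deterministically from one master seed by hashing
the stage name, so a report is byte-identical under the same config.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from . import analytes as A
from .biomarker import biomarker_panel
from .oplsda import fit_oplsda, predict_oplsda
from .profiling import heatmap_summary, linkage_to_newick
from .spectra import BucketSpec, build_bucket_matrix, pca, unit_variance_scale
from .synthetic import (
    ConcentrationTable,
    simulate_cohort,
    simulate_spectra,
    study_config,
)
from .univariate import univariate_profile
from .validation import CvConfig, balanced_subsample_cv, external_validation, mc_2cv
from .validation import inner_component_selection

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cv": {
        "outer_repetitions": 100,
        "inner_repetitions": 50,
        "max_ortho": 5,
        "outer_test_fraction": 0.10,
        "inner_validation_fraction": 0.20,
    },
    "n_balanced_models": 100,
    "spectra_noise_sd": 5e-4,
    "heatmap_k": 30,
    "effects": {},  # kwargs for study_effect_table
}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed: master combined with a stable hash
    of the stage name (always below 2**31)."""
    return (int(master) * 1000003 + zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays so the report is plain JSON."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _merge(base: Mapping, override: Mapping | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _stratum_mask(meta, sex: str | None, groups=("dn2PD", "CTR")) -> np.ndarray:
    m = np.array([mm.group in groups for mm in meta])
    if sex is not None:
        m &= np.array([mm.sex == sex for mm in meta])
    return m


def fingerprint_stratum(bm_values, meta, cv_cfg: CvConfig, n_balanced_models: int,
                        sex: str | None) -> dict:
    """MC-2CV fingerprint for one stratum; balanced subsampling when the two
    group sizes differ (they do at the study's sizes)."""
    mask = _stratum_mask(meta, sex)
    X = bm_values[mask]
    y = np.array([m.group for m in meta])[mask]
    counts = {str(g): int((y == g).sum()) for g in np.unique(y)}
    balanced = len(set(counts.values())) > 1
    if balanced:
        res = balanced_subsample_cv(X, y, cv_cfg, n_models=n_balanced_models)
    else:
        res = mc_2cv(X, y, cv_cfg)
    out = res.summarize()
    out["group_sizes"] = counts
    out["balanced_subsampling"] = balanced
    return out


def _final_model(bm_values, meta, cv_cfg: CvConfig, sex: str | None):
    """Single training model on the full stratum (used for blind projection);
    n_ortho chosen by the inner selection loop on the full training data."""
    mask = _stratum_mask(meta, sex)
    X = bm_values[mask]
    y = np.array([m.group for m in meta])[mask]
    rng = np.random.default_rng(np.random.SeedSequence([cv_cfg.seed, 777]))
    k = inner_component_selection(X, y, cv_cfg, rng)
    return fit_oplsda(X, y, n_ortho=k, positive_class=cv_cfg.positive_class), k


def run_pipeline(config: Mapping | None = None, out_dir: str | Path | None = None) -> dict:
    """Execute the full study replica and return the run report dict.

    ``config`` overrides :data:`DEFAULT_CONFIG` (nested keys merge). When
    ``out_dir`` is given, the report and the main tables are written there.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    master = int(cfg["seed"])
    report: dict = {"config": cfg, "version": __version__, "stages": {}}

    # -- stage 1: cohorts ----------------------------------------------------
    eff = dict(cfg["effects"])
    train_cfg = study_config("training", seed=stage_seed(master, "simulate/training"), **eff)
    valid_cfg = study_config("validation", seed=stage_seed(master, "simulate/validation"), **eff)
    train_tab, train_meta = simulate_cohort(train_cfg)
    valid_tab, valid_meta = simulate_cohort(valid_cfg)
    report["stages"]["simulate"] = {
        "n_training": len(train_meta),
        "n_validation": len(valid_meta),
        "n_analytes": len(train_tab.analyte_names),
    }

    # -- stage 2: spectra + buckets -----------------------------------------
    noise = float(cfg["spectra_noise_sd"])
    spec = BucketSpec()
    tr_spectra = simulate_spectra(train_tab, noise_sd=noise,
                                  seed=stage_seed(master, "spectra/training"))
    va_spectra = simulate_spectra(valid_tab, noise_sd=noise,
                                  seed=stage_seed(master, "spectra/validation"))
    bm_train = build_bucket_matrix(tr_spectra, train_meta, spec)
    bm_valid = build_bucket_matrix(va_spectra, valid_meta, spec)
    report["stages"]["bucket"] = {
        "n_buckets": int(bm_train.values.shape[1]),
        "width_ppm": spec.width_ppm,
        "exclusions": [list(e) for e in spec.exclusions],
    }

    # -- stage 3: exploratory PCA -------------------------------------------
    all_vals = np.vstack([bm_train.values, bm_valid.values])
    scaled, _ = unit_variance_scale(all_vals)
    p = pca(scaled, n_components=3)
    report["stages"]["pca"] = {
        "explained_variance_ratio": p.explained_variance_ratio.tolist()
    }

    # -- stage 4: fingerprint + validation ----------------------------------
    cv_kwargs = dict(cfg["cv"])
    n_models = int(cfg["n_balanced_models"])
    strata = {"overall": None, "male": "M", "female": "F"}
    fp: dict = {}
    ext: dict = {}
    models = {}
    for name, sex in strata.items():
        cv_cfg = CvConfig(seed=stage_seed(master, f"cv/{name}"), **cv_kwargs)
        fp[name] = fingerprint_stratum(bm_train.values, train_meta, cv_cfg, n_models, sex)
        model, k = _final_model(bm_train.values, train_meta, cv_cfg, sex)
        models[name] = model
        vmask = _stratum_mask(valid_meta, sex)
        ext[name] = external_validation(
            model, bm_valid.values[vmask],
            np.array([m.group for m in valid_meta])[vmask], "dn2PD",
        )
        ext[name]["n_ortho"] = k
    report["stages"]["fingerprint"] = fp
    report["stages"]["external_validation"] = ext

    # -- advPD projection (never in training) --------------------------------
    adv_mask = np.array([m.group == "advPD" for m in valid_meta])
    _, adv_labels = predict_oplsda(models["overall"], bm_valid.values[adv_mask])
    frac_pd = float(np.mean(np.asarray(adv_labels).astype(str) == "dn2PD"))
    report["stages"]["advpd_projection"] = {
        "n_advpd": int(adv_mask.sum()),
        "fraction_classified_pd": frac_pd,
    }

    # -- stage 5: univariate --------------------------------------------------
    uni = {}
    uni_results = {}
    for name, sex in (("male", "M"), ("female", "F")):
        res = univariate_profile(train_tab, "dn2PD", "CTR", sex_filter=sex)
        uni_results[name] = res
        sig = res.significant
        uni[name] = {
            "n_significant": int(len(sig)),
            "significant_analytes": sig["analyte"].tolist(),
        }
    report["stages"]["univariate"] = uni

    # -- stage 6: biomarker panel (training males -> validation males) --------
    sig_names = uni_results["male"].significant["analyte"].tolist()
    bio_rows = []
    if sig_names:
        bio = biomarker_panel(train_tab, valid_tab, sig_names, "dn2PD", "CTR", sex_filter="M")
        bio_rows = bio.table.drop(columns=["mean", "sd"]).to_dict(orient="records")
    report["stages"]["biomarker"] = {"n_analytes": len(sig_names), "panel": bio_rows}

    # -- stage 7: heatmap ------------------------------------------------------
    combined = ConcentrationTable(
        np.vstack([train_tab.values, valid_tab.values]),
        list(train_tab.analyte_names),
        list(train_meta) + list(valid_meta),
    )
    hm = heatmap_summary(combined, ["CTR", "dn2PD", "advPD"], k=int(cfg["heatmap_k"]))
    report["stages"]["heatmap"] = {
        "analytes": hm.analytes,
        "group_means": hm.group_means.round(4).to_dict(orient="index"),
        "col_tree_newick": linkage_to_newick(hm.col_linkage, list(hm.group_means.columns)),
    }

    report = _jsonable(report)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from . import io as mio

        mio.write_meta(train_meta, out / "training_meta.tsv")
        mio.write_meta(valid_meta, out / "validation_meta.tsv")
        mio.write_concentrations(train_tab, out / "training_concentrations.csv")
        mio.write_concentrations(valid_tab, out / "validation_concentrations.csv")
        uni_results["male"].table.to_csv(out / "univariate_male.tsv", sep="\t", index=False)
        uni_results["female"].table.to_csv(out / "univariate_female.tsv", sep="\t", index=False)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
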