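#!/usr/bin/env python
"""Blind projection of the validation cohort and the advPD group.

Fits one OPLS-DA model per stratum on the full training buckets (number of
orthogonal components chosen by the inner selection loop), then projects the
never-seen validation samples onto it and scores accuracy / sensitivity /
specificity. The 22 advPD samples — excluded from every fit — are projected
onto the overall dn2PD-vs-CTR model and the fraction labelled PD is
reported, mirroring the study's progression check.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import metabofp as m
from metabofp.oplsda import predict_oplsda
from metabofp.pipeline import _final_model, _stratum_mask, stage_seed
from metabofp.validation import CvConfig, external_validation

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    table, meta = m.simulate_cohort(
        m.study_config("training", seed=stage_seed(args.seed, "simulate/training"))
    )
    bm = m.build_bucket_matrix(
        m.simulate_spectra(table, noise_sd=5e-4,
                           seed=stage_seed(args.seed, "spectra/training")), meta
    )
    vtab, vmeta = m.simulate_cohort(
        m.study_config("validation", seed=stage_seed(args.seed, "simulate/validation"))
    )
    vbm = m.build_bucket_matrix(
        m.simulate_spectra(vtab, noise_sd=5e-4,
                           seed=stage_seed(args.seed, "spectra/validation")), vmeta
    )
    vgroups = np.array([mm.group for mm in vmeta])

    results = {}
    model_overall = None
    for name, sex in (("overall", None), ("male", "M"), ("female", "F")):
        cfg = CvConfig(seed=stage_seed(args.seed, f"cv/{name}"))
        model, k = _final_model(bm.values, meta, cfg, sex)
        if name == "overall":
            model_overall = model
        mask = _stratum_mask(vmeta, sex)
        res = external_validation(model, vbm.values[mask], vgroups[mask], "dn2PD")
        res["n_ortho"] = k
        results[name] = res
        print(f"{name:8s} n_test={res['n']}  accuracy {100 * res['accuracy']:.1f}%  "
              f"sensitivity {100 * res['sensitivity']:.1f}%  "
              f"specificity {100 * res['specificity']:.1f}%  (n_ortho={k})")

    adv = vgroups == "advPD"
    _, labels = predict_oplsda(model_overall, vbm.values[adv])
    frac = float(np.mean(np.asarray(labels) == "dn2PD"))
    results["advpd_projection"] = {"n": int(adv.sum()), "fraction_classified_pd": frac}
    print(f"advPD projection: {100 * frac:.1f}% of {int(adv.sum())} labelled PD")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    with open(out / "external_validation.json", "w") as fh:
        json.dump({"seed": args.seed, **results}, fh, indent=2)
    print(f"wrote {out / 'external_validation.json'}")


if __name__ == "__main__":
    main()
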