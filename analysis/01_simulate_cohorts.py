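#!/usr/bin/env python
"""Generate the synthetic study population.

Draws the training cohort (72 dn2PD vs 59 CTR) and the validation cohort
(156 dn2PD, 20 CTR, 22 advPD) at the study's group/sex sizes, with the male
disease signature (acetone/ornithine/phenylalanine up, the 23-lipoprotein
LDL panel down), damped female effects and an amplified advPD progression
pattern. Raw per-sample tables go to scratch/data/ (they are inputs for
inspection, not results); a compact cohort summary goes to results/.

All later drivers re-derive the same cohorts from the master seed via the
library, so they run standalone.
"""

import argparse
import json
from collections import Counter
from pathlib import Path

import metabofp as m
from metabofp import io as mio
from metabofp.pipeline import stage_seed

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    data_dir = ROOT / "scratch" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for cohort in ("training", "validation"):
        cfg = m.study_config(cohort, seed=stage_seed(args.seed, f"simulate/{cohort}"))
        table, meta = m.simulate_cohort(cfg)
        mio.write_meta(meta, data_dir / f"{cohort}_meta.tsv")
        mio.write_concentrations(table, data_dir / f"{cohort}_concentrations.csv")
        counts = Counter((mm.group, mm.sex) for mm in meta)
        summary[cohort] = {f"{g}/{s}": n for (g, s), n in sorted(counts.items())}
        print(f"{cohort}: {len(meta)} samples, {len(table.analyte_names)} analytes")
        for key, n in summary[cohort].items():
            print(f"  {key}: {n}")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    with open(out / "cohort_summary.json", "w") as fh:
        json.dump({"seed": args.seed, "cohorts": summary}, fh, indent=2)
    print(f"raw tables in {data_dir}, summary in {out / 'cohort_summary.json'}")


if __name__ == "__main__":
    main()
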