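"""Reproduction of the published training-cohort statistics from the study's
deposited concentration table.

The real metabolite/lipoprotein concentrations are distributed by the journal
as a supplementary spreadsheet; this module expects them re-saved as the
package's delimited formats (concentration CSV + metadata TSV, see
:mod:`metabofp.io`) and recomputes the male-stratum univariate profile
(expected: 26 analytes at FDR < 0.05) and the per-analyte logistic odds
ratios (ornithine ~10.7, phenylalanine ~9.28, acetone ~8.43).

The table is not bundled here — it must be downloaded from the journal and
converted by the user; :func:`reproduce_supplementary` raises
``FileNotFoundError`` with instructions when the files are absent.
"""

from __future__ import annotations

from pathlib import Path

from . import io as mio
from .biomarker import biomarker_panel
from .univariate import univariate_profile

DOWNLOAD_HINT = (
    "Supplementary concentration data not found. Download the study's "
    "Supplementary Data table from the journal, export it as "
    "<dir>/concentrations.csv (samples x analytes, sample_id index) and "
    "<dir>/meta.tsv (sample_id, group, sex, cohort), then rerun."
)


def reproduce_supplementary(data_dir: str | Path) -> dict:
    """Recompute the published male-stratum statistics from the deposited
    concentration table.

    Returns a dict with the FDR<0.05 analyte count for training males, the
    significant analyte list, and the odds ratios for ornithine,
    phenylalanine and acetone.
    """
    data_dir = Path(data_dir)
    conc = data_dir / "concentrations.csv"
    meta_path = data_dir / "meta.tsv"
    if not conc.exists() or not meta_path.exists():
        raise FileNotFoundError(DOWNLOAD_HINT)
    meta = mio.read_meta(meta_path)
    table = mio.read_concentrations(conc, meta)
    training = table.subset([m.cohort == "training" for m in table.meta])
    validation = table.subset([m.cohort == "validation" for m in table.meta])

    uni = univariate_profile(training, "dn2PD", "CTR", sex_filter="M")
    sig = uni.significant["analyte"].tolist()
    panel = biomarker_panel(
        training, validation if len(validation.meta) else None,
        sig, "dn2PD", "CTR", sex_filter="M",
    )
    ors = {
        row.analyte: row.odds_ratio
        for row in panel.table.itertuples()
        if row.analyte in ("Ornithine", "Phenylalanine", "Acetone")
    }
    return {
        "n_significant_male": len(sig),
        "significant_analytes": sig,
        "odds_ratios": ors,
        "univariate": uni.table,
        "panel": panel.table,
    }
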