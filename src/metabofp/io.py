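"""Delimited-text I/O for cohorts and spectra.

Formats: metadata TSV (sample_id, group, sex, cohort); concentration CSV
(samples x analytes, analyte-name header, sample_id index); spectra either as
two-column (ppm, intensity) TSV per sample or one wide CSV (first column ppm,
one column per sample).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum
from .synthetic import ConcentrationTable, SampleMeta


def write_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "group": [m.group for m in meta],
            "sex": [m.sex for m in meta],
            "cohort": [m.cohort for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)


def read_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "sex", "cohort"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return [
        SampleMeta(r.sample_id, r.group, r.sex, r.cohort) for r in df.itertuples(index=False)
    ]


def write_concentrations(table: ConcentrationTable, path: str | Path) -> None:
    table.to_frame().rename_axis("sample_id").to_csv(path)


def read_concentrations(path: str | Path, meta: Sequence[SampleMeta]) -> ConcentrationTable:
    df = pd.read_csv(path, index_col=0)
    ids = [m.sample_id for m in meta]
    missing = set(ids) - set(df.index.astype(str))
    if missing:
        raise ValueError(f"concentration table missing samples: {sorted(missing)[:5]}")
    df = df.loc[ids]
    if df.isna().any().any():
        raise ValueError("concentration table contains missing values")
    return ConcentrationTable(df.to_numpy(dtype=float), list(df.columns), list(meta))


def write_spectra_wide(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """One wide CSV: first column ppm, one intensity column per sample.
    Requires all spectra on a shared grid."""
    ppm = spectra[0].ppm
    for s in spectra[1:]:
        if s.ppm.shape != ppm.shape or not np.allclose(s.ppm, ppm):
            raise ValueError("wide format needs a shared ppm grid")
    df = pd.DataFrame({"ppm": ppm})
    for s in spectra:
        df[s.sample_id] = s.intensity
    df.to_csv(path, index=False)


def read_spectra_wide(path: str | Path) -> list[Spectrum]:
    df = pd.read_csv(path)
    if "ppm" not in df.columns:
        raise ValueError("wide spectra CSV needs a 'ppm' column")
    ppm = df["ppm"].to_numpy(dtype=float)
    return [
        Spectrum(ppm=ppm, intensity=df[c].to_numpy(dtype=float), sample_id=str(c))
        for c in df.columns
        if c != "ppm"
    ]


def write_spectrum_tsv(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"ppm": s.ppm, "intensity": s.intensity}).to_csv(path, sep="\t", index=False)


def read_spectrum_tsv(path: str | Path, sample_id: str | None = None) -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    return Spectrum(
        ppm=df.iloc[:, 0].to_numpy(dtype=float),
        intensity=df.iloc[:, 1].to_numpy(dtype=float),
        sample_id=sample_id or Path(path).stem,
    )
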