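"""Seeded synthetic cohorts: metadata, concentration tables and 1D spectra.

The generator emulates the statistical structure the downstream analysis
assumes for a serum NMR study of de novo drug-naive Parkinson's disease
(dn2PD) versus healthy controls (CTR), with an advanced-PD (advPD) group for
progression analyses:

* 27 metabolites + 111 lipoprotein parameters per sample, log-normal
  baselines with multiplicative group/sex effects (2**log2_shift);
* a single latent Gaussian factor shared by the lipoprotein parameters,
  reproducing their block-correlated co-movement;
* spectra as sums of concentration-weighted Lorentzian resonances plus broad
  lipoprotein envelopes, a fixed anomeric-glucose reference singlet at
  5.24 ppm, and i.i.d. Gaussian noise on a uniform ppm grid.

Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import analytes as A
from .spectra import Spectrum

GROUPS = ("CTR", "dn2PD", "advPD")
SEXES = ("M", "F")
COHORTS = ("training", "validation")

REFERENCE_PPM = 5.24  # anomeric glucose proton, calibration convention


class ConfigurationError(ValueError):
    pass


@dataclass
class SampleMeta:
    sample_id: str
    group: str
    sex: str
    cohort: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if self.cohort not in COHORTS:
            raise ConfigurationError(f"unknown cohort {self.cohort!r}")


@dataclass
class ConcentrationTable:
    """Samples x analytes positive concentration matrix with metadata."""

    values: np.ndarray
    analyte_names: list[str]
    meta: list[SampleMeta]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.meta), len(self.analyte_names)):
            raise ValueError("shape must be (n_samples, n_analytes)")
        if len(set(self.analyte_names)) != len(self.analyte_names):
            raise ValueError("analyte names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentrations must be finite")
        ids = [m.sample_id for m in self.meta]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=[m.sample_id for m in self.meta], columns=self.analyte_names
        )

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in self.meta],
                "group": [m.group for m in self.meta],
                "sex": [m.sex for m in self.meta],
                "cohort": [m.cohort for m in self.meta],
            }
        )

    def subset(self, mask: np.ndarray) -> "ConcentrationTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ConcentrationTable(
            self.values[idx], list(self.analyte_names), [self.meta[i] for i in idx]
        )


@dataclass
class CohortConfig:
    """Generative settings for one synthetic cohort.

    ``effect_table`` maps (group, sex) -> {analyte: log2 shift relative to the
    CTR baseline}; absent entries mean no shift. ``n_per_group_per_sex`` maps
    (group, sex) -> count. Lipoprotein parameters share a latent factor whose
    squared loading is ``lipoprotein_block_correlation``.
    """

    n_per_group_per_sex: Mapping[tuple[str, str], int]
    analyte_names: Sequence[str] = field(default_factory=lambda: list(A.ALL_ANALYTES))
    effect_table: Mapping[tuple[str, str], Mapping[str, float]] = field(default_factory=dict)
    baseline_log_mean: Mapping[str, float] | None = None
    baseline_log_sd: Mapping[str, float] | None = None
    lipoprotein_block_correlation: float = 0.5
    noise_sd: float = 5e-4
    cohort_label: str = "training"
    seed: int = 0

    def __post_init__(self) -> None:
        for key, n in self.n_per_group_per_sex.items():
            if key[0] not in GROUPS or key[1] not in SEXES:
                raise ConfigurationError(f"bad group/sex cell {key!r}")
            if int(n) < 0:
                raise ConfigurationError("counts must be >= 0")
        if len(set(self.analyte_names)) != len(self.analyte_names):
            raise ConfigurationError("analyte names must be unique")
        if not (0 <= self.lipoprotein_block_correlation < 1):
            raise ConfigurationError("lipoprotein_block_correlation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        for key, shifts in self.effect_table.items():
            if key[0] not in GROUPS or key[1] not in SEXES:
                raise ConfigurationError(f"bad effect_table cell {key!r}")
            unknown = set(shifts) - set(self.analyte_names)
            if unknown:
                raise ConfigurationError(f"effect_table names unknown analytes: {sorted(unknown)}")
        if self.baseline_log_sd is not None:
            if any(v <= 0 for v in self.baseline_log_sd.values()):
                raise ConfigurationError("baseline_log_sd must be positive")


# -- default baselines -------------------------------------------------------

#: plausible serum concentrations (mmol/L for metabolites; mg/dL-scale
#: numbers for lipoprotein parameters). Values anchor the log-normal
#: baselines; only ratios across groups matter downstream.
_METABOLITE_LEVELS: dict[str, float] = {
    "3-Hydroxybutyric acid": 0.08,
    "2-Aminobutyric acid": 0.02,
    "Acetic acid": 0.04,
    "Acetone": 0.03,
    "Alanine": 0.40,
    "Citric acid": 0.11,
    "Creatine": 0.04,
    "Creatinine": 0.07,
    "Formic acid": 0.03,
    "Glucose": 5.0,
    "Glutamic acid": 0.07,
    "Glutamine": 0.55,
    "Glycine": 0.25,
    "Histidine": 0.08,
    "Isoleucine": 0.06,
    "Lactic acid": 1.5,
    "Leucine": 0.12,
    "Methionine": 0.03,
    "N,N-Dimethylglycine": 0.005,
    "Ornithine": 0.06,
    "Phenylalanine": 0.06,
    "Proline": 0.18,
    "Pyruvic acid": 0.07,
    "Succinic acid": 0.01,
    "Threonine": 0.13,
    "Tyrosine": 0.06,
    "Valine": 0.22,
}


def default_baselines(names: Sequence[str]) -> tuple[dict[str, float], dict[str, float]]:
    """Log-scale (natural log) mean and sd per analyte.

    Metabolites get their tabulated typical levels with 25% log-sd;
    lipoprotein parameters get size-graded levels with 30% log-sd (serum
    lipids are the more variable panel).
    """
    log_mean: dict[str, float] = {}
    log_sd: dict[str, float] = {}
    for name in names:
        if name in _METABOLITE_LEVELS:
            log_mean[name] = float(np.log(_METABOLITE_LEVELS[name]))
            log_sd[name] = 0.25
        else:
            base = 60.0
            if name.startswith(("Cholesterol", "Triglycerides", "Phospholipids")):
                base = 180.0
            elif "/" in name:
                base = 2.0
            elif name.startswith("Apo") or "Apo" in name:
                base = 80.0
            log_mean[name] = float(np.log(base))
            log_sd[name] = 0.30
    return log_mean, log_sd


# -- effect tables -----------------------------------------------------------

def study_effect_table(
    male_up: float = 0.55,
    male_down: float = -0.5,
    female_scale: float = 0.25,
    advpd_scale: float = 1.6,
    progression_shift: float = -0.4,
    dn2pd_specific_up: float = 0.4,
) -> dict[tuple[str, str], dict[str, float]]:
    """Default log2 effect table mirroring the study's reported directions.

    Male dn2PD: acetone/ornithine/phenylalanine up, the 23-lipoprotein LDL
    panel down. Female effects are the male effects damped by
    ``female_scale`` (the female fingerprint is much weaker and yields no
    univariate findings at the study's sample size). advPD extends the dn2PD
    shifts monotonically and adds the progression analytes (citric acid,
    methionine, N,N-dimethylglycine, HDL/ApoA1 parameters) falling along
    CTR > dn2PD > advPD, while formic acid and histidine are elevated in
    dn2PD only.
    """
    table: dict[tuple[str, str], dict[str, float]] = {}
    male: dict[str, float] = {}
    for name in A.MALE_SIGNATURE_UP:
        male[name] = male_up
    for name in A.MALE_SIGNATURE_DOWN:
        male[name] = male_down
    for name in A.PROGRESSION_DOWN:
        male[name] = progression_shift / 2.0
    for name in A.DN2PD_SPECIFIC_UP:
        male[name] = dn2pd_specific_up
    table[("dn2PD", "M")] = dict(male)
    table[("dn2PD", "F")] = {k: v * female_scale for k, v in male.items()}

    adv: dict[str, float] = {k: v * advpd_scale for k, v in male.items()}
    for name in A.PROGRESSION_DOWN:
        adv[name] = progression_shift
    for name in A.DN2PD_SPECIFIC_UP:
        adv[name] = 0.0  # dn2PD-specific elevation absent in advPD
    table[("advPD", "M")] = dict(adv)
    table[("advPD", "F")] = dict(adv)  # small advPD group, no sex split modelled
    return table


def study_config(cohort: str = "training", seed: int = 0, **effect_kwargs) -> CohortConfig:
    """Cohort configuration at the study's group/sex sizes.

    training: 72 dn2PD (40 M / 32 F) vs 59 CTR (36 M / 23 F);
    validation: 156 dn2PD (83 M / 73 F), 20 CTR (8 M / 12 F), 22 advPD
    (15 M / 7 F).
    """
    if cohort == "training":
        counts = {("dn2PD", "M"): 40, ("dn2PD", "F"): 32, ("CTR", "M"): 36, ("CTR", "F"): 23}
    elif cohort == "validation":
        counts = {
            ("dn2PD", "M"): 83,
            ("dn2PD", "F"): 73,
            ("CTR", "M"): 8,
            ("CTR", "F"): 12,
            ("advPD", "M"): 15,
            ("advPD", "F"): 7,
        }
    else:
        raise ConfigurationError(f"unknown cohort {cohort!r}")
    return CohortConfig(
        n_per_group_per_sex=counts,
        effect_table=study_effect_table(**effect_kwargs),
        cohort_label=cohort,
        seed=seed,
    )


def null_config(n_per_cell: int = 30, seed: int = 0) -> CohortConfig:
    """Zero-effect two-group configuration (pure-noise null)."""
    counts = {(g, s): n_per_cell for g in ("CTR", "dn2PD") for s in SEXES}
    return CohortConfig(n_per_group_per_sex=counts, effect_table={}, seed=seed)


# -- cohort simulation -------------------------------------------------------

def simulate_cohort(config: CohortConfig) -> tuple[ConcentrationTable, list[SampleMeta]]:
    """Draw one cohort: log-normal concentrations with multiplicative
    group/sex effects and a shared lipoprotein latent factor.

    Row order is deterministic: cells in (group, sex) iteration order of the
    config, samples numbered within cell.
    """
    names = list(config.analyte_names)
    log_mean_map, log_sd_map = default_baselines(names)
    if config.baseline_log_mean is not None:
        log_mean_map.update(config.baseline_log_mean)
    if config.baseline_log_sd is not None:
        log_sd_map.update(config.baseline_log_sd)
    mu = np.array([log_mean_map[n] for n in names])
    sigma = np.array([log_sd_map[n] for n in names])
    if np.any(sigma <= 0):
        raise ConfigurationError("baseline_log_sd must be positive")

    is_lipo = np.array([n in set(A.LIPOPROTEINS) for n in names])
    rho = config.lipoprotein_block_correlation
    load = np.sqrt(rho)

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 101]))
    meta: list[SampleMeta] = []
    rows: list[np.ndarray] = []
    counter = 0
    for (group, sex), n in config.n_per_group_per_sex.items():
        shifts = np.zeros(len(names))
        cell_effects = config.effect_table.get((group, sex), {})
        for aname, s in cell_effects.items():
            shifts[names.index(aname)] = s
        for _ in range(int(n)):
            counter += 1
            z_common = rng.standard_normal()
            z = rng.standard_normal(len(names))
            z_eff = np.where(is_lipo, load * z_common + np.sqrt(1.0 - rho) * z, z)
            logc = mu + shifts * np.log(2.0) + sigma * z_eff
            rows.append(np.exp(logc))
            meta.append(
                SampleMeta(
                    sample_id=f"{config.cohort_label[:1].upper()}{counter:04d}",
                    group=group,
                    sex=sex,
                    cohort=config.cohort_label,
                )
            )
    if not rows:
        raise ConfigurationError("configuration yields zero samples")
    table = ConcentrationTable(np.vstack(rows), names, meta)
    return table, meta


# -- peak library and spectra ------------------------------------------------

@dataclass(frozen=True)
class PeakLibrary:
    """Per-analyte Lorentzian resonances: (center_ppm, linewidth_ppm, area)."""

    peaks: Mapping[str, tuple[tuple[float, float, float], ...]]
    reference_peak: tuple[float, float, float] = (REFERENCE_PPM, 0.004, 1.0)

    def __post_init__(self) -> None:
        for name, plist in self.peaks.items():
            for c, w, a in plist:
                if not (0.2 <= c <= 10.0):
                    raise ValueError(f"{name}: peak center {c} outside [0.2, 10.0] ppm")
                if w <= 0 or a <= 0:
                    raise ValueError(f"{name}: linewidth and area must be positive")


class PeakLookupError(KeyError):
    pass


#: documented resonance positions (singlet/multiplet centroids) for the 27
#: metabolites; conventional 1H shifts in serum.
_METABOLITE_PEAKS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "3-Hydroxybutyric acid": ((1.20, 0.004, 3.0), (2.31, 0.004, 1.0), (4.13, 0.004, 1.0)),
    "2-Aminobutyric acid": ((0.98, 0.004, 3.0), (1.89, 0.004, 2.0)),
    "Acetic acid": ((1.92, 0.004, 3.0),),
    "Acetone": ((2.22, 0.004, 6.0),),
    "Alanine": ((1.48, 0.004, 3.0), (3.78, 0.004, 1.0)),
    "Citric acid": ((2.54, 0.005, 2.0), (2.66, 0.005, 2.0)),
    "Creatine": ((3.03, 0.004, 3.0), (3.93, 0.004, 2.0)),
    "Creatinine": ((3.04, 0.004, 3.0), (4.05, 0.004, 2.0)),
    "Formic acid": ((8.46, 0.004, 1.0),),
    "Glucose": ((3.24, 0.010, 1.0), (3.47, 0.012, 3.0), (3.72, 0.012, 3.0), (3.90, 0.010, 1.0), (4.64, 0.005, 0.8)),
    "Glutamic acid": ((2.08, 0.006, 2.0), (2.34, 0.006, 2.0), (3.75, 0.004, 1.0)),
    "Glutamine": ((2.13, 0.006, 2.0), (2.45, 0.006, 2.0), (3.77, 0.004, 1.0)),
    "Glycine": ((3.56, 0.004, 2.0),),
    "Histidine": ((7.05, 0.004, 1.0), (7.75, 0.004, 1.0), (3.98, 0.004, 1.0)),
    "Isoleucine": ((0.94, 0.004, 3.0), (1.01, 0.004, 3.0)),
    "Lactic acid": ((1.33, 0.004, 3.0), (4.11, 0.004, 1.0)),
    "Leucine": ((0.96, 0.005, 6.0), (1.70, 0.005, 3.0)),
    "Methionine": ((2.14, 0.004, 3.0), (2.64, 0.004, 2.0)),
    "N,N-Dimethylglycine": ((2.93, 0.004, 6.0), (3.71, 0.004, 2.0)),
    "Ornithine": ((1.73, 0.006, 2.0), (1.82, 0.006, 2.0), (3.05, 0.005, 2.0)),
    "Phenylalanine": ((7.33, 0.005, 3.0), (7.43, 0.005, 2.0), (3.99, 0.004, 1.0)),
    "Proline": ((2.01, 0.006, 3.0), (3.34, 0.005, 1.0), (4.14, 0.004, 1.0)),
    "Pyruvic acid": ((2.37, 0.004, 3.0),),
    "Succinic acid": ((2.41, 0.004, 4.0),),
    "Threonine": ((1.32, 0.004, 3.0), (3.59, 0.004, 1.0), (4.25, 0.004, 1.0)),
    "Tyrosine": ((6.90, 0.004, 2.0), (7.19, 0.004, 2.0)),
    "Valine": ((0.99, 0.004, 3.0), (1.04, 0.004, 3.0), (2.27, 0.004, 1.0)),
}

# lipoprotein envelope model: serum lipid signals are broad methyl (~0.8-0.9
# ppm) and methylene (~1.2-1.3 ppm) humps whose position and width depend on
# particle density class (HDL upfield and narrow, VLDL downfield and broad) -
# the lineshape differences that make subclass quantification from 1D spectra
# possible in the first place. Subclass index nudges the centers further
# (denser subclasses more upfield), and the lipid species carried by the
# fraction adds its own resonances (glyceryl for triglycerides, sterol methyls
# for cholesterol, choline headgroup for phospholipids, broad protein
# aliphatics for the apolipoproteins).
_CLASS_SHIFT = {"HDL": -0.045, "LDL": -0.015, "IDL": 0.01, "VLDL": 0.035}
_CLASS_WIDTH = {"HDL": 0.035, "LDL": 0.055, "IDL": 0.07, "VLDL": 0.09}


def _lipoprotein_envelopes(name: str) -> tuple[tuple[float, float, float], ...]:
    frac = "LDL"
    for cand in ("VLDL", "IDL", "HDL", "LDL"):
        if cand in name.replace("LDLChol/HDLChol", "LDL"):
            frac = cand
            break
    sub = 0
    for ch in name[::-1]:
        if ch.isdigit():
            sub = int(ch)
            break
        if ch.isalpha() and ch not in "12":
            break
    # subclass numbering runs large->dense; denser particles sit upfield
    off = _CLASS_SHIFT[frac] - 0.008 * sub
    width = _CLASS_WIDTH[frac] * (1.0 - 0.05 * sub)
    scale = 0.02  # lipoprotein concentrations are large; keep areas modest
    env = [(0.875 + off, width, 3.0 * scale), (1.285 + off, width * 1.2, 6.0 * scale)]
    if name.startswith("Tg") or "Triglycer" in name:
        env += [(2.22 + off, width, 0.8 * scale), (4.28, 0.03, 0.6 * scale)]
    elif name.startswith(("Chol", "FreeChol")) or "Chol" in name:
        env += [(0.68, 0.02, 0.8 * scale), (1.01 + off, width, 0.8 * scale)]
    elif name.startswith("Pho") or "Phospholip" in name:
        env += [(3.22, 0.03, 1.2 * scale)]
    elif "Apo" in name:
        env += [(0.94 + off, width, 1.0 * scale), (2.95, 0.05, 0.5 * scale)]
    if name == "LDL" or (name.startswith("LDL") and name[3:].isdigit()):
        # particle-number parameters: whole-particle signal, all lipids
        env += [(3.22, 0.03, 0.6 * scale), (2.02 + off, width, 0.6 * scale)]
    return tuple(env)


def default_peak_library() -> PeakLibrary:
    """Deterministic library: >=1 resonance per metabolite; density-class and
    lipid-species dependent broad envelopes per lipoprotein parameter."""
    peaks: dict[str, tuple[tuple[float, float, float], ...]] = dict(_METABOLITE_PEAKS)
    for name in A.LIPOPROTEINS:
        peaks[name] = _lipoprotein_envelopes(name)
    return PeakLibrary(peaks=peaks)


def _lorentzian(ppm: np.ndarray, center: float, width: float, area: float) -> np.ndarray:
    # area-normalised Lorentzian; width = half-width at half-maximum
    return (area / np.pi) * width / ((ppm - center) ** 2 + width**2)


def default_ppm_grid(n_points: int = 16384) -> np.ndarray:
    """Uniform ascending grid over [0.0, 10.2] ppm."""
    return np.linspace(0.0, 10.2, n_points)


def simulate_spectra(
    table: ConcentrationTable,
    library: PeakLibrary | None = None,
    noise_sd: float = 5e-4,
    seed: int = 0,
    ppm: np.ndarray | None = None,
) -> list[Spectrum]:
    """Emit one processed spectrum per table row.

    Each spectrum is the concentration-weighted sum of the library's
    Lorentzians, plus the fixed reference singlet at 5.24 ppm and i.i.d.
    Gaussian noise of standard deviation ``noise_sd``.
    """
    library = library or default_peak_library()
    ppm = default_ppm_grid() if ppm is None else np.asarray(ppm, dtype=float)
    missing = [n for n in table.analyte_names if n not in library.peaks]
    if missing:
        raise PeakLookupError(f"analytes missing from peak library: {missing[:5]}")
    # unit-concentration spectral template per analyte (analytes x points)
    templates = np.zeros((len(table.analyte_names), ppm.size))
    for j, name in enumerate(table.analyte_names):
        for c, w, a in library.peaks[name]:
            templates[j] += _lorentzian(ppm, c, w, a)
    clean = table.values @ templates
    c, w, a = library.reference_peak
    clean += _lorentzian(ppm, c, w, a)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 202]))
    out: list[Spectrum] = []
    for i, m in enumerate(table.meta):
        intensity = clean[i]
        if noise_sd > 0:
            intensity = intensity + rng.normal(0.0, noise_sd, ppm.size)
        out.append(Spectrum(ppm=ppm, intensity=intensity, sample_id=m.sample_id))
    return out
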