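"""Canonical analyte vocabulary: 27 serum metabolites and 111 lipoprotein parameters.

The lipoprotein panel follows the density/size-resolved subclass scheme used in
clinical serum NMR screening: main fractions (VLDL, IDL, LDL, HDL), 15
subclasses (VLDL-1..5, LDL-1..6, HDL-1..4), per-fraction lipid concentrations
(total cholesterol ``Chol``, free cholesterol ``FreeChol``, phospholipids
``Pho``, triglycerides ``Tg``) and apolipoproteins (ApoB on the ApoB-carrying
fractions, ApoA1/ApoA2 on HDL), plus serum totals, two clinical ratios and
LDL particle-number parameters.
"""

from __future__ import annotations

METABOLITES: tuple[str, ...] = (
    "3-Hydroxybutyric acid",
    "2-Aminobutyric acid",
    "Acetic acid",
    "Acetone",
    "Alanine",
    "Citric acid",
    "Creatine",
    "Creatinine",
    "Formic acid",
    "Glucose",
    "Glutamic acid",
    "Glutamine",
    "Glycine",
    "Histidine",
    "Isoleucine",
    "Lactic acid",
    "Leucine",
    "Methionine",
    "N,N-Dimethylglycine",
    "Ornithine",
    "Phenylalanine",
    "Proline",
    "Pyruvic acid",
    "Succinic acid",
    "Threonine",
    "Tyrosine",
    "Valine",
)

_LIPIDS = ("Chol", "FreeChol", "Pho", "Tg")


def _lipoprotein_names() -> tuple[str, ...]:
    names: list[str] = []
    # serum totals and clinical ratios
    names += [
        "Cholesterol",
        "FreeCholesterol",
        "Triglycerides",
        "Phospholipids",
        "ApoA1",
        "ApoA2",
        "ApoB100",
        "LDLChol/HDLChol",
        "ApoB100/ApoA1",
    ]
    # main fractions: lipids in VLDL/IDL/LDL/HDL (LDL cholesterol keeps its
    # conventional clinical name LDLChol, HDL cholesterol HDLChol)
    for frac in ("VLDL", "IDL", "LDL", "HDL"):
        for lipid in _LIPIDS:
            if lipid == "Chol" and frac in ("LDL", "HDL"):
                names.append(f"{frac}Chol")
            else:
                names.append(f"{lipid}-{frac}")
    names += ["ApoB-VLDL", "ApoB-IDL", "ApoB-LDL", "ApoA1-HDL", "ApoA2-HDL"]
    # LDL particle-number parameters (main fraction + six subclasses)
    names += ["LDL"] + [f"LDL{i}" for i in range(1, 7)]
    # subclasses
    for i in range(1, 6):
        for lipid in _LIPIDS:
            names.append(f"{lipid}-VLDL{i}")
    for i in range(1, 7):
        for lipid in (*_LIPIDS, "ApoB"):
            names.append(f"{lipid}-LDL{i}")
    for i in range(1, 5):
        for lipid in (*_LIPIDS, "ApoA1", "ApoA2"):
            names.append(f"{lipid}-HDL{i}")
    return tuple(names)


LIPOPROTEINS: tuple[str, ...] = _lipoprotein_names()

ALL_ANALYTES: tuple[str, ...] = METABOLITES + LIPOPROTEINS

assert len(METABOLITES) == 27
assert len(LIPOPROTEINS) == 111
assert len(set(ALL_ANALYTES)) == 138

#: analytes flagged FDR<0.05 in male dn2PD vs CTR (three metabolites up,
#: the LDL-centred lipoprotein panel down)
MALE_SIGNATURE_UP: tuple[str, ...] = ("Acetone", "Ornithine", "Phenylalanine")
MALE_SIGNATURE_DOWN: tuple[str, ...] = (
    "Cholesterol",
    "LDLChol",
    "ApoB100",
    "LDLChol/HDLChol",
    "ApoB100/ApoA1",
    "LDL",
    "LDL4",
    "LDL5",
    "Tg-LDL",
    "FreeChol-LDL",
    "Pho-LDL",
    "ApoB-LDL",
    "Tg-LDL3",
    "Tg-LDL4",
    "Tg-LDL5",
    "Chol-LDL4",
    "Chol-LDL5",
    "FreeChol-LDL4",
    "FreeChol-LDL5",
    "Pho-LDL4",
    "Pho-LDL5",
    "ApoB-LDL4",
    "ApoB-LDL5",
)
MALE_SIGNATURE: tuple[str, ...] = MALE_SIGNATURE_UP + MALE_SIGNATURE_DOWN

#: analytes that keep falling along the CTR > dn2PD > advPD series
PROGRESSION_DOWN: tuple[str, ...] = (
    "Citric acid",
    "Methionine",
    "N,N-Dimethylglycine",
    "ApoA1",
    "ApoA1-HDL4",
    "FreeChol-HDL",
    "FreeChol-HDL4",
    "ApoA2-HDL3",
)
#: analytes elevated in dn2PD relative to both CTR and advPD
DN2PD_SPECIFIC_UP: tuple[str, ...] = ("Formic acid", "Histidine")
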