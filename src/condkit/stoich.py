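"""Protein/RNA stoichiometry calculators.

Long homopolymeric RNA (e.g. polyU) is dosed by mass concentration
(ng/µl) but phase behaviour is governed by molar and charge ratios, so
these converters make the mapping explicit: chain molarity from the mean
molecular weight, nucleotides per chain from the residue mass, and the
RNA/protein negative-to-positive charge ratio under a stated, recorded
charge convention (one negative charge per nucleotide by default; the
protein's positive-charge count is a required input because it depends
on which residues — Arg/Lys, His, termini — one chooses to count).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class RnaSpec:
    """A polydisperse RNA dosed by mass; defaults describe ~900 kDa polyU."""

    mass_conc_ng_ul: float
    mean_mw_da: float = 900_000.0
    residue_mw_da: float = 306.2      # internal UMP residue
    charge_per_nt: float = -1.0

    def __post_init__(self) -> None:
        if self.mass_conc_ng_ul < 0:
            raise ValueError("mass concentration must be ≥ 0")
        if not self.mean_mw_da > self.residue_mw_da > 0:
            raise ValueError("need mean_mw > residue_mw > 0")

    @property
    def nt_per_chain(self) -> float:
        return self.mean_mw_da / self.residue_mw_da


@dataclass
class ProteinSpec:
    molar_conc_m: float
    positive_charges_per_molecule: float | None = None
    charge_convention: str = "user-specified positive-charge count"

    def __post_init__(self) -> None:
        if self.molar_conc_m < 0:
            raise ValueError("molar concentration must be ≥ 0")
        if (
            self.positive_charges_per_molecule is not None
            and self.positive_charges_per_molecule < 0
        ):
            raise ValueError("charge count must be ≥ 0")


def rna_molar(spec: RnaSpec) -> float:
    """Chain molarity of the RNA: (mass conc in g/L) / mean MW.

    1 ng/µl = 1 mg/ml = 10⁻³ g/L.
    """
    return spec.mass_conc_ng_ul * 1e-3 / spec.mean_mw_da


def molar_ratio(protein: ProteinSpec, rna: RnaSpec) -> float:
    """Protein/RNA chain molar ratio."""
    c_rna = rna_molar(rna)
    if c_rna == 0:
        raise ZeroDivisionError("molar ratio undefined at zero RNA")
    return protein.molar_conc_m / c_rna


def charge_ratio(protein: ProteinSpec, rna: RnaSpec) -> dict:
    """RNA/protein charge ratio (negative over positive charges).

    ratio = C_RNA · nt_per_chain · |charge per nt|
          / (C_protein · positive charges per protein molecule).

    The convention string travels with the number: charge ratios are only
    comparable under the same counting convention.
    """
    if not protein.positive_charges_per_molecule:
        raise ValueError("protein positive-charge count must be set and > 0")
    if protein.molar_conc_m == 0:
        raise ZeroDivisionError("charge ratio undefined at zero protein")
    ratio = (
        rna_molar(rna) * rna.nt_per_chain * abs(rna.charge_per_nt)
    ) / (protein.molar_conc_m * protein.positive_charges_per_molecule)
    return {"ratio": float(ratio), "convention": protein.charge_convention}
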