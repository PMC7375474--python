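"""In-silico proteolytic digestion and peptide mass / m/z computation.

Tryptic digestion cleaves C-terminal to lysine (K) and arginine (R); the
classical rule suppresses cleavage when the next residue is proline.  Up to
``max_missed_cleavages`` internal sites may remain uncleaved, mirroring
incomplete digestion in real samples.  Monoisotopic residue masses come from
pyteomics; carbamidomethylation of cysteine is the only fixed modification
(alkylation during sample preparation), applied as a +57.0215 Da shift per C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from pyteomics import mass as _pmass

from .proteome import CombinedProteome, Proteome

PROTON_MASS = 1.00727646688
WATER_MASS = _pmass.calculate_mass(formula="H2O")
CARBAMIDOMETHYL_MASS = _pmass.calculate_mass(formula="CH2CONH2") - _pmass.calculate_mass(
    formula="H"
)  # H -> CH2-CO-NH2 on cysteine sulfur: net +C2H3NO = 57.02146


class DigestError(ValueError):
    """Invalid digestion input or parameters."""


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings.

    Defaults: trypsin with the classical proline rule, at most two missed
    cleavages, peptide length 7-52 residues (common library-building window).
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 52
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise DigestError(f"unsupported enzyme {self.enzyme!r}")
        if self.max_missed_cleavages < 0:
            raise DigestError("max_missed_cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise DigestError("min_length must be <= max_length")


@dataclass(frozen=True)
class DigestedPeptide:
    """A proteolytic product with its position in the parent protein.

    ``start``/``end`` are 0-based, half-open coordinates into the parent
    sequence; ``missed`` counts internal uncleaved K/R sites.
    """

    sequence: str
    accession: str
    species: str
    start: int
    end: int
    missed: int


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic residue masses plus water/proton and fixed-mod table."""

    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(_pmass.std_aa_mass)
    )
    water: float = WATER_MASS
    proton: float = PROTON_MASS
    fixed_mods: Mapping[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL_MASS}
    )


DEFAULT_MASS_CONSTANTS = MassConstants()


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Positions (between residues i-1 and i) where trypsin cuts.

    A site after K/R is suppressed when the following residue is P and the
    proline rule is on.  The protein termini are not included.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR":
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def digest(
    sequence: str,
    params: DigestParams = DigestParams(),
    accession: str = "",
    species: str = "",
) -> list[DigestedPeptide]:
    """Digest one protein sequence into tryptic peptides.

    Returns every contiguous product whose internal missed-cleavage count is
    at most ``params.max_missed_cleavages``, with the length filter applied
    last.  Positional duplicates are retained (sequence-level deduplication
    belongs to the index built over a whole proteome).
    """
    if not sequence:
        raise DigestError("cannot digest an empty sequence")
    boundaries = [0] + cleavage_sites(sequence, params.proline_rule) + [len(sequence)]
    peptides: list[DigestedPeptide] = []
    n = len(boundaries)
    for i in range(n - 1):
        for j in range(i + 1, min(i + 2 + params.max_missed_cleavages, n)):
            start, end = boundaries[i], boundaries[j]
            if not (params.min_length <= end - start <= params.max_length):
                continue
            peptides.append(
                DigestedPeptide(
                    sequence=sequence[start:end],
                    accession=accession,
                    species=species,
                    start=start,
                    end=end,
                    missed=j - i - 1,
                )
            )
    return peptides


def digest_proteome(
    proteome: Proteome | CombinedProteome,
    params: DigestParams = DigestParams(),
) -> dict[str, set[tuple[str, str]]]:
    """Digest every record; map peptide sequence -> set of (species, accession).

    The multimap over a combined proteome is the input to peptide
    classification: a peptide mapping to exactly one parent is both
    proteotypic and species-discriminating.
    """
    if len(proteome) == 0:
        raise DigestError("cannot digest an empty proteome")
    index: dict[str, set[tuple[str, str]]] = {}
    for rec in proteome:
        for pep in digest(rec.sequence, params, rec.accession, rec.species):
            index.setdefault(pep.sequence, set()).add((rec.species, rec.accession))
    return index


def peptide_mono_mass(
    sequence: str,
    constants: MassConstants = DEFAULT_MASS_CONSTANTS,
    apply_fixed_mods: bool = True,
) -> float:
    """Monoisotopic peptide mass in Da (residue sum + water + fixed mods)."""
    if not sequence:
        raise DigestError("cannot compute the mass of an empty peptide")
    total = constants.water
    for aa in sequence:
        try:
            total += constants.residue_masses[aa]
        except KeyError:
            raise DigestError(f"residue {aa!r} has no defined monoisotopic mass")
        if apply_fixed_mods and aa in constants.fixed_mods:
            total += constants.fixed_mods[aa]
    return total


def precursor_mz(mono_mass: float, charge: int, proton: float = PROTON_MASS) -> float:
    """m/z of a precursor of the given monoisotopic mass and charge."""
    if charge < 1:
        raise DigestError("charge must be a positive integer")
    return (mono_mass + charge * proton) / charge


def fragment_mz(
    sequence: str,
    ion_type: str,
    ordinal: int,
    charge: int = 1,
    constants: MassConstants = DEFAULT_MASS_CONSTANTS,
    apply_fixed_mods: bool = True,
) -> float:
    """m/z of a b- or y-series fragment ion of a peptide."""
    if ion_type not in ("b", "y"):
        raise DigestError(f"unsupported ion type {ion_type!r}")
    if not 1 <= ordinal < len(sequence):
        raise DigestError(f"ordinal {ordinal} out of range for {sequence!r}")
    if charge < 1:
        raise DigestError("charge must be a positive integer")
    piece = sequence[:ordinal] if ion_type == "b" else sequence[-ordinal:]
    residues = peptide_mono_mass(piece, constants, apply_fixed_mods) - constants.water
    neutral = residues if ion_type == "b" else residues + constants.water
    return (neutral + charge * constants.proton) / charge
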