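"""Proteotypic and species-discriminating peptide classification.

The central idea of xenograft deconvolution by sequence: after digesting the
combined multi-species proteome, a peptide is useful for species-split
quantification only if it is

* **proteotypic** — maps to exactly one protein accession within its species,
  so its signal is attributable to one protein; and
* **species-discriminating** — occurs in the digest of only one species'
  proteome, so its signal is attributable to one compartment (tumour vs host).

Both conditions together are equivalent to the peptide having exactly one
parent across the whole combined proteome — the "occurs once in the combined
FASTA" duplicate-count mechanism, which :func:`retained_equivalence_check`
verifies independently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd


class ClassificationError(ValueError):
    pass


# Modifications in common notations: "C[Carbamidomethyl (C)]", "C(UniMod:4)",
# "M[+15.9949]", terminal "_" markers.
_MOD_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)|[^A-Z]")


def strip_modifications(modified_sequence: str) -> str:
    """Reduce a modified peptide string to its plain backbone sequence."""
    return _MOD_RE.sub("", modified_sequence.upper())


def _collapse_il(sequence: str) -> str:
    return sequence.replace("I", "L")


@dataclass(frozen=True)
class PeptideClass:
    """Classification of one peptide sequence against a combined proteome."""

    sequence: str
    parents: Mapping[str, frozenset[str]]  # species -> accessions

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(self.parents)

    @property
    def proteotypic_in(self) -> frozenset[str]:
        return frozenset(sp for sp, accs in self.parents.items() if len(accs) == 1)

    @property
    def is_species_discriminating(self) -> bool:
        return len(self.parents) == 1

    @property
    def assigned_species(self) -> str | None:
        if self.is_species_discriminating:
            return next(iter(self.parents))
        return None

    @property
    def parent_count(self) -> int:
        return sum(len(accs) for accs in self.parents.values())

    @property
    def retained(self) -> bool:
        """Kept for quantification: proteotypic within its species AND
        species-discriminating, i.e. exactly one parent overall."""
        return self.parent_count == 1

    @property
    def assigned_parent(self) -> tuple[str, str] | None:
        """(species, accession) when retained, else None."""
        if not self.retained:
            return None
        species = next(iter(self.parents))
        return species, next(iter(self.parents[species]))


@dataclass
class ClassificationIndex:
    """Peptide sequence -> :class:`PeptideClass` over a combined digest."""

    peptides: dict[str, PeptideClass]
    provenance: dict = field(default_factory=dict)
    il_collapsed: bool = False

    def __len__(self) -> int:
        return len(self.peptides)

    def lookup(self, sequence: str) -> PeptideClass | None:
        """Look up a (possibly modified) peptide by its stripped backbone."""
        key = strip_modifications(sequence)
        if self.il_collapsed:
            key = _collapse_il(key)
        return self.peptides.get(key)

    @property
    def retained_peptides(self) -> set[str]:
        return {seq for seq, cls in self.peptides.items() if cls.retained}

    def retained_by_species(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for seq, cls in self.peptides.items():
            if cls.retained:
                out.setdefault(cls.assigned_species, set()).add(seq)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: peptide, species_set, parent_count, retained."""
        rows = [
            {
                "peptide": seq,
                "species_set": ";".join(sorted(cls.species_set)),
                "parent_count": cls.parent_count,
                "retained": cls.retained,
            }
            for seq, cls in sorted(self.peptides.items())
        ]
        return pd.DataFrame(rows, columns=["peptide", "species_set", "parent_count", "retained"])


def classify_peptides(
    multimap: Mapping[str, set[tuple[str, str]]],
    il_collapsed: bool = False,
    provenance: dict | None = None,
) -> ClassificationIndex:
    """Classify every peptide of a combined-proteome digest.

    Parameters
    ----------
    multimap : mapping peptide -> {(species, accession), ...}
        Output of :func:`xenosplit.digest.digest_proteome` over a combined
        proteome.
    il_collapsed : bool
        Treat isoleucine and leucine as indistinguishable (they are isobaric
        in MS); peptides differing only by I/L then share one classification.
    """
    if not multimap:
        raise ClassificationError("cannot classify an empty peptide multimap")
    merged: dict[str, set[tuple[str, str]]] = {}
    for seq, parents in multimap.items():
        key = _collapse_il(seq) if il_collapsed else seq
        merged.setdefault(key, set()).update(parents)
    peptides = {}
    for seq, parents in merged.items():
        by_species: dict[str, set[str]] = {}
        for species, acc in parents:
            by_species.setdefault(species, set()).add(acc)
        peptides[seq] = PeptideClass(
            sequence=seq,
            parents={sp: frozenset(accs) for sp, accs in by_species.items()},
        )
    return ClassificationIndex(
        peptides=peptides,
        provenance=provenance or {},
        il_collapsed=il_collapsed,
    )


def retained_equivalence_check(
    index: ClassificationIndex,
    multimap: Mapping[str, set[tuple[str, str]]] | None = None,
) -> bool:
    """Independent check of the retention rule via duplicate counting.

    Recomputes the retained set as the peptides whose parent occurrence
    count across the combined proteome is exactly one (a peptide occurring
    more than once is either shared between proteins or between species) and
    compares it with the classification's own retained set.  When the source
    digest ``multimap`` is supplied the counts are re-derived from it,
    making the check independent of the index's stored parent sets.
    """
    if multimap is not None:
        merged: dict[str, set[tuple[str, str]]] = {}
        for seq, parents in multimap.items():
            key = _collapse_il(seq) if index.il_collapsed else seq
            merged.setdefault(key, set()).update(parents)
        by_count = {seq for seq, parents in merged.items() if len(parents) == 1}
    else:
        by_count = {
            seq for seq, cls in index.peptides.items() if cls.parent_count == 1
        }
    return by_count == index.retained_peptides


@dataclass
class IdentificationFilterResult:
    """Disposition of identified peptides against a classification index."""

    by_species: dict[str, list[str]]
    discarded_shared: list[str]
    unmapped: list[str]

    @property
    def total(self) -> int:
        return (
            sum(len(v) for v in self.by_species.values())
            + len(self.discarded_shared)
            + len(self.unmapped)
        )


def filter_identifications(
    identified: Iterable[str],
    index: ClassificationIndex,
) -> IdentificationFilterResult:
    """Partition identified peptides into per-species retained sets.

    Every input peptide lands in exactly one bucket: its assigned species
    (retained), ``discarded_shared`` (present in the index but shared between
    proteins or species), or ``unmapped`` (absent from the index; reported,
    never silently dropped).
    """
    by_species: dict[str, list[str]] = {}
    discarded: list[str] = []
    unmapped: list[str] = []
    for pep in identified:
        cls = index.lookup(pep)
        if cls is None:
            unmapped.append(pep)
        elif cls.retained:
            by_species.setdefault(cls.assigned_species, []).append(pep)
        else:
            discarded.append(pep)
    return IdentificationFilterResult(
        by_species=by_species, discarded_shared=discarded, unmapped=unmapped
    )
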