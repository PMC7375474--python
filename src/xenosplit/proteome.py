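"""Species-tagged proteome containers and FASTA I/O.

A xenograft deconvolution run starts from two (or more) single-species
proteome FASTA files.  Each file is read into a :class:`Proteome` whose
records all carry the caller-supplied species label; proteomes are then
merged into a :class:`CombinedProteome`, the sequence space against which
peptide species-discrimination is decided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Residue codes with no defined monoisotopic mass (ambiguity / rare codes).
NONSTANDARD_AA = frozenset("BJOUZX")

_SPECIES_SEP = "|"


class ProteomeError(ValueError):
    """Malformed proteome input (empty file, duplicate accession, bad residue)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence tagged with its species of origin."""

    accession: str
    species: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ProteomeError("accession must be non-empty")
        if not self.sequence:
            raise ProteomeError(f"record {self.accession!r} has an empty sequence")


@dataclass
class Proteome:
    """Ordered collection of :class:`ProteinRecord` sharing one species label."""

    species: str
    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        index: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.species != self.species:
                raise ProteomeError(
                    f"record {rec.accession!r} carries species {rec.species!r}, "
                    f"expected {self.species!r}"
                )
            if rec.accession in index:
                raise ProteomeError(f"duplicate accession {rec.accession!r}")
            index[rec.accession] = rec
        self._index = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._index[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._index


@dataclass
class CombinedProteome:
    """Concatenation of >=2 single-species proteomes.

    Records are keyed by the pair ``(species, accession)``; identical
    accession strings occurring in different species are both retained.
    """

    proteomes: list[Proteome]

    def __post_init__(self) -> None:
        if len(self.proteomes) < 2:
            raise ProteomeError("a combined proteome needs at least two proteomes")
        labels = [p.species for p in self.proteomes]
        if len(set(labels)) != len(labels):
            raise ProteomeError(f"duplicate species labels in {labels}")

    @property
    def species(self) -> list[str]:
        return [p.species for p in self.proteomes]

    @property
    def records(self) -> list[ProteinRecord]:
        return [rec for p in self.proteomes for rec in p.records]

    def __len__(self) -> int:
        return sum(len(p) for p in self.proteomes)

    def __iter__(self) -> Iterator[ProteinRecord]:
        for p in self.proteomes:
            yield from p


def _validate_residues(accession: str, sequence: str, permissive: bool) -> None:
    bad = set(sequence) - STANDARD_AA
    if not bad:
        return
    unknown = bad - NONSTANDARD_AA
    if unknown:
        raise ProteomeError(
            f"record {accession!r} contains non-amino-acid characters {sorted(unknown)}"
        )
    if not permissive:
        raise ProteomeError(
            f"record {accession!r} contains non-standard residues {sorted(bad)}; "
            "pass permissive=True to keep it (its peptides are excluded from "
            "mass computation)"
        )


def _accession_from_header(header_id: str) -> str:
    # UniProt convention "db|ACC|NAME"; otherwise first whitespace token.
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_id


def read_fasta(path, species: str, permissive: bool = False) -> Proteome:
    """Read a FASTA file into a species-tagged :class:`Proteome`.

    UniProt-style headers ``db|ACC|NAME ...`` yield ``ACC`` as the accession;
    anything else uses the first whitespace-delimited header token.  Sequences
    are uppercased with line breaks removed.

    Parameters
    ----------
    path : str or pathlib.Path
    species : str
        Label attached to every record (e.g. ``"mouse"``).
    permissive : bool
        Keep records containing B/J/O/U/Z/X instead of raising.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        accession = _accession_from_header(entry.id)
        if not seq:
            raise ProteomeError(f"record {accession!r} has an empty sequence")
        if accession in seen:
            raise ProteomeError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        _validate_residues(accession, seq, permissive)
        description = entry.description[len(entry.id):].strip()
        records.append(ProteinRecord(accession, species, description, seq))
    if not records:
        raise ProteomeError(f"no records in {path}")
    return Proteome(species=species, records=records)


def combine_proteomes(proteomes: Iterable[Proteome]) -> CombinedProteome:
    """Concatenate single-species proteomes, preserving species tags."""
    return CombinedProteome(proteomes=list(proteomes))


def read_combined_fasta(path, permissive: bool = False) -> CombinedProteome:
    """Read a combined FASTA written by :func:`write_fasta`.

    Species tags are recovered from the ``<species>|`` header prefix.
    """
    by_species: dict[str, list[ProteinRecord]] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if _SPECIES_SEP not in entry.id:
            raise ProteomeError(
                f"header {entry.id!r} lacks the '<species>|' prefix of a "
                "combined FASTA"
            )
        species, rest = entry.id.split(_SPECIES_SEP, 1)
        seq = str(entry.seq).upper()
        accession = _accession_from_header(rest)
        if not seq:
            raise ProteomeError(f"record {accession!r} has an empty sequence")
        _validate_residues(accession, seq, permissive)
        description = entry.description[len(entry.id):].strip()
        by_species.setdefault(species, []).append(
            ProteinRecord(accession, species, description, seq)
        )
    if not by_species:
        raise ProteomeError(f"no records in {path}")
    return CombinedProteome(
        proteomes=[Proteome(sp, recs) for sp, recs in by_species.items()]
    )


def write_fasta(proteome: Proteome | CombinedProteome, path, wrap: int = 60) -> None:
    """Write a proteome (or combined proteome) to FASTA.

    For a combined proteome the species is prefixed into the header id as
    ``<species>|<original header>`` so that :func:`read_combined_fasta`
    recovers it losslessly.
    """
    if len(proteome) == 0:
        raise ProteomeError("refusing to write an empty proteome")
    combined = isinstance(proteome, CombinedProteome)
    entries = []
    for rec in proteome:
        header = rec.accession
        if combined:
            header = f"{rec.species}{_SPECIES_SEP}{rec.accession}"
        entry = SeqRecord(Seq(rec.sequence), id=header, description=rec.description)
        entries.append(entry)
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(entries)
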