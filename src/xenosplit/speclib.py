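"""SWATH assay-library construction from multi-run PSM tables.

The library build follows the standard DDA-to-library workflow: per-run
retention times are calibrated onto the iRT scale by a linear fit to spiked
standard peptides (runs fitting poorly, r² < 0.8, are excluded); peptide- and
protein-level error rates are controlled at 1% by target-decoy q-values; each
surviving precursor contributes its best-scoring spectrum, trimmed to its
3-6 most intense fragment ions as transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .classify import strip_modifications
from .digest import DEFAULT_MASS_CONSTANTS, peptide_mono_mass, precursor_mz

logger = logging.getLogger(__name__)

LIBRARY_COLUMNS = [
    "PrecursorMz",
    "ProductMz",
    "LibraryIntensity",
    "NormalizedRetentionTime",
    "PeptideSequence",
    "ModifiedPeptideSequence",
    "PrecursorCharge",
    "FragmentType",
    "FragmentSeriesNumber",
    "FragmentCharge",
    "ProteinId",
    "Species",
    "Decoy",
]


class LibraryError(ValueError):
    pass


@dataclass(frozen=True)
class Fragment:
    """One annotated fragment ion of a PSM."""

    ion_type: str  # "b" or "y"
    ordinal: int
    charge: int
    mz: float
    intensity: float


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match from a DDA search."""

    run_id: str
    peptide: str  # stripped sequence
    modified_sequence: str
    charge: int
    score: float
    is_decoy: bool
    rt: float  # observed retention time, minutes
    fragments: tuple[Fragment, ...]
    protein: str
    species: str = ""

    def __post_init__(self) -> None:
        if self.charge not in (2, 3, 4, 5):
            raise LibraryError(f"precursor charge {self.charge} outside 2-5")
        if any(f.intensity < 0 for f in self.fragments):
            raise LibraryError("fragment intensities must be >= 0")


@dataclass(frozen=True)
class RTCalibration:
    """Per-run linear map observed RT = slope * iRT + intercept."""

    run_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    excluded: bool

    def to_irt(self, rt: float) -> float:
        """Invert the calibration: observed RT back to the iRT scale."""
        if self.slope == 0:
            raise LibraryError(f"run {self.run_id!r}: zero calibration slope")
        return (rt - self.intercept) / self.slope


def calibrate_rt(
    psms: Iterable[PSMRecord],
    irt_reference: Mapping[str, float],
    r2_threshold: float = 0.8,
) -> RTCalibration:
    """Fit a run's RT-vs-iRT line from its spiked standard peptides.

    Ordinary least squares of observed RT on reference iRT; the run is
    flagged ``excluded`` when r² falls below ``r2_threshold`` (a poorly
    fitting run cannot place library iRTs reliably).
    """
    psms = list(psms)
    runs = {p.run_id for p in psms}
    if len(runs) != 1:
        raise LibraryError(f"calibrate_rt expects a single run, got {sorted(runs)}")
    run_id = runs.pop()
    pairs: dict[str, tuple[float, float]] = {}
    for p in psms:
        if p.peptide in irt_reference and not p.is_decoy:
            pairs[p.peptide] = (irt_reference[p.peptide], p.rt)
    if len(pairs) < 2:
        raise LibraryError(
            f"uncalibratable run {run_id!r}: {len(pairs)} iRT peptide(s) observed"
        )
    x = np.array([v[0] for v in pairs.values()])
    y = np.array([v[1] for v in pairs.values()])
    fit = _sstats.linregress(x, y)
    r2 = float(fit.rvalue) ** 2
    return RTCalibration(
        run_id=run_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        n_points=len(pairs),
        excluded=r2 < r2_threshold,
    )


def compute_qvalues(
    scores: Sequence[float], is_decoy: Sequence[bool]
) -> np.ndarray:
    """Target-decoy q-values for every PSM (NaN for decoys).

    FDR at threshold s is (#decoys >= s) / (#targets >= s); the q-value of a
    PSM is the running minimum of the FDR over all thresholds at or below its
    score, making q monotone non-increasing in score.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    n_targets = int((~is_decoy).sum())
    n_decoys = int(is_decoy.sum())
    if n_targets == 0 or n_decoys == 0:
        raise LibraryError(
            "q-value estimation needs at least one target and one decoy "
            f"(got {n_targets} targets, {n_decoys} decoys)"
        )
    order = np.argsort(-scores, kind="stable")
    cum_decoys = np.cumsum(is_decoy[order])
    cum_targets = np.cumsum(~is_decoy[order])
    # Ties: every member of a tie group sees the counts at the group's end.
    sorted_scores = scores[order]
    boundary = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    ends = np.flatnonzero(boundary)
    group_end = np.repeat(ends, np.diff(np.r_[-1, ends]))
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = cum_decoys[group_end] / np.maximum(cum_targets[group_end], 1)
    fdr = np.where(cum_targets[group_end] == 0, np.inf, fdr)
    # running minimum from the lowest-scoring PSM upward
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(len(scores), dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    q[is_decoy] = np.nan
    return q


def filter_fdr(
    psms: Sequence[PSMRecord],
    peptide_q_threshold: float = 0.01,
    protein_q_threshold: float = 0.01,
) -> list[PSMRecord]:
    """Two-stage 1% FDR filter: PSM/peptide level, then protein level.

    Protein level uses the best-peptide ("picked"-style) score per protein
    accession, with target-decoy counting over protein best scores; a protein
    failing the protein q-threshold is removed with all of its PSMs.
    """
    psms = list(psms)
    if not psms:
        return []
    q = compute_qvalues([p.score for p in psms], [p.is_decoy for p in psms])
    kept = [
        p
        for p, qv in zip(psms, q)
        if (not p.is_decoy and qv <= peptide_q_threshold) or p.is_decoy
    ]
    # Protein best scores over the peptide-level-surviving target PSMs plus
    # all decoys (decoy proteins estimate the protein-level error).
    best: dict[tuple[str, bool], float] = {}
    for p in kept:
        key = (p.protein, p.is_decoy)
        if key not in best or p.score > best[key]:
            best[key] = p.score
    keys = list(best)
    prot_scores = [best[k] for k in keys]
    prot_decoy = [k[1] for k in keys]
    if not any(prot_decoy) or all(prot_decoy):
        # no decoy (or no target) proteins left: protein FDR is vacuous
        passing = {k[0] for k in keys if not k[1]}
    else:
        prot_q = compute_qvalues(prot_scores, prot_decoy)
        passing = {
            k[0]
            for k, qv in zip(keys, prot_q)
            if not k[1] and qv <= protein_q_threshold
        }
    return [
        p
        for p, qv in zip(psms, q)
        if not p.is_decoy and qv <= peptide_q_threshold and p.protein in passing
    ]


@dataclass(frozen=True)
class LibraryEntry:
    """One precursor assay: identification coordinates plus 3-6 transitions."""

    modified_sequence: str
    peptide: str
    charge: int
    precursor_mz: float
    irt: float
    protein: str
    species: str
    transitions: tuple[Fragment, ...]

    def __post_init__(self) -> None:
        if not 3 <= len(self.transitions) <= 6:
            raise LibraryError(
                f"{self.modified_sequence}/{self.charge}: {len(self.transitions)} "
                "transitions outside the 3-6 band"
            )
        intens = [t.intensity for t in self.transitions]
        if any(b > a for a, b in zip(intens, intens[1:])):
            raise LibraryError("transitions must be sorted by intensity descending")
        if not np.isfinite(self.irt):
            raise LibraryError("iRT must be finite")


@dataclass
class SpectralLibrary:
    """A collection of precursor assays, unique by (modified sequence, charge)."""

    entries: list[LibraryEntry]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(e.modified_sequence, e.charge) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise LibraryError("duplicate (modified sequence, charge) in library")

    def __len__(self) -> int:
        return len(self.entries)


def assemble_library(
    psms: Sequence[PSMRecord],
    calibrations: Mapping[str, RTCalibration],
    min_transitions: int = 3,
    max_transitions: int = 6,
    provenance: dict | None = None,
) -> SpectralLibrary:
    """Build a consensus library from FDR-filtered PSMs.

    Per (modified sequence, charge) the representative spectrum is the
    highest-scoring PSM across runs; its fragments are ranked by intensity
    (ties broken toward lower product m/z), trimmed to ``max_transitions``
    and rescaled to a maximum of 1.  Precursors with fewer than
    ``min_transitions`` fragments are dropped.  iRT is the representative
    run's calibration inverse applied to its observed RT.  PSMs from excluded
    runs are skipped with a log entry.
    """
    best: dict[tuple[str, int], PSMRecord] = {}
    for p in psms:
        if p.is_decoy:
            continue
        cal = calibrations.get(p.run_id)
        if cal is None:
            raise LibraryError(f"no calibration for run {p.run_id!r}")
        if cal.excluded:
            logger.warning(
                "skipping PSM %s/%d from excluded run %s (r²=%.3f)",
                p.modified_sequence, p.charge, p.run_id, cal.r_squared,
            )
            continue
        key = (p.modified_sequence, p.charge)
        if key not in best or p.score > best[key].score:
            best[key] = p
    entries = []
    for (modseq, charge), p in sorted(best.items()):
        frags = sorted(p.fragments, key=lambda f: (-f.intensity, f.mz))
        frags = frags[:max_transitions]
        if len(frags) < min_transitions:
            continue
        top = frags[0].intensity
        scale = top if top > 0 else 1.0
        transitions = tuple(replace(f, intensity=f.intensity / scale) for f in frags)
        cal = calibrations[p.run_id]
        mass = peptide_mono_mass(p.peptide, DEFAULT_MASS_CONSTANTS, True)
        entries.append(
            LibraryEntry(
                modified_sequence=modseq,
                peptide=p.peptide,
                charge=charge,
                precursor_mz=precursor_mz(mass, charge),
                irt=cal.to_irt(p.rt),
                protein=p.protein,
                species=p.species,
                transitions=transitions,
            )
        )
    return SpectralLibrary(entries=entries, provenance=provenance or {})


def write_library_tsv(library: SpectralLibrary, path) -> None:
    """Write a library as a transition-per-row TSV (OpenSWATH-style columns)."""
    rows = []
    for e in library.entries:
        for t in e.transitions:
            rows.append(
                {
                    "PrecursorMz": e.precursor_mz,
                    "ProductMz": t.mz,
                    "LibraryIntensity": t.intensity,
                    "NormalizedRetentionTime": e.irt,
                    "PeptideSequence": e.peptide,
                    "ModifiedPeptideSequence": e.modified_sequence,
                    "PrecursorCharge": e.charge,
                    "FragmentType": t.ion_type,
                    "FragmentSeriesNumber": t.ordinal,
                    "FragmentCharge": t.charge,
                    "ProteinId": e.protein,
                    "Species": e.species,
                    "Decoy": 0,
                }
            )
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library_tsv(path) -> SpectralLibrary:
    """Read a transition-per-row library TSV back into a :class:`SpectralLibrary`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"library TSV is missing mandatory column(s) {missing}")
    entries = []
    for (modseq, charge), grp in df.groupby(
        ["ModifiedPeptideSequence", "PrecursorCharge"], sort=True
    ):
        grp = grp.sort_values(["LibraryIntensity", "ProductMz"], ascending=[False, True])
        transitions = tuple(
            Fragment(
                ion_type=str(r.FragmentType),
                ordinal=int(r.FragmentSeriesNumber),
                charge=int(r.FragmentCharge),
                mz=float(r.ProductMz),
                intensity=float(r.LibraryIntensity),
            )
            for r in grp.itertuples()
        )
        first = grp.iloc[0]
        entries.append(
            LibraryEntry(
                modified_sequence=str(modseq),
                peptide=str(first.PeptideSequence),
                charge=int(charge),
                precursor_mz=float(first.PrecursorMz),
                irt=float(first.NormalizedRetentionTime),
                protein=str(first.ProteinId),
                species="" if pd.isna(first.Species) else str(first.Species),
                transitions=transitions,
            )
        )
    return SpectralLibrary(entries=entries)


def library_stats(
    library: SpectralLibrary, annotated_proteome_size: int | None = None
) -> dict:
    """Characterize a library: protein/peptide counts, peptides-per-protein
    distribution and optional proteome coverage percentage."""
    if len(library) == 0:
        raise LibraryError("cannot characterize an empty library")
    peptides_by_protein: dict[str, set[str]] = {}
    for e in library.entries:
        peptides_by_protein.setdefault(e.protein, set()).add(e.peptide)
    counts = {prot: len(peps) for prot, peps in peptides_by_protein.items()}
    n_proteins = len(counts)
    histogram: dict[int, int] = {}
    for c in counts.values():
        histogram[c] = histogram.get(c, 0) + 1
    out = {
        "n_proteins": n_proteins,
        "n_peptides": len({e.peptide for e in library.entries}),
        "n_precursors": len(library),
        "peptides_per_protein": dict(sorted(histogram.items())),
        "frac_gt1_peptide": sum(1 for c in counts.values() if c > 1) / n_proteins,
        "frac_gt10_peptides": sum(1 for c in counts.values() if c > 10) / n_proteins,
    }
    if annotated_proteome_size is not None:
        out["coverage_pct"] = 100.0 * n_proteins / annotated_proteome_size
    return out


def contribution_analysis(sample_sets: Mapping[str, set]) -> dict:
    """Which proteins are seen in all sample types, and which are exclusive.

    Returns the intersection-of-all set, the per-set exclusive sets, and the
    full membership-pattern lattice (pattern -> proteins seen in exactly that
    combination of sets), whose sizes sum to the size of the union.
    """
    if not sample_sets:
        raise LibraryError("contribution analysis needs at least one named set")
    names = sorted(sample_sets)
    union = set().union(*sample_sets.values())
    lattice: dict[frozenset, set] = {}
    for item in union:
        pattern = frozenset(n for n in names if item in sample_sets[n])
        lattice.setdefault(pattern, set()).add(item)
    in_all = lattice.get(frozenset(names), set())
    exclusive = {n: lattice.get(frozenset([n]), set()) for n in names}
    return {
        "in_all": in_all,
        "exclusive": exclusive,
        "lattice": lattice,
        "union_size": len(union),
    }


def pseudo_reverse_decoy(sequence: str) -> str:
    """Pseudo-reverse decoy: reverse the peptide, keeping its C-terminal
    residue in place (preserves tryptic character)."""
    if len(sequence) < 2:
        return sequence
    return sequence[-2::-1] + sequence[-1]


def decoy_psm(psm: PSMRecord, score: float) -> PSMRecord:
    """Derive a decoy PSM from a target by pseudo-reversing its sequence."""
    seq = pseudo_reverse_decoy(psm.peptide)
    return replace(
        psm,
        peptide=seq,
        modified_sequence=seq,
        score=score,
        is_decoy=True,
        protein="DECOY_" + psm.protein,
        species="",
    )


PSM_COLUMNS = [
    "run_id",
    "peptide",
    "modified_sequence",
    "charge",
    "score",
    "is_decoy",
    "rt",
    "protein",
    "species",
    "fragments",
]


def _encode_fragments(fragments: Sequence[Fragment]) -> str:
    return ";".join(
        f"{f.ion_type}|{f.ordinal}|{f.charge}|{f.mz:.6f}|{f.intensity:.6f}"
        for f in fragments
    )


def _decode_fragments(text: str) -> tuple[Fragment, ...]:
    if not text or pd.isna(text):
        return ()
    frags = []
    for chunk in str(text).split(";"):
        ion_type, ordinal, charge, mz, intensity = chunk.split("|")
        frags.append(
            Fragment(ion_type, int(ordinal), int(charge), float(mz), float(intensity))
        )
    return tuple(frags)


def write_psm_tsv(psms: Iterable[PSMRecord], path) -> None:
    """Write PSMs as a delimited table, fragment lists packed into one column
    (``type|ordinal|charge|mz|intensity`` chunks joined by ';')."""
    rows = [
        {
            "run_id": p.run_id,
            "peptide": p.peptide,
            "modified_sequence": p.modified_sequence,
            "charge": p.charge,
            "score": p.score,
            "is_decoy": int(p.is_decoy),
            "rt": p.rt,
            "protein": p.protein,
            "species": p.species,
            "fragments": _encode_fragments(p.fragments),
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_psm_tsv(path) -> list[PSMRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"PSM TSV is missing mandatory column(s) {missing}")
    psms = []
    for r in df.itertuples():
        psms.append(
            PSMRecord(
                run_id=str(r.run_id),
                peptide=str(r.peptide),
                modified_sequence=str(r.modified_sequence),
                charge=int(r.charge),
                score=float(r.score),
                is_decoy=bool(int(r.is_decoy)),
                rt=float(r.rt),
                fragments=_decode_fragments(r.fragments),
                protein=str(r.protein),
                species="" if pd.isna(r.species) else str(r.species),
            )
        )
    return psms


__all__ = [
    "Fragment",
    "PSMRecord",
    "RTCalibration",
    "LibraryEntry",
    "SpectralLibrary",
    "LibraryError",
    "calibrate_rt",
    "compute_qvalues",
    "filter_fdr",
    "assemble_library",
    "read_library_tsv",
    "write_library_tsv",
    "library_stats",
    "contribution_analysis",
    "pseudo_reverse_decoy",
    "decoy_psm",
    "strip_modifications",
]
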