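"""Species-split quantification: the deconvolution output stage.

A bulk-xenograft peptide quantification matrix (precursor rows x sample
columns) is partitioned by the classification index into per-species
matrices; peptides shared between species are discarded, peptides unknown to
the index are reported as unmapped.  Per-species peptide matrices are then
rolled up to protein-level quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import ClassificationIndex

ROW_KEY = ["modified_sequence", "charge"]


class DeconvolutionError(ValueError):
    pass


@dataclass
class QuantMatrix:
    """Peptide-level intensities: rows keyed by (modified sequence, charge),
    columns by sample id; missing values are NaN, observed values >= 0."""

    values: pd.DataFrame  # index: MultiIndex (modified_sequence, charge)
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if df.index.nlevels != 2:
            raise DeconvolutionError(
                "QuantMatrix rows must be keyed by (modified_sequence, charge)"
            )
        if df.index.duplicated().any():
            raise DeconvolutionError("duplicate (modified_sequence, charge) rows")
        if df.columns.duplicated().any():
            raise DeconvolutionError("duplicate sample columns")
        if (df.to_numpy() < 0).any():
            raise DeconvolutionError("negative intensities are not allowed")
        self.values.index.names = ROW_KEY

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProteinQuantMatrix:
    """Protein-level intensities for one species compartment."""

    species: str
    values: pd.DataFrame  # index: protein accession
    sample_groups: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


@dataclass
class SplitReport:
    """Full accounting of the split: every input row lands in one bucket."""

    counts: dict[str, int]  # species labels + "discarded_shared" + "unmapped"
    disposition: pd.DataFrame  # per-row: modified_sequence, charge, bucket

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def xenosplit(
    quant: QuantMatrix, index: ClassificationIndex
) -> tuple[dict[str, QuantMatrix], SplitReport]:
    """Split a bulk quantification matrix into per-species matrices.

    A row enters the output for species S iff its stripped sequence is
    retained for S (proteotypic and species-discriminating).  Shared
    peptides are discarded; sequences absent from the index are reported as
    unmapped.  Outputs are disjoint and the report partitions the input
    exactly.
    """
    buckets: list[str] = []
    for modseq, _charge in quant.values.index:
        cls = index.lookup(str(modseq))
        if cls is None:
            buckets.append("unmapped")
        elif cls.retained:
            buckets.append(cls.assigned_species)
        else:
            buckets.append("discarded_shared")
    bucket_arr = np.array(buckets, dtype=object)
    species_labels = sorted(
        {b for b in buckets if b not in ("unmapped", "discarded_shared")}
    )
    out = {
        sp: QuantMatrix(
            values=quant.values.loc[bucket_arr == sp].copy(),
            sample_groups=dict(quant.sample_groups),
        )
        for sp in species_labels
    }
    counts = {sp: int((bucket_arr == sp).sum()) for sp in species_labels}
    counts["discarded_shared"] = int((bucket_arr == "discarded_shared").sum())
    counts["unmapped"] = int((bucket_arr == "unmapped").sum())
    disposition = pd.DataFrame(
        {
            "modified_sequence": quant.values.index.get_level_values(0),
            "charge": quant.values.index.get_level_values(1),
            "bucket": buckets,
        }
    )
    return out, SplitReport(counts=counts, disposition=disposition)


ROLLUP_METHODS = ("top3-mean", "sum", "median")


def rollup_protein(
    quant: QuantMatrix,
    index: ClassificationIndex,
    species: str,
    method: str = "top3-mean",
) -> ProteinQuantMatrix:
    """Aggregate a species-split peptide matrix to protein quantities.

    ``top3-mean`` (default): per protein, take the <=3 peptide rows with the
    highest cross-sample mean intensity; the protein value in each sample is
    the mean of those rows' observed intensities (missing ignored;
    all-missing stays missing).  ``sum`` and ``median`` aggregate all
    peptides of the protein.
    """
    if method not in ROLLUP_METHODS:
        raise DeconvolutionError(
            f"unknown rollup method {method!r}; choose from {ROLLUP_METHODS}"
        )
    proteins: dict[str, list[tuple[str, int]]] = {}
    for modseq, charge in quant.values.index:
        cls = index.lookup(str(modseq))
        if cls is None or not cls.retained:
            raise DeconvolutionError(
                f"peptide {modseq!r} is not a retained peptide; split the "
                "matrix before rollup"
            )
        sp, acc = cls.assigned_parent
        if sp != species:
            raise DeconvolutionError(
                f"peptide {modseq!r} belongs to species {sp!r}, not {species!r}"
            )
        proteins.setdefault(acc, []).append((modseq, charge))
    rows = {}
    used: dict[str, list[str]] = {}
    for acc, keys in proteins.items():
        block = quant.values.loc[keys]
        if method == "sum":
            agg = block.sum(axis=0, min_count=1)
        elif method == "median":
            agg = block.median(axis=0)
        else:  # top3-mean
            order = block.mean(axis=1).sort_values(ascending=False)
            top = block.loc[order.index[:3]]
            agg = top.mean(axis=0)
        rows[acc] = agg
        used[acc] = [
            f"{m}/{c}" for m, c in (keys if method != "top3-mean" else order.index[:3])
        ]
    values = pd.DataFrame(rows).T
    values.index.name = "protein"
    values = values[quant.values.columns]
    return ProteinQuantMatrix(
        species=species,
        values=values,
        sample_groups=dict(quant.sample_groups),
        provenance={"method": method, "peptides_used": used},
    )


def read_quant_tsv(path, group_row: bool = False) -> QuantMatrix:
    """Read a peptide quant TSV: columns ``modified_sequence``, ``charge``,
    then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    for col in ROW_KEY:
        if col not in df.columns:
            raise DeconvolutionError(f"quant TSV is missing key column {col!r}")
    df = df.set_index(ROW_KEY)
    return QuantMatrix(values=df.astype(float))


def write_quant_tsv(quant: QuantMatrix | ProteinQuantMatrix, path) -> None:
    quant.values.to_csv(path, sep="\t")


def read_groups_tsv(path) -> dict[str, str]:
    """Read a two-column sample -> group table."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DeconvolutionError("groups TSV needs columns: sample, group")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
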