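"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the statistical structure the pipeline consumes:

* orthologous two-species proteomes with a controllable per-residue
  substitution rate (the knob governing how many tryptic peptides the two
  species share — high sharing is exactly the problem species-discriminating
  filtering solves);
* multi-run PSM tables with separable target/decoy score distributions,
  per-run linear RT transforms and spiked iRT standard peptides;
* two-condition xenograft peptide quantification matrices with known
  differential proteins in each species compartment.

Every generator is driven by a single integer seed and records its ground
truth in a :class:`SyntheticTruth`, sufficient to score split purity,
calibration recovery and differential recovery without re-deriving hidden
state.  The substitution model is deliberately simple (uniform i.i.d.
residues, no codon or domain structure): the pipeline needs controllable
peptide sharing, not evolutionary realism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import ClassificationIndex
from .deconvolve import QuantMatrix
from .digest import DigestParams, digest_proteome, fragment_mz
from .proteome import ProteinRecord, Proteome
from .speclib import Fragment, PSMRecord, pseudo_reverse_decoy

#: Synthetic 11-peptide iRT standard table (stand-in for a commercial
#: calibration kit whose sequences are proprietary; values span the usual
#: iRT scale).  These peptides are injected into every simulated run.
SYNTHETIC_IRT_STANDARDS: dict[str, float] = {
    "AGGSSEPVTGLADK": -24.92,
    "VEATFGVDESANK": 0.0,
    "YILAGVESNK": 12.39,
    "TPVISGGPYYER": 19.79,
    "TPVITGAPYYER": 28.71,
    "GDLDAASYYAPVR": 33.38,
    "DAVTPADFSEWSK": 42.26,
    "TGFIIDPGGVIR": 54.62,
    "GTFIIDPAAIVR": 70.52,
    "FLLQFGAQGSPLFK": 87.23,
    "LGGNEQVTR": 100.00,
}

_ALPHABET = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Proteome defaults give ~200 proteins of 100-400 residues per species at
    5% per-residue ortholog divergence (tryptic peptides then shared between
    species at a high rate, emulating closely related mammalian proteomes).
    PSM defaults give clearly separable target/decoy score distributions and
    gentle per-run RT transforms.  Quant defaults: two groups of four
    replicates, 10% differential proteins per compartment at |log2FC| = 1,
    20% intensity CV, 5% values missing completely at random, and an equal
    tumour/host mixing proportion.
    """

    seed: int = 0
    # ortholog proteomes
    n_proteins: int = 200
    protein_length: tuple[int, int] = (100, 400)
    substitution_rate: float = 0.05
    species: tuple[str, str] = ("human", "mouse")
    # PSM tables
    n_runs: int = 6
    psms_per_run: int = 500
    rt_slope_range: tuple[float, float] = (0.8, 1.2)
    rt_intercept_range: tuple[float, float] = (5.0, 20.0)
    rt_noise_sd: float = 0.15
    target_score_mean: float = 3.5
    target_score_sd: float = 1.0
    decoy_score_mean: float = 0.0
    decoy_score_sd: float = 1.0
    fragment_count_range: tuple[int, int] = (2, 10)
    # xenograft quant matrices
    n_samples_per_group: int = 4
    frac_differential: float = 0.10
    effect_log2fc: float = 1.0
    intensity_cv: float = 0.2
    missingness: float = 0.05
    mixing_proportion: float = 0.5  # weight of species[0]; species[1] gets 1 - this
    max_peptides_per_protein: int = 5
    n_shared_peptides: int = 200
    log2_abundance_mean: float = 20.0
    log2_abundance_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "frac_differential", "missingness",
                     "mixing_proportion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.seed < 0:
            raise SimulationError("seed must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation, serializable next to its outputs."""

    ortholog_map: dict[str, str] = field(default_factory=dict)  # species2 -> species1 acc
    peptide_species: dict[str, str | None] = field(default_factory=dict)
    differential: dict[str, dict[str, float]] = field(default_factory=dict)
    rt_transforms: dict[str, tuple[float, float]] = field(default_factory=dict)
    peptide_irt: dict[str, float] = field(default_factory=dict)
    irt_reference: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["rt_transforms"] = {
            k: tuple(v) for k, v in payload.get("rt_transforms", {}).items()
        }
        return cls(**payload)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def generate_ortholog_proteomes(
    config: SimConfig = SimConfig(),
) -> tuple[Proteome, Proteome, SyntheticTruth]:
    """Generate a base proteome and a diverged ortholog proteome.

    Base-species proteins are i.i.d. residue strings; each ortholog is
    derived by substituting every residue independently with probability
    ``substitution_rate`` (substitutions are unrestricted, so cleavage sites
    can appear or disappear, as in real divergence).
    """
    rng = _rng(config, 1)
    sp1, sp2 = config.species
    lo, hi = config.protein_length
    recs1, recs2 = [], []
    truth = SyntheticTruth()
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = _ALPHABET[rng.integers(0, len(_ALPHABET), size=length)]
        acc1 = f"{sp1[:1].upper()}{i:05d}"
        acc2 = f"{sp2[:1].upper()}{i:05d}"
        sub = rng.random(length) < config.substitution_rate
        ortho = seq.copy()
        if sub.any():
            # replace with a uniformly chosen *different* residue
            shift = rng.integers(1, len(_ALPHABET), size=int(sub.sum()))
            pos = np.searchsorted(_ALPHABET, ortho[sub])
            ortho[sub] = _ALPHABET[(pos + shift) % len(_ALPHABET)]
        recs1.append(ProteinRecord(acc1, sp1, "synthetic", "".join(seq)))
        recs2.append(ProteinRecord(acc2, sp2, "synthetic ortholog", "".join(ortho)))
        truth.ortholog_map[acc2] = acc1
    return Proteome(sp1, recs1), Proteome(sp2, recs2), truth


def generate_psm_dataset(
    proteomes: list[Proteome],
    config: SimConfig = SimConfig(),
    truth: SyntheticTruth | None = None,
    digest_params: DigestParams = DigestParams(),
) -> tuple[dict[str, list[PSMRecord]], SyntheticTruth]:
    """Simulate multi-run DDA PSM tables from digested proteomes.

    Each run draws ``psms_per_run`` target PSMs (peptides sampled from the
    digest, scores ~ N(target mean, sd)) and as many pseudo-reverse decoys
    (scores ~ N(decoy mean, sd)).  Observed RT is a per-run linear transform
    of the peptide's true iRT plus Gaussian noise; the 11 synthetic iRT
    standards are spiked into every run.
    """
    rng = _rng(config, 2)
    truth = truth or SyntheticTruth()
    peptide_parents: dict[str, tuple[str, str]] = {}
    for proteome in proteomes:
        idx = digest_proteome(proteome, digest_params)
        for pep, parents in idx.items():
            if pep not in peptide_parents:
                peptide_parents[pep] = sorted(parents)[0]
    peptides = sorted(peptide_parents)
    if not peptides:
        raise SimulationError("digest produced no peptides to sample")
    for pep in peptides:
        if pep not in truth.peptide_irt:
            truth.peptide_irt[pep] = float(rng.uniform(-20.0, 120.0))
    truth.irt_reference = dict(SYNTHETIC_IRT_STANDARDS)
    runs: dict[str, list[PSMRecord]] = {}
    flo, fhi = config.fragment_count_range
    for r in range(config.n_runs):
        run_id = f"run{r + 1:02d}"
        slope = float(rng.uniform(*config.rt_slope_range))
        intercept = float(rng.uniform(*config.rt_intercept_range))
        truth.rt_transforms[run_id] = (slope, intercept)
        psms: list[PSMRecord] = []

        def observed_rt(irt: float) -> float:
            return slope * irt + intercept + float(rng.normal(0.0, config.rt_noise_sd))

        def make_fragments(seq: str) -> tuple[Fragment, ...]:
            n_possible = len(seq) - 1
            k = int(rng.integers(flo, fhi + 1))
            k = min(k, 2 * n_possible)
            ions = [("y", o) for o in range(1, n_possible + 1)]
            ions += [("b", o) for o in range(2, n_possible + 1)]
            pick = rng.choice(len(ions), size=min(k, len(ions)), replace=False)
            frags = []
            for j in pick:
                ion_type, ordinal = ions[int(j)]
                frags.append(
                    Fragment(
                        ion_type=ion_type,
                        ordinal=ordinal,
                        charge=1,
                        mz=fragment_mz(seq, ion_type, ordinal, 1),
                        intensity=float(rng.lognormal(0.0, 1.0)),
                    )
                )
            return tuple(frags)

        # spiked iRT standards (always enough points to calibrate)
        for pep, irt in SYNTHETIC_IRT_STANDARDS.items():
            psms.append(
                PSMRecord(
                    run_id=run_id,
                    peptide=pep,
                    modified_sequence=pep,
                    charge=2,
                    score=float(
                        rng.normal(config.target_score_mean, config.target_score_sd)
                    ),
                    is_decoy=False,
                    rt=observed_rt(irt),
                    fragments=make_fragments(pep),
                    protein="IRT_STANDARD",
                    species="",
                )
            )
        chosen = rng.integers(0, len(peptides), size=config.psms_per_run)
        for j in chosen:
            pep = peptides[int(j)]
            species, acc = peptide_parents[pep]
            target = PSMRecord(
                run_id=run_id,
                peptide=pep,
                modified_sequence=pep,
                charge=int(rng.choice([2, 3])),
                score=float(
                    rng.normal(config.target_score_mean, config.target_score_sd)
                ),
                is_decoy=False,
                rt=observed_rt(truth.peptide_irt[pep]),
                fragments=make_fragments(pep),
                protein=acc,
                species=species,
            )
            psms.append(target)
            dseq = pseudo_reverse_decoy(pep)
            psms.append(
                PSMRecord(
                    run_id=run_id,
                    peptide=dseq,
                    modified_sequence=dseq,
                    charge=target.charge,
                    score=float(
                        rng.normal(config.decoy_score_mean, config.decoy_score_sd)
                    ),
                    is_decoy=True,
                    rt=float(rng.uniform(0.0, 120.0)),
                    fragments=make_fragments(dseq),
                    protein="DECOY_" + acc,
                    species="",
                )
            )
        runs[run_id] = psms
    return runs, truth


def generate_xenograft_quant(
    proteomes: list[Proteome],
    index: ClassificationIndex,
    config: SimConfig = SimConfig(),
    truth: SyntheticTruth | None = None,
) -> tuple[QuantMatrix, SyntheticTruth]:
    """Simulate a two-condition bulk-xenograft peptide quant matrix.

    Protein baselines are lognormal; each observed peptide's intensity is
    its protein abundance x a peptide-specific efficiency x multiplicative
    lognormal noise at the configured CV.  A fraction of proteins per
    species compartment receives the configured |log2FC| (random sign) in
    group 2.  The first species' proteins are scaled by the mixing
    proportion, the second's by its complement.  Shared (non-discriminating)
    peptides are included and receive summed signal from all their parents;
    missingness is applied completely at random.
    """
    rng = _rng(config, 3)
    truth = truth or SyntheticTruth()
    if len(proteomes) != 2:
        raise SimulationError("xenograft simulation expects exactly two proteomes")
    sp_weights = {
        proteomes[0].species: config.mixing_proportion,
        proteomes[1].species: 1.0 - config.mixing_proportion,
    }
    # peptides per protein from the classification index
    retained_by_protein: dict[tuple[str, str], list[str]] = {}
    shared_peptides: list[str] = []
    for seq, cls in index.peptides.items():
        if cls.retained:
            retained_by_protein.setdefault(cls.assigned_parent, []).append(seq)
        else:
            shared_peptides.append(seq)
    shared_peptides.sort()
    n_groups = 2
    n = config.n_samples_per_group
    samples = [f"G{g + 1}_S{i + 1}" for g in range(n_groups) for i in range(n)]
    groups = {s: f"group{g + 1}" for g in range(n_groups) for i in range(n)
              for s in [f"G{g + 1}_S{i + 1}"]}
    group2 = np.array([groups[s] == "group2" for s in samples])

    abundance: dict[tuple[str, str], float] = {}
    effect: dict[tuple[str, str], float] = {}
    for proteome in proteomes:
        accs = [r.accession for r in proteome]
        n_diff = int(round(config.frac_differential * len(accs)))
        diff_idx = rng.choice(len(accs), size=n_diff, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_diff)
        truth.differential[proteome.species] = {}
        for k, i in enumerate(diff_idx):
            truth.differential[proteome.species][accs[int(i)]] = float(
                signs[k] * config.effect_log2fc
            )
        for acc in accs:
            key = (proteome.species, acc)
            abundance[key] = float(
                sp_weights[proteome.species]
                * 2.0 ** rng.normal(config.log2_abundance_mean, config.log2_abundance_sd)
            )
            effect[key] = truth.differential[proteome.species].get(acc, 0.0)

    noise_sigma = float(np.sqrt(np.log1p(config.intensity_cv**2)))
    rows: dict[tuple[str, int], np.ndarray] = {}
    for key in sorted(retained_by_protein):
        species, acc = key
        if key not in abundance:
            continue
        if sp_weights.get(species, 0.0) == 0.0:
            continue  # compartment absent from the mixture: never observed
        peps = sorted(retained_by_protein[key])
        if len(peps) > config.max_peptides_per_protein:
            pick = rng.choice(len(peps), size=config.max_peptides_per_protein,
                              replace=False)
            peps = [peps[int(i)] for i in sorted(pick)]
        for pep in peps:
            eff = float(rng.lognormal(0.0, 0.5))
            base = abundance[key] * eff
            mean = np.where(group2, base * 2.0 ** effect[key], base)
            noise = rng.lognormal(0.0, noise_sigma, size=len(samples))
            rows[(pep, 2)] = mean * noise
            truth.peptide_species[pep] = species
    # shared peptides: summed contribution of every parent
    n_shared = min(config.n_shared_peptides, len(shared_peptides))
    if n_shared:
        pick = rng.choice(len(shared_peptides), size=n_shared, replace=False)
        for i in sorted(pick):
            pep = shared_peptides[int(i)]
            cls = index.peptides[pep]
            eff = float(rng.lognormal(0.0, 0.5))
            mean = np.zeros(len(samples))
            for species, accs in cls.parents.items():
                for acc in accs:
                    key = (species, acc)
                    if key not in abundance:
                        continue
                    base = abundance[key] * eff
                    mean += np.where(group2, base * 2.0 ** effect[key], base)
            noise = rng.lognormal(0.0, noise_sigma, size=len(samples))
            rows[(pep, 2)] = mean * noise
            truth.peptide_species[pep] = None
    if not rows:
        raise SimulationError("no peptides available to quantify")
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    values.index = pd.MultiIndex.from_tuples(values.index,
                                             names=["modified_sequence", "charge"])
    if config.missingness > 0:
        mask = rng.random(values.shape) < config.missingness
        values = values.mask(mask)
    return QuantMatrix(values=values, sample_groups=groups), truth
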