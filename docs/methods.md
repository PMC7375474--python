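# Methods

## The deconvolution model

`xenosplit` treats species deconvolution of bulk xenograft proteomics as a
purely sequence-level classification problem. Given two single-species
proteomes (tumour species and host species), every tryptic peptide of the
combined sequence space falls into one of three classes:

* **retained** — maps to exactly one accession of exactly one species; its
  signal is attributable to one protein in one compartment and it is the
  unit of quantification;
* **discarded (shared)** — maps to more than one parent, either several
  proteins within a species (not proteotypic) or both species (not
  species-discriminating); its signal is ambiguous and it is excluded;
* **unmapped** — observed in the data but absent from the combined digest
  (wrong database, contaminant, unconsidered modification); it is reported,
  never silently dropped.

Retention is equivalent to "occurs exactly once in the combined database",
so an independent duplicate-count check (`retained_equivalence_check`) can
recompute the retained set from the raw digest and compare. The model's key
assumption is exact sequence matching: a single substituted residue makes a
peptide species-discriminating. Isoleucine and leucine are isobaric in MS
and indistinguishable in practice; the index therefore offers an optional
I=L-collapsed mode, while the default keeps exact string comparison to match
how search engines compare peptides to a FASTA. Modified peptide sequences
are classified by their stripped backbone, since species identity is a
property of the amino-acid sequence, not its modifications.

## Digestion and masses

Trypsin cleaves C-terminal to K/R; the classical rule suppresses cleavage
before proline (default on; a trypsin/P mode is available since search
engines differ). Products with up to `max_missed_cleavages` internal sites
(default 2, the usual database-search setting) are enumerated, then a
7–52-residue length window (a common library-building default; configurable)
is applied. Protein N-terminal methionine is not clipped. Masses are
monoisotopic, taken from pyteomics' residue tables;
carbamidomethyl-cysteine (+57.0215 Da) is the single fixed modification,
reflecting routine alkylation. Fragment m/z values are computed for b/y
series at the usual `(neutral + z·proton)/z`.

## Library construction

The library builder consumes annotated multi-run PSM tables (it does not
touch spectra; peak extraction and scoring belong to the search engine).

* **RT calibration.** Per run, ordinary least squares of observed RT on the
  reference iRT of spiked standard peptides (r² = 1 − SSres/SStot). Runs
  with r² < 0.8 are flagged excluded and contribute nothing. The inverse
  map converts a representative PSM's RT to iRT. The bundled 11-peptide iRT
  table (`SYNTHETIC_IRT_STANDARDS`) is a synthetic stand-in spanning the
  conventional iRT range; any peptide→iRT table can be supplied instead.
* **Error control.** Target-decoy q-values: FDR(s) = #decoys ≥ s / #targets
  ≥ s, q = running minimum from the lowest score upward (ties share the
  counts at the tie group's end). Two-stage filtering at 1%: PSM/peptide
  level first, then protein level on best-peptide scores, removing failing
  proteins with all their PSMs. A pseudo-reverse decoy generator (reverse,
  keep C-terminal residue) supports synthetic pipelines.
* **Consensus.** Per (modified sequence, charge) the representative is the
  highest-scoring PSM across non-excluded runs — a deliberate, simple
  choice over spectrum averaging, recorded in provenance. Transitions are
  the top ≤6 fragments by intensity (ties broken toward lower product m/z
  for determinism), rescaled to max = 1; precursors with <3 fragments are
  dropped. Every entry carries 3–6 transitions as a hard invariant.

## Quantification and statistics

The split partitions quant-matrix rows by classification; the per-species
outputs are disjoint and the report counts always sum to the input rows.
Protein rollup defaults to the top-3-mean: the ≤3 peptides with the highest
cross-sample mean, averaged per sample (missing ignored, all-missing stays
missing); `sum` and `median` are selectable, and the method plus peptides
used are recorded in provenance. No imputation anywhere.

Downstream, each species' matrix is quantile-normalized (classic rank-mean;
with missing values each column contributes its quantile function by linear
interpolation, ties share the mean of the reference values at the ranks
they span, and missing stays missing), log2-transformed (zeros treated as
missing), and tested with a two-tailed equal-variance Student t-test per
protein (≥2 observed values per group required; under-powered proteins are
reported as untested). Benjamini–Hochberg adjustment is applied across
tested proteins; significance is q < 0.05 and the fold-change filter keeps
|log2FC| ≥ 0.58 (≈1.5-fold) inclusively. Degenerate zero-variance proteins
get p = 1 when group means are equal (no evidence) and p = 0 otherwise.
Testing operates on normalized log2 intensities — the conventional
label-free workflow — and this choice is fixed rather than configurable to
keep results comparable across runs.

## The synthetic-data generator

The generator emulates the statistical structure each stage consumes, not
the biology:

* **Ortholog proteomes.** Base-species proteins are i.i.d. uniform residue
  strings (200 proteins of 100–400 residues by default); orthologs
  substitute each residue independently at rate 0.05. With uniform residue
  frequencies, tryptic peptides average ~10 residues, so a typical peptide
  survives unchanged with probability ≈ 0.95¹⁰ ≈ 0.6 — a high shared
  fraction emulating closely related mammalian proteomes, which is exactly
  the regime the discriminating-peptide filter exists for. The model is
  deliberately non-evolutionary (no codon structure, no conservation
  gradients); what matters is a controllable sharing knob that is monotone
  in the substitution rate.
* **PSM tables.** Peptides are sampled from the digest; true iRTs are
  uniform on [−20, 120]; each run applies a linear RT transform (slope
  0.8–1.2, intercept 5–20 min, Gaussian noise sd 0.15 min) and spikes the
  11 iRT standards. Target scores are N(3.5, 1) and decoys N(0, 1) —
  separable but overlapping, as in real search-score distributions; a null
  variant sets the two distributions equal.
* **Xenograft quant matrices.** Protein baselines are lognormal (log2 mean
  20, sd 2, spanning the usual dynamic range); peptide intensity = protein
  abundance × lognormal peptide efficiency × multiplicative noise at 20% CV;
  4 + 4 samples in two conditions; 10% of each species' proteins receive a
  ±1 log2FC effect in group 2; the two compartments are mixed 50:50 (a
  species with weight 0 is simply never observed); 5% of values are missing
  completely at random; up to 5 retained peptides per protein plus 200
  shared peptides (which receive summed signal from all parents). Intensity-
  dependent missingness is a known omission — real DIA data censor low
  intensities preferentially, so false-negative rates on real data will be
  worse for low-abundance proteins than these simulations suggest.

Every generator consumes a single integer seed through numpy's seeded
`default_rng` (per-stage seed sequences), so fixed seeds give identical
outputs; the truth object (ortholog map, per-peptide species of origin,
differential proteins with signed effects, per-run RT transforms, true
iRTs) is serialized as JSON next to the generated files.

What passing these simulations shows — and does not. Split purity,
partition accounting and oracle agreement are exact, data-independent
properties and transfer directly to real data. Recovery and FDR numbers
are specific to the simulated conditions (no batch effects, no correlated
peptides beyond the shared protein factor, MCAR missingness, exact
normality of log-noise) and should be read as verification that the
machinery is wired correctly, not as expected performance on tissue data.

## Evaluation harness sizes

`scripts/acceptance.py` and the acceptance tests use: 100 random sequences
(10–200 residues) × missed ∈ {0,1,2} × proline on/off against the
brute-force digestion oracle; 20 seeded 40-protein ortholog pairs for the
classification oracle and split purity; 1000 random matrices for partition
accounting; ≥10,000 PSMs for null q-value calibration; 200 repetitions of
1000-protein null matrices for false-positive control; and one 1000-protein-
per-species end-to-end study (10% differential, |log2FC| = 1, CV 0.2,
4 vs 4) for recovery. These sizes keep a full run around a minute on one
CPU while leaving the Monte-Carlo error of each estimate well below the
margins being checked.

## Known limitations

* Discrimination is exact-match only; no mismatch-tolerant or
  homology-aware matching.
* Protein-level inference is accession-based (no protein grouping or
  parsimony), matching how proteotypic status is usually defined.
* The library consensus uses the best-scoring run; spectrum averaging is
  not implemented.
* No raw-spectrum, chromatogram or SWATH-window functionality: the package
  starts at PSM tables and quantification matrices.
* Enrichment analysis, network clustering and visualization are out of
  scope.
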