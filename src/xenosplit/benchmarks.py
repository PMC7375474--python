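"""Self-contained evaluation harnesses scoring the pipeline against truth.

These run the full machinery on synthetic studies where the ground truth is
known and measure how well each stage behaves: error-rate calibration of the
target-decoy q-value estimator under a null, false-positive control of the
differential test on null data, and end-to-end recovery of truly
differential proteins through split -> rollup -> normalize -> test -> fold-
change filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import classify_peptides
from .deconvolve import ProteinQuantMatrix, rollup_protein, xenosplit
from .digest import DigestParams, digest_proteome
from .proteome import combine_proteomes
from .simulate import (
    SimConfig,
    generate_ortholog_proteomes,
    generate_psm_dataset,
    generate_xenograft_quant,
)
from .speclib import compute_qvalues
from .stats import differential_test, fold_change_filter, quantile_normalize


def null_fdr_calibration(
    seed: int = 0,
    n_psms: int = 10_000,
    q_threshold: float = 0.01,
) -> dict:
    """Fraction of target PSMs passing a q-value cut under a complete null.

    Target and decoy scores are drawn from the same distribution (no true
    identifications), so any target passing the cut is a false positive; a
    correct estimator keeps the passing fraction at or below the nominal
    threshold.
    """
    psms_per_run = max(1, n_psms // 5)
    cfg = SimConfig(
        seed=seed,
        n_proteins=60,
        n_runs=5,
        psms_per_run=psms_per_run,
        target_score_mean=0.0,
        target_score_sd=1.0,
        decoy_score_mean=0.0,
        decoy_score_sd=1.0,
    )
    p1, p2, _ = generate_ortholog_proteomes(cfg)
    runs, _ = generate_psm_dataset([p1, p2], cfg)
    psms = [p for run in runs.values() for p in run]
    q = compute_qvalues([p.score for p in psms], [p.is_decoy for p in psms])
    targets = ~np.isnan(q)
    passing = np.sum(q[targets] <= q_threshold)
    return {
        "n_targets": int(targets.sum()),
        "n_passing": int(passing),
        "fraction_passing": float(passing / targets.sum()),
    }


def null_differential_fpr(
    seed: int = 0,
    n_reps: int = 200,
    n_proteins: int = 1000,
    n_per_group: int = 4,
    alpha: float = 0.05,
) -> dict:
    """Mean fraction of q < alpha calls on repeated null protein matrices.

    Each repetition draws lognormal intensities with no group effect; the
    BH-adjusted test should call (on average) fewer than alpha of the
    proteins significant.
    """
    rng = np.random.default_rng(seed)
    samples = [f"a{i}" for i in range(n_per_group)] + [
        f"b{i}" for i in range(n_per_group)
    ]
    groups = {s: ("group1" if s.startswith("a") else "group2") for s in samples}
    fractions = []
    for _ in range(n_reps):
        values = rng.lognormal(mean=14.0, sigma=1.0, size=(n_proteins, 2 * n_per_group))
        matrix = ProteinQuantMatrix(
            species="null",
            values=pd.DataFrame(
                values, columns=samples, index=[f"P{i}" for i in range(n_proteins)]
            ),
            sample_groups=groups,
        )
        res = differential_test(matrix, alpha=alpha)
        fractions.append(float(res["significant"].sum()) / n_proteins)
    return {
        "n_reps": n_reps,
        "mean_fraction_significant": float(np.mean(fractions)),
        "max_fraction_significant": float(np.max(fractions)),
    }


def end_to_end_recovery(
    seed: int = 0,
    n_proteins: int = 1000,
    frac_differential: float = 0.10,
    effect_log2fc: float = 1.0,
    intensity_cv: float = 0.2,
    n_per_group: int = 4,
    alpha: float = 0.05,
    fc_threshold: float = 0.58,
) -> dict:
    """Run the full pipeline on a simulated two-condition xenograft and
    score recovery of the truly differential proteins per species.

    Returns per-species recall (recovered / truly differential) and
    empirical FDR (called-but-not-true / called), plus the split report.
    """
    cfg = SimConfig(
        seed=seed,
        n_proteins=n_proteins,
        frac_differential=frac_differential,
        effect_log2fc=effect_log2fc,
        intensity_cv=intensity_cv,
        n_samples_per_group=n_per_group,
    )
    p1, p2, truth = generate_ortholog_proteomes(cfg)
    combined = combine_proteomes([p1, p2])
    index = classify_peptides(digest_proteome(combined, DigestParams()))
    quant, truth = generate_xenograft_quant([p1, p2], index, cfg, truth)
    by_species, report = xenosplit(quant, index)
    out: dict = {"split_counts": report.counts, "species": {}}
    for species, matrix in by_species.items():
        proteins = rollup_protein(matrix, index, species, method="top3-mean")
        normalized = quantile_normalize(proteins)
        results = differential_test(normalized, alpha=alpha)
        hits = fold_change_filter(results[results["significant"]], fc_threshold)
        called = set(hits["protein"])
        true = set(truth.differential.get(species, {}))
        recovered = called & true
        out["species"][species] = {
            "n_quantified": int(len(proteins.values)),
            "n_true_differential": len(true),
            "n_called": len(called),
            "n_recovered": len(recovered),
            "recall": len(recovered) / len(true) if true else float("nan"),
            "empirical_fdr": (len(called) - len(recovered)) / len(called)
            if called
            else 0.0,
        }
    return out
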