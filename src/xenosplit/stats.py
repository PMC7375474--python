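"""Downstream statistics for species-split protein quantification.

The two per-species protein matrices are analysed separately: quantile
normalization to remove sample-wise intensity distribution differences,
log2 transformation, equal-variance two-sample t-tests between conditions
with Benjamini-Hochberg correction, and a |log2 fold change| >= 0.58
(1.5-fold) cut-off on top of q < 0.05 significance.  Evaluation analytics
(set overlaps, reference-list matching, Pearson similarity matrices) mirror
how reference libraries are benchmarked against study-specific ones.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from statsmodels.stats.multitest import multipletests

from .deconvolve import ProteinQuantMatrix


class StatsError(ValueError):
    pass


def _qnorm_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization with missing-value support.

    Missing values are excluded from ranking and remain missing.  Columns
    with unequal observed counts contribute to the reference distribution by
    linear interpolation of their quantile functions; tied values within a
    column share the mean of the reference values at the ranks they span.
    """
    X = df.to_numpy(dtype=float)
    n_rows, n_cols = X.shape
    counts = np.sum(~np.isnan(X), axis=0)
    if np.any(counts == 0):
        raise StatsError("a sample with no observed values cannot be normalized")
    m_ref = int(counts.max())
    probs_ref = np.linspace(0.0, 1.0, m_ref) if m_ref > 1 else np.array([0.5])
    # reference quantile function = mean of per-column quantile functions
    ref_accum = np.zeros(m_ref)
    for j in range(n_cols):
        col = np.sort(X[~np.isnan(X[:, j]), j])
        if len(col) == 1:
            ref_accum += col[0]
            continue
        probs_col = np.linspace(0.0, 1.0, len(col))
        ref_accum += np.interp(probs_ref, probs_col, col)
    reference = ref_accum / n_cols
    out = np.full_like(X, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(X[:, j])
        col = X[mask, j]
        m = len(col)
        if m == 1:
            out[mask, j] = reference.mean() if m_ref > 1 else reference[0]
            continue
        probs_col = np.linspace(0.0, 1.0, m)
        ref_col = np.interp(probs_col, probs_ref, reference)
        order = np.argsort(col, kind="stable")
        normalized = np.empty(m)
        sorted_col = col[order]
        # tie groups share the mean of their rank reference values
        i = 0
        while i < m:
            k = i
            while k + 1 < m and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            normalized[order[i : k + 1]] = ref_col[i : k + 1].mean()
            i = k + 1
        out[mask, j] = normalized
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Quantile-normalize a protein matrix (classic rank-mean scheme)."""
    if matrix.values.shape[1] < 2:
        raise StatsError("quantile normalization needs at least two samples")
    values = _qnorm_frame(matrix.values)
    prov = dict(matrix.provenance)
    prov["quantile_normalized"] = True
    return ProteinQuantMatrix(
        species=matrix.species,
        values=values,
        sample_groups=dict(matrix.sample_groups),
        provenance=prov,
    )


def differential_test(
    matrix: ProteinQuantMatrix,
    group_labels: Mapping[str, str] | None = None,
    groups: tuple[str, str] | None = None,
    min_per_group: int = 2,
    alpha: float = 0.05,
    log2_transform: bool = True,
) -> pd.DataFrame:
    """Two-tailed equal-variance t-test per protein with BH correction.

    Intensities are log2-transformed first (zeros treated as missing);
    log2FC is mean(group2) - mean(group1) in log2 space.  Proteins with
    fewer than ``min_per_group`` observed values in either group are skipped
    and reported with ``tested=False`` rather than dropped.

    Returns a DataFrame with columns: protein, species, n1, n2, log2fc, t,
    p, q, significant, tested.
    """
    labels = group_labels if group_labels is not None else matrix.sample_groups
    if not labels:
        raise StatsError("no group labels supplied")
    if groups is None:
        uniq = sorted(set(labels.values()))
        if len(uniq) != 2:
            raise StatsError(f"expected exactly two groups, got {uniq}")
        groups = (uniq[0], uniq[1])
    g1 = [s for s in matrix.values.columns if labels.get(s) == groups[0]]
    g2 = [s for s in matrix.values.columns if labels.get(s) == groups[1]]
    if not g1 or not g2:
        raise StatsError(f"groups {groups} not found among samples")
    X = matrix.values.to_numpy(dtype=float)
    if log2_transform:
        with np.errstate(divide="ignore", invalid="ignore"):
            X = np.where(X > 0, np.log2(np.where(X > 0, X, 1.0)), np.nan)
    A = matrix.values.columns.get_indexer(g1)
    B = matrix.values.columns.get_indexer(g2)
    xa, xb = X[:, A], X[:, B]
    n1 = np.sum(~np.isnan(xa), axis=1)
    n2 = np.sum(~np.isnan(xb), axis=1)
    tested = (n1 >= min_per_group) & (n2 >= min_per_group)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(xa, axis=1)
        m2 = np.nanmean(xb, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tres = _sstats.ttest_ind(
                xa, xb, axis=1, equal_var=True, nan_policy="omit"
            )
    t = np.asarray(-tres.statistic, dtype=float)  # sign: group2 vs group1
    p = np.asarray(tres.pvalue, dtype=float)
    # degenerate zero-variance proteins: identical means -> no evidence
    with np.errstate(invalid="ignore"):
        degenerate = tested & ~np.isfinite(p)
        equal_means = np.isclose(m1, m2)
        t = np.where(degenerate & equal_means, 0.0, t)
        p = np.where(degenerate & equal_means, 1.0, p)
        p = np.where(degenerate & ~equal_means, 0.0, p)
        t = np.where(degenerate & ~equal_means, np.sign(m2 - m1) * np.inf, t)
    q = np.full(len(p), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "protein": matrix.values.index,
            "species": matrix.species,
            "n1": n1,
            "n2": n2,
            "log2fc": m2 - m1,
            "t": t,
            "p": np.where(tested, p, np.nan),
            "q": q,
            "significant": np.where(tested, q < alpha, False),
            "tested": tested,
        }
    )
    return out


def fold_change_filter(results: pd.DataFrame, threshold_log2: float = 0.58) -> pd.DataFrame:
    """Keep results with |log2FC| >= threshold (inclusive); adds a
    ``direction`` column ("up"/"down", group2 relative to group1)."""
    kept = results[results["log2fc"].abs() >= threshold_log2].copy()
    kept["direction"] = np.where(kept["log2fc"] >= 0, "up", "down")
    return kept


def overlap_sets(set_a: Iterable, set_b: Iterable) -> dict:
    """Venn counts for two sets plus the shared fraction relative to B
    (B playing the role of the reference)."""
    a, b = set(set_a), set(set_b)
    shared = a & b
    return {
        "a_only": len(a - b),
        "shared": len(shared),
        "b_only": len(b - a),
        "shared_fraction_of_b": len(shared) / len(b) if b else 0.0,
        "shared_items": shared,
    }


def match_reference_list(proteins: Iterable, reference: Iterable) -> dict:
    """Subset of proteins present in a reference list (e.g. an organellar
    proteome inventory), with counts."""
    prots, ref = set(proteins), set(reference)
    matched = prots & ref
    return {
        "matched": matched,
        "n_matched": len(matched),
        "n_proteins": len(prots),
        "n_reference": len(ref),
    }


def correlation_matrix(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame | None = None,
    min_complete: int = 3,
) -> pd.DataFrame:
    """Pearson similarity matrix between sample columns.

    When two matrices are given, they are joined on their shared protein
    rows first (the benchmarking use: the same samples quantified through
    two different libraries).  Correlations use pairwise-complete rows; a
    pair with fewer than ``min_complete`` complete rows is NaN (undefined).
    Diagonal entries are 1.
    """
    if matrix_b is not None:
        shared = matrix_a.index.intersection(matrix_b.index)
        if len(shared) < min_complete:
            raise StatsError(
                f"only {len(shared)} shared proteins; need >= {min_complete}"
            )
        combined = pd.concat(
            [matrix_a.loc[shared], matrix_b.loc[shared]], axis=1
        )
    else:
        combined = matrix_a
    corr = combined.corr(method="pearson", min_periods=min_complete)
    np.fill_diagonal(corr.values, 1.0)
    return corr
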