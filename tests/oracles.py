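"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from first principles, by
exhaustive enumeration, without sharing code with the implementation paths
they check.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def oracle_digest(
    sequence: str,
    max_missed: int,
    min_length: int,
    max_length: int,
    proline_rule: bool,
) -> set[tuple[str, int, int, int]]:
    """Enumerate every substring and apply the cleavage definition directly.

    Returns {(peptide, start, end, missed), ...}.  A position p (between
    residues p-1 and p) is a boundary iff it is a protein terminus or a
    cleavage site: residue p-1 is K/R, and (with the proline rule) residue p
    is not P.
    """

    def is_site(p: int) -> bool:
        if p <= 0 or p >= len(sequence):
            return False
        if sequence[p - 1] not in "KR":
            return False
        if proline_rule and sequence[p] == "P":
            return False
        return True

    def is_boundary(p: int) -> bool:
        return p == 0 or p == len(sequence) or is_site(p)

    out = set()
    n = len(sequence)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not (is_boundary(i) and is_boundary(j)):
                continue
            internal = sum(1 for p in range(i + 1, j) if is_site(p))
            if internal > max_missed:
                continue
            if not (min_length <= j - i <= max_length):
                continue
            out.add((sequence[i:j], i, j, internal))
    return out


def oracle_parent_counts(proteomes, digest_fn, params) -> Counter:
    """Occurrence counting over the combined digest: how many distinct
    (species, accession) parents produce each peptide sequence."""
    parents: dict[str, set] = {}
    for proteome in proteomes:
        for rec in proteome:
            for pep in digest_fn(rec.sequence, params, rec.accession, rec.species):
                parents.setdefault(pep.sequence, set()).add(
                    (rec.species, rec.accession)
                )
    return Counter({seq: len(p) for seq, p in parents.items()})


def oracle_qvalues(scores, is_decoy) -> np.ndarray:
    """Target-decoy q-values by brute force over all score thresholds."""
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    thresholds = np.unique(scores)
    fdr_at = {}
    for s in thresholds:
        t = np.sum((scores >= s) & ~is_decoy)
        d = np.sum((scores >= s) & is_decoy)
        fdr_at[s] = d / t if t else np.inf
    q = np.empty(len(scores))
    for i, s in enumerate(scores):
        q[i] = min(min(fdr_at[t] for t in thresholds if t <= s), 1.0)
    q[is_decoy] = np.nan
    return q


def oracle_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up: sorted p * m / rank with a cumulative
    minimum from the largest p downward."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def oracle_pearson(x, y) -> float:
    """Pearson r from the defining sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
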