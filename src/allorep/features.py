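"""Repertoire feature statistics for labeled clonotype subsets.

Covers the descriptive comparisons between alloreactive subsets and whole
repertoires: summed and median clonotype frequencies with a Mann-Whitney
test, V-gene usage vectors and their cosine similarity, the CDR3-length
spectratype with the long/short (>14 aa vs <=14 aa) ratio, and positional
amino-acid occurrence profiles for a fixed CDR3 length.

Counting convention: V usage and positional profiles default to clonotype
weighting (each distinct clonotype counted once); read weighting is
available where clone size should matter.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from allorep.io import AA_ALPHABET, Repertoire


@dataclass
class FrequencyStats:
    sum_frequency: float
    median_ratio: float
    mw_p: float
    n_labeled: int
    n_comparator: int


def frequency_stats(
    labeled: Repertoire,
    whole: Repertoire,
    threshold_keys: set[str] | None = None,
    key_mode: str = "cdr3",
) -> FrequencyStats:
    """Frequency statistics of a labeled subset against the whole repertoire.

    ``threshold_keys`` restricts the whole-repertoire comparator to
    clonotypes passing the same expansion threshold as was applied to the
    labeled subset (so like is compared with like). The test is a two-sided
    Mann-Whitney U on log10 frequencies; the exact method is used for small
    samples (n < 50 in both groups), the tie-corrected normal approximation
    otherwise.
    """
    lab_freqs = np.array([c.frequency for c in labeled if c.frequency > 0])
    comp = whole.clonotypes
    if threshold_keys is not None:
        comp = [c for c in comp if c.key(key_mode) in threshold_keys]
    comp_freqs = np.array([c.frequency for c in comp if c.frequency > 0])
    sum_freq = float(lab_freqs.sum())
    if len(lab_freqs) == 0 or len(comp_freqs) == 0:
        return FrequencyStats(sum_freq, math.nan, math.nan, len(lab_freqs), len(comp_freqs))
    median_ratio = float(np.median(lab_freqs) / np.median(comp_freqs))
    method = "exact" if (len(lab_freqs) < 50 and len(comp_freqs) < 50) else "asymptotic"
    mw = stats.mannwhitneyu(
        np.log10(lab_freqs), np.log10(comp_freqs), alternative="two-sided", method=method
    )
    return FrequencyStats(sum_freq, median_ratio, float(mw.pvalue), len(lab_freqs), len(comp_freqs))


def v_usage(
    rep,
    gene_order: list[str] | None = None,
    weighting: str = "clonotype",
) -> pd.Series:
    """Relative V-gene usage over a fixed, shared gene ordering.

    ``weighting='clonotype'`` counts each clonotype once; ``'read'``
    weights by read count. Genes outside ``gene_order`` are pooled into
    ``other``. The result sums to 1 (all-empty input gives an all-NaN
    vector).
    """
    if weighting not in ("clonotype", "read"):
        raise ValueError("weighting must be 'clonotype' or 'read'")
    weights: dict[str, float] = {}
    for c in rep:
        w = 1.0 if weighting == "clonotype" else float(c.count)
        weights[c.v_gene] = weights.get(c.v_gene, 0.0) + w
    if gene_order is None:
        gene_order = sorted(g for g in weights if g)
    vec = pd.Series(0.0, index=list(gene_order) + ["other"])
    for gene, w in weights.items():
        vec[gene if gene in vec.index else "other"] += w
    total = vec.sum()
    return vec / total if total > 0 else vec * math.nan


def cosine_similarity(u, v) -> float:
    """Cosine similarity of two non-negative usage vectors (1 iff proportional)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return math.nan
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class Spectratype:
    """CDR3 aa length histogram with the long/short clone-count ratio."""

    counts: dict[int, int]
    long_short_ratio: float
    length_cut: int = 14

    def to_series(self) -> pd.Series:
        if not self.counts:
            return pd.Series(dtype=int)
        lo, hi = min(self.counts), max(self.counts)
        return pd.Series({ln: self.counts.get(ln, 0) for ln in range(lo, hi + 1)})


def spectratype(clonotypes, length_cut: int = 14) -> Spectratype:
    """Distinct-clonotype counts per CDR3 length and the >cut/<=cut ratio."""
    lengths = Counter(len(c.cdr3_aa) for c in clonotypes)
    n_long = sum(n for ln, n in lengths.items() if ln > length_cut)
    n_short = sum(n for ln, n in lengths.items() if ln <= length_cut)
    if not lengths:
        ratio = math.nan
    elif n_short == 0:
        ratio = math.inf if n_long else math.nan
    else:
        ratio = n_long / n_short
    return Spectratype(dict(lengths), ratio, length_cut)


def positional_profile(clonotypes, length: int = 14) -> pd.DataFrame:
    """Per-position amino-acid occurrence probabilities at a fixed CDR3 length.

    Rows are 1-based CDR3 positions (including the conserved C and F),
    columns the 20 amino acids; only clonotypes of exactly ``length`` aa
    contribute, each distinct clonotype once. Every row sums to 1.
    """
    seqs = {c.cdr3_aa for c in clonotypes if len(c.cdr3_aa) == length}
    profile = pd.DataFrame(
        0.0, index=range(1, length + 1), columns=list(AA_ALPHABET)
    )
    if not seqs:
        return profile
    for seq in seqs:
        for pos, aa in enumerate(seq, start=1):
            profile.loc[pos, aa] += 1.0
    return profile / len(seqs)
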