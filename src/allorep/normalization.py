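"""Trimmed-mean-of-M-values (TMM) library-size normalization.

Sequencing depth alone is a poor scale for comparing clonotype counts
between samples when a few clones dominate a library. TMM estimates a
per-sample scale factor as the doubly-trimmed, precision-weighted mean of
per-clonotype log-ratios (M-values) against a reference sample: the 30%
most extreme M-values on each side and the 5% most extreme average
abundances (A-values) on each side are trimmed, remaining M-values are
weighted by the inverse of their asymptotic binomial variance, and the
resulting factors are rescaled to geometric mean 1. The effective library
size of a sample is its total count times its factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from allorep.io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """A count matrix with TMM factors and effective library sizes."""

    matrix: CountMatrix
    factors: pd.Series  # per-sample, geometric mean 1
    effective_lib_size: pd.Series  # total count * factor

    @property
    def counts(self) -> pd.DataFrame:
        return self.matrix.counts


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    log_ratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    a_cutoff: float = -1e10,
) -> float:
    """Single-pair TMM factor of ``obs`` against ``ref`` (Robinson-Oshlack)."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return np.nan
    o = obs[both]
    r = ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic (binomial) variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    fin = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a, w = m[fin], a[fin], w[fin]
    if len(m) == 0:
        return np.nan
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(matrix: CountMatrix, ref_sample: str | None = None) -> pd.Series:
    """Per-sample TMM scale factors, rescaled to geometric mean 1.

    ``ref_sample=None`` picks the reference automatically as the sample
    whose 75th-percentile scaled count is closest to the mean across
    samples. A sample sharing no nonzero rows with the reference gets
    factor 1 with a warning.
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive total count")
    if ref_sample is None:
        q75 = counts.apply(lambda col: np.quantile(col[col > 0] / col.sum(), 0.75)
                           if (col > 0).any() else 0.0)
        ref_sample = (q75 - q75.mean()).abs().idxmin()
    if ref_sample not in counts.columns:
        raise ValueError(f"unknown reference sample {ref_sample!r}")
    ref = counts[ref_sample].to_numpy(dtype=float)
    raw = {}
    for sid in counts.columns:
        if sid == ref_sample:
            raw[sid] = 1.0
            continue
        f = _tmm_pair(counts[sid].to_numpy(dtype=float), ref)
        if np.isnan(f):
            logger.warning("%s shares no nonzero rows with reference %s; factor set to 1",
                           sid, ref_sample)
            f = 1.0
        raw[sid] = f
    factors = pd.Series(raw)[counts.columns]
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def normalize(matrix: CountMatrix, ref_sample: str | None = None) -> NormalizedMatrix:
    """Attach TMM factors and effective library sizes to a count matrix."""
    factors = tmm_factors(matrix, ref_sample)
    totals = matrix.counts.sum(axis=0)
    return NormalizedMatrix(matrix, factors, totals * factors)
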