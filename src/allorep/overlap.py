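"""Abundance-weighted repertoire overlap (Morisita-Horn index).

The Morisita-Horn index between two abundance vectors x, y over the union
of clonotype keys is

    C = 2 * sum(x_i * y_i) / ((sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) * X * Y)

with X = sum(x), Y = sum(y). It is 1 for proportional repertoires, 0 for
disjoint ones, and invariant to rescaling either vector — the
abundance-aware overlap measure bounded in [0, 1] used throughout the
repertoire-analysis ecosystem (classic Morisita can exceed 1).

``overlap_grid`` evaluates all pairwise indices after restricting each
repertoire to clonotypes passing each fold-expansion threshold, reproducing
the expansion-threshold ladder (no threshold, 2x ... 32x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from allorep.io import Repertoire


def morisita_horn(x, y) -> float:
    """Morisita-Horn similarity of two aligned abundance vectors.

    Vectors must be indexed over the same (union) key set. Returns NaN for
    an empty union (both vectors all-zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("abundance vectors must be aligned over the union of keys")
    X = x.sum()
    Y = y.sum()
    if X <= 0 or Y <= 0:
        return math.nan
    num = 2.0 * float(np.dot(x, y))
    dx = float(np.dot(x, x)) / (X * X)
    dy = float(np.dot(y, y)) / (Y * Y)
    return num / ((dx + dy) * X * Y)


def _pair_index(rep_a: Repertoire, rep_b: Repertoire, key_mode: str) -> float:
    a = {}
    for c in rep_a:
        k = c.key(key_mode)
        a[k] = a.get(k, 0.0) + c.count
    b = {}
    for c in rep_b:
        k = c.key(key_mode)
        b[k] = b.get(k, 0.0) + c.count
    union = list(a.keys() | b.keys())
    if not union:
        return math.nan
    x = np.array([a.get(k, 0.0) for k in union])
    y = np.array([b.get(k, 0.0) for k in union])
    return morisita_horn(x, y)


@dataclass
class OverlapGrid:
    """Per-threshold symmetric sample x sample Morisita-Horn matrices."""

    thresholds: list[int]
    matrices: dict[int, pd.DataFrame]

    def to_long(self) -> pd.DataFrame:
        rows = []
        for t in self.thresholds:
            m = self.matrices[t]
            for i, sa in enumerate(m.index):
                for sb in m.columns[i:]:
                    rows.append((t, sa, sb, m.loc[sa, sb]))
        return pd.DataFrame(rows, columns=["threshold", "sample_a", "sample_b", "index"])


def overlap_grid(
    reps: list[Repertoire],
    calls: dict[str, list] | None = None,
    thresholds: tuple[int, ...] = (1, 2, 4, 8, 16, 32),
    key_mode: str = "cdr3",
) -> OverlapGrid:
    """Pairwise Morisita-Horn at each expansion threshold.

    ``calls`` maps sample_id to that sample's expansion-call list; at
    threshold t > 1 each repertoire is restricted to clonotypes whose
    fold_bins contain t before the index is computed. Threshold 1 means no
    restriction. A repertoire left empty by the restriction produces NaN
    cells in its row/column (some samples genuinely lack 16x/32x clones).
    """
    matrices = {}
    sids = [r.sample_id for r in reps]
    for t in thresholds:
        restricted = []
        for rep in reps:
            if t <= 1 or calls is None:
                restricted.append(rep)
            else:
                sample_calls = calls.get(rep.sample_id, [])
                keep = {c.clonotype_key for c in sample_calls if t in c.fold_bins}
                restricted.append(rep.subset(keep, key_mode))
        m = pd.DataFrame(np.nan, index=sids, columns=sids, dtype=float)
        for i, ra in enumerate(restricted):
            for j in range(i, len(restricted)):
                val = _pair_index(ra, restricted[j], key_mode)
                m.iloc[i, j] = val
                m.iloc[j, i] = val
        matrices[t] = m
    return OverlapGrid(thresholds=list(thresholds), matrices=matrices)
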