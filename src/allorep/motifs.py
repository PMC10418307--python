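"""Specificity-pattern discovery and pattern-set algebra.

Groups TCRs predicted to bind the same peptide-MHC in the style of the
GLIPH2 (grouping of lymphocyte interactions by paratope hotspots)
approach, using two kinds of pattern over the CDR3 paratope region (the
loop minus 3 N-terminal and 2 C-terminal framework-proximal residues):

* local motifs — contiguous k-mers (k = 4..7 by default) enriched in a
  repertoire relative to a reference, tested with a one-sided Fisher exact
  test (fold >= 10, p <= 1e-3, support >= 3 clonotypes by default);
* global templates — groups of same-length CDR3s identical everywhere
  except one paratope-region position, written with a ``%`` wildcard.

Patterns found in both the directly and the indirectly alloreactive
repertoires cannot be attributed to either pathway and are excluded from
both ("exclusive" sets); clonotypes are then classified by the exclusive
patterns their CDR3 matches, with doubly-matching clonotypes excluded the
same way.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from scipy import stats

logger = logging.getLogger(__name__)

#: paratope-region trim: residues removed from the N- and C-terminal ends
DEFAULT_TRIM = (3, 2)
WILDCARD = "%"


@dataclass(frozen=True)
class SpecificityPattern:
    """An enriched CDR3 motif (local) or one-wildcard template (global)."""

    kind: str  # "local" | "global"
    pattern: str
    members: frozenset[str]  # clonotype keys (CDR3 aa)
    fold: float = float("nan")
    p_value: float = float("nan")
    source_conditions: frozenset[str] = frozenset()

    @property
    def support(self) -> int:
        return len(self.members)

    def identity(self) -> tuple[str, str]:
        """Pattern identity used by set algebra: (kind, pattern string)."""
        return (self.kind, self.pattern)

    def matches(self, cdr3: str) -> bool:
        """Does a CDR3 contain (local) / match (global) this pattern?"""
        if self.kind == "local":
            return self.pattern in cdr3
        if len(cdr3) != len(self.pattern):
            return False
        return all(p == WILDCARD or p == c for p, c in zip(self.pattern, cdr3))


def trimmed_region(cdr3: str, trim: tuple[int, int] = DEFAULT_TRIM) -> str:
    """The paratope region of a CDR3: drop trim[0] left / trim[1] right residues."""
    left, right = trim
    return cdr3[left: len(cdr3) - right]


def enumerate_motifs(
    clonotypes,
    k_range: tuple[int, int] = (4, 7),
    trim: tuple[int, int] = DEFAULT_TRIM,
) -> dict[str, set[str]]:
    """Map each contiguous paratope k-mer to the distinct CDR3s containing it.

    A CDR3 shorter than trim[0] + trim[1] + k contributes nothing at that k.
    """
    kmin, kmax = k_range
    motif_members: dict[str, set[str]] = defaultdict(set)
    seen: set[str] = set()
    for c in clonotypes:
        cdr3 = c if isinstance(c, str) else c.cdr3_aa
        if cdr3 in seen:
            continue
        seen.add(cdr3)
        region = trimmed_region(cdr3, trim)
        for k in range(kmin, kmax + 1):
            for i in range(len(region) - k + 1):
                motif_members[region[i: i + k]].add(cdr3)
    return dict(motif_members)


def enrichment_test(
    a: int,
    n: int,
    b: int,
    m: int,
    min_support: int = 3,
    min_fold: float = 10.0,
    alpha: float = 1e-3,
) -> tuple[bool, float, float]:
    """One-sided Fisher exact enrichment of a motif in sample vs reference.

    The motif occurs in ``a`` of ``n`` sample clonotypes and ``b`` of ``m``
    reference clonotypes. The p-value is the hypergeometric upper tail of
    the 2x2 table (a, n-a; b, m-b); fold = (a/n) / ((b + pc)/m) with
    pseudocount pc = 0.5 applied only when b = 0. Returns
    (reported, fold, p): reported iff a >= min_support and fold >= min_fold
    and p <= alpha.
    """
    if n <= 0 or m <= 0:
        raise ValueError("sample and reference sizes must be positive")
    if a > n or b > m or a < 0 or b < 0:
        raise ValueError("occurrence counts exceed group sizes")
    # P(X >= a) for X ~ Hypergeom(N=n+m, K=a+b, n)
    p = float(stats.hypergeom.sf(a - 1, n + m, a + b, n))
    b_eff = b if b > 0 else 0.5
    fold = (a / n) / (b_eff / m)
    reported = a >= min_support and fold >= min_fold and p <= alpha
    return reported, fold, p


def _condition_set(members, condition_of: dict[str, str] | None) -> frozenset[str]:
    if condition_of is None:
        return frozenset()
    return frozenset(condition_of[m] for m in members if m in condition_of)


def discover_patterns(
    clonotypes,
    reference,
    k_range: tuple[int, int] = (4, 7),
    trim: tuple[int, int] = DEFAULT_TRIM,
    min_support: int = 3,
    min_fold: float = 10.0,
    alpha: float = 1e-3,
    condition_of: dict[str, str] | None = None,
) -> list[SpecificityPattern]:
    """Discover enriched local motifs plus global templates in one repertoire.

    Local motifs are tested for enrichment against ``reference`` (any
    iterable of clonotypes/CDR3s); global templates use the support floor
    only, mirroring the HD-based global-similarity grouping. Every member
    of a returned pattern literally contains/matches the pattern.
    """
    sample_cdr3s = {c if isinstance(c, str) else c.cdr3_aa for c in clonotypes}
    ref_cdr3s = {c if isinstance(c, str) else c.cdr3_aa for c in reference}
    n, m = len(sample_cdr3s), len(ref_cdr3s)
    patterns: list[SpecificityPattern] = []

    if n and m:
        ref_motifs = enumerate_motifs(ref_cdr3s, k_range, trim)
        for motif, members in enumerate_motifs(sample_cdr3s, k_range, trim).items():
            a = len(members)
            if a < min_support:
                continue
            b = len(ref_motifs.get(motif, ()))
            reported, fold, p = enrichment_test(a, n, b, m, min_support, min_fold, alpha)
            if reported:
                patterns.append(
                    SpecificityPattern(
                        "local", motif, frozenset(members), fold, p,
                        _condition_set(members, condition_of),
                    )
                )

    patterns.extend(
        global_templates(sample_cdr3s, trim, min_support, condition_of)
    )
    return patterns


def global_templates(
    clonotypes,
    trim: tuple[int, int] = DEFAULT_TRIM,
    min_support: int = 3,
    condition_of: dict[str, str] | None = None,
) -> list[SpecificityPattern]:
    """Group same-length CDR3s identical except at one paratope position.

    Each group of >= min_support distinct CDR3s becomes a template with a
    ``%`` wildcard at the varying position; the wildcard may only fall in
    the paratope (trimmed) region.
    """
    cdr3s = sorted({c if isinstance(c, str) else c.cdr3_aa for c in clonotypes})
    groups: dict[str, set[str]] = defaultdict(set)
    left, right = trim
    for cdr3 in cdr3s:
        for pos in range(left, len(cdr3) - right):
            template = cdr3[:pos] + WILDCARD + cdr3[pos + 1:]
            groups[template].add(cdr3)
    out = []
    for template, members in groups.items():
        # members identical outside the wildcard; require distinct residues there
        pos = template.index(WILDCARD)
        if len({mm[pos] for mm in members}) >= min_support:
            out.append(
                SpecificityPattern(
                    "global", template, frozenset(members),
                    source_conditions=_condition_set(members, condition_of),
                )
            )
    return out


@dataclass
class PatternSets:
    """Pattern sets of the two alloreactive arms after exclusion algebra."""

    direct: list[SpecificityPattern]
    indirect: list[SpecificityPattern]
    unstim: list[SpecificityPattern]
    direct_exclusive: list[SpecificityPattern] = field(default_factory=list)
    indirect_exclusive: list[SpecificityPattern] = field(default_factory=list)
    shared_di: list[SpecificityPattern] = field(default_factory=list)


def pattern_set_algebra(
    direct: list[SpecificityPattern],
    indirect: list[SpecificityPattern],
    unstim: list[SpecificityPattern] | None = None,
    subtract_unstim: bool = True,
) -> PatternSets:
    """Exclusive pattern sets for the direct and indirect arms.

    Patterns whose (kind, string) identity occurs in both arms cannot be
    attributed to one pathway and are removed from both; with
    ``subtract_unstim`` patterns also present in the unstimulated arm are
    removed as background.
    """
    unstim = unstim or []
    direct_ids = {p.identity() for p in direct}
    indirect_ids = {p.identity() for p in indirect}
    unstim_ids = {p.identity() for p in unstim}
    shared = direct_ids & indirect_ids
    drop = set(shared)
    if subtract_unstim:
        drop |= unstim_ids
    return PatternSets(
        direct=direct,
        indirect=indirect,
        unstim=unstim,
        direct_exclusive=[p for p in direct if p.identity() not in drop],
        indirect_exclusive=[p for p in indirect if p.identity() not in drop],
        shared_di=[p for p in direct if p.identity() in shared],
    )


def assign_clonotypes(rep, sets: PatternSets) -> dict[str, str]:
    """Label clonotypes by the exclusive patterns their CDR3 matches.

    Returns CDR3 -> label in {"direct", "indirect"}; clonotypes matching
    patterns of both arms are ambiguous and excluded from both labels
    (their count is logged), unmatched clonotypes are omitted.
    """
    labels: dict[str, str] = {}
    ambiguous = 0
    cdr3s = {c if isinstance(c, str) else c.cdr3_aa for c in rep}
    for cdr3 in cdr3s:
        hit_direct = any(p.matches(cdr3) for p in sets.direct_exclusive)
        hit_indirect = any(p.matches(cdr3) for p in sets.indirect_exclusive)
        if hit_direct and hit_indirect:
            ambiguous += 1
        elif hit_direct:
            labels[cdr3] = "direct"
        elif hit_indirect:
            labels[cdr3] = "indirect"
    if ambiguous:
        logger.info("%d clonotypes matched both arms and were excluded", ambiguous)
    return labels


def cluster_origins(
    patterns: list[SpecificityPattern],
    condition_of: dict[str, str] | None = None,
) -> tuple[dict[tuple[str, str], int], dict[int, int]]:
    """Count how many distinct conditions contribute members to each pattern.

    Returns (per-pattern origin counts keyed by pattern identity, histogram
    of origin counts over patterns). The histogram sums to the number of
    patterns with at least one attributable member.
    """
    per_pattern: dict[tuple[str, str], int] = {}
    histogram: dict[int, int] = defaultdict(int)
    for p in patterns:
        conds = p.source_conditions
        if condition_of is not None:
            conds = _condition_set(p.members, condition_of)
        n = len(conds)
        per_pattern[p.identity()] = n
        if n > 0:
            histogram[n] += 1
    return per_pattern, dict(histogram)
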