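"""Clonotype data model and readers/writers for clonotype-table formats.

A clonotype is a CDR3 amino-acid sequence (conserved C through conserved F,
inclusive) together with its V/J gene calls, read count, and within-sample
frequency. Repertoires are per-sample clonotype tables; a CountMatrix stacks
repertoires into a clonotypes x samples integer matrix for normalization and
expansion calling.

Two table dialects are supported: MiXCR export TSV (cloneCount,
cloneFraction, aaSeqCDR3, bestVHit/allVHitsWithScore) and AIRR Rearrangement
TSV (junction_aa, v_call, duplicate_count). Out-of-frame or stop-containing
CDR3s (``_`` or ``*``) are dropped at read time: they cannot enter
amino-acid-level analyses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

#: minimum CDR3 length admitted into the data model
MIN_CDR3_LEN = 5


class FormatError(ValueError):
    """A clonotype table is missing a mandatory column or is malformed."""


def _strip_gene(call: str) -> str:
    """Normalize a V/J gene call to a bare gene symbol.

    Drops allele suffixes (``*01``), alignment-score decorations
    (``TRBV31*01(1234.5)``) and keeps only the first hit of a
    comma-separated hit list.
    """
    if not call or pd.isna(call):
        return ""
    first = str(call).split(",")[0].strip()
    first = first.split("(")[0]
    first = first.split("*")[0]
    return first.strip()


@dataclass(frozen=True)
class Clonotype:
    """One TCR-beta clonotype: CDR3 aa sequence, gene calls, abundance."""

    cdr3_aa: str
    v_gene: str = ""
    j_gene: str = ""
    count: float = 0.0
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if not _AA_RE.match(self.cdr3_aa) or len(self.cdr3_aa) < MIN_CDR3_LEN:
            raise ValueError(f"invalid CDR3 aa sequence: {self.cdr3_aa!r}")
        if self.count < 0:
            raise ValueError(f"negative count for {self.cdr3_aa}")
        if not 0.0 <= self.frequency <= 1.0 + 1e-9:
            raise ValueError(f"frequency out of [0,1] for {self.cdr3_aa}")

    def key(self, mode: str = "cdr3") -> str:
        """Clonotype identity key: CDR3 aa alone (default) or CDR3aa+V."""
        if mode == "cdr3":
            return self.cdr3_aa
        if mode == "cdr3v":
            return f"{self.cdr3_aa}|{self.v_gene}"
        raise ValueError(f"unknown key mode {mode!r}")


@dataclass
class Repertoire:
    """A sample's clonotype table with its condition label."""

    sample_id: str
    condition: str
    clonotypes: list[Clonotype] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self):
        return iter(self.clonotypes)

    @property
    def total_count(self) -> float:
        return sum(c.count for c in self.clonotypes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cdr3_aa": [c.cdr3_aa for c in self.clonotypes],
                "v_gene": [c.v_gene for c in self.clonotypes],
                "j_gene": [c.j_gene for c in self.clonotypes],
                "count": [c.count for c in self.clonotypes],
                "frequency": [c.frequency for c in self.clonotypes],
            }
        )

    def subset(self, keys, key_mode: str = "cdr3") -> "Repertoire":
        """Restrict to clonotypes whose identity key is in ``keys``."""
        keys = set(keys)
        kept = [c for c in self.clonotypes if c.key(key_mode) in keys]
        return Repertoire(self.sample_id, self.condition, kept)


def _renormalize(clonotypes: list[Clonotype]) -> list[Clonotype]:
    total = sum(c.frequency for c in clonotypes)
    if total > 0 and abs(total - 1.0) > 1e-6:
        clonotypes = [replace(c, frequency=c.frequency / total) for c in clonotypes]
    return clonotypes


def _merge_duplicates(clonotypes: list[Clonotype], key_mode: str = "cdr3") -> list[Clonotype]:
    """Merge duplicate clonotype keys by summing counts/frequencies.

    The V gene of the merged record is the count-majority V among the
    duplicates; ties go to the lexicographically first symbol.
    """
    groups: dict[str, list[Clonotype]] = {}
    order: list[str] = []
    for c in clonotypes:
        k = c.key(key_mode)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(c)
    merged = []
    for k in order:
        members = groups[k]
        if len(members) == 1:
            merged.append(members[0])
            continue
        v_votes: dict[str, float] = {}
        j = members[0].j_gene
        for m in members:
            v_votes[m.v_gene] = v_votes.get(m.v_gene, 0.0) + m.count
        best_v = sorted(v_votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        merged.append(
            Clonotype(
                cdr3_aa=members[0].cdr3_aa,
                v_gene=best_v,
                j_gene=j,
                count=sum(m.count for m in members),
                frequency=min(1.0, sum(m.frequency for m in members)),
            )
        )
    return merged


def _rows_to_repertoire(
    rows: list[tuple[str, str, str, float, float]],
    sample_id: str,
    condition: str,
) -> Repertoire:
    clonotypes = []
    dropped = 0
    for cdr3, v, j, count, freq in rows:
        cdr3 = str(cdr3).strip()
        if not _AA_RE.match(cdr3) or len(cdr3) < MIN_CDR3_LEN:
            dropped += 1
            continue
        clonotypes.append(
            Clonotype(cdr3, _strip_gene(v), _strip_gene(j), float(count), float(freq))
        )
    if dropped:
        logger.warning(
            "%s: dropped %d rows with non-amino-acid or too-short CDR3", sample_id, dropped
        )
    clonotypes = _merge_duplicates(clonotypes)
    clonotypes = _renormalize(clonotypes)
    rep = Repertoire(sample_id, condition, clonotypes)
    rep.dropped_rows = dropped  # type: ignore[attr-defined]
    return rep


def _pick(header: list[str], candidates: list[str], what: str, path) -> str:
    for c in candidates:
        if c in header:
            return c
    raise FormatError(f"{path}: missing mandatory {what} column (one of {candidates})")


def read_mixcr(path, sample_id: str | None = None, condition: str = "") -> Repertoire:
    """Read a MiXCR clonotype export TSV into a Repertoire.

    Recognizes the usual export column aliases; frequencies are renormalized
    to sum to 1 if they are off by more than 1e-6 (e.g. after row drops
    upstream). Rows whose CDR3 contains a stop (``*``) or frameshift (``_``)
    marker are dropped with a logged tally.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    header = list(df.columns)
    cdr3_col = _pick(header, ["aaSeqCDR3", "cdr3aa", "CDR3.aa"], "CDR3-aa", path)
    count_col = _pick(header, ["cloneCount", "readCount", "count", "Clones"], "count", path)
    frac_col = _pick(header, ["cloneFraction", "readFraction", "frequency", "Proportion"], "fraction", path)
    v_col = next((c for c in ["bestVHit", "allVHitsWithScore", "bestVGene", "v", "V.name"] if c in header), None)
    j_col = next((c for c in ["bestJHit", "allJHitsWithScore", "bestJGene", "j", "J.name"] if c in header), None)

    rows = [
        (
            r[cdr3_col],
            r[v_col] if v_col else "",
            r[j_col] if j_col else "",
            float(r[count_col]),
            float(r[frac_col]),
        )
        for r in df.to_dict("records")
    ]
    sid = sample_id if sample_id is not None else str(path)
    return _rows_to_repertoire(rows, sid, condition)


#: AIRR Rearrangement columns written by write_airr
_AIRR_COLS = ["sequence_id", "junction_aa", "v_call", "j_call", "duplicate_count", "frequency"]


def read_airr(path, sample_id: str | None = None, condition: str = "") -> Repertoire:
    """Read an AIRR Rearrangement TSV (junction_aa / v_call / duplicate_count).

    Falls back to ``consensus_count`` when ``duplicate_count`` is absent
    (logged). The junction is taken as the CDR3 aa sequence. An empty file
    (header only) yields a valid empty repertoire.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    header = list(df.columns)
    cdr3_col = _pick(header, ["junction_aa", "cdr3_aa"], "junction-aa", path)
    if "duplicate_count" in header:
        count_col = "duplicate_count"
    elif "consensus_count" in header:
        count_col = "consensus_count"
        logger.info("%s: duplicate_count absent, using consensus_count", path)
    else:
        raise FormatError(f"{path}: missing mandatory count column "
                          "(duplicate_count or consensus_count)")
    v_col = "v_call" if "v_call" in header else None
    j_col = "j_call" if "j_call" in header else None
    has_freq = "frequency" in header

    counts = pd.to_numeric(df[count_col], errors="coerce").fillna(0.0)
    total = counts.sum()
    rows = []
    for i, r in enumerate(df.to_dict("records")):
        cnt = counts.iloc[i]
        freq = float(r["frequency"]) if has_freq else (cnt / total if total > 0 else 0.0)
        rows.append(
            (r[cdr3_col], r[v_col] if v_col else "", r[j_col] if j_col else "", cnt, freq)
        )
    sid = sample_id if sample_id is not None else str(path)
    return _rows_to_repertoire(rows, sid, condition)


def write_airr(rep: Repertoire, path) -> None:
    """Write a Repertoire as an AIRR Rearrangement TSV (round-trips exactly)."""
    df = pd.DataFrame(
        {
            "sequence_id": [f"{rep.sample_id}.{i}" for i in range(len(rep))],
            "junction_aa": [c.cdr3_aa for c in rep],
            "v_call": [c.v_gene for c in rep],
            "j_call": [c.j_gene for c in rep],
            "duplicate_count": [int(round(c.count)) for c in rep],
            "frequency": [repr(float(c.frequency)) for c in rep],
        },
        columns=_AIRR_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def pool_repertoires(reps: list[Repertoire], label: str, key_mode: str = "cdr3") -> Repertoire:
    """Pool repertoires from replicates of one stimulation into one table.

    Counts are summed per clonotype key and frequencies recomputed from the
    pooled counts, so pooling is associative and order-invariant on counts.
    """
    if not reps:
        raise ValueError("pool_repertoires requires at least one repertoire")
    all_clonotypes = [c for rep in reps for c in rep.clonotypes]
    merged = _merge_duplicates(all_clonotypes, key_mode)
    total = sum(c.count for c in merged)
    if total > 0:
        merged = [replace(c, frequency=c.count / total) for c in merged]
    return Repertoire(sample_id=label, condition=label, clonotypes=merged)


@dataclass
class CountMatrix:
    """Clonotypes x samples integer count matrix with condition metadata."""

    counts: pd.DataFrame  # index = clonotype keys, columns = sample_ids
    conditions: dict[str, str]  # sample_id -> condition label

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def keys(self) -> list[str]:
        return list(self.counts.index)

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def build_count_matrix(reps: list[Repertoire], key_mode: str = "cdr3") -> CountMatrix:
    """Stack repertoires into a union-keyed count matrix (absent = 0)."""
    series = {}
    conditions = {}
    key_order: list[str] = []
    seen: set[str] = set()
    for rep in reps:
        if rep.sample_id in series:
            raise ValueError(f"duplicate sample_id {rep.sample_id!r}")
        s = {}
        for c in rep.clonotypes:
            k = c.key(key_mode)
            s[k] = s.get(k, 0.0) + c.count
            if k not in seen:
                seen.add(k)
                key_order.append(k)
        series[rep.sample_id] = s
        conditions[rep.sample_id] = rep.condition
    mat = pd.DataFrame(
        {sid: [series[sid].get(k, 0.0) for k in key_order] for sid in series},
        index=key_order,
    ).astype(float)
    # drop all-zero rows (cannot arise from real repertoires, but be safe)
    mat = mat.loc[mat.sum(axis=1) > 0]
    return CountMatrix(counts=mat, conditions=conditions)
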