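"""Annotation of CDR3 sequences against TCR specificity databases.

Matches repertoire CDR3 aa sequences exactly (case-sensitive) against
VDJdb-like or McPAS-TCR-like tables of TCRs with known specificity, and
reports the matched share (matched distinct clonotypes / total distinct
clonotypes) with a per-pathology breakdown. A clonotype matching records of
several pathologies contributes once to the share but once to each
pathology bucket.

Species filtering is off by default: cross-species matches can be the
point (mouse queries against human-dominated databases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpecificityRecord:
    cdr3_aa: str
    epitope: str = ""
    pathology: str = ""
    species: str = ""
    source: str = ""


_DIALECTS = {
    # dialect -> (cdr3, epitope, pathology, species) column candidates
    "vdjdb": (["cdr3", "CDR3"], ["antigen.epitope", "Epitope"],
              ["antigen.species", "Pathology"], ["species", "Species"]),
    "mcpas": (["CDR3.beta.aa", "cdr3_beta"], ["Epitope.peptide", "epitope"],
              ["Pathology", "pathology"], ["Species", "species"]),
    "generic": (["cdr3_aa", "cdr3"], ["epitope"], ["pathology"], ["species"]),
}


def load_specificity_db(path, dialect: str = "generic") -> list[SpecificityRecord]:
    """Load a specificity database TSV/CSV with dialect-aware column mapping.

    Duplicate (cdr3, pathology) rows are collapsed to one record.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r} (use vdjdb|mcpas|generic)")
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    cdr3_cands, epi_cands, path_cands, sp_cands = _DIALECTS[dialect]

    def pick(cands):
        return next((c for c in cands if c in df.columns), None)

    cdr3_col = pick(cdr3_cands)
    if cdr3_col is None:
        raise ValueError(f"{path}: no CDR3 column among {cdr3_cands}")
    epi_col, path_col, sp_col = pick(epi_cands), pick(path_cands), pick(sp_cands)

    seen = set()
    records = []
    for r in df.to_dict("records"):
        cdr3 = str(r[cdr3_col]).strip()
        if not cdr3:
            continue
        pathology = str(r[path_col]).strip() if path_col else ""
        if (cdr3, pathology) in seen:
            continue
        seen.add((cdr3, pathology))
        records.append(
            SpecificityRecord(
                cdr3_aa=cdr3,
                epitope=str(r[epi_col]).strip() if epi_col else "",
                pathology=pathology,
                species=str(r[sp_col]).strip() if sp_col else "",
                source=dialect,
            )
        )
    return records


@dataclass
class AnnotationSummary:
    share: float
    n_total: int
    n_matched: int
    pathology_counts: dict[str, int] = field(default_factory=dict)

    def pathology_shares(self) -> dict[str, float]:
        """Per-pathology share of matched clonotypes."""
        if self.n_matched == 0:
            return {}
        return {p: n / self.n_matched for p, n in self.pathology_counts.items()}


def annotate(
    clonotypes,
    db: list[SpecificityRecord],
    species_filter: str | None = None,
) -> tuple[dict[str, list[SpecificityRecord]], AnnotationSummary]:
    """Exact-match CDR3 annotation against a specificity database.

    Returns the per-clonotype match lists (keyed by CDR3) and a summary
    with the matched share and pathology breakdown. ``species_filter``
    restricts the database before matching when given.
    """
    if species_filter is not None:
        db = [r for r in db if r.species == species_filter]
    if not db:
        logger.warning("empty specificity database: all shares are 0")
    by_cdr3: dict[str, list[SpecificityRecord]] = {}
    for rec in db:
        by_cdr3.setdefault(rec.cdr3_aa, []).append(rec)

    queries = {c if isinstance(c, str) else c.cdr3_aa for c in clonotypes}
    matches = {q: by_cdr3[q] for q in queries if q in by_cdr3}
    pathology_counts: dict[str, int] = {}
    for q, recs in matches.items():
        for pathology in {r.pathology for r in recs if r.pathology}:
            pathology_counts[pathology] = pathology_counts.get(pathology, 0) + 1
    share = len(matches) / len(queries) if queries else 0.0
    return matches, AnnotationSummary(
        share=share,
        n_total=len(queries),
        n_matched=len(matches),
        pathology_counts=pathology_counts,
    )
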