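"""Full-pipeline orchestration from a sample manifest.

Runs the analysis stages in their canonical order: load clonotype tables,
TMM-normalize, call fold expansions per stimulated condition against its
assay-matched controls (in vitro conditions vs the pooled unloaded/self-
lysate DC controls; in vivo conditions vs intact mice), pool by condition,
compute overlap grids across expansion thresholds, build CDR3 similarity
graphs with cluster statistics, discover specificity patterns per
repertoire arm (direct / indirect / unstimulated), apply the exclusive
pattern-set algebra, classify clonotypes, compute repertoire features, and
annotate against a specificity database when one is configured.

Every result bundle carries the configuration hash and seed, and a rerun
with the same configuration is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from allorep import annotation as ann
from allorep import features as feat
from allorep.expansion import call_expansions
from allorep.graph import build_graph, cluster_stats
from allorep.io import Repertoire, build_count_matrix, pool_repertoires, read_airr, read_mixcr
from allorep.motifs import (
    assign_clonotypes,
    cluster_origins,
    discover_patterns,
    pattern_set_algebra,
)
from allorep.normalization import normalize
from allorep.overlap import overlap_grid

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """The run configuration is incomplete or inconsistent."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    manifest: str | None = None
    stim_direct: tuple[str, ...] = ("BlL0", "VacDC", "Trans")
    stim_indirect: tuple[str, ...] = ("BaLBl", "VacBl", "Trans")
    unstim: tuple[str, ...] = ("BaL0", "BaLBa", "Int")
    control_invitro: tuple[str, ...] = ("BaL0", "BaLBa")
    control_invivo: tuple[str, ...] = ("Int",)
    invivo_conditions: tuple[str, ...] = ("Trans", "VacDC", "VacBl", "Int", "VacHum")
    posterior_threshold: float = 0.95
    fold_thresholds: tuple[int, ...] = (2, 4, 8, 16, 32)
    arm_fold_threshold: int = 2
    min_support: int = 3
    min_fold: float = 10.0
    alpha: float = 1e-3
    motif_k_range: tuple[int, int] = (4, 7)
    min_cluster_size: int = 5
    subtract_unstim: bool = True
    key_mode: str = "cdr3"
    specificity_db: str | None = None
    specificity_dialect: str = "generic"
    naive_reference: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_manifest(path) -> list[Repertoire]:
    """Load all samples of a dataset manifest YAML (AIRR or MiXCR tables)."""
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    reps = []
    for sample_id, entry in manifest["samples"].items():
        table = path.parent / entry["path"]
        reader = read_mixcr if entry.get("format") == "mixcr" else read_airr
        reps.append(reader(table, sample_id=sample_id, condition=entry["condition"]))
    return reps


def _assay_of(condition: str, config: RunConfig) -> str:
    return "in_vivo" if condition in config.invivo_conditions else "in_vitro"


def run_pipeline(reps: list[Repertoire], config: RunConfig | None = None) -> dict:
    """Execute all analysis stages on loaded repertoires; returns the bundle."""
    config = config or RunConfig()
    if not config.control_invitro and not config.control_invivo:
        raise ConfigurationError("no control conditions configured")
    by_condition: dict[str, list[Repertoire]] = {}
    for rep in reps:
        by_condition.setdefault(rep.condition, []).append(rep)

    stim_conditions = [
        c for c in by_condition
        if c not in config.control_invitro + config.control_invivo
    ]
    if not stim_conditions:
        raise ConfigurationError("manifest contains no stimulated conditions")

    # normalize once over all samples
    matrix = build_count_matrix(reps, config.key_mode)
    normalized = normalize(matrix)

    # expansion calling per stimulated condition vs assay-matched controls
    calls_by_condition: dict[str, list] = {}
    calls_by_sample: dict[str, list] = {}
    for cond in stim_conditions:
        controls = (
            config.control_invivo
            if _assay_of(cond, config) == "in_vivo"
            else config.control_invitro
        )
        ctrl_samples = [
            r.sample_id for c in controls for r in by_condition.get(c, [])
        ]
        if not ctrl_samples:
            raise ConfigurationError(f"no control samples available for {cond}")
        stim_samples = [r.sample_id for r in by_condition[cond]]
        calls = call_expansions(
            normalized,
            stim_samples,
            ctrl_samples,
            posterior_threshold=config.posterior_threshold,
            fold_thresholds=config.fold_thresholds,
            seed=config.seed,
        )
        calls_by_condition[cond] = calls
        for sid in stim_samples:
            calls_by_sample[sid] = calls

    pooled = {
        cond: pool_repertoires(group, cond, config.key_mode)
        for cond, group in by_condition.items()
    }

    # overlap grids per assay, across expansion thresholds
    grids = {}
    for assay in ("in_vitro", "in_vivo"):
        assay_reps = [r for r in reps if _assay_of(r.condition, config) == assay]
        if len(assay_reps) >= 2:
            grids[assay] = overlap_grid(
                assay_reps, calls_by_sample, (1,) + config.fold_thresholds, config.key_mode
            )

    # arm assembly: clonotypes expanded >= arm threshold, pooled per arm
    def arm_keys(conditions: tuple[str, ...]) -> dict[str, str]:
        """expanded clonotype key -> contributing condition (first seen)."""
        out: dict[str, str] = {}
        for cond in conditions:
            for call in calls_by_condition.get(cond, []):
                if config.arm_fold_threshold in call.fold_bins and call.clonotype_key not in out:
                    out[call.clonotype_key] = cond
        return out

    direct_members = arm_keys(config.stim_direct)
    indirect_members = arm_keys(config.stim_indirect)
    unstim_pool = pool_repertoires(
        [r for c in config.unstim for r in by_condition.get(c, [])] or reps,
        "unstim",
        config.key_mode,
    )
    unstim_cdr3s = {c.cdr3_aa for c in unstim_pool}

    arm_clonotype_counts = {}
    graphs = {}
    graph_stats = {}
    for arm, members in (
        ("direct", set(direct_members)),
        ("indirect", set(indirect_members)),
        ("unstim", unstim_cdr3s),
    ):
        sizes: dict[str, float] = {}
        for rep in reps:
            for c in rep:
                if c.cdr3_aa in members:
                    sizes[c.cdr3_aa] = sizes.get(c.cdr3_aa, 0.0) + c.count
        from allorep.io import Clonotype

        clonos = [
            Clonotype(s, count=max(n, 1.0), frequency=0.0) for s, n in sizes.items()
        ]
        g = build_graph(clonos)
        graphs[arm] = g
        graph_stats[arm] = cluster_stats(g, config.min_cluster_size)
        arm_clonotype_counts[arm] = len(members)

    # specificity-pattern discovery per arm, unstimulated pool as reference
    direct_patterns = discover_patterns(
        set(direct_members),
        unstim_cdr3s,
        k_range=config.motif_k_range,
        min_support=config.min_support,
        min_fold=config.min_fold,
        alpha=config.alpha,
        condition_of=direct_members,
    )
    indirect_patterns = discover_patterns(
        set(indirect_members),
        unstim_cdr3s,
        k_range=config.motif_k_range,
        min_support=config.min_support,
        min_fold=config.min_fold,
        alpha=config.alpha,
        condition_of=indirect_members,
    )
    # unstimulated-arm patterns go through the same enrichment discovery;
    # without an external naive reference the unstim pool is its own
    # reference, so only its global templates (public near-identical CDR3
    # groups) survive — motifs merely present in controls at background
    # rates must not be treated as unstimulated-specific
    naive_ref = unstim_cdr3s
    if config.naive_reference:
        naive_ref = {
            c.cdr3_aa
            for c in read_airr(config.naive_reference, sample_id="naive").clonotypes
        }
    unstim_patterns = discover_patterns(
        unstim_cdr3s,
        naive_ref,
        k_range=config.motif_k_range,
        min_support=config.min_support,
        min_fold=config.min_fold,
        alpha=config.alpha,
    )

    sets = pattern_set_algebra(
        direct_patterns, indirect_patterns, unstim_patterns, config.subtract_unstim
    )
    origins = {
        "direct": cluster_origins(sets.direct_exclusive)[1],
        "indirect": cluster_origins(sets.indirect_exclusive)[1],
    }

    # classification over all expanded clonotypes of both arms
    candidate_cdr3s = set(direct_members) | set(indirect_members)
    labels = assign_clonotypes(candidate_cdr3s, sets)

    # repertoire features per stimulated condition
    features = {}
    for cond in stim_conditions:
        rep = pooled[cond]
        threshold_keys = {
            c.clonotype_key
            for c in calls_by_condition.get(cond, [])
            if config.arm_fold_threshold in c.fold_bins
        }
        for arm in ("direct", "indirect"):
            arm_cdr3s = {k for k, lab in labels.items() if lab == arm}
            subset = rep.subset(arm_cdr3s, config.key_mode)
            if len(subset) == 0:
                continue
            stats_ = feat.frequency_stats(subset, rep, threshold_keys or None, config.key_mode)
            features[(cond, arm)] = {
                "frequency": stats_,
                "v_usage": feat.v_usage(subset),
                "spectratype": feat.spectratype(subset),
                "positional_profile": feat.positional_profile(subset),
            }
    whole_features = {
        cond: {
            "v_usage": feat.v_usage(pooled[cond]),
            "spectratype": feat.spectratype(pooled[cond]),
            "positional_profile": feat.positional_profile(pooled[cond]),
        }
        for cond in pooled
    }

    # specificity-database annotation
    annotation_results = {}
    if config.specificity_db:
        db = ann.load_specificity_db(config.specificity_db, config.specificity_dialect)
        for name, cdr3s in (
            ("direct", {k for k, lab in labels.items() if lab == "direct"}),
            ("indirect", {k for k, lab in labels.items() if lab == "indirect"}),
            ("unstim", unstim_cdr3s),
        ):
            if cdr3s:
                annotation_results[name] = ann.annotate(cdr3s, db)[1]

    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "normalized": normalized,
        "calls": calls_by_condition,
        "pooled": pooled,
        "overlap": grids,
        "graphs": graphs,
        "graph_stats": graph_stats,
        "arm_sizes": arm_clonotype_counts,
        "pattern_sets": sets,
        "cluster_origins": origins,
        "labels": labels,
        "features": features,
        "whole_features": whole_features,
        "annotation": annotation_results,
    }


def run_from_manifest(config: RunConfig) -> dict:
    """Load the manifest named in the config and run the full pipeline."""
    if not config.manifest:
        raise ConfigurationError("config.manifest is not set")
    return run_pipeline(load_manifest(config.manifest), config)
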