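"""Synthetic multi-sample mouse TCR-beta repertoires with planted truth.

Emulates the statistical structure the analysis assumes so that every
stage can be validated against known ground truth:

* a background pool of CDR3 clonotypes with Zipf-distributed base clone
  sizes, a mouse-like TRBV usage vector, and a discrete CDR3-length
  distribution centered at 14 aa;
* planted specificity groups — sets of carrier clonotypes sharing a random
  interior motif, plus Hamming-distance-1 neighbors of a carrier to create
  cluster structure; groups are "direct", "indirect", or "shared"
  (responsive in both arms);
* condition-specific clonal expansion: in a stimulated condition the
  responsive groups' expected frequencies are multiplied by the condition's
  expansion factor before multinomial sampling at the configured depth,
  emulating the 2x-32x fold expansions seen over ~5 divisions in mixed
  leukocyte cultures;
* feature skews in the planted carriers that give the alloreactive subsets
  measurable signatures: direct carriers prefer TRBV31 and short CDR3
  loops, indirect carriers prefer TRBV13-1, both avoid TRBV13-2.

All randomness flows from the spec-level seed through named child streams,
so each stage is reproducible independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from allorep.io import AA_ALPHABET, Clonotype, Repertoire

#: mouse-like TRBV symbols and baseline usage weights (implementation
#: constants producing plausible repertoires, not estimates from any study)
DEFAULT_V_GENES = [
    "TRBV1", "TRBV2", "TRBV3", "TRBV4", "TRBV5",
    "TRBV12-1", "TRBV12-2", "TRBV13-1", "TRBV13-2", "TRBV13-3",
    "TRBV14", "TRBV15", "TRBV16", "TRBV17", "TRBV19",
    "TRBV20", "TRBV23", "TRBV26", "TRBV29", "TRBV31",
]
DEFAULT_V_WEIGHTS = [
    0.04, 0.05, 0.03, 0.05, 0.06,
    0.04, 0.04, 0.08, 0.12, 0.06,
    0.05, 0.04, 0.03, 0.02, 0.09,
    0.04, 0.03, 0.04, 0.05, 0.04,
]

#: interior residue profile: glycine/serine-rich, as in TRB junctions
_INTERIOR_AA = "GSLARDQTNEPVFYWHIKMC"
_INTERIOR_W = np.array(
    [0.14, 0.13, 0.09, 0.08, 0.08, 0.07, 0.07, 0.06, 0.06, 0.05,
     0.04, 0.03, 0.02, 0.02, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01]
)

_PREFIX = "CASS"
_SUFFIX = "QYF"

#: stimulation design: which planted group labels respond in each condition.
#: Direct-pathway conditions expand the direct and shared groups, indirect-
#: pathway conditions the indirect and shared groups, so the shared groups
#: are the designed source of the between-arm pattern intersection.
DEFAULT_CONDITIONS: dict[str, tuple[str, ...]] = {
    "BlL0": ("direct", "shared"),
    "BaLBl": ("indirect", "shared"),
    "VacDC": ("direct", "shared"),
    "VacBl": ("indirect", "shared"),
    "BaL0": (),
    "BaLBa": (),
    "Int": (),
}


@dataclass
class SimulationSpec:
    """Study-condition parameters for one synthetic scenario."""

    n_background: int = 3000
    zipf_exponent: float = 1.1
    v_genes: list[str] = field(default_factory=lambda: list(DEFAULT_V_GENES))
    v_usage_base: list[float] = field(default_factory=lambda: list(DEFAULT_V_WEIGHTS))
    length_low: int = 9
    length_high: int = 20
    length_center: int = 14
    length_sd: float = 1.6
    n_groups_direct: int = 10
    n_groups_indirect: int = 10
    n_groups_shared: int = 3
    group_size: int = 8
    hd1_variants: int = 2
    motif_length_range: tuple[int, int] = (4, 6)
    carrier_boost: float = 10.0
    expansion_factor: int = 8
    conditions: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONDITIONS)
    )
    depth: int = 100_000
    replicates: int = 3
    seed: int = 42

    def length_probs(self) -> np.ndarray:
        lengths = np.arange(self.length_low, self.length_high + 1)
        p = np.exp(-0.5 * ((lengths - self.length_center) / self.length_sd) ** 2)
        return p / p.sum()


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated pool."""

    group_of: dict[str, str]  # cdr3 -> group id ("" for background)
    label_of: dict[str, str]  # cdr3 -> direct|indirect|shared|none
    motif_of: dict[str, str]  # group id -> planted motif
    base_weight: dict[str, float]  # cdr3 -> unnormalized base clone size

    def carriers(self, label: str) -> set[str]:
        return {c for c, lab in self.label_of.items() if lab == label}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cdr3, self.group_of[cdr3], self.label_of[cdr3],
             self.motif_of.get(self.group_of[cdr3], ""), self.base_weight[cdr3])
            for cdr3 in self.group_of
        ]
        return pd.DataFrame(
            rows, columns=["cdr3_aa", "group", "label", "motif", "base_weight"]
        )


def _rng(spec: SimulationSpec, *stream) -> np.random.Generator:
    return np.random.default_rng([spec.seed, *stream])


def _draw_lengths(rng, spec: SimulationSpec, n: int, short: bool = False) -> np.ndarray:
    lengths = np.arange(spec.length_low, spec.length_high + 1)
    p = spec.length_probs().copy()
    if short:
        # direct-arm carriers: suppress loops longer than the 14-aa cut
        p[lengths > spec.length_center] *= 0.1
        p = p / p.sum()
    return rng.choice(lengths, size=n, p=p)


def _interior(rng, n_res: int) -> str:
    idx = rng.choice(len(_INTERIOR_AA), size=n_res, p=_INTERIOR_W)
    return "".join(_INTERIOR_AA[i] for i in idx)


def _make_cdr3(rng, length: int) -> str:
    core = length - len(_PREFIX) - len(_SUFFIX)
    return _PREFIX + _interior(rng, core) + _SUFFIX


def _skewed_v_probs(spec: SimulationSpec, favored: str) -> np.ndarray:
    p = np.array(spec.v_usage_base, dtype=float)
    genes = spec.v_genes
    p[genes.index(favored)] *= 4.0
    if "TRBV13-2" in genes:
        p[genes.index("TRBV13-2")] *= 0.25
    return p / p.sum()


def generate_background(spec: SimulationSpec) -> tuple[list[str], dict[str, str], np.ndarray]:
    """Background CDR3 pool with V assignments and Zipf base weights.

    Returns (cdr3 list, cdr3 -> v_gene, base weights aligned with the
    list). Exactly ``n_background`` unique CDR3s are produced,
    reproducibly for a given seed.
    """
    rng = _rng(spec, 0)
    v_p = np.array(spec.v_usage_base, dtype=float)
    v_p = v_p / v_p.sum()
    cdr3s: list[str] = []
    seen: set[str] = set()
    while len(cdr3s) < spec.n_background:
        want = spec.n_background - len(cdr3s)
        for length in _draw_lengths(rng, spec, want):
            s = _make_cdr3(rng, int(length))
            if s not in seen:
                seen.add(s)
                cdr3s.append(s)
    v_of = {
        s: spec.v_genes[i]
        for s, i in zip(cdr3s, rng.choice(len(spec.v_genes), size=len(cdr3s), p=v_p))
    }
    ranks = rng.permutation(spec.n_background) + 1
    weights = ranks.astype(float) ** (-spec.zipf_exponent)
    return cdr3s, v_of, weights


def plant_groups(
    pool: tuple[list[str], dict[str, str], np.ndarray], spec: SimulationSpec
) -> tuple[list[str], dict[str, str], SyntheticTruth]:
    """Add planted motif-sharing specificity groups to a background pool.

    Each group receives a random interior motif; carriers embed the motif
    at a random interior offset, and ``hd1_variants`` extra members are
    single-substitution neighbors of the first carrier (mutated outside
    the motif), guaranteeing HD-1 cluster structure. Carrier base weights
    are ``carrier_boost`` times the median background weight.
    """
    cdr3s, v_of, weights = pool
    rng = _rng(spec, 1)
    group_of = {s: "" for s in cdr3s}
    label_of = {s: "none" for s in cdr3s}
    base_weight = dict(zip(cdr3s, weights))
    motif_of: dict[str, str] = {}
    all_cdr3s = list(cdr3s)
    v_of = dict(v_of)
    taken = set(cdr3s)
    median_w = float(np.median(weights))

    plan = (
        [("direct", i) for i in range(spec.n_groups_direct)]
        + [("indirect", i) for i in range(spec.n_groups_indirect)]
        + [("shared", i) for i in range(spec.n_groups_shared)]
    )
    kmin, kmax = spec.motif_length_range
    for label, i in plan:
        gid = f"{label}_{i}"
        k = int(rng.integers(kmin, kmax + 1))
        motif = "".join(AA_ALPHABET[j] for j in rng.integers(0, len(AA_ALPHABET), size=k))
        motif_of[gid] = motif
        members: list[str] = []
        guard = 0
        while len(members) < spec.group_size and guard < 10_000:
            guard += 1
            length = int(_draw_lengths(rng, spec, 1, short=(label == "direct"))[0])
            core = length - len(_PREFIX) - len(_SUFFIX)
            if core < k:
                continue
            offset = int(rng.integers(0, core - k + 1))
            interior = _interior(rng, core - k)
            s = _PREFIX + interior[:offset] + motif + interior[offset:] + _SUFFIX
            if s in taken:
                continue
            taken.add(s)
            members.append(s)
        # HD-1 neighbors of the first carrier, mutated outside the motif
        if members:
            anchor = members[0]
            start = anchor.index(motif)
            protected = set(range(start, start + k))
            guard = 0
            added = 0
            while added < spec.hd1_variants and guard < 1000:
                guard += 1
                pos = int(rng.integers(len(_PREFIX), len(anchor) - len(_SUFFIX)))
                if pos in protected:
                    continue
                aa = AA_ALPHABET[int(rng.integers(0, len(AA_ALPHABET)))]
                if aa == anchor[pos]:
                    continue
                s = anchor[:pos] + aa + anchor[pos + 1:]
                if s in taken:
                    continue
                taken.add(s)
                members.append(s)
                added += 1
        favored = "TRBV31" if label in ("direct", "shared") else "TRBV13-1"
        v_probs = _skewed_v_probs(spec, favored)
        for s in members:
            all_cdr3s.append(s)
            group_of[s] = gid
            label_of[s] = label
            v_of[s] = spec.v_genes[int(rng.choice(len(spec.v_genes), p=v_probs))]
            base_weight[s] = median_w * spec.carrier_boost * float(rng.uniform(0.7, 1.4))
    truth = SyntheticTruth(group_of, label_of, motif_of, base_weight)
    return all_cdr3s, v_of, truth


def sample_condition(
    cdr3s: list[str],
    v_of: dict[str, str],
    truth: SyntheticTruth,
    condition: str,
    replicate: int,
    spec: SimulationSpec,
) -> Repertoire:
    """Multinomial sample of one replicate of one stimulation condition.

    Expected frequencies are the base weights times the condition's
    expansion factor for responsive groups (factor 1 in controls),
    renormalized; counts are multinomial at ``spec.depth``.
    """
    responsive = set(spec.conditions.get(condition, ()))
    cond_index = sorted(spec.conditions).index(condition) if condition in spec.conditions else 99
    rng = _rng(spec, 2, cond_index, replicate)
    w = np.array(
        [
            truth.base_weight[s]
            * (spec.expansion_factor if truth.label_of.get(s, "none") in responsive else 1.0)
            for s in cdr3s
        ]
    )
    p = w / w.sum()
    counts = rng.multinomial(spec.depth, p)
    clonotypes = [
        Clonotype(s, v_of[s], "", int(c), c / spec.depth)
        for s, c in zip(cdr3s, counts)
        if c > 0
    ]
    return Repertoire(f"{condition}_{replicate + 1}", condition, clonotypes)


def generate_scenario(
    spec: SimulationSpec | None = None,
) -> tuple[list[Repertoire], SyntheticTruth]:
    """Generate all replicates of all conditions of a scenario."""
    spec = spec or SimulationSpec()
    pool = generate_background(spec)
    cdr3s, v_of, truth = plant_groups(pool, spec)
    reps = [
        sample_condition(cdr3s, v_of, truth, cond, r, spec)
        for cond in spec.conditions
        for r in range(spec.replicates)
    ]
    return reps, truth


def write_scenario(spec: SimulationSpec, outdir) -> dict:
    """Write a scenario as AIRR TSVs plus a truth table and manifest YAML."""
    from pathlib import Path

    from allorep.io import write_airr

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reps, truth = generate_scenario(spec)
    manifest = {"seed": spec.seed, "samples": {}}
    for rep in reps:
        fname = f"{rep.sample_id}.airr.tsv"
        write_airr(rep, outdir / fname)
        manifest["samples"][rep.sample_id] = {
            "path": fname,
            "condition": rep.condition,
            "assay": "in_vivo" if rep.condition in ("Trans", "VacDC", "VacBl", "Int") else "in_vitro",
        }
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest["truth"] = "truth.tsv"
    manifest["spec"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(spec).items()
        if k != "conditions"
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
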