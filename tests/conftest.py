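import numpy as np
import pandas as pd
import pytest

from allorep.io import Clonotype, CountMatrix, Repertoire
from allorep.synthetic import SimulationSpec, generate_scenario


def make_repertoire(sample_id, condition, entries):
    """entries: list of (cdr3, v, count); frequencies from counts."""
    total = sum(e[2] for e in entries)
    return Repertoire(
        sample_id,
        condition,
        [Clonotype(c, v, "", n, n / total if total else 0.0) for c, v, n in entries],
    )


@pytest.fixture
def small_rep():
    return make_repertoire(
        "m1", "BlL0",
        [("CASSLGEQYF", "TRBV31", 40), ("CASSDAGGYEQYF", "TRBV13-1", 30),
         ("CASRTGNTEVFF", "TRBV19", 20), ("CASSPGQGAYEQYF", "TRBV13-2", 10)],
    )


@pytest.fixture(scope="session")
def default_scenario():
    """The default synthetic scenario with its planted truth (seed 42)."""
    reps, truth = generate_scenario(SimulationSpec(seed=42))
    return reps, truth


@pytest.fixture(scope="session")
def pipeline_bundle(default_scenario):
    from allorep.pipeline import RunConfig, run_pipeline

    reps, _ = default_scenario
    return run_pipeline(reps, RunConfig(seed=1))


def h0_count_matrix(seed, n=3000, depth=100_000, n_stim=3, n_ctrl=3):
    """Both groups multinomial from the same Zipf frequency vector."""
    rng = np.random.default_rng([9000, seed])
    w = (rng.permutation(n) + 1.0) ** -1.1
    p = w / w.sum()
    cols = {f"s{i}": rng.multinomial(depth, p) for i in range(n_stim + n_ctrl)}
    df = pd.DataFrame(cols, index=[f"c{i}" for i in range(n)]).astype(float)
    df = df.loc[df.sum(axis=1) > 0]
    stim = [f"s{i}" for i in range(n_stim)]
    ctrl = [f"s{i}" for i in range(n_stim, n_stim + n_ctrl)]
    return CountMatrix(df, {c: "x" for c in df.columns}), stim, ctrl


def planted_count_matrix(seed, fold=8, n=3000, depth=100_000, n_planted=30,
                         min_ctrl_freq=1e-4):
    """Plant fold-expansions on clonotypes above a control-frequency floor."""
    rng = np.random.default_rng([9100, seed])
    w = (rng.permutation(n) + 1.0) ** -1.1
    p = w / w.sum()
    eligible = np.where(p >= min_ctrl_freq)[0]
    planted = rng.choice(eligible, n_planted, replace=False)
    w_stim = w.copy()
    w_stim[planted] *= fold
    p_stim = w_stim / w_stim.sum()
    cols = {f"stim{i}": rng.multinomial(depth, p_stim) for i in range(3)}
    cols |= {f"ctrl{i}": rng.multinomial(depth, p) for i in range(3)}
    df = pd.DataFrame(cols, index=[f"c{i}" for i in range(n)]).astype(float)
    df = df.loc[df.sum(axis=1) > 0]
    matrix = CountMatrix(df, {c: "x" for c in df.columns})
    return matrix, [f"stim{i}" for i in range(3)], [f"ctrl{i}" for i in range(3)], \
        {f"c{i}" for i in planted}
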