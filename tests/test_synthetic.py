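import numpy as np
import pytest
from scipy import stats

from allorep.graph import build_graph, cluster_stats
from allorep.io import read_airr
from allorep.overlap import morisita_horn
from allorep.synthetic import (
    SimulationSpec,
    generate_background,
    generate_scenario,
    plant_groups,
    sample_condition,
    write_scenario,
)


class TestGenerateBackground:
    def test_exact_count_unique_and_reproducible(self):
        spec = SimulationSpec(n_background=1000, seed=1)
        cdr3s, v_of, w = generate_background(spec)
        cdr3s2, v_of2, w2 = generate_background(spec)
        assert len(cdr3s) == 1000
        assert len(set(cdr3s)) == 1000
        assert cdr3s == cdr3s2 and v_of == v_of2
        assert np.array_equal(w, w2)

    def test_degenerate_length_model(self):
        spec = SimulationSpec(n_background=200, length_low=14, length_high=14, seed=2)
        cdr3s, _, _ = generate_background(spec)
        assert {len(s) for s in cdr3s} == {14}

    def test_v_usage_matches_base_distribution(self):
        """Empirical V usage agrees with the base vector (chi-square GOF)."""
        spec = SimulationSpec(n_background=10_000, seed=3)
        cdr3s, v_of, _ = generate_background(spec)
        counts = {g: 0 for g in spec.v_genes}
        for s in cdr3s:
            counts[v_of[s]] += 1
        observed = np.array([counts[g] for g in spec.v_genes])
        p = np.array(spec.v_usage_base) / sum(spec.v_usage_base)
        chi2 = stats.chisquare(observed, p * len(cdr3s))
        assert chi2.pvalue > 0.01

    def test_zipf_weights_follow_power_law(self):
        spec = SimulationSpec(n_background=1000, zipf_exponent=1.3, seed=4)
        _, _, w = generate_background(spec)
        sw = np.sort(w)[::-1]
        ranks = np.arange(1, len(sw) + 1)
        slope = np.polyfit(np.log(ranks), np.log(sw), 1)[0]
        assert slope == pytest.approx(-1.3, abs=0.01)


class TestPlantGroups:
    def test_every_carrier_contains_its_motif(self):
        spec = SimulationSpec(seed=5)
        pool = generate_background(spec)
        _, _, truth = plant_groups(pool, spec)
        for cdr3, gid in truth.group_of.items():
            if gid:
                assert truth.motif_of[gid] in cdr3

    def test_hd1_variants_create_cluster_structure(self):
        spec = SimulationSpec(n_groups_direct=1, n_groups_indirect=0,
                              n_groups_shared=0, group_size=5, hd1_variants=2, seed=6)
        pool = generate_background(spec)
        _, _, truth = plant_groups(pool, spec)
        members = [c for c, g in truth.group_of.items() if g]
        g = build_graph(members)
        comp_sizes = [len(c) for c in
                      __import__("networkx").connected_components(g)]
        assert max(comp_sizes) >= 3

    def test_zero_groups_give_empty_truth(self):
        spec = SimulationSpec(n_groups_direct=0, n_groups_indirect=0,
                              n_groups_shared=0, seed=7)
        pool = generate_background(spec)
        cdr3s, _, truth = plant_groups(pool, spec)
        assert set(truth.label_of.values()) == {"none"}
        assert truth.motif_of == {}

    def test_carriers_boosted_above_background_median(self):
        spec = SimulationSpec(seed=8)
        pool = generate_background(spec)
        _, _, truth = plant_groups(pool, spec)
        bg_w = [truth.base_weight[c] for c, g in truth.group_of.items() if not g]
        for cdr3, gid in truth.group_of.items():
            if gid:
                assert truth.base_weight[cdr3] > np.median(bg_w)


class TestSampleCondition:
    def _scenario(self, seed=9):
        spec = SimulationSpec(seed=seed)
        pool = generate_background(spec)
        cdr3s, v_of, truth = plant_groups(pool, spec)
        return spec, cdr3s, v_of, truth

    def test_same_seed_identical_sample(self):
        spec, cdr3s, v_of, truth = self._scenario()
        a = sample_condition(cdr3s, v_of, truth, "BlL0", 0, spec)
        b = sample_condition(cdr3s, v_of, truth, "BlL0", 0, spec)
        assert [(c.cdr3_aa, c.count) for c in a] == [(c.cdr3_aa, c.count) for c in b]

    def test_control_exchangeable_with_control(self):
        """With factor 1 everywhere, stim vs ctrl overlap is as high as
        ctrl vs ctrl (within sampling tolerance)."""
        spec, cdr3s, v_of, truth = self._scenario()
        spec.conditions = {"BlL0": (), "BaL0": ()}  # no responsive groups
        s = sample_condition(cdr3s, v_of, truth, "BlL0", 0, spec)
        c1 = sample_condition(cdr3s, v_of, truth, "BaL0", 0, spec)
        c2 = sample_condition(cdr3s, v_of, truth, "BaL0", 1, spec)
        def mh(a, b):
            union = sorted({x.cdr3_aa for x in a} | {x.cdr3_aa for x in b})
            ax = {x.cdr3_aa: x.count for x in a}
            bx = {x.cdr3_aa: x.count for x in b}
            return morisita_horn([ax.get(k, 0) for k in union],
                                 [bx.get(k, 0) for k in union])
        assert mh(s, c1) >= mh(c1, c2) - 0.05

    def test_expanded_group_counts_within_poisson_bound(self):
        """Factor-boosted carriers hit their expected counts within 3 sigma."""
        spec, cdr3s, v_of, truth = self._scenario(seed=10)
        rep = sample_condition(cdr3s, v_of, truth, "BlL0", 0, spec)
        counts = {c.cdr3_aa: c.count for c in rep}
        w = np.array([truth.base_weight[s] for s in cdr3s])
        responsive = np.array([truth.label_of[s] in ("direct", "shared") for s in cdr3s])
        w_exp = np.where(responsive, w * spec.expansion_factor, w)
        p = w_exp / w_exp.sum()
        expected = p * spec.depth
        carriers = [i for i, s in enumerate(cdr3s) if responsive[i]]
        agg_expected = sum(expected[i] for i in carriers)
        agg_observed = sum(counts.get(cdr3s[i], 0) for i in carriers)
        assert abs(agg_observed - agg_expected) <= 3 * np.sqrt(agg_expected)

    def test_depth_respected(self):
        spec, cdr3s, v_of, truth = self._scenario(seed=11)
        rep = sample_condition(cdr3s, v_of, truth, "Int", 0, spec)
        assert rep.total_count == spec.depth


class TestWriteScenario:
    def test_manifest_and_round_trip(self, tmp_path):
        spec = SimulationSpec(n_background=300, depth=5000, replicates=1, seed=12)
        manifest = write_scenario(spec, tmp_path)
        assert len(manifest["samples"]) == len(spec.conditions)
        for sid, entry in manifest["samples"].items():
            rep = read_airr(tmp_path / entry["path"], sample_id=sid)
            assert len(rep) > 0
        assert (tmp_path / "truth.tsv").exists()
        assert (tmp_path / "manifest.yaml").exists()
        assert manifest["seed"] == 12

    def test_scenario_loader_matches_generator(self, tmp_path):
        from allorep.pipeline import load_manifest

        spec = SimulationSpec(n_background=300, depth=5000, replicates=1, seed=13)
        write_scenario(spec, tmp_path)
        loaded = load_manifest(tmp_path / "manifest.yaml")
        direct, _ = generate_scenario(spec)
        by_id = {r.sample_id: r for r in direct}
        for rep in loaded:
            ref = by_id[rep.sample_id]
            assert {(c.cdr3_aa, c.count) for c in rep} == \
                {(c.cdr3_aa, int(c.count)) for c in ref}
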