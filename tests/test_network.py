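"""Adjacency/TOM primitives, consensus, module detection, and meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import socortex as sc


def brute_force_tom(a):
    """Direct evaluation of the topological-overlap formula."""
    n = a.shape[0]
    t = np.eye(n)
    k = a.sum(axis=0) - np.diag(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def random_adjacency(rng, n):
    r = rng.uniform(0, 1, (n, n))
    a = (r + r.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.arange(8, dtype=float)
        expr = np.vstack([x, 2 * x + 3])
        a = sc.adjacency(expr, beta=4, sign="unsigned")
        assert a[0, 1] == pytest.approx(1.0)

    def test_orthogonal_genes_give_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        z = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        z -= z @ x / (x @ x) * x  # exact r = 0
        a = sc.adjacency(np.vstack([x, z]), beta=6)
        assert a[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_power_of_correlation(self, rng):
        expr = rng.normal(0, 1, (4, 30))
        r = np.corrcoef(expr)
        a_u = sc.adjacency(expr, beta=2, sign="unsigned")
        a_s = sc.adjacency(expr, beta=2, sign="signed")
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(a_u[off], np.abs(r[off]) ** 2)
        assert np.allclose(a_s[off], ((1 + r[off]) / 2) ** 2)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="4 samples"):
            sc.adjacency(rng.normal(0, 1, (5, 3)))

    def test_zero_variance_rows_rejected(self, rng):
        expr = rng.normal(0, 1, (3, 10))
        expr[1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            sc.adjacency(expr)


class TestTom:
    def test_identity_adjacency_no_overlap(self):
        t = sc.tom(np.eye(5))
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(t[off], 0.0)
        assert np.allclose(np.diag(t), 1.0)

    def test_complete_graph_full_overlap(self):
        a = np.ones((6, 6))
        assert np.allclose(sc.tom(a), 1.0)

    def test_three_gene_hand_example(self):
        a = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        assert np.allclose(sc.tom(a), brute_force_tom(a), atol=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_matches_brute_force(self, n):
        for seed in range(8):
            a = random_adjacency(np.random.default_rng(seed), n)
            t = sc.tom(a)
            assert np.allclose(t, brute_force_tom(a), atol=1e-10)
            assert np.all((t >= 0) & (t <= 1))
            assert np.allclose(t, t.T)


class TestConsensus:
    def test_identical_toms_unchanged(self, rng):
        t = sc.tom(random_adjacency(rng, 6))
        cons = sc.consensus_tom({"a": t, "b": t, "c": t})
        assert np.allclose(cons, t)

    def test_minimum_semantics_with_zero_species(self, rng):
        t = sc.tom(random_adjacency(rng, 5))
        zero = np.eye(5)
        cons = sc.consensus_tom([t, zero], quantile=0.0, calibrate=False)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(cons[off], 0.0)

    def test_median_quantile_interpolates(self):
        a = np.full((2, 2), 0.2)
        b = np.full((2, 2), 0.6)
        np.fill_diagonal(a, 1.0)
        np.fill_diagonal(b, 1.0)
        cons = sc.consensus_tom([a, b], quantile=0.5, calibrate=False)
        assert cons[0, 1] == pytest.approx(0.4)

    def test_adding_species_never_increases_minimum(self, rng):
        toms = [sc.tom(random_adjacency(rng, 6)) for _ in range(3)]
        c2 = sc.consensus_tom(toms[:2], quantile=0.0, calibrate=False)
        c3 = sc.consensus_tom(toms, quantile=0.0, calibrate=False)
        assert np.all(c3 <= c2 + 1e-12)

    def test_gene_set_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="share"):
            sc.consensus_tom([np.eye(4), np.eye(5)])


def _planted_tom(rng, sizes, within=0.8, between=0.05, jitter=0.02):
    n = sum(sizes)
    t = np.full((n, n), between)
    start = 0
    for s in sizes:
        t[start:start + s, start:start + s] = within
        start += s
    t += rng.uniform(-jitter, jitter, (n, n))
    t = np.clip((t + t.T) / 2, 0, 1)
    np.fill_diagonal(t, 1.0)
    return t


class TestDetectModules:
    def test_recovers_planted_blocks(self, rng):
        t = _planted_tom(rng, [20, 15])
        genes = [f"g{i}" for i in range(35)]
        mod = sc.detect_modules(t, genes, min_size=10)
        truth = [1] * 20 + [2] * 15
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, mod.tolist()) == 1.0
        assert (mod[:20] == mod.iloc[0]).all()

    def test_min_size_above_n_genes_all_unassigned(self, rng):
        t = _planted_tom(rng, [10])
        mod = sc.detect_modules(t, [f"g{i}" for i in range(10)], min_size=11)
        assert (mod == 0).all()

    def test_relaxation_reveals_small_module(self, rng):
        """A 15-gene module is invisible at min size 30, found at <= 15."""
        t = _planted_tom(rng, [40, 15])
        genes = [f"g{i}" for i in range(55)]
        at30 = sc.detect_modules(t, genes, min_size=30)
        at10 = sc.detect_modules(t, genes, min_size=10)
        assert set(at30[40:]) == {0}
        assert len(set(at10[40:])) == 1 and at10.iloc[40] != 0

    def test_assigned_set_grows_as_size_relaxes(self, rng):
        t = _planted_tom(rng, [25, 18, 12])
        genes = [f"g{i}" for i in range(55)]
        assigned = None
        for ms in (30, 20, 10):
            mod = sc.detect_modules(t, genes, min_size=ms)
            now = set(mod.index[mod > 0])
            if assigned is not None:
                assert assigned <= now
            assigned = now

    def test_labels_ordered_by_size(self, rng):
        t = _planted_tom(rng, [12, 30])
        mod = sc.detect_modules(t, [f"g{i}" for i in range(42)], min_size=10)
        sizes = mod[mod > 0].value_counts()
        assert sizes.loc[1] >= sizes.loc[2]


class TestEigengene:
    def test_identical_genes(self, rng):
        profile = rng.normal(0, 1, 12)
        expr = pd.DataFrame([profile, profile, profile],
                            index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(12)])
        eg = sc.eigengene(expr, ["a", "b", "c"])
        k = sc.kme(expr, eg)
        assert np.allclose(k, 1.0)
        r = np.corrcoef(eg, profile)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_anticorrelated_gene_negative_kme(self, rng):
        profile = rng.normal(0, 1, 10)
        expr = pd.DataFrame(
            [profile, profile + rng.normal(0, 0.1, 10), -profile],
            index=["a", "b", "anti"], columns=[f"s{i}" for i in range(10)])
        eg = sc.eigengene(expr, ["a", "b"])
        k = sc.kme(expr, eg)
        assert k["anti"] < 0

    def test_matches_svd_first_component(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (5, 9)),
                            index=list("abcde"),
                            columns=[f"s{i}" for i in range(9)])
        eg = sc.eigengene(expr, list("abcde"))
        z = stats.zscore(expr.to_numpy(), axis=1, ddof=1)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        r = np.corrcoef(eg.to_numpy(), vt[0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert eg.std(ddof=1) == pytest.approx(1.0)

    def test_singular_module_rejected(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]] * 2, index=["a", "b"],
                            columns=list("wxyz"))
        with pytest.raises(ValueError, match="constant"):
            sc.eigengene(expr, ["a", "b"])


class TestTraitMeta:
    def test_equal_inputs_scale_with_sqrt_s(self):
        r = pd.DataFrame({f"sp{i}": [0.5] for i in range(4)})
        n = {f"sp{i}": 20 for i in range(4)}
        out = sc.stouffer_meta(r, n)
        z_single = np.arctanh(0.5) * np.sqrt(17)
        assert out.meta_z.iloc[0] == pytest.approx(z_single * 2)  # sqrt(4)

    def test_opposite_signs_cancel(self):
        r = pd.DataFrame({"a": [0.9], "b": [-0.9]})
        out = sc.stouffer_meta(r, {"a": 16, "b": 16})
        assert out.meta_z.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_species_hand_value(self):
        r = pd.DataFrame({"a": [0.6], "b": [0.3], "c": [-0.2]})
        n = {"a": 10, "b": 20, "c": 15}
        z = {sp: np.arctanh(r[sp][0]) * np.sqrt(n[sp] - 3) for sp in n}
        w = {sp: np.sqrt(n[sp]) for sp in n}
        want = sum(w[sp] * z[sp] for sp in n) / np.sqrt(sum(w[sp]**2 for sp in n))
        out = sc.stouffer_meta(r, n)
        assert out.meta_z.iloc[0] == pytest.approx(want)
        assert out.p.iloc[0] == pytest.approx(2 * stats.norm.sf(abs(want)))

    def test_constant_phenotype_species_excluded(self, rng, caplog):
        vals = {
            "a": pd.DataFrame(rng.normal(0, 1, (3, 10))),
            "b": pd.DataFrame(rng.normal(0, 1, (3, 10))),
        }
        pheno = {"a": np.array([0, 1] * 5, dtype=float),
                 "b": np.ones(10)}
        with caplog.at_level("WARNING", logger="socortex"):
            r, meta = sc.trait_association(vals, pheno)
        assert list(r.columns) == ["a"]
        assert "constant phenotype" in caplog.text


class TestPreservation:
    def _kme_frame(self, rng, n=60, tight=15):
        k = pd.DataFrame({1: rng.uniform(-0.3, 0.3, n)},
                         index=[f"g{i}" for i in range(n)])
        k.iloc[:tight, 0] = rng.uniform(0.85, 0.99, tight)
        return k

    def test_planted_module_high_z(self, rng):
        k = self._kme_frame(rng)
        modules = pd.Series(0, index=k.index)
        modules.iloc[:15] = 1
        z = sc.preservation_z(k[1], k, modules, n_permutations=200, seed=0)
        assert z[1] > 5

    def test_random_module_near_zero(self, rng):
        zs = []
        for rep in range(10):
            r = np.random.default_rng(rep)
            k = pd.DataFrame({1: r.uniform(-0.5, 0.5, 60)},
                             index=[f"g{i}" for i in range(60)])
            modules = pd.Series(0, index=k.index)
            modules.iloc[r.choice(60, 12, replace=False)] = 1
            z = sc.preservation_z(k[1], k, modules, n_permutations=200, seed=rep)
            zs.append(abs(z[1]))
        assert np.mean(np.array(zs) < 2) >= 0.9

    def test_singleton_module_rejected(self, rng):
        k = self._kme_frame(rng)
        modules = pd.Series(0, index=k.index)
        modules.iloc[0] = 1
        with pytest.raises(ValueError, match="fewer than 2"):
            sc.preservation_z(k[1], k, modules)


@pytest.fixture(scope="module")
def consensus_result(small_net_inputs):
    vst, samples = small_net_inputs
    cfg = sc.NetworkConfig(min_module_sizes=(15, 10), seed=0,
                           n_preservation_permutations=50)
    return sc.run_consensus_network(vst, samples, cfg)


@pytest.fixture(scope="module")
def small_net_inputs():
    cfg = sc.SimulationConfig(
        n_genes=100, n_toolkit_genes=0, n_clade_specific_genes=0,
        n_modules=3, module_size_range=(15, 20), n_trait_modules=1,
        trait_factor_shift=2.0, seed=21)
    ds, truth = sc.simulate_dataset(cfg)
    vst = sc.variance_stabilize(ds)
    return vst, ds.samples


class TestConsensusPipeline:
    def test_result_invariants(self, consensus_result):
        res = consensus_result
        cons = res.consensus_tom
        assert np.allclose(cons, cons.T)
        assert np.all((cons >= 0) & (cons <= 1))
        assert np.allclose(np.diag(cons), 1.0)
        for sp, t in res.per_species_tom.items():
            assert t.shape == cons.shape

    def test_only_trait_module_flagged_significant(self, small_net_inputs):
        """The phenotype-tracking module is flagged; the neutral ones are not."""
        vst, samples = small_net_inputs
        cfg = sc.SimulationConfig(
            n_genes=100, n_toolkit_genes=0, n_clade_specific_genes=0,
            n_modules=3, module_size_range=(15, 20), n_trait_modules=1,
            trait_factor_shift=2.0, seed=21)
        _, truth = sc.simulate_dataset(cfg)
        net_cfg = sc.NetworkConfig(min_module_sizes=(10,), seed=0,
                                   n_preservation_permutations=20)
        res = sc.run_consensus_network(vst, samples, net_cfg)
        mt = res.module_trait[10]
        sig = set(mt.index[(mt.p_adjusted < 0.05).fillna(False)])
        assert len(sig) == 1
        mod = res.modules_by_size[10]
        planted = truth.module_gene_ids(next(iter(truth.trait_modules)))
        detected = set(mod.index[mod == next(iter(sig))])
        assert len(detected & planted) >= len(planted) * 0.7
        assert len(res.trait_genes) > 0

    def test_single_species_network_recovers_modules(self):
        # strong signal: one species' 24 samples at low dispersion suffice
        cfg = sc.SimulationConfig(
            n_genes=100, n_toolkit_genes=0, n_clade_specific_genes=0,
            n_modules=3, module_size_range=(15, 20), n_trait_modules=1,
            trait_factor_shift=2.0, dispersion_shape=(np.log(0.05), 0.3),
            n_samples_per_phenotype={sp: (12, 12) for sp in sc.DEFAULT_SPECIES},
            seed=21)
        ds, truth = sc.simulate_dataset(cfg)
        vst = sc.variance_stabilize(ds)
        cols = ds.samples.index[ds.samples.species == "bee1"]
        out = sc.single_species_network(
            vst.values[cols],
            (ds.samples.loc[cols, "phenotype"] == "reproductive"
             ).to_numpy(float),
            sc.NetworkConfig(min_module_sizes=(10,), soft_power=6))
        mod = out["modules_by_size"][10]
        rec = sc.score_recovery(dict(mod), truth, "module")
        assert rec.ari >= 0.7

    def test_degenerate_single_species_consensus(self, small_net_inputs):
        vst, samples = small_net_inputs
        cols = samples.index[samples.species == "bee1"]
        expr = vst.values[cols]
        kept, _ = sc.filter_variable_genes(expr)
        t = sc.tom(sc.adjacency(kept, beta=6))
        cons = sc.consensus_tom({"bee1": t})
        assert np.allclose(cons, t)

    def test_variance_filter_removes_flat_genes(self, small_net_inputs, rng):
        vst, samples = small_net_inputs
        expr = vst.values.copy()
        expr.iloc[0] = 1.0
        kept, removed = sc.filter_variable_genes(expr)
        assert expr.index[0] in removed
        assert expr.index[0] not in kept.index


class TestResamplingNull:
    def test_literal_rule_degenerate_case(self):
        """All-zero null proportions count as 'more extreme than 50%'."""
        props = np.zeros(10)
        p_literal = float(np.mean(np.abs(props - 0.5) > 0))
        assert p_literal == 1.0

    def test_fixed_seed_reproducible(self, small_net_inputs):
        vst, samples = small_net_inputs
        cfg = sc.NetworkConfig(min_module_sizes=(10,), resampling_k=4, seed=3)
        a = sc.resampling_null(vst, samples, cfg)
        b = sc.resampling_null(vst, samples, cfg)
        assert np.array_equal(a["proportions"], b["proportions"])

    def test_planted_signal_low_exceedance_p(self, small_net_inputs):
        vst, samples = small_net_inputs
        cfg = sc.NetworkConfig(min_module_sizes=(10,), resampling_k=100, seed=5)
        out = sc.resampling_null(vst, samples, cfg)
        assert out["p_exceedance"] <= 0.01
        assert out["p_literal_two_tailed"] >= 0.0  # reported alongside

    def test_empty_point_estimate_rejected(self, small_net_inputs):
        vst, samples = small_net_inputs
        cfg = sc.NetworkConfig(resampling_k=2, seed=0)
        with pytest.raises(ValueError, match="empty point-estimate"):
            sc.resampling_null(vst, samples, cfg, point_estimate=set())
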