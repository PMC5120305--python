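import numpy as np
import pytest
from scipy.special import logsumexp

from bgrmi.design import build_design, build_heterodimers
from bgrmi.io import ExpressionDataset
from bgrmi.priors import sparsity_log_prior
from bgrmi.scoring import zellner_g
from bgrmi.search import SearchConfig, extend_subsets, infer_network, search_gene

from conftest import driven_design
from _oracles import enumerate_edge_posteriors


def _sparsity(subset):
    return sparsity_log_prior(len(subset))


class TestExtendSubsets:
    def test_dedup_from_two_parents(self):
        out = extend_subsets([("A",), ("B",)], ["A", "B", "C"])
        assert out == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_empty_parent_gives_singletons(self):
        assert extend_subsets([()], ["A", "B"]) == {("A",), ("B",)}

    def test_size_cap(self):
        assert extend_subsets([("A", "B")], ["A", "B", "C"], max_model_size=2) == set()


class TestSearchGene:
    def test_pure_noise_target_usually_keeps_null(self):
        """On i.i.d.-noise targets the null model survives the search in
        the majority of replicates, leaving all edge posteriors 0."""
        survived = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 11
            mat = rng.standard_normal((6, n))  # target + 5 candidates, i.i.d.
            ds = ExpressionDataset(
                ["T"] + [f"R{k}" for k in range(5)], [mat], [np.arange(float(n))]
            )
            d = build_design(ds, build_heterodimers(ds), "T")
            post, accepted = search_gene(d, _sparsity, SearchConfig())
            if not accepted:
                assert all(v == 0.0 for v in post.values())
                survived += 1
        assert survived > 20

    def test_strong_driver_dominates(self):
        ds, regs = driven_design(n=50, sigma=0.05, seed=21, n_candidates=4)
        d = build_design(ds, regs, "T")
        post, accepted = search_gene(d, _sparsity, SearchConfig())
        assert accepted
        assert post["R0"] == max(post.values())
        assert post["R0"] > 0.75

    def test_single_candidate_posterior_is_one(self):
        ds, regs = driven_design(n=50, sigma=0.05, seed=22, n_candidates=1)
        d = build_design(ds, regs, "T")
        post, accepted = search_gene(d, _sparsity, SearchConfig())
        assert accepted
        assert post["R0"] == pytest.approx(1.0)

    def test_posterior_equals_direct_summation(self):
        """Edge posterior == mass of accepted models containing the
        regulator over the total accepted mass."""
        ds, regs = driven_design(n=40, sigma=0.1, seed=23, n_candidates=5)
        d = build_design(ds, regs, "T")
        post, accepted = search_gene(d, _sparsity, SearchConfig())
        lp = np.array([m.log_posterior_unnorm for m in accepted])
        nc = logsumexp(lp)
        for rid in d.candidate_ids:
            mass = [m.log_posterior_unnorm for m in accepted if rid in m.regulator_subset]
            expected = float(np.exp(logsumexp(mass) - nc)) if mass else 0.0
            assert post[rid] == pytest.approx(expected, abs=1e-12)

    def test_thresholds_strictly_increase(self):
        """Every accepted model beats the null model's posterior, and in
        stagewise mode acceptance gets strictly harder."""
        ds, regs = driven_design(n=40, sigma=0.1, seed=24, n_candidates=5)
        d = build_design(ds, regs, "T")
        from bgrmi.scoring import score_model
        g = zellner_g(d.n, len(d.candidate_ids))
        null = score_model(d, (), g, _sparsity(()))
        _, accepted = search_gene(d, _sparsity, SearchConfig())
        assert all(m.log_posterior_unnorm > null.log_posterior_unnorm for m in accepted)
        by_size = {}
        for m in accepted:
            by_size.setdefault(len(m.regulator_subset), []).append(m.log_posterior_unnorm)
        sizes = sorted(by_size)
        for a, b in zip(sizes, sizes[1:]):
            assert max(by_size[a]) < max(by_size[b])

    def test_brute_force_enumeration_oracle(self):
        """Independent re-scoring of the accepted set reproduces the
        search's edge posteriors bit-exactly (5 candidates, 2^5 space)."""
        ds, regs = driven_design(n=40, sigma=0.1, seed=25, n_candidates=5)
        d = build_design(ds, regs, "T")
        cfg = SearchConfig(max_model_size=5)
        post, accepted = search_gene(d, _sparsity, cfg)
        g = zellner_g(d.n, len(d.candidate_ids))
        oracle = enumerate_edge_posteriors(
            d, _sparsity, g, [m.regulator_subset for m in accepted]
        )
        for rid in d.candidate_ids:
            assert post[rid] == pytest.approx(oracle[rid], abs=1e-12)

    def test_fixed_mode_accepts_superset(self):
        ds, regs = driven_design(n=40, sigma=0.1, seed=26, n_candidates=5)
        d = build_design(ds, regs, "T")
        _, acc_stage = search_gene(d, _sparsity, SearchConfig(threshold_mode="stagewise"))
        _, acc_fixed = search_gene(d, _sparsity, SearchConfig(threshold_mode="fixed"))
        stage_subsets = {m.regulator_subset for m in acc_stage}
        fixed_subsets = {m.regulator_subset for m in acc_fixed}
        assert stage_subsets <= fixed_subsets

    def test_determinism(self):
        ds, regs = driven_design(n=40, sigma=0.1, seed=27)
        d = build_design(ds, regs, "T")
        p1, a1 = search_gene(d, _sparsity, SearchConfig())
        p2, a2 = search_gene(d, _sparsity, SearchConfig())
        assert p1 == p2
        assert [m.regulator_subset for m in a1] == [m.regulator_subset for m in a2]


class TestInferNetwork:
    def test_posterior_range_and_shape(self, irma_fixture):
        ds, _ = irma_fixture
        res = infer_network(ds, build_heterodimers(ds))
        assert res.posterior.shape == (5, 5)
        assert np.all((res.posterior >= 0) & (res.posterior <= 1))

    def test_gene_order_permutes_rows_only(self, irma_fixture):
        ds, _ = irma_fixture
        perm = [2, 0, 4, 1, 3]
        ds_perm = ExpressionDataset(
            [ds.gene_ids[i] for i in perm],
            [m[perm] for m in ds.series],
            ds.time_stamps,
        )
        r1 = infer_network(ds, build_heterodimers(ds))
        r2 = infer_network(ds_perm, build_heterodimers(ds_perm))
        for tgt in ds.gene_ids:
            for reg in ds.gene_ids:
                i1, j1 = r1.gene_ids.index(tgt), r1.regulator_ids.index(reg)
                i2, j2 = r2.gene_ids.index(tgt), r2.regulator_ids.index(reg)
                assert r1.posterior[i1, j1] == pytest.approx(r2.posterior[i2, j2], abs=1e-10)

    def test_strength_zero_where_posterior_zero(self, irma_fixture):
        ds, _ = irma_fixture
        res = infer_network(ds, build_heterodimers(ds))
        assert np.all(res.strength[res.posterior == 0.0] == 0.0)
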