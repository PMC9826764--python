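"""Co-expression networks: TOM, soft threshold, clustering, eigengenes, GSEA."""

import warnings

import numpy as np
import pandas as pd
import pytest

import fibsig as f
from fibsig.coexpression import (
    CoexpressionConfig,
    _adjacency,
    _enrichment_score,
    adjacency_to_tom,
    class_ranked_list,
    cluster_modules,
    correlation_matrix,
    gsea_module_class,
    module_eigengene,
    select_soft_threshold,
)
from fibsig.counts import NormalizedMatrix


def make_norm(x, genes=None, samples=None):
    x = np.asarray(x, float)
    genes = genes or [f"g{i}" for i in range(x.shape[0])]
    samples = samples or [f"s{j}" for j in range(x.shape[1])]
    return NormalizedMatrix(
        pd.DataFrame(x, index=genes, columns=samples),
        pd.Series(np.ones(len(samples)), index=samples),
    )


def planted_blocks(rng, n_a=40, n_b=40, n_noise=0, n_samples=30, r=0.8):
    """Two latent-factor blocks with within-block correlation about r."""
    lam = np.sqrt(r)
    fa, fb = rng.normal(0, 1, n_samples), rng.normal(0, 1, n_samples)
    noise_sd = np.sqrt(1 - r)
    rows = [lam * fa + rng.normal(0, noise_sd, n_samples) for _ in range(n_a)]
    rows += [lam * fb + rng.normal(0, noise_sd, n_samples) for _ in range(n_b)]
    rows += [rng.normal(0, 1, n_samples) for _ in range(n_noise)]
    return make_norm(np.array(rows))


class TestCorrelationMatrix:
    def test_duplicate_and_negated_gene(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 20)
        norm = make_norm([base, base, -base, rng.normal(0, 1, 20)])
        c = correlation_matrix(norm)
        assert c.iloc[0, 1] == pytest.approx(1.0)
        assert c.iloc[0, 2] == pytest.approx(-1.0)

    def test_independent_noise_off_diagonals_bounded(self):
        rng = np.random.default_rng(4)
        norm = make_norm(rng.normal(0, 1, (12, 50)))
        c = correlation_matrix(norm).to_numpy()
        off = c[np.triu_indices(12, 1)]
        assert np.abs(off).max() < 0.4  # ~3 sigma at n=50

    def test_zero_variance_gene_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (5, 10))
        x[2] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            c = correlation_matrix(make_norm(x))
        assert c.shape == (4, 4)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match=">=4 samples"):
            correlation_matrix(make_norm(np.ones((5, 3))))


class TestSoftThreshold:
    def test_planted_scale_free_structure_reaches_target(self):
        # hub-factor model: gene i loads on a shared factor with weight
        # decaying in i, giving a heavy-tailed connectivity profile
        rng = np.random.default_rng(6)
        n_genes, n_samples = 300, 60
        factor = rng.normal(0, 1, n_samples)
        w = np.clip((np.arange(1, n_genes + 1)) ** -0.5, 0, 0.98)
        x = np.outer(w, factor) + rng.normal(
            0, 1, (n_genes, n_samples)
        ) * np.sqrt(1 - w**2)[:, None]
        beta, rsq = select_soft_threshold(correlation_matrix(make_norm(x)))
        assert rsq >= 0.8
        assert beta in CoexpressionConfig().beta_grid

    def test_degenerate_all_ones_falls_back(self):
        c = pd.DataFrame(np.ones((10, 10)))
        with pytest.warns(UserWarning):
            beta, _ = select_soft_threshold(c)
        assert beta == 6

    def test_adjacency_decreases_with_beta(self):
        rng = np.random.default_rng(2)
        c = correlation_matrix(make_norm(rng.normal(0, 1, (8, 20)))).to_numpy()
        a2 = _adjacency(c, 2, "unsigned")
        a5 = _adjacency(c, 5, "unsigned")
        off = ~np.eye(8, dtype=bool)
        assert (a5[off] <= a2[off] + 1e-12).all()


class TestTom:
    def test_isolated_pair_and_disconnected(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 1.0
        tom = adjacency_to_tom(a)
        assert tom[0, 1] == pytest.approx(1.0)
        assert tom[2, 3] == pytest.approx(0.0)

    def test_matches_brute_force_on_hand_matrix(self):
        rng = np.random.default_rng(7)
        a = rng.random((6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = adjacency_to_tom(a)
        # direct evaluation of the definition
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                l_ij = sum(a[i, u] * a[u, j] for u in range(6) if u not in (i, j))
                k_i = a[i].sum() - 1
                k_j = a[j].sum() - 1
                ref = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(ref, abs=1e-12)

    def test_range_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(8)
        r = np.corrcoef(rng.normal(0, 1, (20, 30)))
        a = _adjacency(r, 6, "unsigned")
        tom = adjacency_to_tom(a)
        assert (tom >= 0).all() and (tom <= 1).all()
        np.testing.assert_allclose(tom, tom.T)
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestClustering:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(10)
        norm = planted_blocks(rng)
        res = f.discover_modules(norm)
        truth_a = set(norm.genes[:40])
        found = {m: set(res.assignments.index[res.assignments == m])
                 for m in res.modules}
        assert len(found) == 2
        best = max(
            len(g & truth_a) / len(g | truth_a) for g in found.values()
        )
        assert best >= 0.9

    def test_min_module_size_filters_everything(self):
        rng = np.random.default_rng(11)
        norm = planted_blocks(rng, n_a=5, n_b=5, n_samples=20)
        cfg = CoexpressionConfig(min_module_size=50)
        with pytest.warns(UserWarning, match="unassigned"):
            labels = cluster_modules(
                adjacency_to_tom(
                    pd.DataFrame(
                        _adjacency(correlation_matrix(norm).to_numpy(), 6,
                                   "unsigned"),
                        index=norm.genes, columns=norm.genes,
                    )
                ),
                cfg,
            )
        assert (labels == "unassigned").all()

    def test_gene_order_permutation_invariant(self):
        rng = np.random.default_rng(12)
        norm = planted_blocks(rng, n_a=25, n_b=25, n_samples=25)
        res1 = f.discover_modules(norm)
        perm = rng.permutation(len(norm.genes))
        norm2 = NormalizedMatrix(norm.values.iloc[perm], norm.size_factors)
        res2 = f.discover_modules(norm2)
        for m in res1.modules:
            assert any(
                res1.module_genes(m) == res2.module_genes(m2)
                for m2 in res2.modules
            )


class TestEigengene:
    def test_single_gene_module_is_standardized_profile(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, (3, 12))
        norm = make_norm(x)
        labels = pd.Series(["M1", "unassigned", "unassigned"], index=norm.genes)
        eig = module_eigengene(norm, labels, "M1")
        z = (x[0] - x[0].mean()) / x[0].std()
        np.testing.assert_allclose(np.abs(eig), np.abs(z) / np.linalg.norm(z),
                                   atol=1e-9)
        assert np.corrcoef(eig, z)[0, 1] > 0.999

    def test_correlates_with_planted_factor(self):
        rng = np.random.default_rng(14)
        factor = rng.normal(0, 1, 40)
        x = np.array([0.9 * factor + rng.normal(0, 0.4, 40) for _ in range(30)])
        norm = make_norm(x)
        labels = pd.Series("M1", index=norm.genes)
        eig = module_eigengene(norm, labels, "M1")
        assert abs(np.corrcoef(eig, factor)[0, 1]) >= 0.95


def paired_annotation():
    rows = []
    for cond, n in [("CD", 3), ("UC", 3), ("CI", 3)]:
        for i in range(n):
            pid = f"{cond}{i}"
            for tissue in ("ILEAL", "SIGMOID"):
                rows.append({"sample_id": f"{pid}_{tissue}", "patient_id": pid,
                             "tissue": tissue, "condition": cond})
    return f.SampleAnnotation(pd.DataFrame(rows))


class TestRankedListAndGsea:
    def test_scores_and_determinism(self):
        ann = paired_annotation()
        rng = np.random.default_rng(15)
        x = rng.normal(5, 1, (20, 18))
        x[0] = 5.0  # constant gene scores 0
        x[1, :3] += 4.0  # elevated exactly in CD patients' ileal samples
        norm = make_norm(x, samples=ann.sample_ids)
        ranking = class_ranked_list(norm, ann, "ILEAL", "CD")
        assert ranking["g0"] == 0.0
        assert ranking.index[0] == "g1" and ranking["g1"] > 1.0

    def test_top_of_ranking_module_has_es_near_one(self):
        scores = np.linspace(3, -3, 100)
        hit = np.zeros(100, bool)
        hit[:10] = True
        assert _enrichment_score(scores, hit) > 0.9

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(16)
        ranking = pd.Series(
            np.sort(rng.normal(0, 1, 200))[::-1],
            index=[f"g{i}" for i in range(200)],
        )
        module = f.GeneSet("m", [f"g{i}" for i in range(0, 200, 7)])
        e1 = gsea_module_class(ranking, module, n_perm=200, seed=5)
        e2 = gsea_module_class(ranking, module, n_perm=200, seed=5)
        assert (e1.nes, e1.p) == (e2.nes, e2.p)

    def test_random_modules_are_mostly_non_significant(self):
        rng = np.random.default_rng(17)
        ranking = pd.Series(
            np.sort(rng.normal(0, 1, 300))[::-1],
            index=[f"g{i}" for i in range(300)],
        )
        n_nonsig = 0
        for trial in range(100):
            genes = rng.choice(300, 25, replace=False)
            module = f.GeneSet("m", [f"g{i}" for i in genes])
            enr = gsea_module_class(ranking, module, n_perm=200, seed=trial)
            n_nonsig += enr.p >= 0.05
        assert n_nonsig >= 90

    def test_empty_overlap_is_error(self):
        ranking = pd.Series([1.0, -1.0], index=["a", "b"])
        with pytest.raises(ValueError, match="no genes"):
            gsea_module_class(ranking, f.GeneSet("m", ["zz"]), n_perm=100)

    def test_nes_sign_follows_es_sign(self):
        rng = np.random.default_rng(18)
        ranking = pd.Series(
            np.sort(rng.normal(0, 1, 150))[::-1],
            index=[f"g{i}" for i in range(150)],
        )
        top = f.GeneSet("top", [f"g{i}" for i in range(12)])
        bottom = f.GeneSet("bot", [f"g{i}" for i in range(138, 150)])
        e_top = gsea_module_class(ranking, top, n_perm=200, seed=1)
        e_bot = gsea_module_class(ranking, bottom, n_perm=200, seed=1)
        assert e_top.es > 0 and e_top.nes > 0
        assert e_bot.es < 0 and e_bot.nes < 0


class TestSingleModuleReplicates:
    def test_planted_module_recovered_across_replicates(self):
        """One module, >=90% of planted genes, in >=95% of 100 replicates."""
        successes = 0
        for seed in range(100):
            spec = f.PairedBiopsySpec(seed=seed)
            counts, _, truth = f.simulate_paired_counts(spec)
            sig = f.GeneSet("sig", counts.genes[: spec.genes])
            norm = f.log_normalize(counts).restrict(sig)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = f.discover_modules(norm)
            if len(res.modules) != 1:
                continue
            m1 = res.module_genes("M1").as_set()
            planted = truth.module_genes.as_set()
            if len(m1 & planted) / len(planted) >= 0.9:
                successes += 1
        assert successes >= 95
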