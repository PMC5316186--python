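"""Signed adjacency/TOM, module detection, eigengenes, hubs, permutation tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stagedyn.coexpression import (
    build_network,
    detect_modules,
    hub_genes,
    intramodular_connectivity,
    module_eigengene,
    preservation_z,
    stage_association_permtest,
    tom_bruteforce,
    tom_from_adjacency,
)
from stagedyn.preprocess import add_stage_labels


def _expr(values, genes=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes, columns=[f"s{j}" for j in range(values.shape[1])])


def _module_expr(rng, n_modules=2, size=30, n_noise=30, n_samples=20, loading=2.0, noise=0.3):
    """Block-correlated expression: each module follows its own latent factor."""
    rows, genes, truth = [], [], []
    for m in range(n_modules):
        factor = rng.normal(0, 1, n_samples)
        for i in range(size):
            rows.append(loading * factor + rng.normal(0, noise, n_samples))
            genes.append(f"m{m}_{i}")
            truth.append(m + 1)
    for i in range(n_noise):
        rows.append(rng.normal(0, 1, n_samples))
        genes.append(f"noise_{i}")
        truth.append(0)
    return _expr(np.array(rows), genes), np.array(truth)


class TestBuildNetwork:
    def test_signed_map_endpoints(self):
        x = np.array([[1.0, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]])
        net = build_network(_expr(x), beta=6)
        i, j, k = 0, 1, 2
        assert np.isclose(net.adjacency[i, j], 1.0)  # perfectly correlated
        assert np.isclose(net.adjacency[i, k], 0.0)  # perfectly anti-correlated

    def test_triangle_tom_closed_form(self):
        """All adjacencies 0.5 on 3 nodes: TOM_12 = (0.25 + 0.5)/(1 + 1 - 0.5)."""
        adj = np.full((3, 3), 0.5)
        tom = tom_from_adjacency(adj)
        assert np.isclose(tom[0, 1], 0.5)

    def test_tom_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.integers(3, 11)
            cor = rng.uniform(-1, 1, (m, m))
            cor = (cor + cor.T) / 2
            np.fill_diagonal(cor, 1.0)
            adj = ((1 + cor) / 2) ** 6
            np.fill_diagonal(adj, 0.0)
            assert np.allclose(tom_from_adjacency(adj), tom_bruteforce(adj), atol=1e-12)

    def test_tom_bounds_and_symmetry(self):
        rng = np.random.default_rng(1)
        net = build_network(_expr(rng.normal(0, 1, (15, 10))), beta=12)
        assert np.allclose(net.tom, net.tom.T, atol=1e-12)
        assert (net.tom >= -1e-12).all() and (net.tom <= 1 + 1e-12).all()
        assert np.allclose(np.diag(net.tom), 1.0)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        x = _expr(rng.normal(0, 1, (10, 8)))
        net_a = build_network(x, beta=6)
        net_b = build_network(x[np.random.default_rng(3).permutation(x.columns)], beta=6)
        assert np.allclose(net_a.adjacency, net_b.adjacency, atol=1e-12)

    def test_gene_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (10, 8))
        net_a = build_network(_expr(x), beta=6)
        net_b = build_network(_expr(x * 3.0 + 11.0), beta=6)
        assert np.allclose(net_a.adjacency, net_b.adjacency, atol=1e-10)

    def test_bad_beta_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            build_network(_expr(np.random.default_rng(0).normal(0, 1, (5, 6))), beta=0)


class TestDetectModules:
    def test_recovers_two_planted_blocks(self):
        # 60 samples keep spurious noise-gene correlations well below the
        # static cut, so the planted blocks are recovered cleanly
        rng = np.random.default_rng(5)
        expr, truth = _module_expr(rng, n_samples=60)
        net = build_network(expr, beta=12)
        modules = detect_modules(net, min_size=10)
        labels = modules.assignment.to_numpy()
        assert len(modules.modules()) == 2
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_independent_genes_all_unassigned(self):
        rng = np.random.default_rng(6)
        net = build_network(_expr(rng.normal(0, 1, (60, 16))), beta=12)
        with pytest.warns(UserWarning, match="minimum size"):
            modules = detect_modules(net)
        assert (modules.assignment == 0).all()

    def test_gene_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(7)
        expr, truth = _module_expr(rng)
        net_a = build_network(expr, beta=12)
        perm = np.random.default_rng(8).permutation(expr.index)
        net_b = build_network(expr.loc[perm], beta=12)
        mod_a = detect_modules(net_a, min_size=10).assignment
        mod_b = detect_modules(net_b, min_size=10).assignment[mod_a.index]
        assert adjusted_rand_score(mod_a.to_numpy(), mod_b.to_numpy()) == 1.0


class TestModuleEigengene:
    def test_rank_one_module(self):
        rng = np.random.default_rng(9)
        profile = rng.normal(0, 1, 12)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        expr = _expr(np.vstack([3 * profile + 1, -0.5 * profile + 4, 2 * profile]))
        # members 0 and 2 share the standardized profile; include only those
        eig, var_exp = module_eigengene(expr, ["g0", "g2"])
        assert np.isclose(var_exp, 1.0, atol=1e-10)
        assert abs(np.corrcoef(eig, z)[0, 1]) > 1 - 1e-10

    def test_two_gene_closed_form(self):
        """The 2-gene eigengene equals the normalized sum of the standardized
        profiles when the genes correlate positively."""
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 10)
        y = x + rng.normal(0, 0.5, 10)
        expr = _expr(np.vstack([x, y]))
        eig, var_exp = module_eigengene(expr, ["g0", "g1"])
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        expected = zx + zy
        expected = expected / expected.std(ddof=1)
        assert np.allclose(np.abs(eig), np.abs(expected), atol=1e-8)
        assert np.corrcoef(eig, expected)[0, 1] > 0.999

    def test_sign_alignment_under_global_flip(self):
        rng = np.random.default_rng(11)
        expr, _ = _module_expr(rng, n_modules=1, size=10, n_noise=0)
        eig_a, _ = module_eigengene(expr, list(expr.index))
        eig_b, _ = module_eigengene(-expr, list(expr.index))
        # flipping every member flips the mean profile too; alignment keeps
        # the eigengene positively correlated with it in both cases
        mean_a = ((expr.sub(expr.mean(axis=1), axis=0)).div(expr.std(axis=1, ddof=1), axis=0)).mean()
        assert np.corrcoef(eig_a, mean_a)[0, 1] >= 0

    def test_eigengene_unit_variance(self):
        rng = np.random.default_rng(12)
        expr, _ = _module_expr(rng, n_modules=1, size=8, n_noise=0)
        eig, var_exp = module_eigengene(expr, list(expr.index))
        assert np.isclose(eig.std(ddof=1), 1.0, atol=1e-10)
        assert 0 < var_exp <= 1


class TestHubGenes:
    def test_star_topology_center_is_top_hub(self):
        rng = np.random.default_rng(13)
        center = rng.normal(0, 1, 30)
        spokes = [center + rng.normal(0, 1.5, 30) for _ in range(6)]
        expr = _expr(np.vstack([center] + spokes), ["center"] + [f"spoke{i}" for i in range(6)])
        net = build_network(expr, beta=6)
        modules = detect_modules(net, cut_height=0.999, min_size=2)
        hubs = hub_genes(net, modules, n=3)
        assert hubs[1][0] == "center"

    def test_kwithin_matches_bruteforce(self):
        rng = np.random.default_rng(14)
        expr, _ = _module_expr(rng, n_modules=1, size=10, n_noise=0, n_samples=12)
        net = build_network(expr, beta=6)
        members = net.genes
        kw = intramodular_connectivity(net, members)
        for gi, g in enumerate(members):
            manual = sum(net.adjacency[gi, gj] for gj in range(len(members)) if gj != gi)
            assert np.isclose(kw[g], manual, atol=1e-12)

    def test_zero_hubs_requested(self):
        rng = np.random.default_rng(15)
        expr, _ = _module_expr(rng)
        net = build_network(expr, beta=12)
        modules = detect_modules(net, min_size=10)
        hubs = hub_genes(net, modules, n=0)
        assert all(v == [] for v in hubs.values())


def _stage_sheet(sample_ids, conditions, weeks):
    return add_stage_labels(
        pd.DataFrame(
            {"sample_id": sample_ids, "condition": conditions, "week": weeks,
             "litter": "L1", "batch": "B1", "age": weeks}
        )
    )


class TestStagePermutationTest:
    def test_monotone_eigengene_minimal_p(self):
        ids = [f"s{i}" for i in range(10)]
        conditions = ["control"] * 2 + ["tumor"] * 8
        weeks = [6, 8] + [6, 6, 8, 8, 10, 10, 12, 12]
        sheet = _stage_sheet(ids, conditions, weeks)
        stage = sheet.set_index("sample_id")["stage_ord"]
        eig = pd.Series(stage.to_numpy(dtype=float) * 2 - 1, index=ids)
        rho, p = stage_association_permtest(eig, sheet, n_permutations=999, seed=0)
        assert rho > 0.99
        assert np.isclose(p, 1 / 1000)

    def test_empirical_matches_exhaustive_on_six_samples(self):
        ids = [f"s{i}" for i in range(6)]
        conditions = ["control", "tumor", "tumor", "tumor", "tumor", "control"]
        weeks = [6, 6, 8, 10, 12, 8]
        sheet = _stage_sheet(ids, conditions, weeks)
        # five distinct stage values (two controls -> tie at 0)
        rng = np.random.default_rng(16)
        eig = pd.Series(rng.normal(0, 1, 6), index=ids)
        rho_a, p_exact = stage_association_permtest(eig, sheet, exact=True)
        rho_b, p_mc = stage_association_permtest(eig, sheet, n_permutations=20_000, seed=1)
        assert np.isclose(rho_a, rho_b)
        mc_err = 3 * np.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(p_mc - p_exact) < mc_err + 1e-4

    def test_null_eigengene_not_significant(self):
        ids = [f"s{i}" for i in range(24)]
        conditions = ["tumor"] * 12 + ["control"] * 12
        weeks = ([6] * 3 + [8] * 3 + [10] * 3 + [12] * 3) * 2
        sheet = _stage_sheet(ids, conditions, weeks)
        rng = np.random.default_rng(17)
        pvals = [
            stage_association_permtest(
                pd.Series(rng.normal(0, 1, 24), index=ids), sheet,
                n_permutations=499, seed=i,
            )[1]
            for i in range(40)
        ]
        assert np.mean(np.array(pvals) > 0.05) >= 0.8

    def test_constant_eigengene_rejected(self):
        ids = [f"s{i}" for i in range(6)]
        sheet = _stage_sheet(ids, ["tumor"] * 3 + ["control"] * 3, [6, 8, 10, 6, 8, 10])
        with pytest.raises(ValueError, match="constant"):
            stage_association_permtest(pd.Series(1.0, index=ids), sheet)


class TestPreservation:
    def test_self_preservation_is_high(self):
        rng = np.random.default_rng(18)
        expr, _ = _module_expr(rng, n_modules=2, size=25, n_noise=50)
        net = build_network(expr, beta=12)
        modules = detect_modules(net, min_size=10)
        assert modules.modules()  # planted modules must be found
        res = preservation_z(net, modules, expr, n_null=100, seed=0)
        assert (res.table["z_density"] > 10).all()
        # with identical reference and test expression the intramodular
        # connectivities agree exactly
        assert np.allclose(res.table["connectivity_cor"], 1.0, atol=1e-10)
        assert (res.table["z_summary"] > 2).all()

    def test_unpreserved_module_near_null(self):
        rng = np.random.default_rng(19)
        ref_expr, _ = _module_expr(rng, n_modules=1, size=20, n_noise=40)
        net = build_network(ref_expr, beta=12)
        modules = detect_modules(net, min_size=10)
        # test expression: same genes, fully independent -> no preservation
        test_expr = pd.DataFrame(
            rng.normal(0, 1, ref_expr.shape), index=ref_expr.index, columns=ref_expr.columns
        )
        res = preservation_z(net, modules, test_expr, n_null=200, seed=1)
        assert (res.table["z_summary"].abs() <= 2.5).all()

    def test_null_resampling_stability(self):
        rng = np.random.default_rng(20)
        expr, _ = _module_expr(rng, n_modules=1, size=15, n_noise=30)
        net = build_network(expr, beta=12)
        modules = detect_modules(net, min_size=10)
        res_a = preservation_z(net, modules, expr, n_null=150, seed=2)
        res_b = preservation_z(net, modules, expr, n_null=300, seed=3)
        za = res_a.table.set_index("module")["z_summary"]
        zb = res_b.table.set_index("module")["z_summary"]
        assert np.allclose(za, zb, rtol=0.5)

    def test_tiny_module_skipped(self):
        rng = np.random.default_rng(21)
        expr, _ = _module_expr(rng, n_modules=1, size=10, n_noise=10)
        net = build_network(expr, beta=12)
        modules = detect_modules(net, min_size=5)
        sub = expr.iloc[: len(expr) // 2]  # drop half the genes from the test set
        small_left = [
            m for m in modules.modules()
            if len([g for g in modules.members(m) if g in sub.index]) < 3
        ]
        if small_left:
            with pytest.warns(UserWarning, match="fewer than 3"):
                preservation_z(net, modules, sub, n_null=20, seed=4)
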