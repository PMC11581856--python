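import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from immunosubtype import network


def _planted_modules(n_modules=5, genes_per=30, n_samples=60, noise=0.3,
                     seed=0, trait_module=0):
    """Genes driven by per-module latent factors; returns (expr, labels,
    trait) where the trait equals module 0's factor."""
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n_modules, n_samples))
    rows, labels = [], []
    for m in range(n_modules):
        for g in range(genes_per):
            rows.append(factors[m] + noise * rng.normal(size=n_samples))
            labels.append(m)
    genes = [f"g{i}" for i in range(len(rows))]
    expr = pd.DataFrame(rows, index=genes,
                        columns=[f"s{i}" for i in range(n_samples)])
    trait = pd.Series(factors[trait_module], index=expr.columns)
    return expr, pd.Series(labels, index=genes), trait


class TestPickSoftPower:
    def test_power_one_adjacency_is_absolute_correlation(self):
        expr, _, _ = _planted_modules(n_modules=2, genes_per=10)
        tom_input = np.abs(np.corrcoef(expr.to_numpy()))
        # the beta = 1 adjacency used in the scan equals |cor| elementwise by
        # definition; verify via the TOM builder's underlying adjacency
        A = np.abs(np.corrcoef(expr.to_numpy())) ** 1
        assert np.allclose(A, tom_input)

    def test_modular_data_reaches_scale_free_fit(self):
        """Hub-and-background structure (heterogeneous module sizes plus
        unconnected genes) admits a power with scale-free fit >= 0.8."""
        rng = np.random.default_rng(3)
        n_samples = 50
        rows = []
        for size in (80, 40, 20, 10, 5):  # 5 planted modules, varied sizes
            factor = rng.normal(size=n_samples)
            for _ in range(size):
                rows.append(factor + 1.5 * rng.normal(size=n_samples))
        for _ in range(500):  # background genes
            rows.append(rng.normal(size=n_samples))
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        beta = network.pick_soft_power(expr)
        C = np.abs(np.corrcoef(expr.to_numpy()))
        np.fill_diagonal(C, 0.0)
        r2 = network.scale_free_fit((C ** beta).sum(axis=1))
        assert r2 >= 0.8

    def test_scale_free_fit_matches_regression_oracle(self):
        rng = np.random.default_rng(5)
        k = rng.pareto(2.0, size=400) + 0.5
        got = network.scale_free_fit(k, n_bins=10)
        # independent oracle: same binning, explicit least squares
        edges = np.linspace(k.min(), k.max(), 11)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs = [k[which == b].mean() for b in range(10) if (which == b).any()]
        ys = [(which == b).mean() for b in range(10) if (which == b).any()]
        slope, intercept, r, _, _ = sps.linregress(np.log10(xs), np.log10(ys))
        assert got == pytest.approx(r ** 2)

    def test_constant_gene_excluded_with_warning(self):
        expr, _, _ = _planted_modules(n_modules=2, genes_per=10)
        expr.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            network.pick_soft_power(expr)


class TestAdjacencyTom:
    def test_two_perfectly_correlated_genes(self):
        x = np.arange(10, dtype=float)
        expr = pd.DataFrame([x, 2 * x + 1], index=["a", "b"])
        tom = network.adjacency_tom(expr, power=1)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_three_gene_toy_matches_hand_formula(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(3, 12)), index=["a", "b", "c"])
        beta = 2
        tom = network.adjacency_tom(expr, power=beta)
        C = np.abs(np.corrcoef(expr.to_numpy())) ** beta
        # hand computation with explicit scalar loops
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            a_ij = C[i, j]
            l_ij = sum(C[i, u] * C[u, j] for u in range(3) if u not in (i, j))
            k_i = sum(C[i, u] for u in range(3) if u != i)
            k_j = sum(C[j, u] for u in range(3) if u != j)
            expected = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
            assert tom.iloc[i, j] == pytest.approx(expected)

    def test_uncorrelated_genes_give_zero_overlap(self):
        expr = pd.DataFrame([[1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]],
                            index=["a", "b", "c"], dtype=float)
        C = np.corrcoef(expr.to_numpy())
        assert np.allclose(C - np.eye(3), 0.0, atol=1e-12)
        tom = network.adjacency_tom(expr, power=1)
        off = tom.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-12)

    def test_constant_gene_named_in_error(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                            index=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            network.adjacency_tom(expr)


class TestDetectModules:
    def test_planted_orthogonal_modules_recovered_exactly(self):
        expr, truth, _ = _planted_modules(n_modules=2, genes_per=20, noise=0.2,
                                          seed=11)
        tom = network.adjacency_tom(expr, power=4)
        res = network.detect_modules(tom, network.NetworkConfig(
            power=4, min_module_size=5, cut_height=0.9))
        assert len(res.modules()) == 2
        for m in res.modules():
            members = set(res.labels.index[res.labels == m])
            planted = [set(truth.index[truth == t]) for t in (0, 1)]
            assert members in planted

    def test_oversized_min_module_greys_everything(self):
        expr, _, _ = _planted_modules(n_modules=2, genes_per=5)
        tom = network.adjacency_tom(expr, power=2)
        with pytest.warns(UserWarning, match="grey"):
            res = network.detect_modules(tom, network.NetworkConfig(
                power=2, min_module_size=50, cut_height=0.9))
        assert (res.labels == network.GREY).all()

    def test_labels_invariant_to_gene_order(self):
        expr, _, _ = _planted_modules(n_modules=3, genes_per=10, seed=13)
        cfg = network.NetworkConfig(power=4, min_module_size=5, cut_height=0.9)
        a = network.detect_modules(network.adjacency_tom(expr, 4), cfg)
        perm = expr.sample(frac=1.0, random_state=1)
        b = network.detect_modules(network.adjacency_tom(perm, 4), cfg)
        pd.testing.assert_series_equal(a.labels.sort_index(),
                                       b.labels.sort_index())

    def test_tom_in_unit_interval_and_symmetric(self, small_lognorm):
        sub = small_lognorm.values.iloc[:80]
        sub = sub[sub.std(axis=1) > 0]
        tom = network.adjacency_tom(sub, power=4).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


class TestEigengenes:
    def test_identical_genes_module_eigengene_is_shared_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = pd.DataFrame([profile, profile, profile],
                            index=["a", "b", "c"])
        labels = pd.Series("M1", index=expr.index)
        eig = network.module_eigengene(expr, labels)
        z = (profile - profile.mean()) / profile.std()
        got = eig.loc["M1"].to_numpy()
        got_z = (got - got.mean()) / got.std()
        assert np.allclose(got_z, z)

    def test_mm_of_identical_members_is_one(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = pd.DataFrame([profile, profile], index=["a", "b"])
        labels = pd.Series("M1", index=expr.index)
        eig = network.module_eigengene(expr, labels)
        trait = pd.Series([0.0, 1.0, 0.0, 1.0, 1.0], index=expr.columns)
        gs, mm = network.gs_mm(expr, eig, labels, trait)
        assert np.allclose(mm, 1.0)

    def test_variance_explained_matches_svd_oracle(self):
        rng = np.random.default_rng(17)
        expr = pd.DataFrame(rng.normal(size=(4, 12)),
                            index=["a", "b", "c", "d"])
        labels = pd.Series("M1", index=expr.index)
        eig = network.module_eigengene(expr, labels).loc["M1"].to_numpy()
        Xs = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=0)).T
        U, S, Vt = np.linalg.svd(Xs.to_numpy(), full_matrices=False)
        assert abs(abs(np.corrcoef(eig, Vt[0])[0, 1]) - 1.0) < 1e-9

    def test_sign_convention_positive_vs_module_mean(self, small_lognorm):
        sub = small_lognorm.values.iloc[:40]
        sub = sub[sub.std(axis=1) > 0]
        labels = pd.Series("M1", index=sub.index)
        eig = network.module_eigengene(sub, labels)
        mean_profile = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1)).T.mean()
        assert np.corrcoef(eig.loc["M1"], mean_profile)[0, 1] > 0


class TestGsMm:
    def test_trait_equal_to_gene_gives_gs_one(self):
        expr, labels, _ = _planted_modules(n_modules=2, genes_per=5, seed=19)
        labels = pd.Series("M1", index=expr.index)
        eig = network.module_eigengene(expr, labels)
        trait = expr.loc["g0"]
        gs, _ = network.gs_mm(expr, eig, labels, trait)
        assert gs["g0"] == pytest.approx(1.0)

    def test_gs_invariant_to_trait_sign_flip(self):
        expr, labels, trait = _planted_modules(n_modules=2, genes_per=5, seed=23)
        labels = pd.Series("M1", index=expr.index)
        eig = network.module_eigengene(expr, labels)
        gs1, _ = network.gs_mm(expr, eig, labels, trait)
        gs2, _ = network.gs_mm(expr, eig, labels, -trait)
        assert np.allclose(gs1, gs2)

    def test_null_trait_mean_gs_matches_expected_absolute_r(self):
        """Independent trait: E|r| for bivariate normal at n samples."""
        rng = np.random.default_rng(29)
        n = 40
        expr = pd.DataFrame(rng.normal(size=(400, n)),
                            index=[f"g{i}" for i in range(400)])
        labels = pd.Series("M1", index=expr.index)
        eig = network.module_eigengene(expr, labels)
        trait = pd.Series(rng.normal(size=n), index=expr.columns)
        gs, _ = network.gs_mm(expr, eig, labels, trait)
        # null |r| has E|r| ~ sqrt(2 / (pi * n)) for large n
        expected = np.sqrt(2 / (np.pi * n))
        assert abs(gs.mean() - expected) < 0.03

    def test_constant_trait_rejected(self):
        expr, labels, _ = _planted_modules(n_modules=2, genes_per=5)
        labels = pd.Series("M1", index=expr.index)
        eig = network.module_eigengene(expr, labels)
        with pytest.raises(ValueError, match="constant"):
            network.gs_mm(expr, eig, labels,
                          pd.Series(1.0, index=expr.columns))


class TestSelectKeyGenes:
    def _fit(self, seed=31, noise=0.3):
        expr, truth, trait = _planted_modules(seed=seed, noise=noise)
        tom = network.adjacency_tom(expr, power=4)
        res = network.detect_modules(tom, network.NetworkConfig(
            power=4, min_module_size=5, cut_height=0.9))
        res.eigengenes = network.module_eigengene(expr, res.labels)
        res.module_trait_cor = network.module_trait_correlation(
            res.eigengenes, trait)
        res.gs, res.mm = network.gs_mm(expr, res.eigengenes, res.labels, trait)
        return expr, truth, trait, res

    def test_planted_trait_module_dominates_selection(self):
        expr, truth, trait, res = self._fit()
        keep = network.select_key_genes(res)
        planted = set(truth.index[truth == 0])
        assert keep, "selection should not be empty"
        recall = len(planted & set(keep)) / len(planted)
        precision = len(planted & set(keep)) / len(keep)
        assert recall >= 0.9 and precision >= 0.9

    def test_impossible_thresholds_give_empty_set(self):
        *_, res = self._fit()
        with pytest.warns(UserWarning, match="empty"):
            out = network.select_key_genes(res, module_cor_min=1.0)
        assert out == []

    def test_zero_thresholds_select_whole_specific_modules(self):
        *_, res = self._fit()
        keep = network.select_key_genes(res, module_cor_min=0.6,
                                        gs_min=0.0, mm_min=-1.0)
        mt = res.module_trait_cor
        specific = [m for m in mt.index
                    if m != network.GREY and abs(mt.loc[m, "cor"]) >= 0.6
                    and mt.loc[m, "p"] < 0.001]
        expected = set(res.labels.index[res.labels.isin(specific)])
        assert set(keep) == expected


class TestOutlierRemoval:
    def test_planted_outlier_dropped(self):
        rng = np.random.default_rng(37)
        base = rng.normal(size=(50, 20))
        expr = pd.DataFrame(base, columns=[f"s{i}" for i in range(20)])
        expr = expr + rng.normal(size=(50, 1))  # shared structure
        expr["weird"] = rng.normal(20, 10, size=50)  # uncorrelated outlier
        with pytest.warns(UserWarning, match="weird"):
            out = network.remove_outlier_samples(expr)
        assert "weird" not in out.columns
        assert out.shape[1] == 20
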