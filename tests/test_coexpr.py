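"""Adjacency, topological overlap, module detection, eigengenes, preservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbidnet import coexpr, expression, synthdata
from comorbidnet.synthdata import ExprScenario


def tom_oracle(a):
    """Brute-force triple loop over the topological overlap definition."""
    n = len(a)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    w = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a0[i, u] * a0[u, j] for u in range(n)
                         if u not in (i, j))
            w[i, j] = (shared + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
    return w


def random_adjacency(rng, n):
    c = rng.uniform(0, 1, size=(n, n))
    a = (c + c.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_power_one_perfect_correlation(self):
        x = np.vstack([np.arange(6.0), 2 * np.arange(6.0) + 1])
        b = synthdata.ExpressionBundle(
            matrix=pd.DataFrame(x, index=["g1", "g2"],
                                columns=[f"s{i}" for i in range(6)]),
            samples=pd.DataFrame({"sample": [f"s{i}" for i in range(6)],
                                  "tissue": "t", "batch": "B1",
                                  "group": "disease", "subtype": "NA",
                                  "disease_activity": 0.0, "crp": 0.0}))
        a = coexpr.adjacency(b, beta=1)
        assert a[0, 1] == pytest.approx(1.0)

    def test_negative_correlation_squares_to_quarter(self):
        # |-0.5|^2 = 0.25 regardless of sign (unsigned network)
        assert abs(-0.5) ** 2 == pytest.approx(0.25)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 30))
        b = synthdata.ExpressionBundle(
            matrix=pd.DataFrame(x, index=[f"g{i}" for i in range(4)],
                                columns=[f"s{i}" for i in range(30)]),
            samples=pd.DataFrame({"sample": [f"s{i}" for i in range(30)],
                                  "tissue": "t", "batch": "B1",
                                  "group": "disease", "subtype": "NA",
                                  "disease_activity": 0.0, "crp": 0.0}))
        a = coexpr.adjacency(b, beta=2)
        c = np.corrcoef(x)
        assert np.allclose(a, np.abs(c) ** 2)
        assert (a >= 0).all() and (a <= 1).all()


class TestTom:
    def test_three_gene_hand_example(self):
        a = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        w = coexpr.tom(a)
        # k = (0.7, 0.9, 0.6); w_12 = (0.2*0.4 + 0.5)/(0.7 + 1 - 0.5)
        assert w[0, 1] == pytest.approx(0.58 / 1.2)

    def test_block_diagonal_perfect_modules(self):
        a = np.zeros((6, 6))
        a[:3, :3] = 1.0
        a[3:, 3:] = 1.0
        w = coexpr.tom(a)
        assert np.allclose(w[:3, :3], 1.0)
        assert np.allclose(w[:3, 3:], 0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_and_stays_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        a = random_adjacency(rng, n)
        w = coexpr.tom(a)
        assert np.allclose(w, tom_oracle(a), atol=1e-10)
        assert (w >= 0).all() and (w <= 1).all()
        assert np.allclose(w, w.T)

    def test_gene_reordering_equivariance(self):
        rng = np.random.default_rng(5)
        a = random_adjacency(rng, 7)
        perm = rng.permutation(7)
        w = coexpr.tom(a)
        w_perm = coexpr.tom(a[np.ix_(perm, perm)])
        assert np.allclose(w_perm, w[np.ix_(perm, perm)], atol=1e-12)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            coexpr.tom(a)


class TestSoftThresholdScan:
    def test_single_power_scan(self, adjusted_bundles):
        scan = coexpr.soft_threshold_scan(adjusted_bundles[0], powers=[6])
        assert len(scan.table) == 1
        assert scan.table["power"].iloc[0] == 6

    def test_default_bundle_reaches_scale_free_criterion(self, adjusted_bundles):
        scan = coexpr.soft_threshold_scan(adjusted_bundles[0])
        assert scan.table["r2_signed"].max() >= 0.85

    def test_pure_noise_flags_criterion_unmet(self):
        sc = ExprScenario(n_genes=300, module_sizes=(), disease_shift=(),
                          seed=0)
        b = synthdata.gen_expression(sc)[0]
        scan = coexpr.soft_threshold_scan(b)
        assert not scan.criterion_met


class TestModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(0)
        n = 80
        w = np.abs(rng.normal(0, 0.002, size=(n, n)))
        w = (w + w.T) / 2
        w[:40, :40] += 0.6
        w[40:, 40:] += 0.6
        np.fill_diagonal(w, 1.0)
        mod = coexpr.detect_modules(w, min_module_size=10)
        labels = mod.to_numpy()
        assert len(set(labels) - {0}) == 2
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1

    def test_zero_tom_leaves_everything_unassigned(self):
        w = np.eye(50)
        mod = coexpr.detect_modules(w)
        assert (mod == 0).all()

    def test_blue_module_recovered_from_default_bundle(self, default_bundles,
                                                       adjusted_bundles):
        b = adjusted_bundles[0]
        a = coexpr.adjacency(b, 12)
        mod = coexpr.detect_modules(coexpr.tom(a), gene_ids=b.matrix.index)
        truth = default_bundles[0].truth["module_of"]
        blue_truth = truth == 1
        recalls = [((mod == lab) & blue_truth).sum() / blue_truth.sum()
                   for lab in set(mod) - {0}]
        assert max(recalls) >= 0.9


class TestEigengene:
    def test_identical_genes_give_their_profile(self, small_bundle):
        x = small_bundle.matrix.copy()
        profile = np.sin(np.arange(12))
        for g in x.index[:5]:
            x.loc[g] = profile
        bundle = synthdata.ExpressionBundle(matrix=x,
                                            samples=small_bundle.samples)
        modules = pd.Series([1] * 5 + [0] * 15, index=x.index)
        eg = coexpr.module_eigengene(bundle, modules).loc[1].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(eg, z)[0, 1]) > 1 - 1e-9

    def test_orientation_flips_with_member_values(self, small_bundle):
        modules = pd.Series([1] * 8 + [0] * 12, index=small_bundle.matrix.index)
        eg = coexpr.module_eigengene(small_bundle, modules).loc[1]
        flipped = synthdata.ExpressionBundle(matrix=-small_bundle.matrix,
                                             samples=small_bundle.samples)
        eg_f = coexpr.module_eigengene(flipped, modules).loc[1]
        assert np.allclose(eg.to_numpy(), -eg_f.to_numpy(), atol=1e-9)

    def test_planted_factor_recovered(self, default_bundles, adjusted_bundles):
        b = adjusted_bundles[0]
        truth = default_bundles[0].truth
        modules = truth["module_of"]
        eg = coexpr.module_eigengene(b, modules).loc[1].to_numpy()
        factor = truth["factors"][0]
        assert abs(np.corrcoef(eg, factor)[0, 1]) >= 0.9


class TestModuleTraitCor:
    def test_self_and_antimonotone_traits(self, small_bundle):
        modules = pd.Series([1] * 6 + [0] * 14, index=small_bundle.matrix.index)
        eg = coexpr.module_eigengene(small_bundle, modules)
        traits = pd.DataFrame({"self": eg.loc[1].to_numpy(),
                               "anti": -eg.loc[1].to_numpy()},
                              index=eg.columns)
        mt = coexpr.module_trait_cor(eg, traits)
        r_self = mt[(mt.module == 1) & (mt.trait == "self")]["r"].iloc[0]
        r_anti = mt[(mt.module == 1) & (mt.trait == "anti")]["r"].iloc[0]
        assert r_self == pytest.approx(1.0)
        assert r_anti == pytest.approx(-1.0)

    def test_blue_disease_activity_near_planted(self, default_bundles,
                                                adjusted_bundles):
        b = adjusted_bundles[0]
        modules = default_bundles[0].truth["module_of"]
        eg = coexpr.module_eigengene(b, modules)
        traits = b.samples.set_index("sample")[["disease_activity"]]
        mt = coexpr.module_trait_cor(eg, traits)
        r = mt[(mt.module == 1)]["r"].iloc[0]
        assert r == pytest.approx(0.92, abs=0.08)


class TestPreservation:
    def test_planted_module_strongly_preserved(self, adjusted_bundles,
                                               default_bundles):
        modules = default_bundles[0].truth["module_of"]
        pres = coexpr.module_preservation(adjusted_bundles[0],
                                          adjusted_bundles[1], modules,
                                          n_perm=50, seed=0)
        blue = pres[pres.module == 1]
        assert blue["zsummary"].iloc[0] > 10

    def test_random_gene_set_scores_near_zero(self, adjusted_bundles):
        rng = np.random.default_rng(0)
        genes = adjusted_bundles[0].matrix.index
        fake = pd.Series(0, index=genes)
        fake.iloc[rng.choice(len(genes), 100, replace=False)] = 1
        pres = coexpr.module_preservation(adjusted_bundles[0],
                                          adjusted_bundles[1], fake,
                                          n_perm=50, seed=1)
        assert abs(pres["zsummary"].iloc[0]) < 3

    def test_zsummary_is_mean_of_component_zs(self, adjusted_bundles,
                                              default_bundles):
        modules = default_bundles[0].truth["module_of"]
        pres = coexpr.module_preservation(adjusted_bundles[0],
                                          adjusted_bundles[1], modules,
                                          n_perm=30, seed=2)
        assert np.allclose(pres["zsummary"],
                           (pres["z_density"] + pres["z_connectivity"]) / 2)

    def test_missing_module_genes_rejected(self, adjusted_bundles,
                                           default_bundles):
        modules = default_bundles[0].truth["module_of"].copy()
        modules.index = [f"X{i}" for i in range(len(modules))]
        with pytest.raises(ValueError, match="absent"):
            coexpr.module_preservation(adjusted_bundles[0],
                                       adjusted_bundles[1], modules,
                                       n_perm=10)


def test_blue_membership_stable_across_powers(default_bundles,
                                              adjusted_bundles):
    """Module membership should barely move across nearby soft powers."""
    b = adjusted_bundles[0]
    truth_blue = default_bundles[0].truth["module_of"] == 1
    members = []
    for beta in (8, 10, 12, 14):
        mod = coexpr.detect_modules(coexpr.tom(coexpr.adjacency(b, beta)),
                                    gene_ids=b.matrix.index)
        overlaps = [(lab, ((mod == lab) & truth_blue).sum())
                    for lab in set(mod) - {0}]
        lab = max(overlaps, key=lambda t: t[1])[0]
        members.append(set(mod.index[mod == lab]))
    for other in members[1:]:
        inter = len(members[0] & other)
        overlap = inter / min(len(members[0]), len(other))
        assert overlap >= 0.95
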