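"""Combination methods against closed-form, exhaustive and hand oracles,
plus the structural identities and direction-concordance guarantees."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from omnimeta import meta
from omnimeta.meta import (
    EffectSizeMatrix,
    MetaResult,
    PValueMatrix,
    combine_effects,
    combine_pvalues,
    combine_ranks,
    compare_signatures,
    consensus_signature,
    estimate_fdr,
    method_concordance,
    rop_default_r,
)


def pmat(p, direction=None):
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if direction is None:
        direction = np.ones_like(p, dtype=int)
    else:
        direction = np.atleast_2d(np.asarray(direction, dtype=int))
    genes = [f"g{i}" for i in range(p.shape[0])]
    cols = [f"S{k}" for k in range(p.shape[1])]
    return PValueMatrix(p=pd.DataFrame(p, index=genes, columns=cols),
                        direction=pd.DataFrame(direction, index=genes,
                                               columns=cols))


class TestClosedFormOracles:
    def test_fisher_two_studies(self):
        res = combine_pvalues(pmat([[0.05, 0.05]]), "fisher")
        assert res.table["statistic"].iloc[0] == pytest.approx(11.9829, abs=1e-4)
        assert res.table["p_meta"].iloc[0] == pytest.approx(
            stats.chi2.sf(11.982929, 4), abs=1e-6)

    def test_stouffer_all_half(self):
        res = combine_pvalues(pmat([[0.5, 0.5, 0.5]]), "stouffer")
        assert res.table["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.table["p_meta"].iloc[0] == pytest.approx(0.5)

    def test_maxp_beta_cdf(self):
        res = combine_pvalues(pmat([[0.2, 0.5]]), "maxp")
        assert res.table["p_meta"].iloc[0] == pytest.approx(0.25)

    def test_rop_beta_cdf(self):
        res = combine_pvalues(pmat([[0.1, 0.2, 0.9]]), "rop", r=2)
        assert res.table["p_meta"].iloc[0] == pytest.approx(0.104, abs=1e-9)

    def test_rop_requires_valid_r(self):
        with pytest.raises(ValueError):
            combine_pvalues(pmat([[0.1, 0.2]]), "rop")
        with pytest.raises(ValueError):
            combine_pvalues(pmat([[0.1, 0.2]]), "rop", r=3)


def test_rop_with_r_equal_K_is_maxp():
    rng = np.random.default_rng(0)
    P = pmat(rng.uniform(size=(500, 5)),
             rng.choice([-1, 1], size=(500, 5)))
    a = combine_pvalues(P, "rop", r=5).table["p_meta"].values
    b = combine_pvalues(P, "maxp").table["p_meta"].values
    assert np.array_equal(a, b)


def test_oc_concordant_beats_discordant():
    conc = combine_pvalues(pmat([[0.01, 0.01]], [[1, 1]]), "fisher",
                           one_sided_correction=True)
    disc = combine_pvalues(pmat([[0.01, 0.01]], [[1, -1]]), "fisher",
                           one_sided_correction=True)
    assert conc.table["p_meta"].iloc[0] < disc.table["p_meta"].iloc[0]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    p=st.lists(st.floats(0.001, 0.999), min_size=2, max_size=6),
    method=st.sampled_from(["fisher", "stouffer", "maxp", "rop"]),
    data=st.data(),
)
def test_oc_direction_guarantee(p, method, data):
    """Identical p magnitudes with uniform direction never score worse
    than the same magnitudes with mixed directions."""
    K = len(p)
    r = data.draw(st.integers(1, K)) if method == "rop" else None
    mixed = data.draw(st.lists(st.sampled_from([-1, 1]), min_size=K,
                               max_size=K))
    if len(set(mixed)) < 2:
        mixed[0] = -mixed[1]
    conc = combine_pvalues(pmat([p], [[1] * K]), method, r=r,
                           one_sided_correction=True)
    disc = combine_pvalues(pmat([p], [mixed]), method, r=r,
                           one_sided_correction=True)
    assert conc.table["p_meta"].iloc[0] <= disc.table["p_meta"].iloc[0] + 1e-12


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_monotonicity_in_single_pvalue(data):
    """Decreasing any one study p never increases the combined p."""
    K = data.draw(st.integers(2, 5))
    p = np.array(data.draw(st.lists(st.floats(0.01, 0.99), min_size=K,
                                    max_size=K)))
    k = data.draw(st.integers(0, K - 1))
    p2 = p.copy()
    p2[k] = p[k] * data.draw(st.floats(0.05, 0.95))
    for method, r in (("fisher", None), ("stouffer", None),
                      ("rop", data.draw(st.integers(1, K)))):
        a = combine_pvalues(pmat([p]), method, r=r).table["p_meta"].iloc[0]
        b = combine_pvalues(pmat([p2]), method, r=r).table["p_meta"].iloc[0]
        assert b <= a + 1e-12


class TestRankCombination:
    def test_top_ranked_gene_attains_minimum(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 1, size=(20, 3))
        p[0] = 1e-6  # rank 1 everywhere
        P = pmat(p)
        for method in ("pr", "sr"):
            res = combine_ranks(P, method, B_null=10, seed=0)
            assert res.table["statistic"].idxmin() == "g0"

    def test_exact_null_matches_bruteforce_enumeration(self):
        p = np.array([[0.1, 0.5], [0.4, 0.2], [0.9, 0.8]])
        P = pmat(p)
        res = combine_ranks(P, "sr", B_null="exact")
        ranks = np.column_stack([stats.rankdata(p[:, k]) for k in range(2)])
        obs = ranks.sum(axis=1)
        null = []
        for pa in itertools.permutations([1, 2, 3]):
            for pb in itertools.permutations([1, 2, 3]):
                null.extend(np.array(pa) + np.array(pb))
        null = np.sort(null)
        for gi in range(3):
            expected = (null <= obs[gi]).mean()
            assert res.table["p_meta"].iloc[gi] == pytest.approx(expected)

    def test_pr_and_sr_identical_ordering_for_single_study(self):
        rng = np.random.default_rng(2)
        P = pmat(rng.uniform(size=(30, 1)))
        a = combine_ranks(P, "pr", B_null=20, seed=1).table["statistic"]
        b = combine_ranks(P, "sr", B_null=20, seed=1).table["statistic"]
        assert list(a.sort_values().index) == list(b.sort_values().index)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError, match="genes"):
            combine_ranks(pmat([[0.5, 0.5]]), "pr")


class TestEffectCombination:
    def test_fem_hand_arithmetic(self):
        E = EffectSizeMatrix(
            g=pd.DataFrame([[0.0, 2.0]], index=["g0"], columns=["a", "b"]),
            v=pd.DataFrame([[1.0, 1.0]], index=["g0"], columns=["a", "b"]))
        res = combine_effects(E, "fem")
        assert res.table["mu_hat"].iloc[0] == pytest.approx(1.0)
        assert res.table["se"].iloc[0] == pytest.approx(math.sqrt(0.5))
        assert res.table["z"].iloc[0] == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_rem_dersimonian_laird_hand_arithmetic(self):
        E = EffectSizeMatrix(
            g=pd.DataFrame([[0.0, 2.0]], index=["g0"], columns=["a", "b"]),
            v=pd.DataFrame([[1.0, 1.0]], index=["g0"], columns=["a", "b"]))
        res = combine_effects(E, "rem")
        row = res.table.iloc[0]
        assert row["tau2_hat"] == pytest.approx(1.0)
        assert row["mu_hat"] == pytest.approx(1.0)
        assert row["se"] == pytest.approx(1.0)
        assert row["z"] == pytest.approx(1.0)

    def test_rem_equals_fem_when_homogeneous(self):
        rng = np.random.default_rng(3)
        K, G = 4, 50
        v = rng.uniform(0.04, 0.06, size=(G, K))
        g = np.full((G, K), 0.5) + rng.normal(0, 0.001, size=(G, K))
        E = EffectSizeMatrix(
            g=pd.DataFrame(g, columns=[f"S{k}" for k in range(K)]),
            v=pd.DataFrame(v, columns=[f"S{k}" for k in range(K)]))
        rem = combine_effects(E, "rem")
        fem = combine_effects(E, "fem")
        clamped = rem.table["tau2_hat"] == 0
        assert clamped.mean() > 0.9
        assert np.allclose(rem.table.loc[clamped, "mu_hat"],
                           fem.table.loc[clamped, "mu_hat"])
        assert np.allclose(rem.table.loc[clamped, "se"],
                           fem.table.loc[clamped, "se"])

    def test_tau2_recovery(self):
        """DL estimate recovers the true between-study variance on average
        (200 replicates, K=50, v=0.04, tau2=0.25)."""
        rng = np.random.default_rng(4)
        K, R, tau2 = 50, 200, 0.25
        g = rng.normal(0, math.sqrt(0.04 + tau2), size=(R, K))
        E = EffectSizeMatrix(
            g=pd.DataFrame(g, columns=[f"S{k}" for k in range(K)]),
            v=pd.DataFrame(np.full((R, K), 0.04),
                           columns=[f"S{k}" for k in range(K)]))
        est = combine_effects(E, "rem").table["tau2_hat"].mean()
        assert abs(est - tau2) <= 0.2 * tau2

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            EffectSizeMatrix(
                g=pd.DataFrame([[0.0, 1.0]], columns=["a", "b"]),
                v=pd.DataFrame([[1.0, 0.0]], columns=["a", "b"]))


class TestFDR:
    def _result(self, p):
        genes = [f"g{i}" for i in range(len(p))]
        tab = pd.DataFrame({"statistic": p, "p_meta": p,
                            "direction": 1, "z": 0.0}, index=genes)
        return MetaResult(method="fisher", hs="HS_B", table=tab)

    def test_bh_step_up_hand_calculation(self):
        res = estimate_fdr(self._result([0.01, 0.02, 0.03, 0.04]), "bh")
        assert np.allclose(res.table["q"], 0.04)

    def test_all_ones_stay_one(self):
        res = estimate_fdr(self._result([1.0, 1.0, 1.0]), "bh")
        assert (res.table["q"] == 1.0).all()

    def test_permutation_fdr_near_one_on_null(self):
        rng = np.random.default_rng(5)
        obs = rng.uniform(size=500)
        null = rng.uniform(size=(20, 500))
        res = estimate_fdr(self._result(obs), "permutation", null_p=null)
        assert res.table["q"].median() > 0.8
        q_sorted = res.table.sort_values("p_meta")["q"].values
        assert (np.diff(q_sorted) >= -1e-12).all()

    def test_permutation_fdr_requires_null(self):
        with pytest.raises(ValueError, match="null"):
            estimate_fdr(self._result([0.1]), "permutation")


class TestConsensus:
    def _result(self, method, q, direction):
        genes = [f"g{i}" for i in range(len(q))]
        tab = pd.DataFrame({
            "statistic": 0.0, "p_meta": q, "direction": direction,
            "z": np.asarray(direction) * 2.0, "q": q,
        }, index=genes)
        return MetaResult(method=method, hs="", table=tab)

    def test_gene_significant_in_one_method_only_excluded(self):
        a = self._result("rop.oc", [0.01, 0.5], [1, 1])
        b = self._result("rem", [0.01, 0.01], [1, 1])
        sig = consensus_signature([a, b], fdr=0.05)
        assert sig.up == ["g0"] and sig.down == []

    def test_concordant_up_gene_lands_in_up_list(self):
        a = self._result("rop.oc", [0.01], [1])
        b = self._result("rem", [0.01], [1])
        sig = consensus_signature([a, b])
        assert sig.up == ["g0"]

    def test_direction_conflict_drops_gene(self):
        a = self._result("rop.oc", [0.001], [1])
        b = self._result("rem", [0.001], [-1])
        sig = consensus_signature([a, b])
        assert sig.up == [] and sig.down == []
        assert sig.provenance["direction_conflicts"] == 1

    def test_z_taken_from_effect_size_result(self):
        a = self._result("rop.oc", [0.01], [1])
        b = self._result("rem", [0.01], [1])
        b.table["z"] = 7.7
        sig = consensus_signature([a, b])
        assert sig.z.iloc[0] == 7.7


class TestConcordanceAndSignatures:
    def test_self_concordance_is_one(self):
        rng = np.random.default_rng(6)
        P = pmat(rng.uniform(size=(100, 3)))
        res = combine_pvalues(P, "fisher")
        mat = method_concordance([res, res])
        assert mat.values == pytest.approx(np.ones((2, 2)))

    def test_rop_K_vs_maxp_is_unit_correlation(self):
        rng = np.random.default_rng(7)
        P = pmat(rng.uniform(size=(200, 4)))
        mat = method_concordance([
            combine_pvalues(P, "rop", r=4), combine_pvalues(P, "maxp")])
        assert mat.iloc[0, 1] == pytest.approx(1.0)

    def test_requires_two_methods(self):
        P = pmat(np.random.default_rng(8).uniform(size=(10, 2)))
        with pytest.raises(ValueError):
            method_concordance([combine_pvalues(P, "fisher")])

    def test_compare_signatures_trivial_cases(self):
        z = pd.Series([1.0, -2.0, 3.0, 0.5], index=list("abcd"))
        assert compare_signatures(z, z) == pytest.approx(1.0)
        assert compare_signatures(z, -z) == pytest.approx(-1.0)

    def test_compare_signatures_needs_shared_genes(self):
        z1 = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        z2 = pd.Series([1.0, 2.0, 3.0], index=list("xyz"))
        with pytest.raises(ValueError, match="shared"):
            compare_signatures(z1, z2)


def test_rop_default_r_is_seventy_percent_rule():
    assert rop_default_r(10) == 7
    assert rop_default_r(5) == 4  # ceil(3.5)
    assert rop_default_r(1) == 1


def test_split_panel_signatures_positively_correlated():
    """Two meta-analyses of disjoint study panels drawn from one truth
    produce positively correlated signed scores."""
    from omnimeta.datatypes import StudyCollection, SyntheticConfig
    from omnimeta.de_stats import analyze_study
    from omnimeta.syndata import generate_collection

    coll, truth = generate_collection(SyntheticConfig(
        K=8, G=400, n_case=10, n_control=10, pi_de=0.2, scenario="HS_A",
        mu=0.8, tau2=0.05, seed=61))
    halves = [StudyCollection(coll.studies[:4]),
              StudyCollection(coll.studies[4:])]
    zs = []
    for half in halves:
        des = [analyze_study(s, B=60, seed=6) for s in half]
        E = EffectSizeMatrix.from_per_study(des)
        zs.append(combine_effects(E, "rem").table["z"])
    rho = compare_signatures(zs[0], zs[1])
    n = len(zs[0])
    p = stats.norm.sf(rho * math.sqrt(n - 3))  # Fisher z approximation
    assert rho > 0 and p < 0.01
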