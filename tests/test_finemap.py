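"""Fine-mapping engines, selection rules, the CCV union, and conditional
association, checked against closed forms and brute-force enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locusdissect.finemap import (
    ABFPrior,
    CredibleSet,
    FineMapResult,
    LDMatrix,
    SummaryStats,
    conditional_z,
    ld_supplement,
    llr_select,
    retain_credible_sets,
    single_effect_finemap,
    susie_rss,
    union_ccv,
    wakefield_log_abf,
)
from locusdissect.simulate import LocusSpec, make_ld, simulate_locus


def _stats(z, n=10_000):
    return SummaryStats(ids=[f"rs{i+1}" for i in range(len(z))], z=np.asarray(z, float), n=n)


class TestWakefieldAbf:
    def test_null_z_shrinks_toward_h0(self):
        prior = ABFPrior(W=0.04, V=0.01)
        assert wakefield_log_abf(0.0, prior) == pytest.approx(
            0.5 * np.log(0.01 / 0.05)
        )
        assert wakefield_log_abf(0.0, prior) < 0

    def test_degenerate_prior_limit(self):
        assert wakefield_log_abf(3.0, ABFPrior(W=1e-12, V=1.0)) == pytest.approx(
            0.0, abs=1e-5
        )

    def test_closed_form_value(self):
        # 0.5*log(0.01/0.05) + 0.5*25*0.04/0.05, evaluated independently
        assert wakefield_log_abf(5.0, ABFPrior(W=0.04, V=0.01)) == pytest.approx(
            9.19528104378295, abs=1e-12
        )

    def test_monotone_in_abs_z(self):
        prior = ABFPrior(W=0.1, V=0.5)
        vals = wakefield_log_abf(np.array([0.0, -1.0, 2.0, -3.5, 6.0]), prior)
        assert list(np.argsort(vals)) == [0, 1, 2, 3, 4]

    @pytest.mark.parametrize("W,V", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_invalid_prior_rejected(self, W, V):
        with pytest.raises(ValueError):
            ABFPrior(W=W, V=V)


class TestSingleEffect:
    def test_symmetric_pair(self):
        res = single_effect_finemap(_stats([3.0, -3.0]))
        np.testing.assert_allclose(res.pip, [0.5, 0.5])

    def test_single_variant_pip_one(self):
        res = single_effect_finemap(_stats([2.0]))
        assert res.pip[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 3, 10)
        prior = ABFPrior(W=0.0225, V=1e-4)
        res = single_effect_finemap(_stats(z), prior)
        # brute force over the 10 single-causal models
        abf = np.exp([wakefield_log_abf(zi, prior) for zi in z])
        np.testing.assert_allclose(res.pip, abf / abf.sum(), atol=1e-12)


class TestSusieRss:
    def test_l1_equals_single_effect(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 2, 25)
        stats = _stats(z)
        ld = make_ld(LocusSpec(n_variants=25, block_sizes=[25], rho=0.6))
        W = 0.0225 * stats.n
        res = susie_rss(
            stats, ld, L=1, prior_variance=W, estimate_prior_variance=False
        )
        ref = single_effect_finemap(stats, ABFPrior(W=W, V=1.0))
        assert np.max(np.abs(res.pip - ref.pip)) < 1e-6

    def test_null_z_uniform_alpha_fixed_prior(self):
        m, L = 20, 5
        stats = _stats(np.zeros(m))
        ld = make_ld(LocusSpec(n_variants=m, block_sizes=[m], rho=0.5))
        res = susie_rss(
            stats, ld, L=L, prior_variance=10.0, estimate_prior_variance=False
        )
        np.testing.assert_allclose(res.alpha, 1.0 / m, atol=1e-12)
        np.testing.assert_allclose(res.pip, 1 - (1 - 1 / m) ** L, atol=1e-12)

    def test_null_z_eb_switches_effects_off(self):
        stats = _stats(np.zeros(30))
        ld = make_ld(LocusSpec(n_variants=30, block_sizes=[30], rho=0.5))
        res = susie_rss(stats, ld, L=5)
        assert np.all(res.prior_variance < 1e-9)
        assert res.credible_sets == []

    def test_two_separated_causals_recovered(self):
        hits = 0
        for seed in range(10):
            spec = LocusSpec(
                n_variants=200,
                block_sizes=[200],
                rho=0.95,
                causal_effects={"g": [(50, 11 / np.sqrt(50_000)), (150, 11 / np.sqrt(50_000))]},
                sample_sizes={"g": 50_000},
                seed=seed,
            )
            locus = simulate_locus(spec)
            res = retain_credible_sets(susie_rss(locus.stats("g"), locus.ld, L=5))
            found = set()
            for cs in res.credible_sets:
                found |= {locus.ld.ids.index(v) for v in cs.variants} & {50, 150}
            hits += found == {50, 150}
        assert hits >= 8

    def test_alpha_rows_sum_to_one_and_elbo_monotone(self, shared_causal_locus):
        res = susie_rss(shared_causal_locus.stats("gwas"), shared_causal_locus.ld)
        np.testing.assert_allclose(res.alpha.sum(axis=1), 1.0, atol=1e-10)
        elbo = np.array(res.elbo)
        assert np.all(np.diff(elbo) >= -1e-6 * (1 + np.abs(elbo[:-1])))
        assert res.converged

    def test_non_psd_ld_regularized_with_warning(self):
        R = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
        ld = LDMatrix(ids=["rs1", "rs2", "rs3"], R=R)
        stats = _stats([1.0, 2.0, 0.5])
        with pytest.warns(UserWarning, match="not PSD"):
            susie_rss(stats, ld, L=1)
        with pytest.raises(ValueError, match="not PSD"):
            susie_rss(stats, ld, L=1, reject_non_psd=True)


class TestLlrSelect:
    def test_lead_always_retained(self):
        sel = llr_select(_stats([1.0, 6.0, 0.2]), "rs2")
        assert "rs2" in sel

    def test_equal_z_retained(self):
        sel = llr_select(_stats([6.0, -6.0]), "rs1")
        assert sel == {"rs1", "rs2"}

    def test_closed_form_boundary(self):
        # |z| boundary at sqrt(z_lead^2 - 2 ln ratio) = 4.7100 for z_lead = 6
        sel = llr_select(_stats([6.0, 4.72, 4.70]), "rs1", ratio=1000)
        assert sel == {"rs1", "rs2"}

    def test_missing_lead_named_in_error(self):
        with pytest.raises(KeyError, match="rs99"):
            llr_select(_stats([1.0]), "rs99")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        z=st.lists(st.floats(-8, 8), min_size=2, max_size=12),
        r1=st.floats(10, 500),
        r2=st.floats(501, 5_000),
    )
    def test_monotone_in_ratio(self, z, r1, r2):
        stats = _stats(z)
        assert llr_select(stats, "rs1", r1) <= llr_select(stats, "rs1", r2)


class TestLdSupplement:
    def test_strict_threshold(self):
        out = ld_supplement("lead", {"a": 0.8, "b": 0.81}, stats_ids=set())
        assert out == {"b"}

    def test_already_assessed_excluded(self):
        out = ld_supplement("lead", {"a": 0.95}, stats_ids={"a"})
        assert out == set()

    def test_empty_proxy_table(self):
        assert ld_supplement("lead", {}, stats_ids={"a"}) == set()


def _result_with_sets(pips, sets):
    m = len(pips)
    ids = [f"rs{i+1}" for i in range(m)]
    alpha = np.full((max(1, len(sets)), m), 1.0 / m)
    cs = []
    for l, (members, alphas) in enumerate(sets):
        row = np.zeros(m)
        row[members] = alphas
        rest = np.setdiff1d(np.arange(m), members)
        if rest.size:
            row[rest] = (1 - row.sum()) / rest.size
        else:
            row /= row.sum()
        alpha[l] = row
        cs.append(
            CredibleSet(
                effect=l,
                variants=[ids[i] for i in members],
                alpha=np.asarray(alphas, float),
                cum_alpha=float(np.sum(alphas)),
                purity=1.0,
            )
        )
    return FineMapResult(
        method="x",
        ids=ids,
        pip=np.asarray(pips, float),
        alpha=alpha,
        lbf=np.zeros_like(alpha),
        prior_variance=np.ones(alpha.shape[0]),
        credible_sets=cs,
    )


class TestRetention:
    def test_low_cumulative_set_dropped(self):
        res = _result_with_sets([0.5, 0.34, 0.1], [([0, 1], [0.5, 0.34])])
        assert retain_credible_sets(res).credible_sets == []

    def test_low_pip_member_removed(self):
        res = _result_with_sets([0.9, 0.004, 0.05], [([0, 1], [0.9, 0.08])])
        kept = retain_credible_sets(res).credible_sets
        assert len(kept) == 1 and kept[0].variants == ["rs1"]

    def test_clean_set_unchanged(self):
        res = _result_with_sets([0.01] * 10, [(list(range(10)), [0.099] * 10)])
        kept = retain_credible_sets(res).credible_sets
        assert kept[0].variants == [f"rs{i+1}" for i in range(10)]


class TestUnionCcv:
    def _res(self, members):
        return _result_with_sets(
            [0.2] * 5, [(members, [0.9 / len(members)] * len(members))]
        )

    def test_idempotent_over_identical_sources(self):
        res = self._res([0, 1])
        ccv = union_ccv([res, res, res], None, None, lead_id="rs1")
        assert set(ccv.ids) == {"rs1", "rs2"}

    def test_disjoint_union_with_flags(self):
        ccv = union_ccv([self._res([0, 1])], None, {"rs9"}, lead_id="rs1")
        assert set(ccv.ids) == {"rs1", "rs2", "rs9"}
        assert "ld_proxy" in ccv.provenance["rs9"]
        assert "bayesian" in ccv.provenance["rs1"]

    def test_order_invariant(self):
        a, b = self._res([0, 1]), self._res([2, 3])
        u1 = union_ccv([a, b], {"rs5"}, None, "rs1")
        u2 = union_ccv([b, a], {"rs5"}, None, "rs1")
        assert u1.ids == u2.ids and u1.provenance == u2.provenance

    def test_all_sources_empty_rejected(self):
        with pytest.raises(ValueError):
            union_ccv([], set(), set(), "rs1")


class TestConditionalZ:
    def test_orthogonal_variant_unchanged(self):
        stats = _stats([2.0, 5.0, 1.0])
        ld = LDMatrix(ids=stats.ids, R=np.eye(3))
        res = conditional_z(stats, ld, ["rs2"])
        assert res.ids == ["rs1", "rs3"]
        np.testing.assert_allclose(res.z, [2.0, 1.0], atol=1e-9)

    def test_empty_conditioning_is_identity(self):
        stats = _stats([2.0, -1.0])
        ld = LDMatrix(ids=stats.ids, R=np.array([[1.0, 0.5], [0.5, 1.0]]))
        res = conditional_z(stats, ld, [])
        np.testing.assert_array_equal(res.z, stats.z)
        assert res.ids == stats.ids

    def test_collinear_variant_flagged(self):
        R = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        stats = _stats([4.0, 4.0, 1.0])
        ld = LDMatrix(ids=stats.ids, R=R)
        res = conditional_z(stats, ld, ["rs1"], ridge=0.0)
        assert res.collinear == ["rs2"]
        assert res.ids == ["rs3"]

    def test_conditioning_on_causal_removes_signal(self, shared_causal_locus):
        stats = shared_causal_locus.stats("gwas")
        causal = stats.ids[50]
        res = conditional_z(stats, shared_causal_locus.ld, [causal])
        assert np.max(np.abs(res.z)) < 5.45
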