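"""Mutation-model classification, expression association against the pooled
t-statistic, Firth-Cox against lifelines, and the weighted z meta-analysis."""

import numpy as np
import pandas as pd
import pytest

from locusdissect.simulate import CohortSpec, make_cohort
from locusdissect.tumor import (
    Cohort,
    classify_sample,
    dichotomize,
    expr_association,
    filter_stage,
    firth_cox,
    meta,
    model_spec,
    run_cohort_panel,
)


class TestClassify:
    def test_braf_v600e_mutant_under_all_models(self):
        muts = [("BRAF", "V600E", True)]
        for k in range(1, 6):
            assert classify_sample(muts, model_spec(k)) == "mutant"

    def test_non_hotspot_driver_wt_model1_mutant_model2(self):
        muts = [("BRAF", "D594N", True)]
        assert classify_sample(muts, model_spec(1)) == "WT"
        assert classify_sample(muts, model_spec(2)) == "mutant"

    def test_no_mutations_wild_type(self):
        for k in range(1, 6):
            assert classify_sample([], model_spec(k)) == "WT"

    def test_hotspot_position_matching_any_alt(self):
        # notation V600|K601, Q61|G12|G13 matches by codon, not alt residue
        assert classify_sample([("BRAF", "V600K", False)], model_spec(1)) == "mutant"
        assert classify_sample([("NRAS", "G13R", False)], model_spec(1)) == "mutant"
        assert classify_sample([("NRAS", "A146T", True)], model_spec(1)) == "WT"

    def test_unparseable_protein_change_warns(self):
        with pytest.warns(UserWarning, match="unparseable"):
            out = classify_sample([("BRAF", "splice?", False)], model_spec(1))
        assert out == "WT"

    def test_assessed_gene_restriction(self):
        muts = [("NF1", "R100*", True)]
        m4 = model_spec(4, assessed_genes=frozenset({"BRAF", "NRAS"}))
        assert classify_sample(muts, m4) == "WT"
        assert classify_sample(muts, model_spec(4)) == "mutant"

    def test_model_nesting_fuzz(self):
        rng = np.random.default_rng(0)
        genes = ["BRAF", "NRAS", "KRAS", "HRAS", "NF1", "MAP2K1", "TP53"]
        hotspot_changes = {
            "BRAF": ["V600E", "K601E", "D594N"],
            "NRAS": ["Q61R", "G12D", "G13C", "A146T"],
        }
        models = [model_spec(k) for k in range(1, 6)]
        for _ in range(1_000):
            muts = []
            for g in genes:
                if rng.random() < 0.2:
                    change = rng.choice(hotspot_changes.get(g, [f"X{rng.integers(1, 900)}Y"]))
                    muts.append((g, str(change), True))
            labels = [classify_sample(muts, m) for m in models]
            for k in range(4):
                assert not (labels[k] == "mutant" and labels[k + 1] == "WT")


class TestExprAssociation:
    def _cohort(self, delta=0.0, n=400, seed=0):
        return make_cohort(
            CohortSpec(
                n_samples=n,
                mutation_rates={("BRAF", "V600E", True): 0.45},
                delta=delta,
                seed=seed,
            )
        )

    def test_no_covariates_equals_pooled_t(self):
        cohort = self._cohort(delta=0.5)
        res = expr_association(cohort, model_spec(1), covariates=())
        wt = cohort.classify(model_spec(1)) == "WT"
        x = cohort.samples.loc[wt, "expression"].to_numpy()
        y = cohort.samples.loc[~wt, "expression"].to_numpy()
        # pooled-variance two-sample t computed independently
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert res.z == pytest.approx(t, abs=1e-8)

    def test_positive_beta_when_wt_higher(self):
        res = expr_association(self._cohort(delta=1.0), model_spec(1))
        assert res.beta > 0 and res.p < 0.01

    def test_null_calibration(self):
        rej = 0
        for seed in range(100):
            res = expr_association(
                self._cohort(delta=0.0, n=300, seed=seed), model_spec(1)
            )
            rej += res.p < 0.05
        assert rej <= 12  # ~5% expected

    def test_empty_group_named_error(self):
        cohort = make_cohort(CohortSpec(n_samples=50, seed=1), name="leeds")
        with pytest.raises(ValueError, match="leeds"):
            expr_association(cohort, model_spec(1))

    def test_fully_missing_covariate_dropped(self):
        cohort = self._cohort(delta=0.5)
        cohort.samples["purity"] = np.nan
        res = expr_association(cohort, model_spec(1))
        assert "purity" not in res.covariates


class TestDichotomize:
    def test_even_split(self):
        high = dichotomize(np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(high, [False, False, True, True])

    def test_value_at_median_goes_low(self):
        high = dichotomize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(high, [False, False, True])

    def test_all_equal_warns(self):
        with pytest.warns(UserWarning, match="median"):
            high = dichotomize(np.ones(5))
        assert not high.any()

    @pytest.mark.parametrize("n", [5, 9, 13])
    def test_odd_distinct_split_sizes(self, n):
        rng = np.random.default_rng(n)
        high = dichotomize(rng.permutation(np.arange(n, dtype=float)))
        assert high.sum() == n // 2


class TestFilterStage:
    def _cohort(self, stages):
        samples = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(len(stages))],
                "expression": np.arange(len(stages), dtype=float),
                "stage": stages,
            }
        )
        muts = pd.DataFrame(columns=["sample", "gene", "protein_change", "driver"])
        return Cohort("c", samples, muts)

    def test_stage_one_excluded_missing_kept(self):
        out = filter_stage(self._cohort(["I", "II", "III", None]))
        assert len(out.samples) == 3

    def test_empty_exclusion_identity(self):
        c = self._cohort(["I", "II"])
        assert len(filter_stage(c, set()).samples) == 2

    def test_all_stage_one_warns_empty(self):
        with pytest.warns(UserWarning, match="removed"):
            out = filter_stage(self._cohort(["I", "I"]))
        assert len(out.samples) == 0


class TestFirthCox:
    def _survival_data(self, n=600, log_hr=0.5, seed=0):
        rng = np.random.default_rng(seed)
        group = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0 / (0.001 * np.exp(log_hr * group)))
        c = rng.exponential(2_000, n)
        return np.minimum(t, c), (t <= c).astype(int), group

    def test_matches_lifelines_without_separation(self):
        from lifelines import CoxPHFitter

        time, event, group = self._survival_data()
        res = firth_cox(time, event, group)
        df = pd.DataFrame({"t": time, "e": event, "g": group})
        ll = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        ref = float(ll.params_["g"])
        assert res.log_hr == pytest.approx(ref, rel=0.02)

    def test_finite_under_complete_separation(self):
        rng = np.random.default_rng(1)
        t = np.concatenate([rng.exponential(100, 25), rng.exponential(100, 25) + 2_000])
        e = np.ones(50)
        g = np.concatenate([np.ones(25), np.zeros(25)])
        res = firth_cox(t, e, g)
        assert np.isfinite(res.log_hr) and abs(res.log_hr) < 15
        unpen = firth_cox(t, e, g, firth=False)
        assert abs(unpen.log_hr) > 10  # monotone likelihood drifts to infinity

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            firth_cox([1.0, 2.0], [0, 0], [0.0, 1.0])

    def test_with_covariate(self):
        rng = np.random.default_rng(2)
        time, event, group = self._survival_data(seed=2)
        cov = rng.normal(60, 10, len(time))
        res = firth_cox(time, event, group, covariates=cov)
        assert np.isfinite(res.log_hr) and res.se > 0

    def test_efron_handles_ties(self):
        time = np.array([5.0, 5.0, 5.0, 8.0, 8.0, 12.0, 15.0, 20.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        group = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        res = firth_cox(time, event, group)
        assert np.isfinite(res.log_hr)


class TestMeta:
    def test_single_cohort_passthrough(self):
        res = meta([2.5], [40], [60])
        assert res.z_meta == pytest.approx(2.5)

    def test_antisymmetric_cancellation(self):
        res = meta([1.0, -1.0], [50, 50], [50, 50])
        assert res.z_meta == pytest.approx(0.0, abs=1e-12)

    def test_weights_normalized_and_order_invariant(self):
        z = [1.2, -0.5, 2.0]
        np_, nm = [30, 80, 50], [70, 20, 50]
        a = meta(z, np_, nm)
        b = meta(z[::-1], np_[::-1], nm[::-1])
        assert np.sum(a.weights**2) == pytest.approx(1.0, abs=1e-12)
        assert a.z_meta == pytest.approx(b.z_meta, abs=1e-12)

    def test_invalid_group_sizes(self):
        with pytest.raises(ValueError):
            meta([1.0], [0], [10])


class TestCohortPanel:
    def _cohorts(self, delta, log_hr, n_list=(250, 200, 150), treatment="non-immunotherapy"):
        rates = {("BRAF", "V600E", True): 0.4, ("NRAS", "Q61R", True): 0.15}
        return [
            make_cohort(
                CohortSpec(
                    n_samples=n,
                    mutation_rates=rates,
                    delta=delta,
                    log_hr_high_expr=log_hr,
                    treatment_class=treatment,
                    seed=i,
                ),
                name=f"c{i}",
            )
            for i, n in enumerate(n_list)
        ]

    def test_planted_shift_without_hazard(self):
        cohorts = self._cohorts(delta=0.8, log_hr=0.0)
        expr = run_cohort_panel(cohorts, model_spec(1), "expression")
        surv = run_cohort_panel(cohorts, model_spec(1), "survival")
        (m_expr,) = expr.meta.values()
        (m_surv,) = surv.meta.values()
        assert m_expr.p < 1e-4 and m_expr.z_meta > 0
        assert m_surv.p > 0.05

    def test_single_cohort_survival_meta_is_cohort_z(self):
        cohorts = self._cohorts(delta=0.0, log_hr=0.4, n_list=(300,))
        panel = run_cohort_panel(cohorts, model_spec(1), "survival")
        (m,) = panel.meta.values()
        (results,) = panel.per_cohort.values()
        assert m.z_meta == pytest.approx(results[0].z)

    def test_treatment_stratification(self):
        cohorts = self._cohorts(0.5, 0.0) + self._cohorts(
            0.5, 0.0, n_list=(150,), treatment="immunotherapy"
        )
        panel = run_cohort_panel(cohorts, model_spec(1), "expression")
        assert set(panel.meta) == {"non-immunotherapy", "immunotherapy"}

    def test_no_cohorts_rejected(self):
        with pytest.raises(ValueError):
            run_cohort_panel([], model_spec(1))
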