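"""Cohort generation contracts, dose-adjustment rules, safety invariants
and the multi-output recommender."""

import numpy as np
import pandas as pd
import pytest

from pulmodx import prescribe as P


@pytest.fixture(scope="module")
def formulary():
    return P.load_formulary()


class TestGenerateCohort:
    def test_default_size_and_comorbidity_quota(self, default_cohort_run):
        df = default_cohort_run["cohort"]
        assert len(df) == 2000
        comorbid = (df["renal_impaired"] | df["hepatic_impaired"]).sum()
        # quota sampling: exactly round(2000 x 0.15)
        assert comorbid == 300

    def test_seeded_determinism(self):
        a = P.generate_cohort(P.CohortConfig(n=50, seed=9))
        b = P.generate_cohort(P.CohortConfig(n=50, seed=9))
        assert all(ra == rb for ra, rb in zip(a, b))

    def test_renal_flag_matches_egfr(self):
        for rec in P.generate_cohort(P.CohortConfig(n=300, seed=2)):
            assert rec.renal_impaired == (rec.eGFR < 60.0)
            assert 1 <= rec.age <= 95

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            P.CohortConfig(prevalence={"COPD": 0.5})
        with pytest.raises(ValueError):
            P.CohortConfig(comorbidity_rate=1.5)

    def test_minors_never_smoke(self):
        for rec in P.generate_cohort(P.CohortConfig(n=400, seed=3)):
            if rec.age < 18:
                assert rec.smoking == "never"


class TestDoseAdjustment:
    def test_preserved_above_threshold(self):
        assert P.adjust_dose(500.0, 60.0) == 500.0
        assert P.adjust_dose(500.0, 120.0) == 500.0

    def test_exact_hit_snaps_to_vocabulary_class(self):
        # eGFR 30, base 500 mg -> 250 mg exactly
        raw = P.adjust_dose(500.0, 30.0)
        assert raw == 250.0
        assert P.snap_dosage(raw) == "250 mg"

    def test_nearest_lower_snap_matches_bruteforce(self):
        # oracle: exhaustive search over the mg-valued vocabulary
        def brute(value):
            below = {lbl: v for lbl, v in P.MG_CLASSES.items() if v <= value}
            if not below:
                return min(P.MG_CLASSES, key=P.MG_CLASSES.get)
            return max(below, key=below.get)

        rng = np.random.default_rng(0)
        for value in list(rng.uniform(0.1, 700, 200)) + [250.0, 400.0, 0.4]:
            assert P.snap_dosage(value) == brute(value), value
        # the worked case: eGFR 45, base 400 -> 300 -> snapped to 250 mg
        assert P.snap_dosage(P.adjust_dose(400.0, 45.0)) == "250 mg"

    def test_nonpositive_inputs_error(self):
        with pytest.raises(ValueError):
            P.adjust_dose(0.0, 50.0)
        with pytest.raises(ValueError):
            P.adjust_dose(500.0, -1.0)

    def test_adjusted_never_exceeds_base(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            base = float(rng.choice(list(P.MG_CLASSES.values())))
            egfr = float(rng.uniform(5, 150))
            assert P.adjust_dose(base, egfr) <= base


class TestAssignPrescription:
    def _record(self, **kw):
        defaults = dict(id="T", age=40, sex="male", smoking="never",
                        diagnosis="healthy", renal_impaired=False,
                        hepatic_impaired=False, eGFR=95.0, weight=70.0)
        defaults.update(kw)
        return P.PatientRecord(**defaults)

    def test_healthy_gets_supportive_care(self, formulary):
        p = P.assign_prescription(self._record(), formulary)
        assert (p.drug, p.dosage, p.frequency) == (
            "Supportive Care Only", "N/A", "N/A")

    def test_asthma_never_gets_beta_blocker(self, formulary):
        blockers = formulary.contraindicated["asthma"]
        for rec in P.generate_cohort(P.CohortConfig(n=500, seed=4)):
            if rec.diagnosis != "asthma":
                continue
            p = P.assign_prescription(rec, formulary)
            assert p.drug not in blockers

    def test_renal_impairment_lowers_antibiotic_class(self, formulary):
        healthy_kidneys = self._record(diagnosis="pneumonia", age=40)
        impaired = self._record(diagnosis="pneumonia", age=40,
                                renal_impaired=True, eGFR=30.0)
        p_norm = P.assign_prescription(healthy_kidneys, formulary)
        p_imp = P.assign_prescription(impaired, formulary)
        assert p_norm.dosage == "500 mg"
        assert P.MG_CLASSES[p_imp.dosage] <= P.MG_CLASSES[p_norm.dosage]

    def test_pediatric_weight_based_dosing(self, formulary):
        child = self._record(diagnosis="pneumonia", age=6)
        p = P.assign_prescription(child, formulary)
        assert p.dosage == "90 mg/kg/day"
        assert p.frequency == "Divided in 2 doses"

    def test_interaction_screen_substitutes_alternate(self, formulary):
        on_warfarin = self._record(diagnosis="LRTI", age=50,
                                   background_med="Warfarin")
        p = P.assign_prescription(on_warfarin, formulary)
        assert p.drug == "Amoxicillin"  # azithromycin interacts
        clean = P.assign_prescription(
            self._record(diagnosis="LRTI", age=50), formulary)
        assert clean.drug == "Azithromycin"

    def test_uncovered_band_errors(self, formulary):
        import copy

        broken = copy.deepcopy(formulary)
        del broken.rules[("asthma", "elderly")]
        with pytest.raises(KeyError, match="asthma"):
            P.assign_prescription(self._record(diagnosis="asthma", age=80),
                                  broken)

    def test_vocabulary_closure_on_cohort(self, default_cohort_run):
        df = default_cohort_run["cohort"]
        assert df["drug"].isin(P.DRUGS).all()
        assert df["dosage"].isin(P.DOSAGES).all()
        assert df["frequency"].isin(P.FREQUENCIES).all()
        # every drug category appears with non-zero support
        assert set(df["drug"]) == set(P.DRUGS)


class TestOversampleRare:
    def test_no_rare_pairs_is_noop(self):
        df = pd.DataFrame({
            "diagnosis": ["COPD"] * 10 + ["asthma"] * 10,
            "drug": ["Tiotropium"] * 10 + ["Fluticasone"] * 10,
            "age": range(20), "eGFR": [90.0] * 20, "weight": [70.0] * 20,
        })
        out = P.oversample_rare(df, threshold=0.05, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_one_percent_pair_reaches_five_percent(self, default_cohort_run):
        tr = default_cohort_run["train"]
        out = P.oversample_rare(tr, threshold=0.05, seed=0)
        n = len(tr)
        target = int(np.ceil(0.05 * n))
        counts = out.groupby(["diagnosis", "drug"]).size()
        assert counts.min() >= target
        # originals untouched, synthetic rows appended
        pd.testing.assert_frame_equal(out.iloc[:n].reset_index(drop=True),
                                      tr.reset_index(drop=True),
                                      check_dtype=False)

    def test_synthetic_ages_inside_parent_range(self, default_cohort_run):
        tr = default_cohort_run["train"]
        out = P.oversample_rare(tr, threshold=0.05, seed=0)
        synth = out.iloc[len(tr):]
        for (diag, drug), group in synth.groupby(["diagnosis", "drug"]):
            parents = tr[(tr["diagnosis"] == diag) & (tr["drug"] == drug)]
            if len(parents) >= 2:
                assert group["age"].min() >= parents["age"].min() - 0
                assert group["age"].max() <= parents["age"].max() + 0
            else:
                # singleton pairs: duplicated with +/-2 year jitter
                assert (group["age"] - parents["age"].iloc[0]).abs().max() <= 2

    def test_bad_threshold_rejected(self, default_cohort_run):
        with pytest.raises(ValueError):
            P.oversample_rare(default_cohort_run["train"], threshold=0.0)


class TestRecommender:
    def test_config_echoes_ensemble_settings(self, default_cohort_run):
        cfg = default_cohort_run["model"].config
        assert (cfg.trees, cfg.criterion, cfg.max_depth,
                cfg.min_samples_leaf) == (500, "gini", 15, 2)
        rf = default_cohort_run["model"].pipeline.named_steps["rf"]
        assert rf.n_estimators == 500 and rf.max_depth == 15

    def test_training_set_drug_accuracy_is_perfect(self, default_cohort_run):
        # labels are deterministic in the features: the ensemble must
        # reproduce the generating rule table on its own training rows
        model = default_cohort_run["model"]
        tr = default_cohort_run["train"]
        pred = model.predict(tr)
        assert np.mean(pred["drug"].to_numpy() == tr["drug"].to_numpy()) == 1.0

    def test_missing_target_column_errors(self, default_cohort_run):
        with pytest.raises(ValueError):
            P.train_recommender(default_cohort_run["train"].drop(columns=["dosage"]))

    def test_seed_stability_below_one_percent(self, default_cohort_run):
        tr, te = default_cohort_run["train"], default_cohort_run["test"]
        accs = []
        for seed in range(3):
            model = P.train_recommender(P.oversample_rare(tr, seed=seed),
                                        seed=seed)
            pred = model.predict(te)
            accs.append(np.mean(pred["drug"].to_numpy() == te["drug"].to_numpy()))
        assert max(accs) - min(accs) < 0.01


class TestEvaluateRecommender:
    def test_test_partition_size(self, default_cohort_run):
        assert len(default_cohort_run["test"]) == 400

    def test_support_sums_to_test_size(self, default_cohort_run):
        for target, table in default_cohort_run["reports"].items():
            class_rows = table.drop(index=["macro avg", "weighted avg"])
            assert class_rows["support"].sum() == 400

    def test_empty_test_set_errors(self, default_cohort_run):
        with pytest.raises(ValueError):
            P.evaluate_recommender(default_cohort_run["model"],
                                   default_cohort_run["test"].iloc[:0])

    def test_low_confidence_rows_flagged(self, default_cohort_run):
        flagged = default_cohort_run["flagged"]
        conf = default_cohort_run["model"].confidence(
            default_cohort_run["test"])
        assert len(flagged) == int((conf < 0.5).any(axis=1).sum())
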