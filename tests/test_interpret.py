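"""Shapley attribution: axioms, closed forms, cross-cohort presence."""

import numpy as np
import pytest
from scipy.special import expit

from gwaskd.interpret import (
    AttributionSummary,
    attribute_student,
    cross_cohort_presence,
    top_k_snps,
)
from gwaskd.models import (
    DeepConfig,
    TeacherModel,
    WideConfig,
    build_student,
    train_teacher,
)


class _LinearProbModel:
    """f(x) = clip-free linear map into [0,1] via a gentle sigmoid."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = b

    def predict_proba(self, X):
        p = expit(X @ self.w + self.b)
        return np.column_stack([1 - p, p])


class TestAttributeStudent:
    def test_local_accuracy_exact(self, rng):
        w = rng.normal(size=5)
        model = _LinearProbModel(w)
        background = rng.binomial(2, 0.4, size=(12, 5)).astype(float)
        explain = rng.binomial(2, 0.4, size=(6, 5)).astype(float)
        s = attribute_student(model, background, explain, n_permutations=24,
                              seed=0)
        f = model.predict_proba(explain)[:, 1]
        residual = s.per_sample_shap.sum(axis=1) + s.base_value - f
        assert np.abs(residual).max() < 0.01

    def test_null_player_gets_exact_zero(self, rng):
        """A feature the model ignores receives shap exactly 0."""
        w = np.array([1.0, 0.0, -0.5])
        model = _LinearProbModel(w)
        background = rng.binomial(2, 0.5, size=(8, 3)).astype(float)
        explain = rng.binomial(2, 0.5, size=(4, 3)).astype(float)
        s = attribute_student(model, background, explain, n_permutations=8,
                              seed=1)
        np.testing.assert_array_equal(s.per_sample_shap[:, 1], 0.0)

    def test_linear_model_closed_form(self, rng):
        """Near-linear regime: shap_j ~ w_j (x_j - mean background_j)."""
        w = rng.normal(scale=0.15, size=6)  # small weights keep sigmoid linear
        model = _LinearProbModel(w)
        background = rng.binomial(2, 0.5, size=(40, 6)).astype(float)
        explain = rng.binomial(2, 0.5, size=(5, 6)).astype(float)
        s = attribute_student(model, background, explain, n_permutations=128,
                              seed=2)
        # sigmoid slope at the operating point ~ p(1-p) with p near 0.5
        base_p = model.predict_proba(background)[:, 1].mean()
        slope = base_p * (1 - base_p)
        expected = slope * w * (explain - background.mean(axis=0))
        assert np.abs(s.per_sample_shap - expected).max() < 0.02

    def test_deterministic_given_seed(self, rng):
        model = _LinearProbModel(rng.normal(size=4))
        background = rng.binomial(2, 0.4, size=(10, 4)).astype(float)
        explain = rng.binomial(2, 0.4, size=(3, 4)).astype(float)
        a = attribute_student(model, background, explain, seed=5)
        b = attribute_student(model, background, explain, seed=5)
        np.testing.assert_array_equal(a.per_sample_shap, b.per_sample_shap)

    def test_explain_order_invariance_of_mean_abs(self, rng):
        model = _LinearProbModel(rng.normal(size=4))
        background = rng.binomial(2, 0.4, size=(10, 4)).astype(float)
        explain = rng.binomial(2, 0.4, size=(6, 4)).astype(float)
        a = attribute_student(model, background, explain, seed=3)
        b = attribute_student(model, background, explain[::-1].copy(), seed=3)
        np.testing.assert_allclose(
            np.sort(a.mean_abs_shap), np.sort(b.mean_abs_shap), atol=1e-12
        )
        np.testing.assert_allclose(a.mean_abs_shap, b.mean_abs_shap, atol=1e-12)

    def test_duplicate_features_near_symmetric(self, rng):
        """Two identical SNP columns get mean|shap| within 20%."""
        w = np.array([0.4, 0.4, -0.2])
        model = _LinearProbModel(w)
        col = rng.binomial(2, 0.5, size=20).astype(float)
        other = rng.binomial(2, 0.5, size=20).astype(float)
        background = np.column_stack([col, col, other])
        ecol = rng.binomial(2, 0.5, size=8).astype(float)
        eoth = rng.binomial(2, 0.5, size=8).astype(float)
        explain = np.column_stack([ecol, ecol, eoth])
        s = attribute_student(model, background, explain, n_permutations=256,
                              seed=4)
        a, b = s.mean_abs_shap[0], s.mean_abs_shap[1]
        assert abs(a - b) <= 0.2 * max(a, b)

    def test_feature_mismatch_errors(self, rng):
        model = _LinearProbModel(np.ones(3))
        with pytest.raises(ValueError, match="mismatch"):
            attribute_student(
                model, np.zeros((4, 3)), np.zeros((2, 5)), seed=0
            )

    def test_trained_student_null_embedding_is_null_player(self, rng):
        """A student whose embedding row for one SNP is zeroed (and that SNP
        absent from wide inputs) attributes exactly zero to it."""
        teacher = TeacherModel(
            6, wide=WideConfig(include_raw=False, cross_product_pairs=[(0, 1)]),
            deep=DeepConfig(embedding_dim=3, hidden_layer_sizes=[6],
                            dropout_rate=0.0),
            attention=None, seed=0,
        )
        student = build_student(teacher, seed=1)
        # silence SNP 5 everywhere
        student.net.params["embed_W"][5] = 0.0
        student.net.params["embed_b"][5] = 0.0
        background = rng.binomial(2, 0.4, size=(10, 6)).astype(float)
        explain = rng.binomial(2, 0.4, size=(4, 6)).astype(float)
        s = attribute_student(student, background, explain, n_permutations=8,
                              seed=2)
        np.testing.assert_array_equal(s.per_sample_shap[:, 5], 0.0)


class TestTopK:
    def _summary(self, mean_abs, rsids=None):
        mean_abs = np.asarray(mean_abs, dtype=float)
        p = mean_abs.size
        per_sample = np.tile(mean_abs, (3, 1))
        return AttributionSummary(
            cohort="c",
            rsids=rsids or [f"rs{j}" for j in range(p)],
            mean_abs_shap=mean_abs,
            per_sample_shap=per_sample,
            background_size=10,
            base_value=0.5,
        )

    def test_full_k_is_permutation(self):
        s = self._summary([0.1, 0.5, 0.3])
        assert sorted(top_k_snps(s, 3)) == sorted(s.rsids)

    def test_dominant_snp_first(self):
        s = self._summary([0.1, 0.9, 0.2])
        assert top_k_snps(s, 2)[0] == "rs1"

    def test_invalid_k(self):
        s = self._summary([0.1, 0.2])
        with pytest.raises(ValueError):
            top_k_snps(s, 0)
        with pytest.raises(ValueError):
            top_k_snps(s, 3)


class TestCrossCohortPresence:
    def _summary(self, mean_abs, rsids):
        return AttributionSummary(
            cohort="x",
            rsids=rsids,
            mean_abs_shap=np.asarray(mean_abs, dtype=float),
            per_sample_shap=np.tile(mean_abs, (2, 1)),
            background_size=5,
            base_value=0.5,
        )

    def test_identical_summaries_all_present(self):
        rsids = ["a", "b", "c", "d"]
        s = self._summary([0.4, 0.3, 0.2, 0.1], rsids)
        table = cross_cohort_presence({"c1": s, "c2": s, "c3": s}, k=2)
        for row in table.rows:
            assert row["cohorts_present"] == {"c1", "c2", "c3"}
        assert len(table.rows) == 2

    def test_disjoint_top_sets_single_membership(self):
        rsids = ["a", "b", "c", "d"]
        s1 = self._summary([1.0, 0.9, 0.0, 0.0], rsids)
        s2 = self._summary([0.0, 0.0, 1.0, 0.9], rsids)
        table = cross_cohort_presence({"c1": s1, "c2": s2}, k=2)
        assert len(table.rows) == 4
        for row in table.rows:
            assert len(row["cohorts_present"]) == 1

    def test_row_count_bounded(self):
        rsids = [f"r{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        summaries = {
            f"c{i}": self._summary(rng.uniform(size=10), rsids)
            for i in range(4)
        }
        table = cross_cohort_presence(summaries, k=3)
        assert len(table.rows) <= 4 * 3

    def test_inconsistent_universe_errors(self):
        s1 = self._summary([0.1, 0.2], ["a", "b"])
        s2 = self._summary([0.1, 0.2], ["a", "c"])
        with pytest.raises(ValueError, match="harmonise"):
            cross_cohort_presence({"c1": s1, "c2": s2}, k=1)

    def test_shared_causal_snps_dominate_presence(self):
        """Students trained per cohort on data sharing 3 strong causal SNPs
        (plus cohort-private ones) rank the shared SNPs as most present."""
        from gwaskd import io_preprocess as iop
        from gwaskd.simulate import SimulationConfig, simulate_cohorts

        n_cohorts = 3
        # causal 0..2 shared; 3..5 private to one cohort each
        mults = []
        for c in range(n_cohorts):
            m = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
            m[3 + c] = 1.0
            mults.append(m)
        cfg = SimulationConfig(
            n_cohorts=n_cohorts,
            n_samples_per_cohort=[500] * n_cohorts,
            n_snps=20,
            n_causal=6,
            effect_sizes=[1.2] * 6,
            case_fraction_per_cohort=[0.5] * n_cohorts,
            base_maf_range=(0.2, 0.5),
            missing_rate=0.0,
            effect_size_multiplier_per_cohort=mults,
            seed=60,
        )
        datasets, truth = simulate_cohorts(cfg)
        shared_rsids = {
            datasets[0].rsids[i] for i in truth.causal_indices[:3]
        }
        summaries = {}
        for ds in datasets:
            split = iop.stratified_split(ds, 0.3, seed=1)
            teacher = TeacherModel(
                20, wide=WideConfig(),
                deep=DeepConfig(embedding_dim=4, hidden_layer_sizes=[12],
                                dropout_rate=0.0),
                attention=None, seed=2,
            )
            train_teacher(
                teacher, split.train.genotypes, split.train.labels,
                epochs=20, seed=3,
                X_val=split.test.genotypes, y_val=split.test.labels,
            )
            student = build_student(teacher, seed=4)
            from gwaskd.distill import DistillationConfig, train_student

            train_student(
                teacher, student,
                (split.train.genotypes, split.train.labels), None,
                DistillationConfig(epochs=15, seed=5),
            )
            summaries[ds.name] = attribute_student(
                student, split.train.genotypes[:40],
                split.test.genotypes[:30], n_permutations=16, seed=6,
                rsids=list(ds.rsids), cohort=ds.name,
            )
        table = cross_cohort_presence(summaries, k=6)
        # the 3 shared causal SNPs should sit among the most-present rows
        counts = {
            row["rsid"]: len(row["cohorts_present"]) for row in table.rows
        }
        shared_presence = [counts.get(r, 0) for r in shared_rsids]
        other_presence = [
            c for r, c in counts.items() if r not in shared_rsids
        ] or [0]
        assert np.mean(shared_presence) >= np.mean(other_presence)


class TestPlantedRecoveryThroughStudent:
    def test_causal_snps_reach_student_top_ten(self):
        """5 strong causal SNPs among 75: most appear in the student's
        top-10 by mean |shap|."""
        from gwaskd import io_preprocess as iop
        from gwaskd.distill import DistillationConfig, train_student
        from gwaskd.simulate import SimulationConfig, simulate_cohorts

        hits = 0
        n_seeds = 3
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_cohorts=1,
                n_samples_per_cohort=[800],
                n_snps=75,
                n_causal=5,
                effect_sizes=[1.5] * 5,
                case_fraction_per_cohort=[0.5],
                base_maf_range=(0.2, 0.5),
                missing_rate=0.0,
                seed=seed + 70,
            )
            (ds,), truth = simulate_cohorts(cfg)
            split = iop.stratified_split(ds, 0.25, seed=seed)
            teacher = TeacherModel(
                75, wide=WideConfig(),
                deep=DeepConfig(embedding_dim=4, hidden_layer_sizes=[16],
                                dropout_rate=0.0),
                attention=None, seed=seed,
            )
            train_teacher(
                teacher, split.train.genotypes, split.train.labels,
                epochs=25, seed=seed + 1,
                X_val=split.test.genotypes, y_val=split.test.labels,
            )
            student = build_student(teacher, seed=seed + 2)
            train_student(
                teacher, student,
                (split.train.genotypes, split.train.labels), None,
                DistillationConfig(epochs=20, seed=seed + 3),
            )
            summary = attribute_student(
                student, split.train.genotypes[:50],
                split.test.genotypes[:40], n_permutations=16,
                seed=seed + 4, rsids=list(ds.rsids),
            )
            top10 = set(top_k_snps(summary, 10))
            causal = {ds.rsids[i] for i in truth.causal_indices}
            if len(top10 & causal) >= 4:
                hits += 1
        assert hits > n_seeds / 2
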