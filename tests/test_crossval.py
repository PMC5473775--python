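import numpy as np
import pandas as pd
import pytest

import kernelgp as kg


def single_env_records(n_lines=100):
    df = pd.DataFrame(
        {
            "line": [f"L{i}" for i in range(n_lines)],
            "env": "e1",
            "trait": "t",
            "value": np.linspace(0, 1, n_lines),
        }
    )
    return kg.PhenotypeRecords(df)


def grid_records(lines, envs, rng=None):
    rows = []
    r = rng or np.random.default_rng(0)
    for l in lines:
        for e in envs:
            rows.append((l, e, "t", float(r.standard_normal())))
    return kg.PhenotypeRecords(pd.DataFrame(rows, columns=["line", "env", "trait", "value"]))


class TestMakeCVPlan:
    def test_within_env_folds_partition_lines(self):
        rec = single_env_records(100)
        plan = kg.make_cv_plan(rec, "within_env", folds=5, replicates=1, seed=1)
        assert len(plan) == 5
        sizes = [p.sum() for p in plan.partitions]
        assert sizes == [20] * 5
        union = np.zeros(100, dtype=int)
        for p in plan.partitions:
            union += p.astype(int)
        assert np.all(union == 1)

    def test_cv1_masks_all_records_of_test_lines(self):
        rec = grid_records(list("ABCDE"), ["e1", "e2", "e3"])
        plan = kg.make_cv_plan(rec, "CV1", folds=5, replicates=1, seed=2)
        lines = rec.df["line"].to_numpy()
        for tst in plan.partitions:
            tst_lines = set(lines[tst])
            for l in tst_lines:
                assert np.all(tst[lines == l]), f"line {l} only partially masked"

    def test_cv2_each_record_tested_once_per_replicate(self):
        rec = grid_records([f"L{i}" for i in range(40)], ["e1", "e2", "e3", "e4", "e5"])
        assert len(rec) == 200
        plan = kg.make_cv_plan(rec, "CV2", folds=5, replicates=10, seed=3)
        assert len(plan) == 50
        counts = np.zeros(200, dtype=int)
        for tst in plan.partitions:
            counts += tst.astype(int)
        assert np.all(counts == 10)  # once per replicate

    def test_coverage_exact_within_each_replicate(self):
        rec = grid_records([f"L{i}" for i in range(25)], ["e1", "e2"])
        for scheme in ("CV1", "CV2"):
            plan = kg.make_cv_plan(rec, scheme, folds=5, replicates=3, seed=4)
            for r in range(3):
                union = np.zeros(len(rec), dtype=int)
                for f in range(5):
                    union += plan.partitions[r * 5 + f].astype(int)
                assert np.all(union == 1)

    def test_too_few_units_raises(self):
        rec = single_env_records(3)
        with pytest.raises(ValueError, match="folds"):
            kg.make_cv_plan(rec, "within_env", folds=5, replicates=1)

    def test_deterministic_under_seed(self):
        rec = grid_records([f"L{i}" for i in range(30)], ["e1", "e2"])
        p1 = kg.make_cv_plan(rec, "CV2", folds=5, replicates=2, seed=9)
        p2 = kg.make_cv_plan(rec, "CV2", folds=5, replicates=2, seed=9)
        for a, b in zip(p1.partitions, p2.partitions):
            np.testing.assert_array_equal(a, b)


class TestPearsonWithinEnv:
    def test_affine_transform_gives_unit_correlation(self, rng):
        obs = rng.standard_normal(20)
        assert kg.pearson_within_env(2 * obs + 1, obs) == pytest.approx(1.0)
        assert kg.pearson_within_env(-obs, obs) == pytest.approx(-1.0)

    def test_constant_prediction_is_undefined_not_zero(self):
        r = kg.pearson_within_env(np.ones(5), np.arange(5.0))
        assert np.isnan(r)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert kg.pearson_within_env(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_short_vectors_undefined(self):
        assert np.isnan(kg.pearson_within_env(np.array([1.0, 2.0]), np.array([1.0, 2.0])))


class TestPercentChange:
    @pytest.mark.parametrize(
        "base,new,expected",
        [(0.64, 0.73, 14), (0.32, 0.51, 59), (0.39, 0.58, 49), (0.37, 0.49, 32),
         (0.5, 0.5, 0), (0.33, 0.56, 70), (0.5, 0.4, -20)],
    )
    def test_accuracy_gain_integers(self, base, new, expected):
        assert kg.percent_change(base, new) == expected

    def test_zero_base_raises(self):
        with pytest.raises(ZeroDivisionError):
            kg.percent_change(0.0, 0.5)


class TestHeritability:
    def test_direct_arithmetic(self):
        assert kg.broad_sense_heritability(1, 1, 1, s=2, r=2) == pytest.approx(1 / 1.75)

    def test_no_interaction_no_noise_gives_one(self):
        assert kg.broad_sense_heritability(2.0, 0.0, 0.0, s=3, r=2) == 1.0

    def test_monotone_in_replicates_toward_limit(self):
        vals = [kg.broad_sense_heritability(1.0, 0.5, 1.0, s=2, r=r) for r in (1, 4, 16, 256)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        limit = 1.0 / (1.0 + 0.25)
        assert vals[-1] < limit
        assert limit - vals[-1] < 0.01

    def test_all_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            kg.broad_sense_heritability(0.0, 0.0, 0.0, s=2, r=2)


class TestRunCVExperiment:
    def test_oracle_predictor_gives_perfect_correlations(self, small_trial):
        records = small_trial["records"]
        plan = kg.make_cv_plan(records, "CV2", folds=5, replicates=1, seed=5)
        spec = kg.ModelSpec(model="MM", method="GB").reduced()

        def oracle(recs, tst, spec):
            return recs.df["value"].to_numpy()

        report = kg.run_cv_experiment(records, {"GB": small_trial["GB"]}, [spec],
                                      plan, predictor=oracle)
        s = report.summary()
        assert np.allclose(s["mean"], 1.0)
        assert np.allclose(s["sd"], 0.0)

    def test_identical_seed_identical_report(self, small_trial):
        records = small_trial["records"]
        plan = kg.make_cv_plan(records, "CV2", folds=5, replicates=1, seed=6)
        spec = kg.ModelSpec(model="MM", method="GB", seed=6).reduced()
        r1 = kg.run_cv_experiment(records, {"GB": small_trial["GB"]}, [spec], plan)
        r2 = kg.run_cv_experiment(records, {"GB": small_trial["GB"]}, [spec], plan)
        pd.testing.assert_frame_equal(r1.df, r2.df)

    def test_sm_rejected_outside_within_env(self, small_trial):
        records = small_trial["records"]
        plan = kg.make_cv_plan(records, "CV2", folds=5, replicates=1, seed=7)
        spec = kg.ModelSpec(model="SM", method="GB").reduced()
        with pytest.raises(ValueError, match="within_env"):
            kg.run_cv_experiment(records, {"GB": small_trial["GB"]}, [spec], plan)

    def test_no_leakage_masking_vs_deleting_values(self, small_trial):
        """Overwriting test phenotype values changes nothing in predictions:
        correlations per partition are identical."""
        records = small_trial["records"]
        plan = kg.make_cv_plan(records, "CV2", folds=5, replicates=1, seed=8)
        spec = kg.ModelSpec(model="MM", method="GB", seed=8).reduced()
        r1 = kg.run_cv_experiment(records, {"GB": small_trial["GB"]}, [spec], plan)

        # same partitions, but test values replaced by an arbitrary constant
        # before fitting; observed values used for correlation stay original
        df2 = records.df.copy()
        preds = {}
        from kernelgp.design import build_design_matrices, standardize_phenotypes
        from kernelgp.gibbs import eigendecompose_component, gibbs_fit
        from kernelgp.design import assemble_model, fixed_effects_design
        from dataclasses import replace

        design = build_design_matrices(records)
        comps = assemble_model("MM", design, small_trial["GB"])
        eigs = [eigendecompose_component(c) for c in comps]
        W = fixed_effects_design(design, "MM")
        for pidx, tst in enumerate(plan.partitions):
            corrupted = kg.PhenotypeRecords(
                records.df.assign(value=np.where(tst, 123.0, records.df["value"]))
            )
            std = standardize_phenotypes(corrupted, reference_mask=~tst)
            part_spec = replace(spec, seed=(spec.seed * 10_007 + pidx) % (2**31 - 1))
            post = gibbs_fit(std.df["value"].to_numpy(), ~tst, W, eigs, part_spec)
            preds[pidx] = post.fitted_values

        envs = records.df["env"].to_numpy()
        obs = records.df["value"].to_numpy()
        for pidx, tst in enumerate(plan.partitions):
            for env in sorted(set(envs)):
                sel = tst & (envs == env)
                if sel.sum() < 3:
                    continue
                r_clean = r1.df[(r1.df["partition"] == pidx) & (r1.df["env"] == env)]["r"].iloc[0]
                r_corrupt = kg.pearson_within_env(preds[pidx][sel], obs[sel])
                assert r_corrupt == pytest.approx(r_clean, abs=1e-12)

    def test_cv2_beats_cv1_with_correlated_environments(self):
        """With a shared main genetic effect across environments, observing a
        line elsewhere (CV2) must help relative to never observing it (CV1).
        A wide founder base keeps hybrids weakly related, so the kernel alone
        cannot substitute for a line's own records in other environments."""
        cfg = kg.SimConfig(n_parents=60, n_hybrids=80, p=300, s=3,
                           sigma2_u0=0.5, sigma2_ue=0.1, sigma2_e=0.4,
                           sparsity=0.0, seed=17)
        founders, crosses = kg.simulate_founders_and_hybrids(cfg)
        hybrids = kg.make_hybrid_genotypes(founders, crosses)
        records = kg.simulate_multienv_phenotypes(hybrids, cfg)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            X = kg.standardize_markers(hybrids)
        K = {"GB": kg.linear_kernel(X)}
        spec = kg.ModelSpec(model="MDs", method="GB", seed=17).reduced()
        means = {}
        for scheme in ("CV1", "CV2"):
            plan = kg.make_cv_plan(records, scheme, folds=5, replicates=2, seed=17)
            rep = kg.run_cv_experiment(records, K, [spec], plan)
            means[scheme] = rep.mean_accuracy("MDs", "GB")
        assert means["CV2"] > means["CV1"]
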