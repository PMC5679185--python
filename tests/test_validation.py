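import numpy as np
import pandas as pd
import pytest

import oracles
from gfrens import synthetic
from gfrens.equations import estimate_gfr_frame
from gfrens.validation import (
    DifferenceVector,
    SubgroupSpec,
    bootstrap_ci,
    compare_accuracy_mcnemar,
    compare_bias_wilcoxon,
    compare_precision_bootstrap,
    differences,
    evaluate_models,
    iqr_precision,
    median_bias,
    p30_accuracy,
    p30_hits,
    stratified_summary,
)


def _dv(values, start=0):
    return DifferenceVector(
        values=np.asarray(values, dtype=float),
        paired_ids=tuple(f"p{i}" for i in range(start, start + len(values))),
    )


class TestDifferences:
    def test_direction_and_pairing(self):
        cohort = pd.DataFrame(
            {"id": ["a", "b"], "age": [50, 60], "sex": ["male", "female"],
             "scr": [1.0, 1.0], "mgfr": [50.0, 60.0]}
        )
        d = differences(cohort, np.array([45.0, 65.0]))
        np.testing.assert_array_equal(d.values, [5.0, -5.0])
        assert d.paired_ids == ("a", "b")
        rev = differences(cohort, np.array([45.0, 65.0]), direction="egfr_minus_mgfr")
        np.testing.assert_array_equal(rev.values, [-5.0, 5.0])

    def test_identity_gives_zeros(self, toy_cohort):
        d = differences(toy_cohort, toy_cohort["mgfr"].to_numpy())
        assert np.all(d.values == 0.0)

    def test_length_mismatch_rejected(self, toy_cohort):
        with pytest.raises(ValueError):
            differences(toy_cohort, np.ones(3))


class TestPointMetrics:
    def test_small_examples(self):
        assert median_bias(_dv([-1, 0, 1])) == 0.0
        assert median_bias(_dv([1, 2, 3, 10])) == 2.5
        assert median_bias(_dv([7])) == 7.0
        assert iqr_precision(_dv([4.0, 4.0, 4.0, 4.0])) == 0.0
        assert iqr_precision(_dv(range(1, 9))) == pytest.approx(
            oracles.iqr_oracle(range(1, 9))
        )

    def test_iqr_location_invariant(self, rng):
        vals = rng.normal(size=31)
        assert iqr_precision(_dv(vals + 10.0)) == pytest.approx(
            iqr_precision(_dv(vals)), abs=1e-12
        )

    def test_p30_boundary_inclusive(self):
        cohort = pd.DataFrame(
            {"id": ["a", "b"], "age": [50, 50], "sex": ["male", "male"],
             "scr": [1.0, 1.0], "mgfr": [100.0, 100.0]}
        )
        assert p30_accuracy(cohort, np.array([130.0, 70.0])) == 1.0
        assert p30_accuracy(cohort, np.array([130.01, 100.0])) == 0.5

    def test_metrics_match_brute_force_on_random_inputs(self, rng):
        """Median, IQR and P30 agree with sort-based brute-force oracles."""
        for _ in range(300):
            n = int(rng.integers(2, 25))
            vals = rng.normal(scale=10, size=n)
            assert median_bias(_dv(vals)) == pytest.approx(oracles.median_oracle(vals))
            assert iqr_precision(_dv(vals)) == pytest.approx(oracles.iqr_oracle(vals))
            mgfr = rng.uniform(10, 150, size=n)
            egfr = mgfr * rng.uniform(0.5, 1.5, size=n)
            cohort = pd.DataFrame(
                {"id": [f"i{k}" for k in range(n)], "age": 50.0, "sex": "male",
                 "scr": 1.0, "mgfr": mgfr}
            )
            assert p30_accuracy(cohort, egfr) == pytest.approx(
                oracles.p30_oracle(mgfr, egfr)
            )

    def test_reordering_invariance(self, rng):
        mgfr = rng.uniform(10, 150, size=40)
        egfr = mgfr * rng.uniform(0.6, 1.4, size=40)
        perm = rng.permutation(40)
        cohort = pd.DataFrame(
            {"id": [f"i{k}" for k in range(40)], "age": 50.0, "sex": "male",
             "scr": 1.0, "mgfr": mgfr}
        )
        shuffled = cohort.iloc[perm].reset_index(drop=True)
        assert p30_accuracy(cohort, egfr) == p30_accuracy(shuffled, egfr[perm])
        assert median_bias(differences(cohort, egfr)) == median_bias(
            differences(shuffled, egfr[perm])
        )


class TestBootstrap:
    def test_constant_data_degenerate_interval(self):
        lo, hi = bootstrap_ci(np.median, np.full(20, 3.5), B=200, seed=0)
        assert lo == hi == 3.5

    def test_seed_reproducibility(self, rng):
        data = rng.normal(size=50)
        a = bootstrap_ci(np.median, data, B=500, seed=42)
        b = bootstrap_ci(np.median, data, B=500, seed=42)
        assert a == b
        c = bootstrap_ci(np.median, data, B=500, seed=43)
        assert a != c

    def test_vectorised_and_loop_paths_agree(self, rng):
        data = rng.normal(size=60)

        def scalar_median(x):  # no axis kwarg -> loop path
            return float(np.median(x))

        a = bootstrap_ci(np.median, data, B=300, seed=9)
        b = bootstrap_ci(scalar_median, data, B=300, seed=9)
        assert a == pytest.approx(b)

    def test_undersized_inputs_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.median, np.array([1.0]), B=200, seed=0)
        with pytest.raises(ValueError):
            bootstrap_ci(np.median, np.ones(10), B=50, seed=0)


class TestWilcoxon:
    def test_identical_vectors_p_one(self):
        d = _dv([1.0, -2.0, 3.0])
        assert compare_bias_wilcoxon(d, d) == 1.0

    def test_matches_exact_enumeration(self, rng):
        """Signed-rank p equals brute-force enumeration of all sign
        assignments for small untied samples."""
        for _ in range(60):
            n = int(rng.integers(3, 13))
            z = rng.normal(size=n)
            dA = _dv(z)
            dB = _dv(np.zeros(n))
            assert compare_bias_wilcoxon(dA, dB) == pytest.approx(
                oracles.wilcoxon_enumeration_p(z), abs=1e-12
            )

    def test_constant_shift_detected(self, rng):
        vals = rng.normal(size=50)
        assert compare_bias_wilcoxon(_dv(vals + 5.0), _dv(vals)) < 0.01

    def test_pairing_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_bias_wilcoxon(_dv([1.0, 2.0]), _dv([1.0, 2.0], start=5))


class TestPrecisionBootstrap:
    def test_null_gives_large_p(self, rng):
        vals = rng.normal(size=200)
        p = compare_precision_bootstrap(_dv(vals), _dv(vals.copy()), B=500, seed=1)
        assert p > 0.5

    def test_unequal_spreads_detected(self, rng):
        n = 400
        p = compare_precision_bootstrap(
            _dv(rng.normal(scale=1.0, size=n)), _dv(rng.normal(scale=3.0, size=n)),
            B=1000, seed=2,
        )
        assert p < 0.01

    def test_seeded_reproducibility(self, rng):
        dA, dB = _dv(rng.normal(size=80)), _dv(rng.normal(size=80))
        assert compare_precision_bootstrap(dA, dB, B=300, seed=5) == \
            compare_precision_bootstrap(dA, dB, B=300, seed=5)


class TestMcNemar:
    def test_equal_discordance_p_one(self):
        hits = np.array([1, 0, 1, 0, 1, 1])
        assert compare_accuracy_mcnemar(hits, hits) == 1.0
        a = np.array([1, 0, 1, 0])
        b = np.array([0, 1, 1, 0])  # b = c = 1
        assert compare_accuracy_mcnemar(a, b) == 1.0

    def test_closed_form_binomial(self):
        a = np.concatenate([np.ones(10), np.zeros(5)]).astype(int)
        b = np.zeros(15, dtype=int)
        # b=10 discordant hits for A, c=0
        assert compare_accuracy_mcnemar(a, b) == pytest.approx(2 * 0.5**10)

    def test_depends_only_on_discordant_counts(self, rng):
        a = np.array([1, 1, 0, 0, 1])
        b = np.array([0, 1, 1, 0, 1])
        p = compare_accuracy_mcnemar(a, b)
        concordant = rng.integers(0, 2, size=30)
        assert compare_accuracy_mcnemar(
            np.concatenate([a, concordant]), np.concatenate([b, concordant])
        ) == pytest.approx(p)

    def test_matches_oracle_random_counts(self, rng):
        for _ in range(200):
            b, c = rng.integers(0, 12, size=2)
            hitsA = np.concatenate([np.ones(b), np.zeros(c)]).astype(int)
            hitsB = np.concatenate([np.zeros(b), np.ones(c)]).astype(int)
            if b + c == 0:
                hitsA = hitsB = np.zeros(1, dtype=int)
            assert compare_accuracy_mcnemar(hitsA, hitsB) == pytest.approx(
                oracles.mcnemar_exact_p(int(b), int(c)) if b + c else 1.0, rel=1e-9
            )

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            compare_accuracy_mcnemar(np.array([1, 2]), np.array([0, 1]))


class TestSubgroups:
    def test_half_open_bin_assignment(self):
        spec = SubgroupSpec()
        assert list(spec.assign(np.array([29.9, 30.0, 59.9, 60.0]))) == [0, 1, 1, 2]
        assert spec.labels == ("<30", "[30,60)", ">=60")

    def test_overall_matches_direct_computation(self, toy_cohort):
        egfr = estimate_gfr_frame(toy_cohort)
        out = stratified_summary(toy_cohort, {"regression": egfr}, B=200, seed=0)
        s = out["regression"]["overall"]
        d = toy_cohort["mgfr"].to_numpy() - egfr
        assert s.n == len(toy_cohort)
        assert s.bias.value == pytest.approx(float(np.median(d)))
        q1, q3 = np.quantile(d, [0.25, 0.75])
        assert s.precision.value == pytest.approx(q3 - q1)

    def test_empty_bin_reported_not_raised(self):
        cohort = pd.DataFrame(
            {"id": ["a", "b", "c"], "age": 50.0, "sex": "male", "scr": 2.0,
             "mgfr": [35.0, 45.0, 55.0]}
        )
        out = stratified_summary(cohort, {"m": np.array([30.0, 40.0, 50.0])}, B=200, seed=0)
        assert out["m"]["<30"].n == 0 and out["m"]["<30"].bias is None
        assert out["m"]["[30,60)"].n == 3


class TestEvaluateModels:
    def test_benchmark_required(self, toy_cohort):
        with pytest.raises(ValueError):
            evaluate_models(toy_cohort, {"a": np.ones(6)}, benchmark="missing", B=200)

    def test_identical_candidate_p_values_one(self, toy_cohort):
        egfr = estimate_gfr_frame(toy_cohort)
        report = evaluate_models(
            toy_cohort, {"regression": egfr, "twin": egfr.copy()},
            benchmark="regression", B=200, seed=1,
        )
        comp = report.comparisons["twin"]["overall"]
        assert comp.p_bias == 1.0 and comp.p_accuracy == 1.0
        assert comp.p_precision > 0.5

    def test_noiseless_equation_cohort_is_perfect(self):
        """On a cohort generated exactly by the equation, the regression
        model has zero bias and spread and full P30."""
        spec = synthetic.development_spec(n=120, seed=5, noise_sigma=0.0, age_coupled=True)
        cohort = synthetic.simulate_cohort(spec)
        egfr = estimate_gfr_frame(cohort)
        report = evaluate_models(cohort, {"regression": egfr}, benchmark="regression", B=200, seed=0)
        s = report.summaries["regression"]["overall"]
        assert s.bias.value == pytest.approx(0.0, abs=1e-10)
        assert s.precision.value == pytest.approx(0.0, abs=1e-10)
        assert s.accuracy_p30.value == 1.0

    def test_precision_gain_detected_with_matched_bias(self, rng):
        """A candidate with half the error spread but identical bias and
        near-identical P30 flags only the precision comparison."""
        n = 400
        mgfr = rng.uniform(30, 90, size=n)
        noise = rng.normal(size=n)
        bench = mgfr + 12.0 * noise
        cand = mgfr + 6.0 * noise  # same error directions, half the spread
        cohort = pd.DataFrame(
            {"id": [f"i{k}" for k in range(n)], "age": 50.0, "sex": "male",
             "scr": 2.0, "mgfr": mgfr}
        )
        report = evaluate_models(
            cohort, {"bench": bench, "cand": cand}, benchmark="bench", B=500, seed=3,
        )
        comp = report.comparisons["cand"]["overall"]
        assert comp.p_precision < 0.05
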