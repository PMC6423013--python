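"""Background error rates, Wilson intervals, Beta-Binomial fit, distance test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seduplex import end_distance_test, fit_beta, panel_error_rates, wilson_ci
from seduplex.error_model import build_error_model
from seduplex.panel import BASES


def counts_frame(rows):
    """rows: (chrom, pos, ref, N, {alt: n})"""
    out = []
    for chrom, pos, ref, N, alts in rows:
        row = {"chrom": chrom, "pos": pos, "ref": ref, "N_fam": N}
        for b in BASES:
            row[f"n_{b}"] = alts.get(b, 0)
        out.append(row)
    return pd.DataFrame(out)


class TestPanelErrorRates:
    def test_pooled_rate_formula(self):
        df = counts_frame(
            [
                ("c", 1, "A", 1000, {"G": 1}),
                ("c", 2, "A", 2000, {"G": 2}),
            ]
        )
        rates = panel_error_rates(df)
        rate, lo, hi, n, N = rates["A>G"]
        assert rate == pytest.approx(3 / 3000)
        assert (n, N) == (3, 3000)
        assert lo <= rate <= hi

    def test_zero_errors_give_zero_rate_with_positive_upper_bound(self):
        df = counts_frame([("c", i, "C", 500, {}) for i in range(4)])
        rate, lo, hi, n, N = panel_error_rates(df)["C>A"]
        assert rate == 0.0
        assert lo == pytest.approx(0.0, abs=1e-12)
        assert hi > 0.0

    def test_types_without_sites_are_missing_not_zero(self):
        df = counts_frame([("c", 1, "A", 100, {})])
        rates = panel_error_rates(df)
        assert "A>G" in rates
        assert "C>A" not in rates

    def test_known_variant_sites_excluded(self):
        df = counts_frame(
            [("c", 1, "A", 1000, {"G": 50}), ("c", 2, "A", 1000, {"G": 1})]
        )
        rates = panel_error_rates(df, exclude_sites={("c", 1)})
        assert rates["A>G"][0] == pytest.approx(1 / 1000)

    def test_empty_panel_is_an_error(self):
        with pytest.raises(ValueError):
            panel_error_rates(pd.DataFrame())

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        """Pooled estimator equals naive per-site accumulation exactly."""
        for _ in range(50):
            n_sites = int(rng.integers(3, 30))
            rows = []
            for i in range(n_sites):
                ref = str(rng.choice(list(BASES)))
                N = int(rng.integers(1, 500))
                alts = {}
                budget = N
                for b in BASES:
                    if b == ref:
                        continue
                    k = int(rng.integers(0, max(1, budget // 4)))
                    alts[b] = k
                    budget -= k
                rows.append(("c", i, ref, N, alts))
            df = counts_frame(rows)
            rates = panel_error_rates(df)
            # oracle: literal loop over sites
            for ref in BASES:
                for alt in BASES:
                    if alt == ref:
                        continue
                    num = sum(r[4].get(alt, 0) for r in rows if r[2] == ref)
                    den = sum(r[3] for r in rows if r[2] == ref)
                    key = f"{ref}>{alt}"
                    if den == 0:
                        assert key not in rates
                    else:
                        assert rates[key][0] == num / den

    def test_permutation_invariance(self, rng):
        rows = [("c", i, "G", int(rng.integers(10, 100)), {"A": int(rng.integers(0, 3))})
                for i in range(20)]
        r1 = panel_error_rates(counts_frame(rows))
        rng.shuffle(rows)
        r2 = panel_error_rates(counts_frame(rows))
        assert r1 == r2


class TestWilsonCI:
    @pytest.mark.parametrize(
        "n,N,expected",
        [
            (0, 100, (0.0, 0.0370)),
            (5, 10, (0.2366, 0.7634)),
            (100, 100, (0.9630, 1.0)),
        ],
    )
    def test_closed_form_values(self, n, N, expected):
        lo, hi = wilson_ci(n, N)
        assert lo == pytest.approx(expected[0], abs=2e-4)
        assert hi == pytest.approx(expected[1], abs=2e-4)

    def test_symmetry_about_half(self):
        lo, hi = wilson_ci(5, 10)
        assert lo + hi == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)

    @given(N=st.integers(1, 10_000), frac=st.floats(0, 1))
    @settings(derandomize=True, max_examples=80)
    def test_interval_contains_point_estimate(self, N, frac):
        n = int(round(frac * N))
        lo, hi = wilson_ci(n, N)
        assert lo - 1e-12 <= n / N <= hi + 1e-12

    def test_width_shrinks_with_depth(self):
        widths = []
        for N in (10, 100, 1000, 10_000):
            lo, hi = wilson_ci(N // 10, N)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)


class TestBetaBinomialFit:
    def test_recovers_simulated_mean(self, rng):
        a, b = 2.0, 40_000.0
        N = np.full(1500, 20_000)
        p = rng.beta(a, b, size=len(N))
        n = rng.binomial(N, p)
        fit = fit_beta(n, N)
        assert fit.status == "OK"
        truth_mean = a / (a + b)
        assert fit.mean == pytest.approx(truth_mean, rel=0.2)

    def test_fitted_mean_consistent_with_pooled_rate(self, rng):
        N = np.full(800, 10_000)
        p = rng.beta(1.5, 20_000, size=len(N))
        n = rng.binomial(N, p)
        fit = fit_beta(n, N)
        pooled = n.sum() / N.sum()
        assert fit.mean == pytest.approx(pooled, rel=0.1)

    def test_all_zero_counts_flagged_undetermined(self):
        fit = fit_beta(np.zeros(50, int), np.full(50, 1000))
        assert fit.status == "UNDETERMINED"

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            fit_beta(np.ones(5, int), np.full(5, 100))


class TestEndDistanceTest:
    def test_identical_groups_give_half(self):
        assert end_distance_test([1.0, 2, 3], [1.0, 2, 3]) == pytest.approx(0.5)

    def test_textbook_welch_value(self):
        # one-sided Welch t on {1,2,3} vs {4,5,6}: t=-3.674, df=4
        p = end_distance_test([1.0, 2, 3], [4.0, 5, 6])
        assert p == pytest.approx(0.01066, abs=5e-4)

    def test_degenerate_equal_constant_groups(self):
        assert end_distance_test([2.0, 2.0], [2.0, 2.0]) == 0.5

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            end_distance_test([1.0], [1.0, 2.0])


class TestBuildErrorModel:
    def test_fits_dominant_type_profile(self, rng):
        rows = []
        for i in range(400):
            N = 2000
            p = rng.beta(2.0, 40_000)
            rows.append(("c", i, "G", N, {"A": int(rng.binomial(N, p))}))
        em = build_error_model(counts_frame(rows))
        assert em.fit_status == "OK"
        assert em.mean == pytest.approx(5e-5, rel=0.5)
        assert "G>A" in em.mean_rate_per_type

    def test_roundtrip_json(self, rng, tmp_path):
        rows = [("c", i, "G", 1000, {"A": int(rng.integers(0, 2))}) for i in range(30)]
        em = build_error_model(counts_frame(rows))
        path = tmp_path / "model.json"
        em.to_json(path)
        from seduplex import ErrorDistribution

        back = ErrorDistribution.from_json(path)
        assert back.beta_alpha == pytest.approx(em.beta_alpha)
        assert back.mean_rate_per_type == em.mean_rate_per_type
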