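"""Pearson formula, phase-shift scan, rejection and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oculopulse import (
    PhaseCouplingScan,
    generate_cohort,
    pearson_r,
    pooled_max_correlation,
    records_to_dataframe,
    reject_outliers,
    scan_phase_shifts,
    shift_phase,
    significance,
)
from oculopulse import datasets
from oculopulse.exceptions import EmptyRetainedSetError, UndefinedCorrelationError


def brute_force_r(x, y):
    """Direct term-by-term evaluation of the centred-sum correlation formula."""
    k = len(x)
    mx = sum(x) / k
    my = sum(y) / k
    num = sum((x[i] - mx) * (y[i] - my) for i in range(k))
    den = (sum((x[i] - mx) ** 2 for i in range(k)) * sum((y[i] - my) ** 2 for i in range(k))) ** 0.5
    return num / den


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        """x=(1..6), y=(2,1,4,3,6,5): centred sums give 14.5/17.5 = 29/35."""
        assert pearson_r([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5]) == pytest.approx(29 / 35, abs=1e-12)

    def test_matches_bruteforce_and_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(3, 12))
            x = rng.normal(size=k)
            y = rng.normal(size=k)
            r = pearson_r(x, y)
            assert r == pytest.approx(brute_force_r(list(x), list(y)), abs=1e-12)
            assert r == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])


class TestShiftPhase:
    def test_wraparound_and_identities(self):
        assert shift_phase([350.0], 30.0)[0] == pytest.approx(20.0)
        assert np.allclose(shift_phase([10.0, 200.0], 0.0), [10.0, 200.0])
        assert np.allclose(shift_phase([10.0, 200.0], 360.0), [10.0, 200.0])


class TestSignificance:
    def test_zero_correlation_is_chance(self):
        assert significance(0.0, 6) == pytest.approx(1.0)

    def test_strong_correlation_significant_at_k6(self):
        assert significance(0.95, 6) < 0.05

    def test_critical_value_at_df4(self):
        """r = 0.811 with K = 6 sits at the two-sided 5 % boundary."""
        assert significance(0.811, 6) == pytest.approx(0.05, abs=0.005)

    def test_perfect_correlation_limit(self):
        assert significance(1.0, 6) == 0.0


class TestScan:
    phases = (np.arange(6) * 60.0 + 25.0) % 360.0

    def test_self_correlation_reaches_unity_on_inverse_shift_plateau(self):
        """Correlating the shifted phase against itself: r = 1, and the
        inverse shift lies on the maximal plateau (r is constant between
        wrap events, so the whole plateau attains 1)."""
        feature = shift_phase(self.phases, 40.0)
        scan = scan_phase_shifts(feature, self.phases)
        assert scan.r_max == pytest.approx(1.0, abs=1e-12)
        # at phi = 40 the shifted phases reproduce the feature exactly
        i = np.flatnonzero(scan.phi_grid_deg == 40.0)[0]
        assert scan.r_of_phi[i] == pytest.approx(1.0, abs=1e-12)
        # and the reported optimum lies on the r = 1 plateau
        j = np.flatnonzero(scan.phi_grid_deg == scan.phi_max_deg)[0]
        assert scan.r_of_phi[j] == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetry_for_sinusoidal_features(self):
        """For uniformly spaced phases and any first-harmonic feature,
        r(phi+180) = -r(phi) across the grid, so the scan minimum mirrors the
        maximum 180 degrees away."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            delta = rng.uniform(0, 360)
            v = rng.uniform(0.5, 3) * np.cos(np.deg2rad(self.phases - delta)) + rng.normal(10, 1)
            scan = scan_phase_shifts(v, self.phases)
            r = scan.r_of_phi
            assert np.nanmax(np.abs(np.roll(r, -18) + r)) < 1e-12
            assert scan.r_min == pytest.approx(-scan.r_max, abs=1e-12)
            assert (scan.phi_min_deg - scan.phi_max_deg) % 360 == pytest.approx(180.0)

    def test_noiseless_cosine_recovers_generative_shift(self):
        """With noise off, the scan optimum matches the shift implied by the
        injected cosine peak within one grid step."""
        from oculopulse import peak_phase_to_shift

        rng = np.random.default_rng(5)
        for peak in (0.0, 60.0, 210.0, 300.0):
            phases = (rng.uniform(0, 360) + np.arange(6) * 60.0) % 360.0
            v = 15 + 0.75 * np.cos(np.deg2rad(phases - peak))
            scan = scan_phase_shifts(v, phases)
            expected = peak_phase_to_shift(peak)
            d = abs((scan.phi_max_deg - expected + 180) % 360 - 180)
            assert d <= 30.0  # within the plateau containing the optimum

    def test_shift_equivariance(self):
        """Rotating all measurement phases by delta moves the optimum shift by
        -delta and leaves r_max unchanged."""
        rng = np.random.default_rng(9)
        v = rng.normal(15, 1, 6)
        base = scan_phase_shifts(v, self.phases)
        delta = 40.0
        moved = scan_phase_shifts(v, shift_phase(self.phases, delta))
        assert moved.r_max == pytest.approx(base.r_max, abs=1e-12)
        assert (moved.phi_max_deg + delta) % 360 == pytest.approx(base.phi_max_deg % 360)

    def test_constant_feature_undefined_everywhere(self):
        with pytest.raises(UndefinedCorrelationError):
            scan_phase_shifts(np.full(6, 15.0), self.phases)


class TestRejection:
    def test_reference_extrema_rejection_counts(self):
        """On the reference cohort's extrema: the thick-error preset keeps 9
        of 10 subjects, the strict preset 7, a zero threshold all 10."""
        extrema = datasets.load_scan_extrema()
        max_abs = dict(zip(extrema["subject"], extrema["r_max"].abs()))
        assert len(reject_outliers(max_abs, "thick")[0]) == 9
        assert len(reject_outliers(max_abs, "strict")[0]) == 7
        assert len(reject_outliers(max_abs, 0.0)[0]) == 10

    def test_all_rejected_raises(self):
        with pytest.raises(EmptyRetainedSetError):
            reject_outliers({1: 0.1, 2: 0.2}, "thick")


@pytest.fixture(scope="module")
def fitted():
    records, _ = generate_cohort(10, 6, seed=1, mode="fast")
    model = PhaseCouplingScan(records_to_dataframe(records))
    return model.fit()


class TestModelResults:
    def test_feature_table_matches_direct_statistics(self, fitted):
        df = fitted.data
        sub1 = df[df["subject"] == 1]["w5_mmHg"]
        row = fitted.feature_table.set_index("subject").loc[1]
        assert row["w5_mmHg_mean"] == pytest.approx(sub1.mean())
        assert row["w5_mmHg_std"] == pytest.approx(sub1.std(ddof=1))

    def test_pooled_summary_uses_retained_subjects_only(self, fitted):
        tab = fitted.corr_extrema.set_index("subject")
        kept = tab.loc[fitted.retained, "r_max"].to_numpy()
        assert fitted.pooled_r_mean == pytest.approx(kept.mean())
        assert fitted.pooled_r_std_population == pytest.approx(kept.std(ddof=0))

    def test_summary_text_reports_key_quantities(self, fitted):
        text = fitted.summary()
        assert "Phase-coupling scan summary" in text
        assert "max correlation" in text and "optimum shift" in text

    def test_refit_is_deterministic(self, fitted):
        records, _ = generate_cohort(10, 6, seed=1, mode="fast")
        again = PhaseCouplingScan(records_to_dataframe(records)).fit()
        pd.testing.assert_frame_equal(fitted.extrema, again.extrema, check_exact=True)

    def test_subjects_with_too_few_measurements_rejected(self):
        records, _ = generate_cohort(2, 6, seed=0, mode="fast")
        df = records_to_dataframe(records).iloc[:8]  # second subject has 2 rows
        with pytest.raises(ValueError):
            PhaseCouplingScan(df)


class TestPooledMaxCorrelation:
    def test_single_retained_subject_flags_sample_std(self):
        extrema = pd.DataFrame({"subject": [1, 2], "r_max": [0.9, 0.1]})
        pool = pooled_max_correlation(extrema, "thick")
        assert pool["n_retained"] == 1
        assert np.isnan(pool["std_sample"])
        assert pool["std_population"] == 0.0
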