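"""Baseline normalization, washout recovery, t-test, and force conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from needlebeat.response import (
    ForceUnavailableError,
    NeedleProperties,
    TimepointSummary,
    compare_groups,
    force_from_deflection,
    normalize_to_baseline,
    washout_recovery,
)


def _series(amps, labels=None, rates=None):
    n = len(amps)
    labels = labels or (["baseline"] + [f"t{i}" for i in range(1, n)])
    rates = rates or [6.0] * n
    return [
        TimepointSummary(label=lab, time_s=60.0 * i, beats_per_10s=r, mean_amplitude_px=a)
        for i, (lab, a, r) in enumerate(zip(labels, amps, rates))
    ]


class TestNormalizeToBaseline:
    def test_baseline_maps_to_exactly_one(self):
        tc = normalize_to_baseline(_series([7.3, 9.1, 7.5]))
        assert tc.timepoints[0].normalized_amplitude == 1.0

    def test_isoproterenol_like_rise_then_washout_return(self):
        """Amplitude x1.5 under drug, drifting back toward baseline after washout."""
        tps = _series(
            [8.0, 12.0, 10.4, 8.3],
            labels=["baseline", "drug", "washout", "post"],
            rates=[6.0, 9.0, 7.0, 6.0],
        )
        tc = normalize_to_baseline(tps)
        by_label = {tp.label: tp for tp in tc.timepoints}
        assert by_label["drug"].normalized_amplitude == pytest.approx(1.5)
        assert by_label["drug"].beats_per_10s == 9.0  # rates pass through unnormalized
        recovered, t_rec = washout_recovery(tc)
        assert recovered and t_rec == by_label["post"].time_s

    def test_blebbistatin_like_amplitude_loss_with_stable_rate(self):
        """Amplitude x0.3 while beats/10 s stays at baseline."""
        tps = _series([8.0, 2.4], labels=["baseline", "drug"], rates=[6.0, 6.0])
        tc = normalize_to_baseline(tps)
        drug = tc.timepoints[-1]
        assert drug.normalized_amplitude == pytest.approx(0.3)
        assert drug.beats_per_10s == 6.0

    def test_no_beats_timepoint_maps_to_zero(self):
        """Contraction arrest (72 h cardiotoxicity endpoint) is amplitude 0."""
        tps = _series([8.0, 4.0])
        tps.append(TimepointSummary("72h", 72 * 3600.0, 0.0, None))
        tc = normalize_to_baseline(tps)
        assert tc.timepoints[-1].normalized_amplitude == 0.0

    def test_zero_baseline_is_undefined(self):
        tps = _series([0.0, 4.0])
        with pytest.raises(ValueError, match="undefined"):
            normalize_to_baseline(tps)

    def test_normalization_is_idempotent(self):
        tc = normalize_to_baseline(_series([8.0, 12.0, 6.0]))
        again = normalize_to_baseline(
            [
                TimepointSummary(tp.label, tp.time_s, tp.beats_per_10s, tp.normalized_amplitude)
                for tp in tc.timepoints
            ]
        )
        np.testing.assert_allclose(again.normalized_amplitudes, tc.normalized_amplitudes)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    def test_scale_invariance(self, scale):
        """Multiplying all raw amplitudes by c > 0 leaves the time course unchanged."""
        amps = [8.0, 12.0, 2.4, 7.9]
        base = normalize_to_baseline(_series(amps))
        scaled = normalize_to_baseline(_series([a * scale for a in amps]))
        np.testing.assert_allclose(
            scaled.normalized_amplitudes, base.normalized_amplitudes, rtol=1e-12
        )


class TestWashoutRecovery:
    def test_series_ending_at_baseline_recovers(self):
        tc = normalize_to_baseline(
            _series([8.0, 2.0, 8.0], labels=["baseline", "drug", "washout"])
        )
        recovered, t = washout_recovery(tc)
        assert recovered and t == tc.timepoints[-1].time_s

    def test_monotone_decline_never_recovers(self):
        """Doxorubicin-like irreversible decline: no post-washout return."""
        tc = normalize_to_baseline(
            _series([8.0, 4.0, 2.0, 0.5], labels=["baseline", "t1", "washout", "t3"])
        )
        recovered, t = washout_recovery(tc)
        assert not recovered and t is None

    def test_infinite_band_recovers_at_first_post_washout_point(self):
        tc = normalize_to_baseline(
            _series([8.0, 2.0, 3.0], labels=["baseline", "drug", "washout"])
        )
        recovered, t = washout_recovery(tc, band=np.inf)
        assert recovered and t == tc.timepoints[2].time_s


def _pooled_t_oracle(a, b):
    """Closed-form pooled-variance two-sample t statistic and two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb_ = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb_ - 1) * b.var(ddof=1)) / (na + nb_ - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb_))
    p = 2 * tdist.sf(abs(t), na + nb_ - 2)
    return t, p


class TestCompareGroups:
    def test_identical_groups_give_t0_p1(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert not res.significant_05

    def test_separated_groups_significant_at_01(self):
        a, b = [0.1, 0.2, 0.15], [1.0, 1.1, 0.9]
        res = compare_groups(a, b)
        t_ref, p_ref = _pooled_t_oracle(a, b)
        assert res.t == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)
        assert res.p < 0.01 and res.significant_01

    def test_zero_variance_cases(self):
        same = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0])
        assert same.p == 1.0
        apart = compare_groups([2.0, 2.0, 2.0], [5.0, 5.0])
        assert apart.p == 0.0 and apart.significant_01

    def test_matches_permutation_test_decisions(self):
        """Significance at alpha=0.05 agrees with a permutation oracle >= 95% of cells.

        Grid: clearly separated pairs and identical-distribution pairs, fixed
        seeds, n=6 per group, 4000 label permutations.
        """
        rng = np.random.default_rng(1234)

        def perm_p(a, b, n_perm=4000):
            pooled = np.concatenate([a, b])
            obs = abs(a.mean() - b.mean())
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                if abs(perm[: len(a)].mean() - perm[len(a):].mean()) >= obs - 1e-12:
                    count += 1
            return (count + 1) / (n_perm + 1)

        agree = total = 0
        for delta in [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 3.0, 3.0, 4.0, 4.0, 5.0, 5.0]:
            a = rng.normal(0.0, 1.0, 6)
            b = rng.normal(delta, 1.0, 6)
            t_sig = compare_groups(a, b).significant_05
            p_sig = perm_p(a, b) < 0.05
            agree += int(t_sig == p_sig)
            total += 1
        assert agree / total >= 0.95

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestForceFromDeflection:
    def test_zero_deflection_zero_force(self):
        needle = NeedleProperties(200e9, 0.2e-3, 10e-3)
        assert force_from_deflection(0.0, needle, pixel_size_um=1.0) == 0.0

    def test_matches_closed_form_cantilever(self):
        """F = 3 E I delta / L^3 with I = pi d^4 / 64 for a steel-like needle."""
        E, d, L, delta = 200e9, 0.2e-3, 10e-3, 10e-6
        needle = NeedleProperties(E, d, L)
        expected = 3 * E * (math.pi * d**4 / 64) * delta / L**3
        got = force_from_deflection(delta, needle, deflection_in_px=False)
        assert got == pytest.approx(expected, rel=1e-12)
        # same via pixel units
        got_px = force_from_deflection(10.0, needle, pixel_size_um=1.0)
        assert got_px == pytest.approx(expected, rel=1e-12)

    def test_missing_property_is_unavailable(self):
        needle = NeedleProperties(youngs_modulus_pa=None, diameter_m=0.2e-3, free_length_m=10e-3)
        with pytest.raises(ForceUnavailableError, match="youngs_modulus"):
            force_from_deflection(5.0, needle, pixel_size_um=1.0)
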