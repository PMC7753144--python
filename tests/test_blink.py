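"""Tests of the blinking-statistics counting core.

Independent oracles used here:

* brute-force convolution of geometric pmfs for multi-emitter appearance counts;
* numeric root-finding on d_to_q for the q -> d conversion;
* Monte-Carlo simulation of labeled/detected protomers for the dimer pmf and
  the detectability correction.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmkit import (
    BlinkHistogram,
    DataError,
    DomainError,
    LocalizationTable,
    ParameterError,
    absolute_detection,
    bootstrap_ci,
    cluster_events,
    d_to_q,
    extract_appearances,
    fit_mixture,
    fit_p,
    fit_q,
    observed_dimer_fraction,
    pmf_appearances,
    pmf_dimer,
    q_to_d,
    true_dimer_fraction,
)
from palmkit.blink import AppearanceEvent
from palmkit.simulate import sim_blink_counts, sim_localization_field

from conftest import make_config


def geometric_pmf(n, p):
    return p * (1 - p) ** (n - 1)


def convolved_pmf(n, m, p):
    """Oracle: brute-force convolution of m geometric counts."""
    if m == 1:
        return geometric_pmf(n, p)
    return sum(geometric_pmf(k, p) * convolved_pmf(n - k, m - 1, p)
               for k in range(1, n - m + 2))


class TestPmfAppearances:
    @pytest.mark.parametrize("n,m,p,expected", [
        (1, 1, 0.27, 0.27),              # geometric first term
        (2, 2, 0.5, 0.25),               # p^2, single arrangement
        (3, 2, 0.27, 0.106434),          # enumeration oracle value
    ])
    def test_known_values(self, n, m, p, expected):
        assert pmf_appearances(n, m, p) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("p", [0.05, 0.27, 0.34, 0.9])
    def test_matches_convolution_oracle(self, m, p):
        for n in range(m, m + 12):
            assert pmf_appearances(n, m, p) == pytest.approx(convolved_pmf(n, m, p), rel=1e-9)

    @pytest.mark.parametrize("m,p", [(1, 0.27), (2, 0.27), (2, 0.05), (3, 0.34)])
    def test_normalizes(self, m, p):
        ns = np.arange(m, 501)
        assert pmf_appearances(ns, m, p).sum() == pytest.approx(1.0, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            pmf_appearances(1, 2, 0.5)
        with pytest.raises(ParameterError):
            pmf_appearances(1, 1, 0.0)


class TestPmfDimer:
    def test_single_appearance_value(self):
        q = d_to_q(0.64)
        assert q == pytest.approx(0.529412, abs=1e-6)
        # only the single-emitter branch can produce n = 1
        assert pmf_dimer(1, 0.27, q) == pytest.approx(q * 0.27, abs=1e-9)
        assert pmf_dimer(1, 0.27, q) == pytest.approx(0.142938, abs=1e-5)

    def test_q_zero_needs_two_appearances(self):
        assert pmf_dimer(1, 0.27, 0.0) == 0.0

    def test_q_one_limit_is_monomer(self):
        ns = np.arange(1, 30)
        np.testing.assert_allclose(pmf_dimer(ns, 0.27, 1.0 - 1e-12),
                                   pmf_appearances(ns, 1, 0.27), rtol=1e-6)

    def test_matches_monte_carlo_oracle(self, rng):
        """TV distance < 0.01 against 1e5 draws of the generative process."""
        p, d = 0.27, 0.64
        q = d_to_q(d)
        n_samp = 100_000
        det = rng.binomial(2, d, n_samp * 2)
        det = det[det >= 1][:n_samp]
        counts = rng.geometric(p, n_samp) + np.where(det == 2, rng.geometric(p, n_samp), 0)
        emp = np.bincount(counts, minlength=101)[1:101] / n_samp
        model = pmf_dimer(np.arange(1, 101), p, q)
        assert 0.5 * np.abs(emp - model).sum() < 0.01


class TestDetectionConversion:
    @pytest.mark.parametrize("q,d", [(0.35, 0.7879), (0.0, 1.0), (0.39, 0.757764)])
    def test_q_to_d_values(self, q, d):
        assert q_to_d(q) == pytest.approx(d, abs=1e-4)

    def test_printed_pair_rounds_to_79_percent(self):
        assert round(q_to_d(0.35) * 100) == 79

    def test_q_to_d_matches_root_finding_oracle(self):
        from scipy.optimize import brentq
        for q in (0.1, 0.35, 0.39, 0.7):
            d_oracle = brentq(lambda d: d_to_q(d) - q, 1e-9, 1.0)
            assert q_to_d(q) == pytest.approx(d_oracle, abs=1e-9)

    @given(d=st.floats(min_value=1e-6, max_value=1.0))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, d):
        assert q_to_d(d_to_q(d)) == pytest.approx(d, abs=1e-12)

    def test_d_to_q_monte_carlo(self, rng):
        """q = P(exactly one of two Bernoulli(d) labels | >= 1 detected)."""
        d = 0.64
        det = rng.binomial(2, d, 200_000)
        det = det[det >= 1]
        assert (det == 1).mean() == pytest.approx(d_to_q(d), abs=0.005)

    @pytest.mark.parametrize("d,L,expected", [(0.79, 0.81, 0.64), (0.5, 1.0, 0.5), (1.0, 1.0, 1.0)])
    def test_absolute_detection(self, d, L, expected):
        assert round(absolute_detection(d, L), 2) == pytest.approx(expected)

    def test_range_errors(self):
        with pytest.raises(ParameterError):
            q_to_d(1.0)
        with pytest.raises(ParameterError):
            d_to_q(0.0)
        with pytest.raises(ParameterError):
            absolute_detection(1.2, 0.5)


class TestDetectabilityCorrection:
    def test_closed_form_example(self):
        assert observed_dimer_fraction(0.71, 0.64) == pytest.approx(0.7690, abs=1e-4)

    def test_inverse(self):
        for f in (0.05, 0.3, 0.71, 0.95):
            assert true_dimer_fraction(observed_dimer_fraction(f, 0.64), 0.64) == pytest.approx(f, abs=1e-12)

    def test_monte_carlo(self, rng):
        f_true, d_abs = 0.71, 0.64
        sizes = (rng.random(200_000) < f_true) + 1
        det = rng.binomial(sizes, d_abs)
        obs_dimer = (sizes[det >= 1] == 2).mean()
        assert obs_dimer == pytest.approx(observed_dimer_fraction(f_true, d_abs), abs=0.01)


class TestExtractAppearances:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["frame", "x", "y"])
        return LocalizationTable(data=df)

    def test_contiguous_burst_is_one_event(self):
        t = self._table([(1, 0.0, 0.0), (2, 1.0, 0.0), (3, 0.0, 1.0)])
        events = extract_appearances(t, max_dark_frames=1, merge_radius=30.0)
        assert len(events) == 1
        assert events[0].n_locs == 3

    def test_long_gap_splits_events(self):
        t = self._table([(1, 0.0, 0.0), (10, 0.0, 0.0)])
        events = extract_appearances(t, max_dark_frames=3, merge_radius=30.0)
        assert len(events) == 2

    def test_distant_localizations_split(self):
        t = self._table([(1, 0.0, 0.0), (2, 500.0, 0.0)])
        events = extract_appearances(t, max_dark_frames=3, merge_radius=30.0)
        assert len(events) == 2

    def test_simulated_train_ground_truth(self):
        table, truth = sim_localization_field(make_config(seed=7))
        events = extract_appearances(table, max_dark_frames=3, merge_radius=30.0)
        assert len(events) == truth.clusters["n_appearances"].sum()

    def test_negative_params(self):
        t = self._table([(0, 0.0, 0.0)])
        with pytest.raises(ParameterError):
            extract_appearances(t, max_dark_frames=-1, merge_radius=30.0)


class TestClusterEvents:
    def _events(self, positions):
        return [AppearanceEvent(0, 0, x, y, 1) for x, y in positions]

    def test_nearby_events_merge(self):
        clusters = cluster_events(self._events([(0, 0), (5, 0)]), eps=50.0)
        assert len(clusters) == 1
        assert clusters[0].n == 2

    def test_distant_events_split(self):
        clusters = cluster_events(self._events([(0, 0), (500, 0)]), eps=50.0)
        assert len(clusters) == 2

    def test_recovers_simulated_cluster_count(self):
        table, truth = sim_localization_field(make_config(seed=8))
        events = extract_appearances(table, 3, 30.0)
        clusters = cluster_events(events, eps=50.0, min_events=1)
        n_true = len(truth.clusters)
        assert abs(len(clusters) - n_true) / n_true < 0.05

    def test_bad_eps(self):
        with pytest.raises(ParameterError):
            cluster_events(self._events([(0, 0)]), eps=0.0)


class TestFitP:
    def test_closed_form_inverse_mean(self):
        hist = BlinkHistogram.from_counts([1, 3, 1, 3])  # mean 2
        assert fit_p(hist, B=100).value == pytest.approx(0.5)

    def test_no_blinking(self):
        hist = BlinkHistogram.from_counts([1] * 50)
        assert fit_p(hist, B=100).value == 1.0

    def test_recovers_simulated_p(self):
        cfg = make_config(seed=3, photophysics={"p": 0.34, "d": 0.79, "L": 0.81},
                          population={"density": 0.63, "dimer_fraction": 0.0})
        hist, _ = sim_blink_counts(10_000, cfg)
        fit = fit_p(hist, B=200, seed=0)
        assert fit.value == pytest.approx(0.34, abs=0.01)
        # bootstrap SD at n = 10,000 should sit at the analytic scale
        # p^2 sqrt(1-p) / (p sqrt(n)) ~ 0.003
        assert 0.001 < fit.sd < 0.01

    def test_empty_histogram(self):
        with pytest.raises(DataError):
            fit_p(BlinkHistogram(counts=np.zeros(50)))


class TestFitQ:
    def test_self_consistency_on_exact_histogram(self):
        ns = np.arange(1, 51)
        counts = pmf_dimer(ns, 0.27, 0.35) * 1e6
        fit = fit_q(BlinkHistogram(counts=counts), p=0.27, B=100)
        assert fit.value == pytest.approx(0.35, abs=1e-6)

    def test_all_singletons_hits_boundary(self):
        hist = BlinkHistogram.from_counts([1] * 100)
        fit = fit_q(hist, p=0.27, B=100)
        assert fit.at_boundary
        assert not fit.converged

    def test_recovers_simulated_q(self):
        # pure dimers at absolute detection 0.64: q should come out near 0.5294
        cfg = make_config(seed=4, photophysics={"p": 0.27, "d": 0.64, "L": 1.0},
                          population={"density": 0.63, "dimer_fraction": 1.0})
        hist, _ = sim_blink_counts(5_000, cfg)
        fit = fit_q(hist, p=0.27, B=200, seed=0)
        assert fit.value == pytest.approx(d_to_q(0.64), abs=0.02)


class TestFitMixture:
    def test_self_consistency_observed_weight(self):
        ns = np.arange(1, 51)
        q = d_to_q(0.64)
        mono = pmf_appearances(ns, 1, 0.27)
        dim = pmf_dimer(ns, 0.27, q)
        counts = (0.5 * dim / dim.sum() + 0.5 * mono / mono.sum()) * 1e6
        fit = fit_mixture(BlinkHistogram(counts=counts), p=0.27, d_abs=0.64, B=100)
        assert fit.fractions_observed[1] == pytest.approx(0.5, abs=1e-6)

    def test_fractions_sum_to_one(self):
        hist = BlinkHistogram.from_counts([1, 2, 3, 4, 2, 1])
        fit = fit_mixture(hist, p=0.27, d_abs=0.64, B=100)
        assert sum(fit.fractions) == pytest.approx(1.0, abs=1e-9)
        assert sum(fit.fractions_observed) == pytest.approx(1.0, abs=1e-9)

    def test_unbiased_recovery_at_cramer_rao_spread(self):
        """Mean over replicates recovers the truth; spread matches the
        information bound (sd ~ 0.035 at 5,000 clusters for 71% dimers)."""
        ests = []
        for seed in range(20):
            cfg = make_config(seed=100 + seed,
                              photophysics={"p": 0.27, "d": 0.64, "L": 1.0},
                              population={"density": 0.63, "dimer_fraction": 0.71})
            hist, _ = sim_blink_counts(5_000, cfg)
            fit = fit_mixture(hist, p=0.27, d_abs=0.64, B=100, seed=0)
            ests.append(fit.fractions[1])
        ests = np.asarray(ests)
        assert ests.mean() == pytest.approx(0.71, abs=3 * 0.035 / np.sqrt(len(ests)))
        assert 0.015 < ests.std() < 0.07

    def test_least_squares_objective_agrees(self):
        cfg = make_config(seed=5, photophysics={"p": 0.27, "d": 0.64, "L": 1.0},
                          population={"density": 0.63, "dimer_fraction": 0.5})
        hist, _ = sim_blink_counts(5_000, cfg)
        mle = fit_mixture(hist, 0.27, 0.64, B=100, objective="mle")
        ls = fit_mixture(hist, 0.27, 0.64, B=100, objective="ls")
        assert mle.fractions[1] == pytest.approx(ls.fractions[1], abs=0.08)


class TestBootstrap:
    def test_degenerate_histogram_zero_width(self):
        counts = np.zeros(50)
        counts[2] = 40
        hist = BlinkHistogram(counts=counts)
        ci, sd = bootstrap_ci(hist, lambda h: h.mean, B=200, seed=1)
        assert ci[0] == ci[1]
        assert sd == 0.0

    def test_deterministic_given_seed(self):
        hist = BlinkHistogram.from_counts([1, 2, 2, 3, 4, 5, 1, 2])
        a = bootstrap_ci(hist, lambda h: h.mean, B=200, seed=7)
        b = bootstrap_ci(hist, lambda h: h.mean, B=200, seed=7)
        assert a == b

    def test_b_too_small(self):
        hist = BlinkHistogram.from_counts([1, 2])
        with pytest.raises(ParameterError):
            bootstrap_ci(hist, lambda h: h.mean, B=50)

    def test_p_interval_coverage(self):
        """Bootstrap CIs achieve near-nominal coverage for the geometric fit."""
        p_true, hits, n_rep = 0.34, 0, 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            hist = BlinkHistogram.from_counts(rng.geometric(p_true, 2000))
            fit = fit_p(hist, B=150, seed=seed)
            hits += fit.ci[0] <= p_true <= fit.ci[1]
        assert hits >= 0.90 * n_rep

    def test_mixture_interval_coverage(self):
        f_true, hits, n_rep = 0.71, 0, 40
        for seed in range(n_rep):
            cfg = make_config(seed=2000 + seed,
                              photophysics={"p": 0.27, "d": 0.64, "L": 1.0},
                              population={"density": 0.63, "dimer_fraction": f_true})
            hist, _ = sim_blink_counts(2_000, cfg)
            fit = fit_mixture(hist, 0.27, 0.64, B=120, seed=seed)
            lo, hi = fit.ci["dimer_true"]
            hits += lo <= f_true <= hi
        assert hits >= 0.90 * n_rep
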