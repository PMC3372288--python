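"""Spacing histogram, detrending and the normalised periodicity spectrum."""

import io

import numpy as np
import pytest

from perioscan import fixtures
from perioscan.spectrum import (
    DegenerateInput,
    ProcessedSpacing,
    SpacingHistogram,
    count_pair_spacings,
    expected_pair_counts,
    normalize_and_detrend,
    perplot,
    power_spectrum,
    write_spectrum_tsv,
)
from perioscan.tracts import (
    TractOccurrenceSet,
    build_method,
    find_tracts,
    reverse_complement,
)

from conftest import random_sequence

A2T2 = build_method("A2T2")


def occ_from(positions, L, method=A2T2):
    return TractOccurrenceSet(method=method, positions=np.asarray(positions), seq_length=L)


def brute_pair_count(positions, s_hist_max):
    """O(m^2) double-loop oracle for N(s)."""
    counts = np.zeros(s_hist_max, dtype=int)
    pos = list(positions)
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            s = pos[j] - pos[i]
            if 1 <= s <= s_hist_max:
                counts[s - 1] += 1
    return counts


class TestCountPairSpacings:
    def test_three_positions(self):
        hist = count_pair_spacings(occ_from([0, 10, 21], 100), s_hist_max=30)
        expected = {10: 1, 11: 1, 21: 1}
        for s in range(1, 31):
            assert hist.n_of(s) == expected.get(s, 0)

    def test_empty_and_singleton_give_zero(self):
        for positions in ([], [5]):
            hist = count_pair_spacings(occ_from(positions, 100), s_hist_max=20)
            assert hist.counts.sum() == 0

    def test_matches_double_loop_oracle(self, rng):
        seq = random_sequence(rng, 5000)
        occ = find_tracts(seq, A2T2)
        hist = count_pair_spacings(occ, s_hist_max=101)
        np.testing.assert_array_equal(
            hist.counts, brute_pair_count(occ.positions, 101)
        )

    def test_total_bounded_by_all_pairs(self, rng):
        seq = random_sequence(rng, 3000)
        occ = find_tracts(seq, A2T2)
        hist = count_pair_spacings(occ, s_hist_max=200)
        m = len(occ)
        assert hist.counts.sum() <= m * (m - 1) // 2


def synthetic_hist(values, m=1000, L=100_000, s_hist_max=101):
    """Histogram whose normalised counts n(s) equal `values(s)` exactly."""
    s = np.arange(1, s_hist_max + 1)
    counts = values(s) * expected_pair_counts(m, L, s)
    return SpacingHistogram(counts=counts, m=m, L=L, method=A2T2)


class TestNormalizeAndDetrend:
    def test_counts_equal_expectation_give_zero(self):
        hist = synthetic_hist(lambda s: np.ones_like(s, dtype=float))
        ps = normalize_and_detrend(hist, 30, 100)
        np.testing.assert_allclose(ps.y, 0.0, atol=1e-12)

    @pytest.mark.parametrize("a, b", [(0.01, 0.0), (0.0, 1e-4), (-0.02, 3e-4)])
    def test_quadratic_trends_absorbed(self, a, b):
        hist = synthetic_hist(lambda s: 1.0 + a * s + b * s**2)
        ps = normalize_and_detrend(hist, 30, 100)
        np.testing.assert_allclose(ps.y, 0.0, atol=1e-9)

    def test_cosine_on_linear_trend_recovered(self):
        # independent oracle: smooth then polyfit-and-subtract by hand
        hist = synthetic_hist(
            lambda s: 1.0 + 0.005 * s + 0.1 * np.cos(2 * np.pi * s / 10.0)
        )
        ps = normalize_and_detrend(hist, 30, 100)
        s_ext = np.arange(29, 102)
        n = hist.counts[28:101] / expected_pair_counts(hist.m, hist.L, s_ext)
        sm = (n[:-2] + n[1:-1] + n[2:]) / 3.0
        s = np.arange(30, 101)
        oracle = sm - np.polyval(np.polyfit(s, sm, 2), s)
        np.testing.assert_allclose(ps.y, oracle, atol=1e-12)
        # the smoothed cosine keeps its period: dominant residual frequency at 10 bp
        sp = power_spectrum(ps)
        assert sp.p_max_q == pytest.approx(10.0, abs=0.05)

    def test_residual_mean_is_zero(self, rng):
        seq = random_sequence(rng, 20000)
        occ = find_tracts(seq, A2T2)
        ps = normalize_and_detrend(count_pair_spacings(occ, 101), 30, 100)
        assert abs(ps.y.mean()) < 1e-12

    def test_fewer_than_two_occurrences_degenerate(self):
        hist = SpacingHistogram(
            counts=np.zeros(101, dtype=int), m=1, L=1000, method=A2T2
        )
        with pytest.raises(DegenerateInput):
            normalize_and_detrend(hist, 30, 100)


class TestPowerSpectrum:
    def test_pure_cosine_peak_at_its_period(self):
        s = np.arange(30, 101)
        ps = ProcessedSpacing(y=np.cos(2 * np.pi * s / 10.5), s_min=30, s_max=100)
        sp = power_spectrum(ps)
        assert sp.p_max_q == pytest.approx(10.5, abs=0.05)

    def test_unit_mean_over_norm_range(self, rng):
        ps = ProcessedSpacing(y=rng.normal(size=71), s_min=30, s_max=100)
        sp = power_spectrum(ps)
        mask = (sp.periods >= 5) & (sp.periods <= 20)
        assert abs(sp.q[mask].mean() - 1.0) < 1e-9

    def test_scale_invariance(self, rng):
        y = rng.normal(size=71)
        sp1 = power_spectrum(ProcessedSpacing(y=y, s_min=30, s_max=100))
        sp2 = power_spectrum(ProcessedSpacing(y=137.5 * y, s_min=30, s_max=100))
        np.testing.assert_allclose(sp1.q, sp2.q, rtol=1e-12)
        assert sp1.max_q == pytest.approx(sp2.max_q, rel=1e-12)

    def test_zero_signal_degenerate(self):
        ps = ProcessedSpacing(y=np.zeros(71), s_min=30, s_max=100)
        with pytest.raises(DegenerateInput):
            power_spectrum(ps)


class TestPerplot:
    def test_reverse_complement_invariance_exact(self, rng):
        seq = random_sequence(rng, 30000)
        sp_fwd = perplot(seq)
        sp_rev = perplot(reverse_complement(seq))
        np.testing.assert_array_equal(sp_fwd.q, sp_rev.q)
        assert sp_fwd.max_q == sp_rev.max_q
        assert sp_fwd.p_max_q == sp_rev.p_max_q

    def test_translation_invariance(self, rng):
        # prepending G's changes no pair spacing; only the expected-count
        # model sees the longer L, perturbing the spectrum at O(n/L) level
        seq = random_sequence(rng, 20000)
        sp1 = perplot(seq)
        sp2 = perplot("G" * 500 + seq)
        hist1 = count_pair_spacings(find_tracts(seq, A2T2), 101)
        hist2 = count_pair_spacings(find_tracts("G" * 500 + seq, A2T2), 101)
        np.testing.assert_array_equal(hist1.counts, hist2.counts)
        np.testing.assert_allclose(sp1.q, sp2.q, atol=0.02)
        assert sp1.p_max_q == sp2.p_max_q

    def test_planted_phasing_detected(self, planted_sequence):
        seq, _ = planted_sequence
        sp = perplot(seq)
        assert sp.p_max_q == pytest.approx(10.5, abs=0.2)
        assert sp.max_q > 3.5

    @pytest.mark.parametrize("period", [10.0, 10.5, 11.0, 12.0])
    def test_planted_period_recovered(self, period):
        spec = fixtures.PlantedPeriodicitySpec(
            length=50_000, period=period, tract="AA", density=1.0, jitter=0, seed=5
        )
        seq, _ = fixtures.plant_periodicity(spec)
        sp = perplot(seq)
        assert sp.p_max_q == pytest.approx(period, abs=0.2)

    def test_no_occurrences_flagged_not_nan(self):
        sp = perplot("GC" * 2000, method="A2T2")
        assert sp.degenerate
        assert sp.max_q is None
        assert sp.q.size == 0

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError, match="s_max"):
            perplot("ACGT" * 10)


def test_spectrum_tsv_has_indices_and_grid(rng):
    seq = random_sequence(rng, 20000)
    sp = perplot(seq)
    buf = io.StringIO()
    write_spectrum_tsv(sp, buf)
    lines = buf.getvalue().splitlines()
    header = {l.split("\t")[0][2:]: l.split("\t")[1] for l in lines if l.startswith("#")}
    assert float(header["MaxQ"]) == pytest.approx(sp.max_q, rel=1e-4)
    assert float(header["PMaxQ"]) == pytest.approx(sp.p_max_q, abs=0.01)
    data = [l for l in lines if not l.startswith("#") and not l.startswith("period")]
    assert len(data) == sp.periods.size
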