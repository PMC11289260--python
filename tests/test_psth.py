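import itertools

import numpy as np
import pytest

import popdyn as P
from popdyn.binning import TrialGrid
from popdyn.psth import EPOCHS, dtw_distance


class TestBuildPsth:
    def test_homogeneous_poisson_recovers_rate(self, rng):
        rate, trials, bins = 10.0, 500, 200
        counts = rng.poisson(rate * 0.01, (trials, bins))
        psth = P.build_psth(counts)
        se = np.sqrt(rate / (0.01 * trials))  # per-bin SE, before smoothing
        assert np.all(np.abs(psth.rate_hz - rate) < 3 * se)

    def test_single_spike_kernel_mass(self):
        counts = np.zeros((1, 200))
        counts[0, 100] = 1
        psth = P.build_psth(counts)
        # integral of the smoothed rate = 1 spike
        assert psth.rate_hz.sum() * 0.01 == pytest.approx(1.0, abs=0.01)

    def test_zero_spikes(self):
        psth = P.build_psth(np.zeros((10, 200)))
        assert np.all(psth.rate_hz == 0)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            P.build_psth(np.zeros((0, 200)))


class TestReliability:
    def _strong_counts(self, rng, n=40):
        lam = np.full(200, 0.02)
        lam[20:120] = 0.25  # 25 Hz stimulus response
        return rng.poisson(lam, (n, 200))

    def test_strong_response_passes_all_criteria(self, rng):
        counts = self._strong_counts(rng)
        blanks = rng.poisson(0.02, (15, 200))
        r = P.assess_reliability(counts, blanks, rng=rng)
        assert r.range_ok and r.z_ok and r.shape_ok and r.reliable

    def test_small_range_fails_first_criterion(self, rng):
        # a clean 2 Hz modulation fails the range criterion regardless of
        # how reliable its shape is (identical trials at the expected rate)
        lam = np.full(200, 0.10)
        lam[20:120] = 0.12
        counts = np.tile(lam, (12, 1))
        blanks = rng.poisson(0.10, (15, 200))
        r = P.assess_reliability(counts, blanks, rng=rng)
        assert not r.range_ok and not r.reliable

    def test_missing_blanks_rejected(self, rng):
        with pytest.raises(ValueError, match="blank"):
            P.assess_reliability(self._strong_counts(rng), np.zeros((0, 200)),
                                 rng=rng)

    def test_reliable_flag_is_conjunction(self, rng):
        r = P.assess_reliability(self._strong_counts(rng),
                                 rng.poisson(0.02, (15, 200)), rng=rng)
        assert r.reliable == (r.range_ok and r.z_ok and r.shape_ok)


def _profile_with_onset_shape(shape, rng, noise=0.05):
    """Full 200-bin profile whose onset epoch (bins 20-50) has a known
    shape; the rest sits at the shape's end value."""
    E = 30
    x = np.arange(E)
    if shape == "Decay":
        seg = np.exp(-x / 6.0)
    elif shape == "Rise":
        seg = 1.0 - np.exp(-x / 6.0)
    elif shape == "Peak":
        seg = 0.2 + 0.7 * np.exp(-((x - 15) ** 2) / (2 * 4.0**2))
    elif shape == "Trough":
        seg = 0.9 - 0.7 * np.exp(-((x - 15) ** 2) / (2 * 4.0**2))
    else:  # Flat
        seg = np.full(E, 0.5)
    prof = np.full(200, seg[-1])
    prof[:20] = seg[0]
    prof[20:50] = seg
    if shape == "Flat":
        # give the whole profile some range elsewhere so normalisation
        # does not blow up the flat epoch
        prof[120:170] = 1.0
        prof[:20] = 0.0
    return prof + rng.normal(0, noise, 200)


class TestFeatureClassifier:
    @pytest.mark.parametrize("shape", ["Decay", "Rise", "Peak", "Trough", "Flat"])
    def test_noiseless_shapes_recovered(self, shape, rng):
        prof = _profile_with_onset_shape(shape, rng, noise=0.0)
        fit = P.classify_features(P.Psth(rate_hz=prof), "onset")
        assert fit.label == shape

    def test_corpus_recovery_rate(self):
        rng = np.random.default_rng(42)
        shapes = ["Decay", "Rise", "Peak", "Trough", "Flat"]
        correct = total = 0
        for shape in shapes:
            for _ in range(10):
                prof = _profile_with_onset_shape(shape, rng, noise=0.05)
                fit = P.classify_features(P.Psth(rate_hz=prof), "onset")
                correct += fit.label == shape
                total += 1
        assert correct / total >= 0.9

    def test_prominence_threshold_behaviour(self, rng):
        # a mid-window bump with prominence 0.5 is a Peak; scaled to 0.1
        # the epoch range drops below 0.2 and the response is Flat
        E = 30
        x = np.arange(E)
        for prom, expect in [(0.5, "Peak"), (0.1, "Flat")]:
            prof = np.zeros(200)
            prof[20:50] = prom * np.exp(-((x - 15) ** 2) / (2 * 4.0**2))
            prof[120:170] = 1.0  # normalisation anchor outside the epoch
            fit = P.classify_features(P.Psth(rate_hz=prof), "onset")
            assert fit.label == expect, prom

    def test_epoch_windows(self):
        assert EPOCHS["onset"] == (0.0, 300.0)
        assert EPOCHS["offset"] == (1000.0, 1500.0)


class TestSustainedness:
    def test_constant_above_baseline_is_one(self):
        psth = P.Psth(rate_hz=np.full(200, 10.0))
        assert P.sustainedness(psth, 2.0).index == pytest.approx(1.0)

    def test_transient_arithmetic(self):
        grid = TrialGrid(0.0, 100.0, 0.0)  # 10 bins, all stimulus
        rate = np.zeros(10)
        rate[0] = 10.0
        psth = P.Psth(rate_hz=rate, grid=grid)
        s = P.sustainedness(psth, 0.0, grid=grid)
        assert s.index == pytest.approx(0.1)
        assert s.mean_delta_hz == pytest.approx(1.0)
        assert s.peak_delta_hz == pytest.approx(10.0)

    def test_suppressed_constant_is_one(self):
        psth = P.Psth(rate_hz=np.full(200, 4.0))
        s = P.sustainedness(psth, 10.0)
        assert s.suppressed and s.index == pytest.approx(1.0)

    def test_flat_at_baseline_is_undefined(self):
        psth = P.Psth(rate_hz=np.full(200, 5.0))
        assert np.isnan(P.sustainedness(psth, 5.0).index)

    def test_index_invariant_to_joint_rescaling(self, rng):
        rate = np.abs(rng.normal(5, 2, 200))
        psth1 = P.Psth(rate_hz=rate)
        psth2 = P.Psth(rate_hz=3.0 * rate)
        a = P.sustainedness(psth1, 1.0).index
        b = P.sustainedness(psth2, 3.0).index
        assert a == pytest.approx(b)


def _brute_force_dtw(x, y):
    """Unbanded DTW by full dynamic programming (independent oracle)."""
    n, m = len(x), len(y)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(x[i - 1] - y[j - 1])
            D[i, j] = c + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return D[n, m]


class TestDtwSorting:
    def test_identical_series_distance_zero(self, rng):
        x = rng.random(50)
        assert dtw_distance(x, x) == 0.0

    def test_matches_bruteforce_when_band_covers(self, rng):
        for _ in range(5):
            x, y = rng.random(12), rng.random(12)
            assert dtw_distance(x, y, band=12) == pytest.approx(
                _brute_force_dtw(x, y)
            )

    def test_shifted_copy_cheaper_than_euclidean(self, rng):
        x = np.exp(-((np.arange(60) - 20) ** 2) / 30.0)
        y = np.roll(x, 5)
        assert dtw_distance(x, y, band=10) < np.abs(x - y).sum()

    def test_symmetry(self, rng):
        x, y = rng.random(30), rng.random(30)
        assert dtw_distance(x, y) == pytest.approx(dtw_distance(y, x))

    def test_near_duplicates_end_up_adjacent(self, rng):
        a = np.exp(-((np.arange(100) - 30) ** 2) / 50.0)
        b = a + rng.normal(0, 0.01, 100)
        c = np.exp(-((np.arange(100) - 70) ** 2) / 50.0)
        order = list(P.sort_psths([c, a, b]))
        ia, ib = order.index(1), order.index(2)
        assert abs(ia - ib) == 1
        # the adjacency is optimal: check against all 3! orderings
        profs = [c, a, b]
        D = {(i, j): dtw_distance(profs[i], profs[j]) for i in range(3)
             for j in range(3)}
        best = min(itertools.permutations(range(3)),
                   key=lambda p: D[p[0], p[1]] + D[p[1], p[2]])
        cost = lambda p: D[p[0], p[1]] + D[p[1], p[2]]
        assert cost(tuple(order)) == pytest.approx(cost(best))

    def test_nan_rejected(self):
        bad = np.full(20, np.nan)
        with pytest.raises(ValueError):
            P.sort_psths([bad, bad])


class TestUnitFilter:
    def test_rules_table(self):
        import pandas as pd

        units = pd.DataFrame(
            {
                "unit_id": [0, 1, 2, 3],
                "waveform_duration_us": [400.0, 500.0, 600.0, 700.0],
                "acg_tau_ms": [2.0, 6.0, 8.0, np.nan],
                "isi_violation_frac": [0.01, 0.05, 0.12, 0.02],
                "amp_cutoff_frac": [0.02, 0.01, 0.01, 0.01],
                "mean_amp_uv": [120.0, 80.0, 100.0, 40.0],
            }
        )
        out = P.filter_and_type_units(units)
        assert list(out["cell_type"]) == [
            "narrow interneuron", "pyramidal", "wide interneuron", "unassigned",
        ]
        assert list(out["quality"]) == [True, True, False, False]

    def test_missing_columns_named(self):
        import pandas as pd

        with pytest.raises(ValueError, match="mean_amp_uv"):
            P.filter_and_type_units(pd.DataFrame({"waveform_duration_us": [1.0]}))
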