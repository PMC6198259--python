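"""Case studies: periodic development, blowflies, host-parasitoid, SIR."""

import numpy as np
import pytest

from agepop.casestudies import (
    BlowflyParams,
    NBHParams,
    SIRParams,
    blowflies,
    count_peaks,
    nicholson_bailey,
    sir,
    worked_example,
)
from agepop.simulate import run


class TestCountPeaks:
    def test_plateau_takes_first_index(self):
        v = [0, 1, 2, 2, 1, 0, 3, 0]
        assert count_peaks(v, threshold_frac=0.0) == 2

    def test_threshold_filters_small_maxima(self):
        v = [0, 0.05, 0, 1.0, 0]
        assert count_peaks(v, threshold_frac=0.1) == 1

    def test_time_window(self):
        v = [0, 1, 0, 1, 0]
        t = [0, 10, 20, 30, 40]
        assert count_peaks(v, times=t, lo=25, hi=40) == 1


class TestWorkedExample:
    def test_population_dies_out_within_horizon(self, worked_example_det):
        frame = worked_example_det.frame
        below = frame[frame["size"] < 1.0]
        assert len(below) > 0
        assert below["step"].iloc[0] / 24.0 < 20.0

    def test_multiple_development_cycles_complete(self, worked_example_det):
        per_cycle = worked_example_det.developed_per_cycle()
        assert (per_cycle >= 1.0).sum() >= 5

    def test_stochastic_reintroduction_conserves_individuals(self):
        # with the devtable fed back, only the dead leave the population
        ts = run(worked_example(stochastic=True, seed=3))
        frame = ts.frame
        sizes = frame["size"].to_numpy()
        dead = frame["dead"].to_numpy()
        assert sizes[0] == 1000 - dead[0]
        assert np.array_equal(sizes[1:], sizes[:-1] - dead[1:])


def major_peaks(day, values, min_sep=20.0, threshold_frac=0.1):
    """Merge raw peaks closer than ``min_sep`` days, keeping the higher."""
    v = np.asarray(values, float)
    t = np.asarray(day, float)
    starts = np.flatnonzero(np.r_[True, v[1:] != v[:-1]])
    w = v[starts]
    idx = [starts[j] for j in range(1, len(w) - 1)
           if w[j] > w[j - 1] and w[j] > w[j + 1] and w[j] > threshold_frac * v.max()]
    merged = []
    for i in idx:
        if merged and t[i] - t[merged[-1]] < min_sep:
            if v[i] > v[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return t[merged], v[merged]


@pytest.fixture(scope="module")
def det():
    return blowflies()


class TestBlowflies:
    def test_sustained_quasi_cyclic_oscillations(self, det):
        ad = det["adults"].to_numpy()
        day = det["day"].to_numpy()
        assert count_peaks(ad, times=day, lo=100, hi=300) >= 5
        # amplitude does not die out
        late = ad[(day >= 250) & (day <= 350)].max()
        early = ad[(day >= 50) & (day <= 150)].max()
        assert late > 0.5 * early

    def test_oscillation_period_matches_delayed_recruitment(self, det):
        # major peaks recur roughly every total development delay plus the
        # adult lifespan timescale (~35-40 days for the default parameters)
        t, _ = major_peaks(det["day"], det["adults"])
        gaps = np.diff(t[(t >= 50) & (t <= 350)])
        assert np.all((gaps > 25) & (gaps < 50))

    def test_zero_fecundity_decline_to_extinction(self):
        params = BlowflyParams.from_fixture(fecundity_per_adult_day=0.0, horizon_days=60)
        frame = blowflies(params)
        ad = frame["adults"].to_numpy()
        assert np.all(np.diff(ad) <= 1e-12)
        assert ad[-1] < 1.0

    def test_stochastic_preserves_frequency_varies_amplitude(self):
        det = blowflies(BlowflyParams.from_fixture(horizon_days=300))
        t_det, _ = major_peaks(det["day"], det["adults"])
        n_det = ((t_det >= 50) & (t_det <= 280)).sum()
        counts, mean_amps = [], []
        for seed in range(3):
            rep = blowflies(BlowflyParams.from_fixture(horizon_days=300),
                            stochastic=True, seed=seed)
            t, amps = major_peaks(rep["day"], rep["adults"])
            sel = (t >= 50) & (t <= 280)
            counts.append(int(sel.sum()))
            mean_amps.append(amps[sel].mean())
        # frequency conserved: same number of major peaks give or take one
        assert all(abs(c - n_det) <= 1 for c in counts)
        # across replicates the amplitude fluctuates more than the frequency
        count_cv = np.std(counts) / np.mean(counts)
        amp_cv = np.std(mean_amps) / np.mean(mean_amps)
        assert amp_cv > count_cv

    def test_deterministic_matches_stochastic_mean_level(self):
        params = BlowflyParams.from_fixture(horizon_days=150)
        det = blowflies(params)
        sel = (det["day"] >= 50) & (det["day"] <= 150)
        det_level = det.loc[sel, "adults"].mean()
        levels = []
        for seed in range(6):
            rep = blowflies(params, stochastic=True, seed=100 + seed)
            levels.append(rep.loc[sel.to_numpy(), "adults"].mean())
        levels = np.array(levels)
        se = levels.std(ddof=1) / np.sqrt(len(levels))
        # binomial noise plus a small allowance for the nonlinearity of the
        # density-dependent fecundity (the deterministic model is the
        # large-population limit, not the exact mean)
        assert abs(levels.mean() - det_level) < 3 * se + 0.05 * det_level


def classical_map(R, a, H0, P0, generations):
    H, P = float(H0), float(P0)
    rows = []
    for _ in range(generations):
        rows.append((H, P))
        H, P = R * H * np.exp(-a * P), H * -np.expm1(-a * P)
    return np.array(rows)


class TestNicholsonBailey:
    def test_without_age_structure_matches_classical_map(self):
        p = NBHParams.from_fixture(generations=40)
        frame = nicholson_bailey(p, age_structured=False)
        oracle = classical_map(p.reproduction, p.searching_efficiency,
                               p.initial_hosts, p.initial_parasites, 40)
        # atol covers the post-crash regime where populations underflow to
        # zero through cancellation in n - n*q while the closed form keeps
        # a denormal-sized remnant
        np.testing.assert_allclose(frame["hosts"].to_numpy(), oracle[:, 0],
                                   rtol=1e-10, atol=1e-15)
        np.testing.assert_allclose(frame["parasites"].to_numpy(), oracle[:, 1],
                                   rtol=1e-10, atol=1e-15)

    def test_classical_oscillations_grow(self):
        frame = nicholson_bailey(age_structured=False)
        h = frame["hosts"].to_numpy()[:60]
        peaks = [i for i in range(1, len(h) - 1) if h[i] > h[i - 1] and h[i] > h[i + 1]]
        amps = h[peaks]
        assert len(amps) >= 3
        assert np.all(np.diff(amps) > 0)  # diverging around the unstable point

    def test_fixed_adult_survival_stabilises(self):
        frame = nicholson_bailey(age_structured=True)
        h = frame["hosts"].to_numpy()
        window = 20
        amps = [h[i:i + window].max() - h[i:i + window].min()
                for i in range(20, len(h) - window, window)]
        assert np.all(np.diff(amps) <= 1e-6)  # non-increasing after transient
        assert amps[-1] < amps[0]

    def test_stability_degrades_as_lifetime_narrows(self):
        spread = {}
        for sigma in (5.0, 2.5, 1.25):
            p = NBHParams.from_fixture(survival=("gamma", 10.0, sigma), generations=200)
            frame = nicholson_bailey(p, age_structured=True)
            h = frame["hosts"].to_numpy()[-50:]
            spread[sigma] = h.max() - h.min()
        assert spread[1.25] > spread[2.5] > spread[5.0]


class TestSir:
    def test_memoryless_limit_matches_difference_equation(self):
        p = SIRParams.from_fixture(infectious_sd_days=11.71)  # sigma = mu
        frame = sir(p)
        beta, mu, a = p.transmission_per_day, p.infectious_mean_days, p.alpha
        S = float(p.initial_susceptible)
        I = float(p.initial_infectious)
        R = 0.0
        g = 1.0 - np.exp(-1.0 / (mu * a))  # constant removal probability
        worst = 0.0
        for step in range(int(p.horizon_days * a)):
            new_inf = S * -np.expm1(-beta * I / a)
            S, I, R = S - new_inf, I * (1 - g) + new_inf, R + I * g
            row = frame.iloc[step]
            worst = max(worst, abs(row.S - S), abs(row.I - I), abs(row.R - R))
        assert worst < 1e-9

    def test_precise_infectious_period_resolves_outbreak_faster(self):
        def time_to_resolution(sd):
            frame = sir(SIRParams.from_fixture(infectious_sd_days=sd))
            gone = frame[(frame["I"] < 1.0) & (frame["day"] > 5)]
            return gone["day"].iloc[0]

        assert time_to_resolution(0.0) < time_to_resolution(11.71)

    def test_zero_transmission(self):
        frame = sir(SIRParams.from_fixture(transmission_per_day=0.0))
        assert frame["S"].nunique() == 1
        assert frame["I"].iloc[-1] == 0.0

    def test_deterministic_matches_stochastic_mean_final_size(self):
        # start with enough cases that stochastic fade-out is negligible
        p = SIRParams.from_fixture(initial_infectious=20, horizon_days=150)
        det_final = sir(p).iloc[-1]["R"]
        finals = np.array([sir(p, stochastic=True, seed=s).iloc[-1]["R"]
                           for s in range(40)], dtype=float)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - det_final) < 3 * se + 0.02 * det_final
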