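"""Gillespie denervation: mechanism behavior, survival curves, fits."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from striatum.denervation import (
    CAUSE_DEATH,
    CAUSE_INFECTION,
    DenervationParams,
    fit_stretched_exponential,
    largest_cac_curve,
    sid_rate,
    simulate_denervation,
    snapshot,
    survival_curve,
    tipping_point,
)
from striatum.geometry import contiguous_arbor_classes, generate_striatum, overlap_counts

from conftest import scaled_config, toy_network


@pytest.fixture(scope="module")
def trajectories(net10k):
    """One nearly complete run of each mechanism on the shared 10k network."""
    return {
        model: simulate_denervation(
            net10k, DenervationParams(model=model, seed=17), until_fraction=0.995
        )
        for model in ("rd", "pld", "sid")
    }


class TestParams:
    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            DenervationParams(model="viral")

    def test_sid_rate_limits(self):
        p = DenervationParams(model="sid")
        assert sid_rate(0.0, p) == pytest.approx(p.base_rate, rel=1e-3)
        assert sid_rate(100.0, p) == pytest.approx(0.0, abs=1e-6)
        assert sid_rate(p.sid_midpoint, p) == pytest.approx(p.base_rate / 2)


class TestRandomDenervation:
    def test_mean_time_matches_pure_death_theory(self, net10k):
        # time to remove fraction f of n neurons at unit rate ~ -ln(1-f)
        times = []
        for seed in range(10):
            traj = simulate_denervation(
                net10k, DenervationParams(model="rd", seed=seed), until_fraction=0.5
            )
            times.append(traj.death_times[-1])
        assert np.mean(times) == pytest.approx(np.log(2.0), rel=0.05)

    def test_death_order_exchangeable(self):
        # the rank at which a fixed arbor dies is uniform over seeds
        net = generate_striatum(scaled_config(20, seed=1))
        ranks = []
        for seed in range(300):
            traj = simulate_denervation(net, DenervationParams(model="rd", seed=seed))
            ranks.append(int(np.flatnonzero(traj.death_order == 0)[0]))
        counts = np.bincount(ranks, minlength=20)
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue > 1e-3

    def test_survival_curve_is_exponential(self, trajectories):
        t, f = survival_curve(trajectories["rd"])
        mask = f > 0.02
        assert np.max(np.abs(f[mask] - np.exp(-t[mask]))) < 0.05

    def test_snapshot_is_uniform_thinning(self, net10k):
        traj = simulate_denervation(net10k, DenervationParams(model="rd", seed=2))
        thin = snapshot(traj, 0.75)
        from striatum.geometry import NetworkConfig

        fresh = generate_striatum(
            NetworkConfig(n_neurons=2_500, ellipsoid=net10k.config.ellipsoid, seed=99)
        )
        m_thin = overlap_counts(thin).mean()
        m_fresh = overlap_counts(fresh).mean()
        assert m_thin == pytest.approx(m_fresh, rel=0.1)


class TestPrionLikeDenervation:
    def test_infected_count_grows_by_one_per_event(self, net10k):
        traj = simulate_denervation(
            net10k, DenervationParams(model="pld", seed=5), until_fraction=0.2
        )
        # while every dying neuron still finds two uninfected contacts, each
        # death adds two infections, so after k deaths the infected set holds
        # 1 + k; later, locally exhausted neighborhoods reduce the yield
        deaths = np.cumsum(traj.causes == CAUSE_DEATH)
        infections = np.cumsum(traj.causes == CAUSE_INFECTION)
        idx = int(np.searchsorted(deaths, 30))
        assert infections[idx] == 2 * deaths[idx]
        assert 1 + infections[idx] - deaths[idx] == 1 + deaths[idx]
        # bookkeeping bounds hold throughout
        assert np.all(infections <= 2 * deaths + 2)
        assert np.all(1 + infections - deaths >= 0)

    def test_dead_region_is_spatially_contiguous(self, net10k, trajectories):
        # at 50% denervation the PLD dead set forms far fewer components of
        # the overlap graph than the RD dead set
        def n_dead_components(traj):
            net = snapshot(traj, 0.5)
            return contiguous_arbor_classes(net.with_alive(~net.alive)).n_classes

        assert n_dead_components(trajectories["pld"]) < 0.8 * n_dead_components(
            trajectories["rd"]
        )

    def test_survival_curve_is_convex(self, trajectories):
        t, f = survival_curve(trajectories["pld"])
        # coarse-grain to suppress event noise, then check the second
        # difference of the decreasing curve is nonnegative on average
        grid = np.linspace(0, t[f > 0.02][-1], 30)
        fg = np.interp(grid, t, f)
        d2 = np.diff(fg, 2)
        assert d2.mean() < 0  # accelerating decay: curve bends downward

    def test_reseeding_on_burnout(self):
        # two far-apart pairs: the wave cannot jump between them, so killing
        # everything requires a fresh seed infection
        net = toy_network([[0, 0, 0], [0.3, 0, 0], [10, 0, 0], [10.3, 0, 0]])
        traj = simulate_denervation(net, DenervationParams(model="pld", seed=0))
        assert traj.n_deaths == 4


class TestStressInducedDenervation:
    def test_sparse_neurons_die_first(self, net10k, trajectories):
        healthy_counts = overlap_counts(net10k)
        order = trajectories["sid"].death_order
        first_half = healthy_counts[np.searchsorted(net10k.live_ids, order[:5000])]
        second_half = healthy_counts[np.searchsorted(net10k.live_ids, order[5000:])]
        assert first_half.mean() < second_half.mean()

    def test_survivor_enrichment_at_80_percent(self, net10k, trajectories):
        healthy_counts = overlap_counts(net10k)
        net = snapshot(trajectories["sid"], 0.8)
        survivors = healthy_counts[net.alive[net10k.live_ids]]
        assert survivors.mean() > healthy_counts.mean()

    def test_survival_curve_is_concave(self, trajectories):
        t, f = survival_curve(trajectories["sid"])
        grid = np.linspace(0, t[f > 0.02][-1], 30)
        fg = np.interp(grid, t, f)
        assert np.diff(fg, 2).mean() > 0  # decelerating decay


class TestGillespieOracle:
    def test_death_order_probabilities_match_rate_ratios(self):
        # 3 neurons with distinct sigmoidal rates (neighbor counts 0, 1, 1):
        # death-order probabilities factorize over the remaining rates
        params = DenervationParams(model="sid", sid_midpoint=1.0, sid_slope=0.5, seed=0)
        net = toy_network([[0, 0, 0], [5, 0, 0], [5.3, 0, 0]])
        r = np.array([sid_rate(k, params) for k in (0, 1, 1)])

        def exact_order_prob(order):
            rem = list(range(3))
            p = 1.0
            for i in order:
                p *= r[i] / r[rem].sum() if len(rem) > 1 else 1.0
                rem.remove(i)
            return p

        n_runs = 4000
        observed = {p: 0 for p in itertools.permutations(range(3))}
        for seed in range(n_runs):
            traj = simulate_denervation(
                net, DenervationParams(model="sid", sid_midpoint=1.0, sid_slope=0.5, seed=seed)
            )
            observed[tuple(traj.death_order)] += 1
        for order, count in observed.items():
            expected = exact_order_prob(list(order))
            se = np.sqrt(expected * (1 - expected) / n_runs)
            assert abs(count / n_runs - expected) < 5 * se + 1e-9


class TestSnapshot:
    def test_endpoints(self, net10k, trajectories):
        assert snapshot(trajectories["rd"], 0.0).n_live == net10k.n_live
        traj_full = simulate_denervation(net10k, DenervationParams(model="rd", seed=8))
        assert snapshot(traj_full, 1.0).n_live == 0

    def test_fraction_beyond_trajectory_rejected(self, net10k):
        traj = simulate_denervation(
            net10k, DenervationParams(model="rd", seed=0), until_fraction=0.3
        )
        with pytest.raises(ValueError):
            snapshot(traj, 0.9)


class TestStretchedExponentialFit:
    def test_recovers_pure_exponential(self):
        t = np.linspace(0, 5, 400)
        fit = fit_stretched_exponential(t, np.exp(-t))
        assert fit.b == pytest.approx(1.0, abs=1e-3)
        assert fit.c == pytest.approx(1.0, abs=1e-3)

    def test_recovers_gaussian_decay(self):
        t = np.linspace(0, 3, 400)
        fit = fit_stretched_exponential(t, np.exp(-0.5 * t**2))
        assert fit.b == pytest.approx(0.5, abs=1e-3)
        assert fit.c == pytest.approx(2.0, abs=1e-3)

    @given(
        b=st.floats(0.3, 3.0),
        c=st.floats(0.4, 3.0),
    )
    def test_recovers_noisy_stretched_exponential(self, b, c):
        rng = np.random.default_rng(12)
        t = np.linspace(0.01, (3.9 / b) ** (1 / c), 500)
        f = np.exp(-b * t**c) * np.exp(rng.normal(0, 0.01, t.size))
        fit = fit_stretched_exponential(t, f)
        assert fit.c == pytest.approx(c, rel=0.05)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_stretched_exponential(np.array([0.0, 1.0]), np.array([1.0, 0.5]))

    def test_exponent_ordering_across_mechanisms(self, trajectories):
        cs = {}
        for model, traj in trajectories.items():
            t, f = survival_curve(traj)
            cs[model] = fit_stretched_exponential(t, f).c
        assert cs["sid"] < 0.9
        assert cs["rd"] == pytest.approx(1.0, abs=0.1)
        assert cs["pld"] > 1.5


class TestLargestCACCurve:
    def test_healthy_level_is_one_class(self, trajectories):
        fr = largest_cac_curve(trajectories["rd"], [0.0])
        assert fr[0] > 0.999

    def test_exhaustive_denervation_gives_singletons(self, net10k):
        traj = simulate_denervation(net10k, DenervationParams(model="rd", seed=1))
        fr = largest_cac_curve(traj, [0.999])
        live = net10k.n_live - int(0.999 * net10k.n_live)
        assert fr[0] >= 1.0 / live

    def test_pld_keeps_dominant_class(self, trajectories):
        fr = largest_cac_curve(trajectories["pld"], [0.25, 0.5, 0.7])
        assert np.all(fr > 0.5)

    def test_tipping_point_trivia(self):
        assert tipping_point([0.1, 0.2], [1.0, 1.0]) is None
        levels = np.arange(0, 1, 0.1)
        fr = np.where(levels < 0.6, 1.0, 0.2)
        assert tipping_point(levels, fr) == pytest.approx(0.6)
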