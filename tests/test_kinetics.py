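"""Rates (k = f/p), stabilities, barrier conversions, efficiency."""

import numpy as np
import pytest

import switchpath as sp
from switchpath.errors import (ConfigurationError, UndefinedStateError)
from switchpath.kinetics import (RateEstimate, StateDefinition,
                                 barrier_reduction, define_states,
                                 efficiency, estimate_rate,
                                 estimate_stability, mfpt)
from switchpath.units import R_KCAL_PER_MOL_K
from switchpath.we import LABEL_I, LABEL_J, WEArchive, WEIteration


def synthetic_archive(fluxes, p_i=0.5, tau=1.0, mode="steady-state",
                      positions=None):
    """Hand-built archive: one walker labeled i with weight p_i and one
    labeled j with weight 1 - p_i per iteration."""
    arch = WEArchive(mode=mode, tau=tau, sample_interval=tau, seed=0,
                     walkers_per_bin=1, progress_dim=1,
                     initial_coords=np.zeros((2, 1)),
                     initial_progress=np.zeros((2, 1)))
    for t, fl in enumerate(fluxes):
        pos = positions[t] if positions is not None else [-1.0, 1.0]
        arch.iterations.append(WEIteration(
            index=t, weights=np.array([p_i, 1.0 - p_i]),
            labels=np.array([LABEL_I, LABEL_J], dtype=np.int8),
            parents=np.array([0, 1], dtype=np.int32),
            end_progress=np.array(pos, dtype=float).reshape(2, 1),
            recycled=np.array([False, fl > 0]),
            bin_index=np.zeros(2, dtype=np.int32),
            recycled_flux=float(fl), weight_error=0.0))
    return arch


# ---------------------------------------------------------------------------
# define_states
# ---------------------------------------------------------------------------

class TestDefineStates:
    def test_symmetric_double_well_histogram(self):
        edges = np.linspace(-2, 2, 41)
        centers = 0.5 * (edges[:-1] + edges[1:])
        hist = np.exp(-4.0 * ((centers ** 2 - 1.0) ** 2))
        si, sj = define_states(hist, edges)
        # boundaries at the modes (+-1); the barrier region is open between
        assert si.upper[0] == pytest.approx(-1.0, abs=0.06)
        assert sj.lower[0] == pytest.approx(1.0, abs=0.06)
        assert si.contains([-1.2]) and not si.contains([-0.9])
        assert sj.contains([1.2]) and not sj.contains([0.9])

    def test_hand_built_modes_at_bins_3_and_17(self):
        hist = np.full(21, 0.5)
        hist[3] = 4.0
        hist[17] = 5.0
        hist[10] = 0.1
        edges = np.arange(22, dtype=float)
        si, sj = define_states(hist, edges)
        assert si.upper[0] == pytest.approx(3.5)
        assert sj.lower[0] == pytest.approx(17.5)

    def test_flat_histogram_rejected(self):
        with pytest.raises(UndefinedStateError):
            define_states(np.ones(20), np.arange(21, dtype=float))

    def test_unimodal_histogram_rejected(self):
        edges = np.linspace(-2, 2, 31)
        centers = 0.5 * (edges[:-1] + edges[1:])
        with pytest.raises(UndefinedStateError):
            define_states(np.exp(-centers ** 2), edges)


# ---------------------------------------------------------------------------
# estimate_rate
# ---------------------------------------------------------------------------

class TestEstimateRate:
    def test_constant_flux_arithmetic(self):
        # f = 0.02 per tau at p_i = 0.5 -> k = 0.04 per tau
        arch = synthetic_archive([0.02] * 100, p_i=0.5)
        est = estimate_rate(arch, burn_in_fraction=0.1)
        assert est.k == pytest.approx(0.04)
        assert est.f == pytest.approx(0.02)
        assert est.k == est.f / est.p

    def test_unit_occupancy_limit(self):
        arch = synthetic_archive([0.01] * 50, p_i=1.0 - 1e-15)
        est = estimate_rate(arch)
        assert est.k == pytest.approx(est.f, rel=1e-9)

    def test_zero_flux_reports_upper_bound(self):
        arch = synthetic_archive([0.0] * 50)
        with pytest.warns(UserWarning, match="upper bound"):
            est = estimate_rate(arch)
        assert est.upper_bound and est.k > 0

    def test_markov_chain_rate_matches_closed_form(self):
        # two-state Markov propagator with switch probability q per tau:
        # the label-based rate is exactly q/tau in expectation
        q01, q10 = 0.02, 0.05

        class MarkovProp:
            tau = 1.0
            sample_interval = 1.0
            ndim = 1

            def propagate(self, coords, rng):
                x = float(np.atleast_1d(coords)[0])
                q = q01 if x < 0 else q10
                if rng.random() < q:
                    x = -x
                seg = sp.TrajectorySegment(
                    frames=np.array([x]), times=np.array([1.0]),
                    end_coords=np.array([x]))
                return seg

            def progress(self, coords):
                return np.atleast_1d(coords)

        prop = MarkovProp()
        si = StateDefinition("i", (-np.inf,), (-0.5,))
        sj = StateDefinition("j", (0.5,), (np.inf,))
        ks = []
        for seed in range(4):
            cfg = sp.WEConfig(
                mode="steady-state", n_iterations=3000,
                bin_mapper=sp.BinMapper(edges=(np.array([0.0]),)),
                initial_sampler=lambda rng: np.array([-1.0]),
                state_i=si, state_j=sj, seed=seed, walkers_per_bin=8,
                store_samples=False, store_end=False)
            arch = sp.run_we(prop, cfg)
            ks.append(estimate_rate(arch).k)
        est = estimate_rate(
            [sp.run_we(prop, sp.WEConfig(
                mode="steady-state", n_iterations=3000,
                bin_mapper=sp.BinMapper(edges=(np.array([0.0]),)),
                initial_sampler=lambda rng: np.array([-1.0]),
                state_i=si, state_j=sj, seed=100 + s, walkers_per_bin=8,
                store_samples=False, store_end=False))
             for s in range(4)])
        assert abs(est.k - q01) <= 3 * est.sem

    def test_rate_invariant_holds_exactly(self):
        est = RateEstimate(k=0.5, f=0.25, p=0.5, burn_in_fraction=0.1)
        assert est.k == est.f / est.p
        with pytest.raises(ConfigurationError):
            RateEstimate(k=0.4, f=0.25, p=0.5, burn_in_fraction=0.1)


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------

folded = StateDefinition("folded", (-np.inf,), (-0.5,))
unfolded = StateDefinition("unfolded", (0.5,), (np.inf,))


class TestStability:
    def test_equal_weights_give_zero(self):
        arch = synthetic_archive([0.0] * 40, p_i=0.5)
        est = estimate_stability(folded, unfolded,
                                 equilibrium_archives=arch)
        assert est.dG_fold == pytest.approx(0.0, abs=1e-12)

    def test_tenfold_ratio_at_room_temperature(self):
        arch = synthetic_archive([0.0] * 40, p_i=10.0 / 11.0)
        est = estimate_stability(folded, unfolded,
                                 equilibrium_archives=arch,
                                 temperature=293.15, units="real")
        expected = -R_KCAL_PER_MOL_K * 293.15 * np.log(10.0)
        assert est.dG_fold == pytest.approx(expected, abs=1e-10)
        assert est.dG_fold == pytest.approx(-1.341, abs=5e-4)

    def test_empty_state_rejected(self):
        arch = synthetic_archive([0.0] * 40, p_i=1.0 - 1e-18,
                                 positions=[[-1.0, -1.0]] * 40)
        with pytest.raises(UndefinedStateError):
            estimate_stability(folded, unfolded, equilibrium_archives=arch)

    def test_opposing_steady_states_recover_detailed_balance(self):
        # fabricate folding flux 0.02 and unfolding flux 0.002: the
        # combined estimate must reproduce dG = -kT ln(k_f / k_u)
        fold = synthetic_archive([0.02] * 60, p_i=1.0 - 1e-15)
        unfold = synthetic_archive([0.002] * 60, p_i=1.0 - 1e-15)
        est = estimate_stability(folded, unfolded,
                                 folding_archives=fold,
                                 unfolding_archives=unfold,
                                 temperature=1.0, units="reduced")
        assert est.dG_fold == pytest.approx(-np.log(10.0), rel=1e-9)


# ---------------------------------------------------------------------------
# Barrier conversions, MFPT, efficiency
# ---------------------------------------------------------------------------

class TestBarrierConversion:
    @pytest.mark.parametrize("fold,expected", [(32, 2.0), (7, 1.1),
                                               (21, 1.8)])
    def test_reverse_direction_fold_changes(self, fold, expected):
        br = barrier_reduction(fold, temperature=293.15)
        assert round(br.ddG_barrier, 1) == expected

    def test_unit_fold_change_is_zero(self):
        assert barrier_reduction(1.0).ddG_barrier == 0.0

    def test_closed_form_to_high_precision(self):
        br = barrier_reduction(np.e, temperature=293.15)
        assert br.ddG_barrier == pytest.approx(R_KCAL_PER_MOL_K * 293.15,
                                               abs=1e-10)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ConfigurationError):
            barrier_reduction(0.0)


class TestMFPTAndEfficiency:
    def test_reciprocal_rate(self):
        est = RateEstimate(k=2.0, f=1.0, p=0.5, burn_in_fraction=0.1,
                           sem=0.2, n_runs=3)
        t, sem = mfpt(est)
        assert t == 0.5 and sem == pytest.approx(0.05)

    def test_reduced_unit_contract(self):
        est = RateEstimate(k=0.25, f=0.25, p=1.0, burn_in_fraction=0.1)
        assert mfpt(est)[0] == 4.0   # rate per tau -> MFPT in tau

    def test_efficiency_arithmetic(self):
        est = RateEstimate(k=1e-6, f=1e-6, p=1.0, burn_in_fraction=0.1)
        arch = synthetic_archive([0.01] * 10 + [0.0] * 0, p_i=0.5)
        # 10 iterations x 2 walkers x tau 1.0 of aggregate time
        rep = efficiency(est, arch, burn_in_fraction=0.0)
        assert rep.mfpt == 1e6
        assert rep.n_events == 10
        assert rep.we_cost == 20.0
        assert rep.S == pytest.approx(1e6 * 10 / 20.0)

    def test_equal_costs_give_unit_efficiency(self):
        arch = synthetic_archive([0.01] * 10, p_i=0.5)
        est = RateEstimate(k=0.5, f=0.25, p=0.5, burn_in_fraction=0.0)
        rep = efficiency(est, arch, burn_in_fraction=0.0)
        assert rep.S == pytest.approx(rep.brute_force_cost / rep.we_cost)

    def test_zero_events_rejected(self):
        est = RateEstimate(k=1.0, f=1.0, p=1.0, burn_in_fraction=0.1)
        arch = synthetic_archive([0.0] * 10, p_i=0.5)
        with pytest.raises(ConfigurationError):
            efficiency(est, arch)
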