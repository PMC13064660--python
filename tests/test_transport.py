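"""Phloem budgets, ring accumulation, cellulose synthesis and the forward model."""

import numpy as np
import pandas as pd
import pytest

from isoring.chronology import TimeWindow
from isoring.fractionation import VPDB, VSMOW, delta_to_ratio, ratio_to_delta
from isoring.params import IsotopeParams
from isoring.transport import (
    CoverageError,
    PhloemDepletionError,
    PhloemState,
    RingArchive,
    cellulose_delta_C,
    cellulose_delta_O,
    cellulose_from_wood,
    lignin_uncertainty,
    phloem_wsc_delta,
    run_forward,
    step_phloem,
    wood_from_cellulose,
)


class TestPhloemStep:
    def test_carbon_pool_fixed_point(self, params):
        """Constant fluxes drive C_ps to (A - F_wood)/k."""
        state = PhloemState(1e6, delta_to_ratio(30.0), delta_to_ratio(-26.0, VPDB))
        a_n, r_d = 3.0, 0.4
        for _ in range(5000):
            state, _ = step_phloem(state, a_n, r_d, state.r_ps_o, state.r_ps_c,
                                   params, dt=86400.0)
        expected = (a_n - params.f_wood_of_rd * r_d) / params.k_per_second
        assert state.c_ps == pytest.approx(expected, rel=1e-6)

    def test_isotope_fixed_point_is_leaf_ratio(self, params):
        """With e = x = 0 and constant R_ls the pool ratio converges to R_ls."""
        r_ls = delta_to_ratio(32.0)
        state = PhloemState(2e6, delta_to_ratio(20.0), delta_to_ratio(-26.0, VPDB))
        for _ in range(4000):
            state, _ = step_phloem(state, 3.0, 0.4, r_ls, state.r_ps_c,
                                   params, dt=86400.0)
        assert state.r_ps_o == pytest.approx(r_ls, rel=1e-9)

    def test_stepwise_budget_closure(self, params):
        """Per-step isotopologue bookkeeping closes: in - out = pool change."""
        rng = np.random.default_rng(0)
        state = PhloemState(2e6, delta_to_ratio(28.0), delta_to_ratio(-26.0, VPDB))
        m0 = state.c_ps * state.r_ps_o
        total_in = total_out = 0.0
        for _ in range(500):
            a_n = float(rng.uniform(-0.5, 6.0))
            state, flux = step_phloem(state, a_n, 0.4, delta_to_ratio(30.0),
                                      delta_to_ratio(-26.0, VPDB), params, 1800.0)
            total_in += flux["o_in"]
            total_out += flux["o_out"]
        assert abs(total_in - total_out - (state.c_ps * state.r_ps_o - m0)) \
            / max(abs(total_in), 1.0) < 1e-12

    def test_depletion_raises(self, params):
        state = PhloemState(1e4, delta_to_ratio(28.0), delta_to_ratio(-26.0, VPDB))
        with pytest.raises(PhloemDepletionError):
            for _ in range(50):
                state, _ = step_phloem(state, -1.0, 2.0, delta_to_ratio(30.0),
                                       delta_to_ratio(-26.0, VPDB), params, 86400.0)


class TestRingArchive:
    def _fill(self, archive, year, doys, c, sw, o, c13, dt=1800.0):
        for d in doys:
            archive.add_step(year, d, c, sw, o, c13, dt)

    def test_outside_window_is_ignored(self):
        w = TimeWindow(2015, 150, 160)
        archive = RingArchive([w])
        archive.add_step(2015, 140, 1e6, 2e-3, 2e-3, 1e-2, 1800.0)
        archive.add_step(2016, 155, 1e6, 2e-3, 2e-3, 1e-2, 1800.0)
        assert archive.entries[0].int_cps == 0.0

    def test_additivity_over_split_windows(self):
        whole = RingArchive([TimeWindow(2015, 150, 169)])
        halves = RingArchive([TimeWindow(2015, 150, 159), TimeWindow(2015, 160, 169)])
        rng = np.random.default_rng(1)
        for d in range(150, 170):
            c, sw, o, c13 = rng.uniform(0.5, 2.0, 4)
            whole.add_step(2015, d, c, sw, o, c13, 1800.0)
            halves.add_step(2015, d, c, sw, o, c13, 1800.0)
        a, (b1, b2) = whole.entries[0], halves.entries
        assert a.int_cps == pytest.approx(b1.int_cps + b2.int_cps, rel=1e-14)
        assert a.int_ps_o == pytest.approx(b1.int_ps_o + b2.int_ps_o, rel=1e-14)

    def test_constant_integrand(self):
        w = TimeWindow(2015, 150, 151)
        archive = RingArchive([w])
        self._fill(archive, 2015, [150, 151], 2.0, 3.0, 5.0, 7.0, dt=10.0)
        acc = archive.entries[0]
        assert acc.int_cps == pytest.approx(2.0 * 10.0 * 2)
        assert acc.mean_ps_o == pytest.approx(5.0)


class TestCellulose:
    @pytest.fixture()
    def acc(self):
        archive = RingArchive([TimeWindow(2015, 150, 151)])
        # two steps with different pool sizes: a real weighted mean
        archive.add_step(2015, 150, 1.0, 2.00e-3, 2.10e-3, 1.10e-2, 1800.0)
        archive.add_step(2015, 151, 3.0, 2.02e-3, 2.06e-3, 1.12e-2, 1800.0)
        return archive.entries[0]

    def test_pex_endmembers(self, acc):
        assert cellulose_delta_O(acc, 0.0) == ratio_to_delta(acc.mean_ps_o, VSMOW)
        assert cellulose_delta_O(acc, 1.0) == pytest.approx(
            ratio_to_delta(acc.mean_sw_term, VSMOW), abs=1e-12
        )

    def test_hand_worked_weighted_mean(self, acc):
        # C_ps-weighted mean of R_ps over the two steps, by hand
        expected = (1.0 * 2.10e-3 + 3.0 * 2.06e-3) / 4.0
        assert acc.mean_ps_o == pytest.approx(expected, rel=1e-14)

    def test_carbon_equation_is_oxygen_at_pex_zero(self, acc):
        """Bit-exact: the carbon weighted mean equals the mixing equation
        evaluated at p_ex = 0 on the carbon accumulators."""
        assert cellulose_delta_C(acc) == ratio_to_delta(acc.mean_ps_c, VPDB)

    def test_pex_round_trip(self, acc):
        from isoring.analysis import invert_apparent_pex

        d_cel = cellulose_delta_O(acc, 0.36)
        d_wood = wood_from_cellulose(d_cel, "O")
        est = invert_apparent_pex(d_wood, acc.mean_sw_term, acc.mean_ps_o)
        assert est.p_ex == pytest.approx(0.36, abs=1e-10)


class TestWoodOffsets:
    @pytest.mark.parametrize("delta,iso,expected",
                             [(30.0, "O", 25.6), (-23.0, "C", -24.1)])
    def test_constant_shift(self, delta, iso, expected):
        assert wood_from_cellulose(delta, iso) == pytest.approx(expected, abs=1e-12)

    def test_round_trip_identity(self):
        for iso in ("O", "C"):
            assert cellulose_from_wood(wood_from_cellulose(27.3, iso), iso) == \
                pytest.approx(27.3, abs=1e-12)

    def test_unknown_isotope(self):
        with pytest.raises(KeyError):
            wood_from_cellulose(30.0, "H")


class TestLignin:
    def test_carbon_half_range(self):
        assert lignin_uncertainty(0.75, 0.05, -1.1) == pytest.approx(0.22, abs=1e-12)

    def test_oxygen_half_range(self):
        assert lignin_uncertainty(0.75, 0.05, -4.4) == pytest.approx(0.88, abs=1e-12)

    def test_zero_swing(self):
        assert lignin_uncertainty(0.75, 0.0, -4.4) == 0.0

    def test_degenerate_fraction(self):
        with pytest.raises(ValueError):
            lignin_uncertainty(1.0, 0.05, -4.4)


class TestPhloemWsc:
    def test_no_exchange_no_pinitol_is_identity(self):
        p = IsotopeParams(pinitol_phloem_frac=0.0, phloem_loading_exchange=0.0)
        r = delta_to_ratio(31.0)
        assert phloem_wsc_delta(r, delta_to_ratio(-12.0), 1.027, p) == \
            pytest.approx(31.0, abs=1e-12)

    def test_exchange_noop_when_already_equilibrated(self):
        p = IsotopeParams(pinitol_phloem_frac=0.0)
        r_sw = delta_to_ratio(-12.0)
        r_ps = 1.027 * r_sw
        assert phloem_wsc_delta(r_ps, r_sw, 1.027, p) == \
            pytest.approx(ratio_to_delta(r_ps, VSMOW), abs=1e-12)

    def test_hand_worked_mixture(self):
        p = IsotopeParams()
        r_ps = delta_to_ratio(35.0)
        r_sw_term = delta_to_ratio(15.0)  # alpha_wc * R_sw equivalent of 15 permil
        exchanged = (3.0 / 11.0) * r_sw_term + (8.0 / 11.0) * r_ps
        expected = ratio_to_delta(
            (exchanged + 0.15 * delta_to_ratio(25.0)) / 1.15, VSMOW
        )
        got = phloem_wsc_delta(r_ps, r_sw_term / 1.0, 1.0, p)
        assert got == pytest.approx(expected, abs=1e-12)


class TestRunForward:
    def test_deterministic(self, dataset, windows, params):
        a = run_forward(dataset.drivers, windows, params)
        b = run_forward(dataset.drivers, windows, params)
        assert np.array_equal(a.table["d18o_wood_permil"], b.table["d18o_wood_permil"])
        assert np.array_equal(a.pools.d18o_ps, b.pools.d18o_ps)

    def test_constant_forcing_gives_flat_ring(self, constant_drivers, params):
        wins = [TimeWindow(2015, 150 + 20 * i, 170 + 20 * i) for i in range(4)]
        fwd = run_forward(constant_drivers, wins, params,
                          season_doy=(91, 300), spinup_days=30)
        vals = fwd.table["d18o_wood_permil"].to_numpy()
        assert vals.max() - vals.min() < 0.05

    def test_conservation_per_year(self, forward):
        for budget in forward.budgets:
            assert budget["o_closure_rel"] < 1e-9
            assert budget["c13_closure_rel"] < 1e-9

    def test_low_pass_variance_ordering(self, forward):
        """Phloem smooths leaf sugar, which smooths leaf water."""
        idx = forward.pools.index
        july = idx.month == 7
        lw_scaled = forward.pools.alpha_wc[july] * (forward.pools.d18o_lw[july] + 1000.0)
        assert (np.var(forward.pools.d18o_ps[july])
                <= np.var(forward.pools.d18o_ls[july])
                <= np.var(lw_scaled))

    def test_rh_anticorrelation_with_constant_source_water(self, dataset, windows, params):
        drivers = dataset.drivers.copy()
        drivers["d18o_sw_permil"] = -12.0
        fwd = run_forward(drivers, windows, params)
        t = fwd.table
        r = np.corrcoef(t["d18o_wood_permil"], t["rh_an_weighted_pct"])[0, 1]
        assert r < 0

    def test_window_outside_span_raises(self, dataset, params):
        with pytest.raises(CoverageError):
            run_forward(dataset.drivers, [TimeWindow(2015, 60, 120)], params)
        with pytest.raises(CoverageError):
            run_forward(dataset.drivers, [TimeWindow(2019, 150, 200)], params)

    def test_golden_regression(self, dataset, windows, params, request):
        """Frozen forward run: guards the full numerical chain."""
        fwd = run_forward(dataset.drivers, windows, params)
        path = request.path.parent / "data" / "golden_forward.csv"
        golden = pd.read_csv(path)
        for col in ("d18o_wood_permil", "d13c_wood_permil"):
            assert np.allclose(fwd.table[col], golden[col], atol=1e-9)
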