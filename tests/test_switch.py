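import math

import numpy as np
import pytest

import replisim as rs
from replisim.params import StepProfile
from replisim.models.switch import (
    ld_rhs,
    oscillation_amplitude,
    switch_initiation_predicate,
    switch_rhs,
)

from conftest import engine


class TestLDRightHandSide:
    P = rs.SwitchParams.ld()

    def test_fully_active_state_is_pushed_down(self):
        # at f=1 the activation term vanishes; only deactivation remains
        val = ld_rhs(1.0, ori_conc=1.0, params=self.P, lam=0.0)
        beta = self.P.beta_data.value(math.inf)
        assert val == pytest.approx(-beta * 1.0 / (self.P.k_data + 1.0))
        assert val < 0

    def test_fully_inactive_state_is_pushed_up(self):
        val = ld_rhs(0.0, ori_conc=1.0, params=self.P, lam=0.0)
        act = self.P.alpha_l * self.P.mean_l
        assert val == pytest.approx(act * 1.0 / (self.P.k_l + 1.0))
        assert val > 0

    def test_symmetric_rates_balance_at_one_half(self):
        # equal max rates and equal Michaelis constants: steady state f=1/2
        p = rs.SwitchParams.ld(
            alpha_l=0.1, mean_l=1.0, k_l=0.2, k_data=0.2,
            beta_data=StepProfile(low=0.1, high=0.1),
        )
        assert ld_rhs(0.5, ori_conc=1.0, params=p, lam=0.0) == pytest.approx(0.0)

    def test_f_outside_unit_interval_is_rejected(self):
        with pytest.raises(ValueError):
            switch_rhs(1.5, 1.0, 1.0, 0.1, 0.1, 0.0)


def test_lddr_rhs_matches_independent_expression():
    """Independent oracle: the full time-dependent right-hand side written
    out directly from its definition, term by term."""
    p = rs.SwitchParams()
    lam = 0.01
    f, l, V, n_ori, n_d1, n_d2 = 0.41, 0.28, 1.7, 2, 2.0, 1.0
    dt_i = 20.0  # datA low, DARS2 high window
    act = p.alpha_l * l + (p.alpha_d1 * n_d1 + p.alpha_d2.high * n_d2) / V
    deact = (p.beta_data.low + p.beta_rida) * n_ori / V
    expected = (
        act * (1 - f) / (p.k_l + 1 - f)
        - deact * f / (p.k_data + f)
        + lam * (1 - f)
    )
    # same quantities through the model machinery
    m = rs.make_model("lddr")
    cell = rs.CellState(
        t=100.0, V=V,
        chrom=rs.ChromosomeConfiguration(n_ori=n_ori, completed=1.0),
    )
    cell.chrom.active_rounds = [rs.ReplicationRound(90.0, 1.0)]  # forks active
    m.reset(rs.EngineParams(growth_rate=lam), cell, np.random.default_rng(0))
    m.f, m.l, m.n_d1, m.n_d2 = f, l, n_d1, n_d2
    m._t_last_init = cell.t - dt_i
    a, d = m.active_rates(cell)
    got = switch_rhs(f, a, d, p.k_l, p.k_data, lam)
    assert got == pytest.approx(expected, rel=1e-12)


def test_rida_activity_follows_replication_state():
    p = rs.SwitchParams()
    m = rs.make_model("lddr")
    cell = rs.CellState(t=50.0, V=1.0,
                        chrom=rs.ChromosomeConfiguration(n_ori=2, completed=1.0))
    m.reset(rs.EngineParams(growth_rate=0.01), cell, np.random.default_rng(0))
    m._t_last_init = 30.0
    _, deact_no_forks = m.active_rates(cell)
    cell.chrom.active_rounds = [rs.ReplicationRound(45.0, 1.0)]
    _, deact_forks = m.active_rates(cell)
    assert deact_forks - deact_no_forks == pytest.approx(p.beta_rida * 2 / 1.0)


def test_dars2_copy_number_is_delayed_after_initiation():
    """The DARS2 copy count doubles only tau_d2 minutes after the origins
    fired."""
    ep = engine(120.0, trace_interval=-1.0, n_generations=4)
    m = rs.make_model("lddr")
    rec_unused = None
    cell = rs.CellState(t=0.0, V=1.0, chrom=rs.ChromosomeConfiguration())
    m.reset(ep, cell, np.random.default_rng(0))
    cell.chrom.start_round(100.0)
    m.on_initiation(cell, 100.0)
    assert m.n_d2 == 1.0
    cell.t = 100.0 + m.params.tau_d2 - 0.5
    m.step(cell, 0.01, np.random.default_rng(0))
    assert m.n_d2 == 1.0        # still pre-duplication
    cell.t = 100.0 + m.params.tau_d2 + 0.5
    m.step(cell, 0.01, np.random.default_rng(0))
    assert m.n_d2 == 2.0


@pytest.mark.parametrize(
    "f, eclipse, expected",
    [(0.749, False, False), (0.75, True, False), (0.75, False, True)],
)
def test_switch_initiation_predicate(f, eclipse, expected):
    assert switch_initiation_predicate(f, 0.75, eclipse) is expected


class TestOscillationAmplitude:
    def test_constant_trace_at_threshold_has_zero_amplitude(self):
        assert oscillation_amplitude(np.full(50, 0.8), 0.8) == pytest.approx(0.0)

    def test_amplitude_is_threshold_minus_minimum(self):
        tr = np.concatenate([np.linspace(0.8, 0.3, 25), np.linspace(0.3, 0.8, 25)])
        assert oscillation_amplitude(tr, 0.8) == pytest.approx(0.5)

    def test_short_trace_is_rejected(self):
        with pytest.raises(ValueError):
            oscillation_amplitude([0.5], 0.8)


def _delta_f(record, f_star, burn=10):
    tb = record.divisions["time_min"].iloc[burn]
    f = record.trace.loc[record.trace.time_min > tb, "f"].to_numpy()
    return oscillation_amplitude(f, f_star)


class TestSwitchDynamics:
    def test_lddr_reduces_bitwise_to_ld(self):
        """Zeroing DARS1/2 and RIDA and flattening datA makes the LDDR
        integration bit-identical to the LD configuration."""
        ld = rs.SwitchParams.ld()
        reduced = rs.SwitchParams(
            alpha_l=ld.alpha_l, mean_l=ld.mean_l, k_l=ld.k_l, k_data=ld.k_data,
            beta_data=StepProfile(low=0.025, high=0.025),
            alpha_d1=0.0, alpha_d2=StepProfile(low=0.0, high=0.0),
            beta_rida=0.0,
        )
        noise = rs.NoiseParams(cv_l=0.08)
        ep = engine(60.0, dt=0.05, n_generations=15, seed=13, trace_interval=2.0)
        rec_ld = rs.run_simulation(rs.make_model("ld", ld, noise=noise), ep)
        rec_red = rs.run_simulation(
            rs.models.SwitchModel(reduced, noise=noise, name="lddr"), ep
        )
        assert np.array_equal(
            rec_ld.trace["f"].to_numpy(), rec_red.trace["f"].to_numpy()
        )
        assert np.array_equal(
            rec_ld.initiations["v_star"].to_numpy(),
            rec_red.initiations["v_star"].to_numpy(),
        )

    def test_f_stays_in_unit_interval(self, lddr_slow_record):
        f = lddr_slow_record.trace.f.to_numpy()
        assert f.min() >= 0.0 and f.max() <= 1.0

    def test_origin_doubling_strictly_decreases_f_drive(self):
        """Doubling the origin concentration doubles the deactivation term,
        strictly lowering df/dt (the mechanism that prevents immediate
        reinitiation)."""
        p = rs.SwitchParams.ld()
        for f in (0.2, 0.5, 0.75):
            r1 = ld_rhs(f, ori_conc=1.0, params=p, lam=0.005)
            r2 = ld_rhs(f, ori_conc=2.0, params=p, lam=0.005)
            assert r2 < r1

    def test_ld_initiation_volume_constant_at_each_growth_rate(self):
        for tau_d in (120.0, 45.0, 25.0):
            ep = engine(tau_d, n_generations=30)
            rec = rs.run_simulation(rs.make_model("ld"), ep)
            v = rec.v_star_series()
            assert v.std() / v.mean() < 1e-3

    def test_ld_amplitude_decreases_with_growth_rate(self):
        f_star = rs.SwitchParams.ld().f_star
        dfs = []
        for tau_d in (120.0, 60.0, 30.0, 21.0):
            ep = engine(tau_d, n_generations=25, trace_interval=0.25)
            rec = rs.run_simulation(rs.make_model("ld"), ep)
            dfs.append(_delta_f(rec, f_star))
        assert all(a > b for a, b in zip(dfs, dfs[1:]))

    def test_lddr_amplitude_exceeds_ld_at_fast_growth(self):
        tau_d = 60.0 * math.log(2) / 2.0  # lambda = 2 per hour
        ep = engine(tau_d, n_generations=25, trace_interval=0.25)
        rec_ld = rs.run_simulation(rs.make_model("ld"), ep)
        rec_lddr = rs.run_simulation(rs.make_model("lddr"), ep)
        df_ld = _delta_f(rec_ld, rs.SwitchParams.ld().f_star)
        df_lddr = _delta_f(rec_lddr, rs.SwitchParams().f_star)
        assert df_lddr > df_ld

    def test_high_rates_give_larger_amplitude_than_realistic_rates(self):
        """At slow growth the oscillation amplitude grows with the overall
        (de)activation rate scale."""
        f_star = rs.SwitchParams.ld().f_star
        dfs = {}
        for scale in (1.0, 100.0):
            p = rs.SwitchParams.ld(
                alpha_l=0.115 * scale,
                beta_data=StepProfile(low=0.025 * scale, high=0.025 * scale),
            )
            ep = engine(120.0, dt=0.01, n_generations=20, trace_interval=0.25)
            rec = rs.run_simulation(rs.models.SwitchModel(p, name="ld"), ep)
            dfs[scale] = _delta_f(rec, f_star)
        assert dfs[100.0] > dfs[1.0]
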