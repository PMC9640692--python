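import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import replisim as rs
from replisim.chromosome import ChromosomeConfiguration
from replisim.models.ait import (
    ait_initiation_predicate,
    dnaA_synthesis_rate,
    free_initiator_concentration,
    titration_site_count,
)

from conftest import engine


class TestBindingQuadratic:
    def test_no_sites_leaves_everything_free(self):
        assert free_initiator_concentration(3.0, 0.0, 1.0) == pytest.approx(3.0)

    def test_tight_binding_limit(self):
        # K_s -> 0 with excess protein: free = total - sites
        assert free_initiator_concentration(2.0, 1.0, 1e-12) == pytest.approx(
            1.0, rel=1e-6
        )

    def test_generic_root_matches_numeric_equilibrium_solver(self):
        """Independent oracle: solve the two-species binding equilibrium
        p_free * s_free / complex = K numerically."""
        p_tot, s_tot, k = 2.0, 1.0, 0.1

        def residual(p_free):
            c = p_tot - p_free          # bound protein = occupied sites
            s_free = s_tot - c
            return p_free * s_free - k * c

        oracle = brentq(residual, max(p_tot - s_tot, 0.0), p_tot, xtol=1e-15)
        got = free_initiator_concentration(p_tot, s_tot, k)
        assert got == pytest.approx(oracle, rel=1e-9)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        p_tot=st.floats(0.0, 1e4),
        s_tot=st.floats(0.0, 1e4),
        k=st.floats(1e-6, 1e3),
    )
    def test_conservation_and_bounds(self, p_tot, s_tot, k):
        """Bound + free = total, and the free concentration is physical."""
        p_free = free_initiator_concentration(p_tot, s_tot, k)
        assert 0.0 <= p_free <= p_tot + 1e-9
        bound = p_tot - p_free
        assert bound <= s_tot + 1e-6 * max(s_tot, 1.0)
        # mass-action residual vanishes
        s_free = s_tot - bound
        resid = p_free * s_free - k * bound
        # double-precision root: residual scales with the square of the
        # largest concentration entering the quadratic
        scale = max(p_tot, s_tot, k, 1.0) ** 2
        assert abs(resid) < 1e-9 * scale


class TestSynthesisRate:
    P = rs.AITParams()

    def test_unrepressed_maximum(self):
        lam = 0.01
        assert dnaA_synthesis_rate(2.0, 0.0, self.P, lam) == pytest.approx(
            self.P.phi0 * lam * 2.0
        )

    @pytest.mark.parametrize("hill", [1.0, 2.0, 5.0])
    def test_half_maximum_at_promoter_kd(self, hill):
        p = rs.AITParams(hill_n=hill)
        lam = 0.01
        rate = dnaA_synthesis_rate(1.0, p.k_p, p, lam)
        assert rate == pytest.approx(0.5 * p.phi0 * lam)

    def test_seqa_synthesis_block_silences_the_promoter(self):
        p = rs.AITParams(seqa_mode="synthesis_block")
        assert dnaA_synthesis_rate(1.0, 0.0, p, 0.01, in_block=True) == 0.0
        # origin-block-only mode does not silence synthesis
        q = rs.AITParams(seqa_mode="origin_block_only")
        assert dnaA_synthesis_rate(1.0, 0.0, q, 0.01, in_block=True) > 0.0


def test_titration_site_count_reduces_to_single_round_ramp():
    n_s = 300
    chrom = ChromosomeConfiguration(n_ori=1, completed=1.0)
    assert titration_site_count(chrom, n_s, 0.0, 40.0) == pytest.approx(n_s)
    chrom.start_round(0.0)
    assert titration_site_count(chrom, n_s, 20.0, 40.0) == pytest.approx(1.5 * n_s)
    chrom.retire_completed(40.0, 40.0)
    assert titration_site_count(chrom, n_s, 45.0, 40.0) == pytest.approx(2 * n_s)


@pytest.mark.parametrize(
    "p_free_rel, eclipse, expected",
    [(0.99, False, False), (1.0, True, False), (1.0, False, True), (1.3, False, True)],
)
def test_initiation_predicate_threshold_and_eclipse(p_free_rel, eclipse, expected):
    k_ori = 150.0
    assert ait_initiation_predicate(p_free_rel * k_ori, k_ori, eclipse) is expected


class TestAITRegimes:
    def test_low_growth_titration_keeps_free_concentration_low(self):
        """While unoccupied sites exist the free concentration stays far
        below the origin threshold; it rises sharply near initiation."""
        ep = engine(120.0, trace_interval=1.0)
        m = rs.make_model("ait")
        rec = rs.run_simulation(m, ep)
        tr = rec.trace
        t0, t1 = rec.initiations.time_min.iloc[-2], rec.initiations.time_min.iloc[-1]
        cycle = tr[(tr.time_min > t0 + 1) & (tr.time_min <= t1 + 0.5)]
        p = cycle.p_free.to_numpy()
        # deep in the accumulation phase the free pool is titrated away
        assert p.min() < 0.1 * p.max()
        # and the concentration spends a substantial part of the cycle well
        # below the origin threshold before rising sharply to reach it
        assert np.mean(p < 0.5 * m.params.k_ori) > 0.3
        assert p.max() >= 0.99 * m.params.k_ori

    def test_low_growth_v_star_converges(self):
        ep = engine(120.0, n_generations=40)
        rec = rs.run_simulation(rs.make_model("ait"), ep)
        v = rec.v_star_series()
        assert v.std() / v.mean() < 1e-3

    def test_fork_overlap_causes_premature_reinitiation(self):
        """Below the fork-overlap boundary (tau_d < T_C) the titration
        mechanism reinitiates prematurely: some inter-initiation intervals
        drop well below the doubling time and the deterministic CV of v*
        rises by orders of magnitude."""
        ep35 = engine(35.0, n_generations=50)
        rec35 = rs.run_simulation(rs.make_model("ait"), ep35)
        iv = rec35.inter_initiation_intervals()
        assert iv.min() < 31.0
        v35 = rec35.v_star_series()
        cv35 = v35.std() / v35.mean()
        ep44 = engine(44.0, n_generations=50)
        rec44 = rs.run_simulation(rs.make_model("ait"), ep44)
        v44 = rec44.v_star_series()
        cv44 = v44.std() / v44.mean()
        assert cv35 > 100 * cv44

    def test_deep_overlap_reinitiates_at_eclipse_end(self):
        """For tau_d below ~ln2*T_C the free concentration never falls
        below threshold during the eclipse and reinitiation happens at the
        eclipse end."""
        ep = engine(26.0, n_generations=50)
        rec = rs.run_simulation(rs.make_model("ait"), ep)
        iv = rec.inter_initiation_intervals()
        assert iv.min() < ep.tau_b + 1.0

    def test_poisson_expression_noise_gives_adder_like_correlations(self):
        """With dnaA expression noise the titration model keeps stable
        cycles; dv* regresses on v* with a shallow slope."""
        ep = engine(120.0, dt=0.05, n_generations=220, seed=11)
        noise = rs.NoiseParams(dnaa_noise_mode="poisson_birth")
        rec = rs.run_simulation(rs.make_model("ait", noise=noise), ep)
        stats = rs.adder_regression(rec.v_star_series())
        assert abs(stats.slope) < 0.35
        assert stats.adder_ratio == pytest.approx(1.0, abs=0.05)
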