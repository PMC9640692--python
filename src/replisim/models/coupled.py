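"""Full titration-switch model.

Tracks the total DnaA copy number ``N_T`` and the ATP-bound copy number
``N_ATP`` explicitly.  Synthesis follows the autoregulated volume-
proportional rate law, repressed by the *free* total DnaA concentration
(only DnaA not sequestered on titration sites can reach the promoter) and
silenced during the SeqA synthesis block.  All newly made DnaA is counted
as ATP-bound (cytoplasmic ATP far exceeds ADP).  Activation and
deactivation fluxes are the LDDR set acting on copy numbers:

    dN_ATP/dt = synthesis
              + (alpha_l [l] V + alpha_d1 n_d1 + alpha_d2(t) n_d2)
                * [D]_ADP / (K_D + [D]_ADP)
              - (beta_datA(t) + beta_rida(t)) n_ori
                * [D]_ATP / (K_D + [D]_ATP).

Active and inactive DnaA share one titration-site affinity, so the free
total concentration ``[D]_T,f`` follows the same binding quadratic as the
titration model, and the free ATP-DnaA concentration factorizes as
``[D]_ATP,f = [D]_T,f * f`` with ``f = N_ATP / N_T``.  Replication fires
when ``[D]_ATP,f`` reaches the critical threshold.
"""

from __future__ import annotations

import math

import numpy as np

from ..engine import CellState
from ..params import CoupledParams, EngineParams, NoiseParams
from .ait import free_initiator_concentration, titration_site_count


def free_total_dnaA(
    n_t: float, V: float, s_total_count: float, k_s: float
) -> float:
    """Free total DnaA concentration from the titration quadratic."""
    if V <= 0:
        raise ValueError("volume must be positive")
    return free_initiator_concentration(n_t / V, s_total_count / V, k_s)


def coupled_initiation_predicate(
    d_atp_free: float, threshold: float, eclipse: bool
) -> bool:
    """True when the free ATP-DnaA concentration has reached the critical
    initiation threshold and the origin is not eclipsed."""
    return (d_atp_free >= threshold) and not eclipse


class CoupledModel:
    """Engine adapter for the coupled titration-switch model."""

    trace_columns = ("N_T", "N_ATP", "f", "D_T_free", "D_ATP_free", "N_s", "lipid")

    def __init__(self, params: CoupledParams | None = None,
                 noise: NoiseParams | None = None,
                 init_l: float | None = None):
        self.params = params if params is not None else CoupledParams()
        self.noise = noise if noise is not None else NoiseParams()
        self.name = "coupled"
        self.init_l = init_l
        self._poisson = (
            self.params.dnaa_noise or self.noise.dnaa_noise_mode == "poisson_birth"
        )
        self.N_T: float = 0.0
        self.N_ATP: float = 0.0
        self.l: float = self.params.mean_l
        self.n_d1: float = 1.0
        self.n_d2: float = 1.0
        self._pending_loci: list[tuple[float, float, int]] = []
        self._t_last_init = -math.inf
        self._lam = 0.0
        self._t_c = 40.0

    @property
    def threshold(self) -> float:
        return self.params.threshold

    def reset(self, engine: EngineParams, cell: CellState,
              rng: np.random.Generator) -> None:
        self._lam = engine.growth_rate
        self._t_c = engine.t_c
        self.N_T = 0.6 * self.params.n_s
        self.N_ATP = 0.5 * self.N_T
        self.l = self.params.mean_l if self.init_l is None else self.init_l
        self.n_d1 = 1.0
        self.n_d2 = 1.0
        self._pending_loci = []
        self._t_last_init = -math.inf

    # -- derived quantities ------------------------------------------------
    def site_count(self, cell: CellState) -> float:
        return titration_site_count(cell.chrom, self.params.n_s, cell.t, self._t_c)

    def free_atp_conc(self, cell: CellState) -> float:
        d_t_free = free_total_dnaA(
            self.N_T, cell.V, self.site_count(cell), self.params.k_s
        )
        return d_t_free * (self.N_ATP / self.N_T)

    def rhs(self, cell: CellState) -> tuple[float, float]:
        """(dN_T/dt, dN_ATP/dt) at the current state."""
        p = self.params
        V = cell.V
        d_t_free = free_total_dnaA(self.N_T, V, self.site_count(cell), p.k_s)
        in_block = p.seqa_mode == "synthesis_block" and cell.t < cell.eclipse_until
        if in_block:
            synth = 0.0
        else:
            synth = p.phi0 * self._lam * V / (
                1.0 + (d_t_free / p.k_p) ** p.hill_n
            )
        d_atp = self.N_ATP / V
        d_adp = (self.N_T - self.N_ATP) / V
        if d_adp < 0.0:
            raise ValueError("N_ATP exceeds N_T")
        dt_i = cell.t - self._t_last_init
        act = (
            p.alpha_l * self.l * V
            + p.alpha_d1 * self.n_d1
            + p.alpha_d2.value(dt_i) * self.n_d2
        ) * d_adp / (p.k_d + d_adp)
        rida = p.beta_rida if cell.chrom.replicating() else 0.0
        deact = (p.beta_data.value(dt_i) + rida) * cell.chrom.n_ori * d_atp / (
            p.k_d + d_atp
        )
        return synth, synth + act - deact

    # -- engine interface --------------------------------------------------
    def step(self, cell: CellState, dt: float, rng: np.random.Generator) -> None:
        while self._pending_loci and self._pending_loci[0][0] <= cell.t:
            _, amount, which = self._pending_loci.pop(0)
            if which == 1:
                self.n_d1 += amount
            else:
                self.n_d2 += amount
        p = self.params
        alpha = self._lam * p.mean_l
        l_new = self.l + (alpha - self._lam * self.l) * dt
        if self.noise.cv_l > 0.0:
            sigma = p.mean_l * self.noise.cv_l * math.sqrt(2.0 * self._lam)
            l_new += sigma * math.sqrt(dt) * rng.standard_normal()
            if l_new < 0.0:
                l_new = 0.0
        d_n_t, d_n_atp = self.rhs(cell)
        # substep when the (de)activation fluxes would move the ATP pool by
        # more than ~2% of the total in one Euler step (stiff switch limit)
        n_sub = 1
        est = abs(d_n_atp) * dt
        if est > 0.02 * max(self.N_T, 1.0):
            n_sub = min(int(est / (0.02 * max(self.N_T, 1.0))) + 1, 200)
        if self._poisson:
            made = float(rng.poisson(d_n_t * dt))
            self.N_T += made
            self.N_ATP += made + (d_n_atp - d_n_t) * dt
            self._clamp_atp()
        else:
            h = dt / n_sub
            for _ in range(n_sub):
                if n_sub > 1:
                    d_n_t, d_n_atp = self.rhs(cell)
                self.N_T += d_n_t * h
                self.N_ATP += d_n_atp * h
                self._clamp_atp()
        self.l = l_new

    def _clamp_atp(self) -> None:
        if self.N_ATP < 0.0:
            self.N_ATP = 0.0
        elif self.N_ATP > self.N_T:
            self.N_ATP = self.N_T

    def signal(self, cell: CellState) -> float:
        return self.free_atp_conc(cell)

    def on_initiation(self, cell: CellState, t_event: float) -> None:
        fired = cell.chrom.n_ori / 2.0
        p = self.params
        self._pending_loci.append((t_event + p.tau_d1, fired, 1))
        self._pending_loci.append((t_event + p.tau_d2, fired, 2))
        self._pending_loci.sort(key=lambda e: e[0])
        self._t_last_init = t_event

    def on_division(self, cell: CellState, rng: np.random.Generator) -> None:
        if self._poisson:
            n_atp = int(round(self.N_ATP))
            n_adp = int(round(self.N_T - self.N_ATP))
            self.N_ATP = float(rng.binomial(n_atp, 0.5))
            self.N_T = self.N_ATP + float(rng.binomial(n_adp, 0.5))
        else:
            self.N_T /= 2.0
            self.N_ATP /= 2.0
        self.n_d1 /= 2.0
        self.n_d2 /= 2.0
        self._pending_loci = [
            (t, amount / 2.0, which) for (t, amount, which) in self._pending_loci
        ]
        if self.noise.partition_kick > 0.0:
            self.l += self.noise.partition_kick * self.l * rng.standard_normal()
            if self.l < 0.0:
                self.l = 0.0

    def trace_values(self, cell: CellState) -> tuple:
        d_t_free = free_total_dnaA(
            self.N_T, cell.V, self.site_count(cell), self.params.k_s
        )
        f = self.N_ATP / self.N_T
        return (self.N_T, self.N_ATP, f, d_t_free, d_t_free * f,
                self.site_count(cell), self.l)
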