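"""Autoregulated initiator-titration (AIT) model.

DnaA is synthesized at a volume-proportional rate under negative
autoregulation by its own free cytoplasmic concentration,

    dN_p/dt = phi0 * lam * V / (1 + ([p]/K_p)^n),

and binds high-affinity titration sites distributed homogeneously on the
chromosome (``n_s`` per genome equivalent, so the site count ramps linearly
during replication).  Site binding is treated in quasi-equilibrium: the free
concentration solves the mass-action quadratic for one protein species and
one site species.  Replication initiates when the free concentration reaches
the origin dissociation constant ``K_ori > K_s``.

SeqA enters in two variants: the eclipse (origin block) is engine-level and
always present; ``seqa_mode="synthesis_block"`` additionally suppresses DnaA
synthesis while the eclipse clock is running.
"""

from __future__ import annotations

import math

import numpy as np

from ..chromosome import ChromosomeConfiguration
from ..engine import CellState
from ..params import AITParams, EngineParams, NoiseParams


def free_initiator_concentration(
    p_total: float, s_total: float, k_s: float
) -> float:
    """Free initiator concentration from binding quasi-equilibrium.

    Solves ``p_f^2 + p_f*(s_tot - p_tot + K_s) - K_s*p_tot = 0`` for the
    physical root in ``[0, p_tot]`` (mass-action binding of one protein to
    one site species with site conservation).
    """
    if p_total < 0 or s_total < 0:
        raise ValueError("total concentrations must be non-negative")
    if k_s <= 0:
        raise ValueError("k_s must be positive")
    b = s_total - p_total + k_s
    disc = b * b + 4.0 * k_s * p_total
    assert disc >= 0.0, "binding quadratic discriminant cannot be negative"
    p_free = 0.5 * (-b + math.sqrt(disc))
    # numerical guard: the exact root lies in [0, p_total]
    if p_free < 0.0:
        p_free = 0.0
    elif p_free > p_total:
        p_free = p_total
    return p_free


def titration_site_count(
    chrom: ChromosomeConfiguration, n_s: int, t: float, t_c: float
) -> float:
    """Total titration sites: ``n_s`` per genome equivalent.

    For a single replication round this is the piecewise-linear ramp
    ``N_0 -> 2*N_0`` over the C period; with multifork replication every
    active round contributes its own ramp.
    """
    return n_s * chrom.genome_equivalents(t, t_c)


def dnaA_synthesis_rate(
    V: float,
    p_free: float,
    params: AITParams,
    lam: float,
    in_block: bool = False,
) -> float:
    """Autoregulated synthesis rate (proteins/min); zero during the SeqA
    synthesis block when that variant is enabled."""
    if V <= 0:
        raise ValueError("volume must be positive")
    if p_free < 0:
        raise ValueError("p_free must be non-negative")
    if params.seqa_mode == "synthesis_block" and in_block:
        return 0.0
    return params.phi0 * lam * V / (1.0 + (p_free / params.k_p) ** params.hill_n)


def ait_initiation_predicate(
    p_free: float, k_ori: float, eclipse: bool
) -> bool:
    """True when the free initiator concentration has reached the origin
    dissociation constant and the origin is not eclipsed."""
    return (p_free >= k_ori) and not eclipse


class AITModel:
    """Engine adapter for the AIT model (one cell at a time)."""

    trace_columns = ("N_p", "N_s", "p_total", "p_free")

    def __init__(self, params: AITParams | None = None,
                 noise: NoiseParams | None = None):
        self.params = params if params is not None else AITParams()
        self.noise = noise if noise is not None else NoiseParams()
        self.name = "ait_seqa" if self.params.seqa_mode == "synthesis_block" else "ait"
        self._poisson = (
            self.params.dnaa_noise or self.noise.dnaa_noise_mode == "poisson_birth"
        )
        self.N_p: float = 0.0
        self._lam = 0.0
        self._t_c = 40.0

    @property
    def threshold(self) -> float:
        return self.params.k_ori

    def reset(self, engine: EngineParams, cell: CellState,
              rng: np.random.Generator) -> None:
        self._lam = engine.growth_rate
        self._t_c = engine.t_c
        # start sub-threshold: sites in excess of proteins
        self.N_p = 0.6 * self.params.n_s

    # -- helpers -----------------------------------------------------------
    def site_count(self, cell: CellState) -> float:
        return titration_site_count(cell.chrom, self.params.n_s, cell.t, self._t_c)

    def p_free(self, cell: CellState) -> float:
        return free_initiator_concentration(
            self.N_p / cell.V, self.site_count(cell) / cell.V, self.params.k_s
        )

    # -- engine interface --------------------------------------------------
    def step(self, cell: CellState, dt: float, rng: np.random.Generator) -> None:
        in_block = cell.t < cell.eclipse_until
        rate = dnaA_synthesis_rate(
            cell.V, self.p_free(cell), self.params, self._lam, in_block
        )
        if self._poisson:
            self.N_p += rng.poisson(rate * dt)
        else:
            self.N_p += rate * dt

    def signal(self, cell: CellState) -> float:
        return self.p_free(cell)

    def on_initiation(self, cell: CellState, t_event: float) -> None:
        pass  # the site ramp starts through the chromosome bookkeeping

    def on_division(self, cell: CellState, rng: np.random.Generator) -> None:
        if self._poisson:
            self.N_p = float(rng.binomial(int(round(self.N_p)), 0.5))
        else:
            self.N_p /= 2.0

    def trace_values(self, cell: CellState) -> tuple:
        n_s = self.site_count(cell)
        p_tot = self.N_p / cell.V
        return (self.N_p, n_s, p_tot,
                free_initiator_concentration(p_tot, n_s / cell.V, self.params.k_s))
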