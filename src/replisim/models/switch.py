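"""DnaA activation-switch models (LD and LDDR).

The total DnaA concentration is held strictly constant; the state variable
is the ATP-bound fraction ``f``.  Activation (lipids, DARS1, DARS2) and
deactivation (datA/DDAH, RIDA) are zero-order-ultrasensitive push-pull
reactions,

    df/dt = A(t) (1-f)/(K_act + 1-f) - B(t) f/(K_deact + f) + lam (1-f),

where the activation total ``A`` contains a volume-independent lipid term
and locus terms proportional to the DARS copy-number concentrations, while
the deactivation total ``B`` is proportional to the origin concentration
(datA sits next to the origin; RIDA rides on active forks).  Because ``B``
falls with the volume while the lipid part of ``A`` does not, the steady
fraction rises as the cell grows: the switch senses the origin density.
Replication fires at the critical fraction ``f*``.

The LD configuration keeps only the lipid and a flat datA rate; the LDDR
configuration adds DARS1 (constant), DARS2 and datA two-level activity
profiles anchored to the latest initiation, RIDA while forks are active,
and the replication delays of the DARS loci.  Both run through the same
code path, so zeroing the extra LDDR rates reproduces LD bit for bit.
"""

from __future__ import annotations

import math

import numpy as np

from ..engine import CellState
from ..params import EngineParams, NoiseParams, SwitchParams

_F_TOL = 1e-9  # integrator overshoot tolerance before clamping


def switch_rhs(
    f: float,
    act_total: float,
    deact_total: float,
    k_act: float,
    k_deact: float,
    lam: float,
) -> float:
    """Shared push-pull right-hand side for both switch configurations."""
    if f < -_F_TOL or f > 1.0 + _F_TOL:
        raise ValueError(f"ATP-DnaA fraction f={f} outside [0, 1]")
    return (
        act_total * (1.0 - f) / (k_act + 1.0 - f)
        - deact_total * f / (k_deact + f)
        + lam * (1.0 - f)
    )


def ld_rhs(
    f: float,
    ori_conc: float,
    params: SwitchParams,
    lam: float,
    l: float | None = None,
) -> float:
    """LD right-hand side: lipid activation against flat datA deactivation.

    ``ori_conc`` is the origin (= datA) concentration ``n_ori / V``.
    """
    if l is None:
        l = params.mean_l
    act = params.alpha_l * l
    deact = params.beta_data.value(math.inf) * ori_conc
    return switch_rhs(f, act, deact, params.k_l, params.k_data, lam)


def lddr_rhs(
    f: float,
    act_total: float,
    deact_total: float,
    params: SwitchParams,
    lam: float,
) -> float:
    """LDDR right-hand side given the time-dependent rate totals."""
    return switch_rhs(f, act_total, deact_total, params.k_l, params.k_data, lam)


def switch_initiation_predicate(f: float, f_star: float, eclipse: bool) -> bool:
    return (f >= f_star) and not eclipse


def oscillation_amplitude(f_trace, f_star: float) -> float:
    """Amplitude of the activation oscillation, ``Delta f = f* - min f``.

    ``f_trace`` must cover at least one full steady cycle after burn-in.
    """
    f_trace = np.asarray(f_trace, dtype=float)
    if f_trace.size < 2:
        raise ValueError("trace too short: need at least one full cycle")
    return float(f_star - f_trace.min())


class SwitchModel:
    """Engine adapter for the activation switch (LD and LDDR)."""

    trace_columns = ("f", "ori_conc", "act_total", "deact_total", "lipid")

    def __init__(
        self,
        params: SwitchParams | None = None,
        noise: NoiseParams | None = None,
        name: str = "lddr",
        init_l: float | None = None,
        perturb_at_division: int | None = None,
        perturb_l: float | None = None,
    ):
        self.params = params if params is not None else SwitchParams()
        self.noise = noise if noise is not None else NoiseParams()
        self.name = name
        self.init_l = init_l
        # optional perturbation-relaxation protocol: at the given division
        # event the lipid concentration is reset to ``perturb_l``
        self.perturb_at_division = perturb_at_division
        self.perturb_l = perturb_l
        self.f: float = 0.0
        self.l: float = self.params.mean_l
        self.n_d1: float = 1.0
        self.n_d2: float = 1.0
        self._pending_loci: list[tuple[float, float, int]] = []
        self._t_last_init = -math.inf
        self._lam = 0.0
        self._div_count = 0
        self.initiation_samples: list[tuple[int, float]] = []  # (div_count, l)

    @property
    def threshold(self) -> float:
        return self.params.f_star

    def reset(self, engine: EngineParams, cell: CellState,
              rng: np.random.Generator) -> None:
        self._lam = engine.growth_rate
        self.f = 0.5 * self.params.f_star
        self.l = self.params.mean_l if self.init_l is None else self.init_l
        self.n_d1 = 1.0
        self.n_d2 = 1.0
        self._pending_loci = []
        self._t_last_init = -math.inf
        self._div_count = 0
        self.initiation_samples = []

    # -- rates -------------------------------------------------------------
    def active_rates(self, cell: CellState) -> tuple[float, float]:
        """Activation and deactivation totals at the current cell state.

        The DARS copy numbers are the delayed locus counts (origins present
        ``tau_d1``/``tau_d2`` ago); RIDA contributes only while a round of
        replication is active.
        """
        p = self.params
        dt_i = cell.t - self._t_last_init
        act = p.alpha_l * self.l + (
            p.alpha_d1 * self.n_d1 + p.alpha_d2.value(dt_i) * self.n_d2
        ) / cell.V
        if cell.chrom.replicating():
            if p.rida_per_replisome:
                n_rida = sum(r.n_origins_at_start for r in cell.chrom.active_rounds)
            else:
                n_rida = cell.chrom.n_ori
            rida = p.beta_rida * n_rida / cell.V
        else:
            rida = 0.0
        deact = p.beta_data.value(dt_i) * cell.chrom.n_ori / cell.V + rida
        return act, deact

    # -- engine interface --------------------------------------------------
    def step(self, cell: CellState, dt: float, rng: np.random.Generator) -> None:
        while self._pending_loci and self._pending_loci[0][0] <= cell.t:
            _, amount, which = self._pending_loci.pop(0)
            if which == 1:
                self.n_d1 += amount
            else:
                self.n_d2 += amount
        # lipid dynamics: dl = (alpha - lam*l) dt + sigma dW
        p = self.params
        alpha = self._lam * p.mean_l
        l_new = self.l + (alpha - self._lam * self.l) * dt
        if self.noise.cv_l > 0.0:
            sigma = p.mean_l * self.noise.cv_l * math.sqrt(2.0 * self._lam)
            l_new += sigma * math.sqrt(dt) * rng.standard_normal()
            if l_new < 0.0:
                l_new = 0.0
        act, deact = self.active_rates(cell)
        # the push-pull terms are stiff near the f boundaries when the
        # (de)activation totals are large; substep the f update so a single
        # Euler step never moves f by more than ~0.01
        f = self.f
        rhs = switch_rhs(f, act, deact, p.k_l, p.k_data, self._lam)
        # stiffness bound |d rhs/df| <= act/k_l + deact/k_data + lam; keep
        # each Euler substep well inside the stability limit so f cannot
        # cross the [0, 1] boundaries
        stiff = act / p.k_l + deact / p.k_data + self._lam
        n_sub = 1
        if stiff * dt > 0.4:
            n_sub = min(int(stiff * dt / 0.4) + 1, 500)
        h = dt / n_sub
        for _ in range(n_sub):
            if n_sub > 1:
                rhs = switch_rhs(f, act, deact, p.k_l, p.k_data, self._lam)
            f += rhs * h
            if f < 0.0:
                if f < -_F_TOL:
                    raise ArithmeticError(
                        f"integrator overshoot: f={f} at t={cell.t}"
                    )
                f = 0.0
            elif f > 1.0:
                if f > 1.0 + _F_TOL:
                    raise ArithmeticError(
                        f"integrator overshoot: f={f} at t={cell.t}"
                    )
                f = 1.0
        self.f = f
        self.l = l_new

    def signal(self, cell: CellState) -> float:
        return self.f

    def on_initiation(self, cell: CellState, t_event: float) -> None:
        # chromosome already doubled; the newly fired origins number n_ori/2
        fired = cell.chrom.n_ori / 2.0
        p = self.params
        self._pending_loci.append((t_event + p.tau_d1, fired, 1))
        self._pending_loci.append((t_event + p.tau_d2, fired, 2))
        self._pending_loci.sort(key=lambda e: e[0])
        self._t_last_init = t_event
        self.initiation_samples.append((self._div_count, self.l))

    def on_division(self, cell: CellState, rng: np.random.Generator) -> None:
        self._div_count += 1
        if (
            self.perturb_at_division is not None
            and self._div_count == self.perturb_at_division
        ):
            self.l = self.perturb_l
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
        act, deact = self.active_rates(cell)
        return (self.f, cell.chrom.n_ori / cell.V, act, deact, self.l)
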