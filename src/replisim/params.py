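"""Parameter containers for the cell-cycle engine and the model families.

Units used throughout the package:

* time — minutes (the CLI and config accept growth rates in h^-1),
* volume — cubic micrometres,
* concentrations — molecules per cubic micrometre,
* rates carrying a "per concentration" factor — um^3 / min.

The engine parameters encode the Cooper–Helmstetter scaffold: exponential
growth at rate ``lam``, a C period ``t_c`` for fork traversal, a D period
``t_d_period`` from termination to division, division a fixed cycling time
``tau_cc = T_C + T_D`` after the initiation event that triggered it, and an
eclipse ``tau_b`` after each initiation during which reinitiation at the
origin is blocked (SeqA sequestration).

The kinetic constants of the model families are not free-floating numbers in
the literature; where a measured scale exists (C period ~40 min, eclipse
~10 min, datA-mediated hydrolysis ~10 DnaA/min per datA, lipid activation
4.6x the datA rate) the defaults use it, and the remaining constants were
fixed once so that each deterministic model family reproduces its
characteristic regime behaviour (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

LN2 = math.log(2.0)


def growth_rate_per_min(growth_rate_per_h: float) -> float:
    """Convert a growth rate from h^-1 to min^-1."""
    return growth_rate_per_h / 60.0


@dataclass
class EngineParams:
    """Cell-cycle scaffold parameters (time in minutes)."""

    growth_rate: float = LN2 / 120.0  # min^-1; default doubling time 2 h
    t_c: float = 40.0                 # C period (fork traversal time)
    t_d_period: float = 20.0          # D period (termination -> division)
    tau_b: float = 10.0               # eclipse (SeqA origin block)
    dt: float = 0.01                  # Euler timestep
    n_generations: int = 40           # divisions to simulate
    burn_in_generations: int = 10     # discarded in downstream statistics
    seed: int = 0
    v_init: float = 0.5               # birth volume of the founder cell (um^3)
    trace_interval: float = 1.0       # trace sampling period (min); <=0: off
    max_steps: int | None = None      # safety cap; default derived from run

    def __post_init__(self) -> None:
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if self.t_c <= 0:
            raise ValueError("t_c must be positive")
        if self.t_d_period < 0:
            raise ValueError("t_d_period must be non-negative")
        if self.tau_b < 0:
            raise ValueError("tau_b must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_b > 0 and self.dt > self.tau_b / 10.0:
            raise ValueError("dt must be small compared to the eclipse tau_b")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.burn_in_generations < 0:
            raise ValueError("burn_in_generations must be >= 0")
        if self.v_init <= 0:
            raise ValueError("v_init must be positive")

    @property
    def doubling_time(self) -> float:
        return LN2 / self.growth_rate

    @property
    def tau_cc(self) -> float:
        """Initiation-to-division delay, T_C + T_D."""
        return self.t_c + self.t_d_period

    @classmethod
    def from_doubling_time(cls, tau_d: float, **kw) -> "EngineParams":
        return cls(growth_rate=LN2 / tau_d, **kw)

    @classmethod
    def from_growth_rate_per_h(cls, lam_h: float, **kw) -> "EngineParams":
        return cls(growth_rate=growth_rate_per_min(lam_h), **kw)

    def to_dict(self) -> dict:
        return asdict(self)


SEQA_MODES = ("none", "origin_block_only", "synthesis_block")


@dataclass
class AITParams:
    """Autoregulated initiator-titration model constants.

    ``phi0`` is the gene allocation density of the initiator: the protein
    density the cell would reach with an unrepressed promoter.  Synthesis is
    repressed by the free cytoplasmic initiator concentration through a Hill
    function with midpoint ``k_p`` and coefficient ``hill_n``.  Initiators
    bind ``n_s`` chromosomal titration sites per genome equivalent with
    dissociation constant ``k_s`` and the origin with the weaker ``k_ori``;
    replication fires when the free concentration reaches ``k_ori``.
    """

    phi0: float = 500.0        # gene allocation density (um^-3)
    k_p: float = 200.0         # promoter dissociation constant (um^-3)
    hill_n: float = 5.0        # promoter Hill coefficient
    k_s: float = 1.0           # titration-site dissociation constant (um^-3)
    k_ori: float = 150.0       # origin dissociation constant (um^-3)
    n_s: int = 300             # titration sites per chromosome
    seqa_mode: str = "origin_block_only"
    dnaa_noise: bool = False   # Poisson-driven synthesis + binomial splits

    def __post_init__(self) -> None:
        if self.k_ori <= self.k_s:
            raise ValueError(
                "titration requires k_ori > k_s (origin binds weaker than "
                "the titration sites)"
            )
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.n_s <= 0:
            raise ValueError("n_s must be positive")
        if min(self.phi0, self.k_p, self.k_s) <= 0:
            raise ValueError("phi0, k_p and k_s must be positive")
        if self.seqa_mode not in SEQA_MODES:
            raise ValueError(
                f"seqa_mode must be one of {SEQA_MODES}, got {self.seqa_mode!r}"
            )


@dataclass
class StepProfile:
    """Two-level activity profile anchored to the latest initiation.

    The activity is ``high`` while ``t - t_i`` lies in ``[on, off)`` and
    ``low`` outside the window.  ``off = inf`` recovers a single step.
    """

    low: float
    high: float
    on: float = 0.0
    off: float = math.inf

    def __post_init__(self) -> None:
        if self.low < 0 or self.high < 0:
            raise ValueError("step profile rates must be non-negative")
        if self.off < self.on:
            raise ValueError("step profile window must have off >= on")

    def value(self, dt_since_initiation: float) -> float:
        if self.on <= dt_since_initiation < self.off:
            return self.high
        return self.low


def _default_data_profile() -> StepProfile:
    # DDAH boosted by IHF for ~15 min after initiation, basal otherwise.
    return StepProfile(low=0.07, high=0.6, on=0.0, off=15.0)


def _default_dars2_profile() -> StepProfile:
    # DARS2 active from its duplication until fork completion; the high
    # rate balances RIDA so the initiation volume stays comparable across
    # growth regimes.
    return StepProfile(low=0.005, high=1.86, on=16.0, off=40.0)


@dataclass
class SwitchParams:
    """DnaA activation-switch constants (LD and LDDR families).

    All rates are normalized by the (constant) total DnaA concentration, so
    activation/deactivation terms have units of min^-1 once multiplied by a
    concentration.  The datA rate equals the per-site hydrolysis capacity
    ~10 DnaA/min divided by a total DnaA concentration of 400 um^-3, and the
    lipid activation rate is 4.6x the datA rate.
    """

    total_dnaa: float = 400.0        # [D]_T (um^-3); normalization only
    alpha_l: float = 0.115           # lipid activation (um^3/min per [l])
    mean_l: float = 0.3              # mean lipid concentration (um^-3)
    k_l: float = 0.1                 # activation Michaelis constant (of f)
    k_data: float = 0.1              # deactivation Michaelis constant (of f)
    beta_data: StepProfile = field(default_factory=_default_data_profile)
    alpha_d1: float = 0.0375         # DARS1, constant, much weaker than DARS2
    alpha_d2: StepProfile = field(default_factory=_default_dars2_profile)
    beta_rida: float = 1.5           # RIDA, active while any fork is active
    tau_d1: float = 12.0             # DARS1 replication delay (min)
    tau_d2: float = 16.0             # DARS2 replication delay (min)
    f_star: float = 0.75             # critical ATP-DnaA fraction
    rida_per_replisome: bool = False  # scale RIDA with fork pairs, not n_ori

    def __post_init__(self) -> None:
        if not 0.0 < self.f_star < 1.0:
            raise ValueError("f_star must lie strictly between 0 and 1")
        for name in ("alpha_l", "alpha_d1", "beta_rida"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_l <= 0 or self.k_data <= 0:
            raise ValueError("Michaelis constants must be positive")
        if self.mean_l <= 0:
            raise ValueError("mean_l must be positive")
        if self.tau_d1 < 0 or self.tau_d2 < 0:
            raise ValueError("locus delays must be non-negative")

    @classmethod
    def ld(cls, **kw) -> "SwitchParams":
        """LD configuration: lipids + constant datA, no DARS, no RIDA."""
        kw.setdefault("beta_data", StepProfile(low=0.025, high=0.025))
        kw.setdefault("alpha_d1", 0.0)
        kw.setdefault("alpha_d2", StepProfile(low=0.0, high=0.0))
        kw.setdefault("beta_rida", 0.0)
        return cls(**kw)


@dataclass
class CoupledParams:
    """Full titration-switch model: explicit DnaA counts plus the LDDR
    (de)activators and titration of both nucleotide forms.

    Active and inactive DnaA share one titration-site affinity ``k_s`` and
    one promoter affinity ``k_p``; promoter repression is exerted by the
    *free* total DnaA concentration.  Replication fires when the free
    ATP-DnaA concentration reaches ``threshold``.
    """

    # synthesis / titration (initiator = DnaA)
    phi0: float = 500.0
    k_p: float = 200.0
    hill_n: float = 5.0
    k_s: float = 1.0
    n_s: int = 300
    seqa_mode: str = "synthesis_block"
    # switch, un-normalized (the activation-switch rates times a total DnaA
    # concentration scale of 400 um^-3); concentration-scale Michaelis K
    k_d: float = 40.0                # K_D for (de)activation (um^-3)
    alpha_l: float = 46.0            # lipid activation (DnaA/min per [l] per um^3)
    mean_l: float = 0.3
    beta_data: StepProfile = field(
        default_factory=lambda: StepProfile(low=28.0, high=240.0, on=0.0, off=15.0)
    )
    alpha_d1: float = 15.0
    alpha_d2: StepProfile = field(
        default_factory=lambda: StepProfile(low=2.0, high=744.0, on=16.0, off=40.0)
    )
    beta_rida: float = 600.0
    tau_d1: float = 12.0
    tau_d2: float = 16.0
    threshold: float = 50.0          # critical free ATP-DnaA conc (um^-3)
    dnaa_noise: bool = False

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.k_d <= 0 or self.k_s <= 0 or self.k_p <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.n_s <= 0:
            raise ValueError("n_s must be positive")
        if self.seqa_mode not in SEQA_MODES:
            raise ValueError(
                f"seqa_mode must be one of {SEQA_MODES}, got {self.seqa_mode!r}"
            )


@dataclass
class NoiseParams:
    """Stochastic fluctuation settings.

    The lipid concentration follows an Ornstein–Uhlenbeck process
    ``dl = (alpha - lam*l) dt + sigma dW`` whose stationary mean is
    ``mean_l = alpha/lam``; the amplitude is parameterized by the stationary
    coefficient of variation ``cv_l``, giving ``sigma =
    mean_l*cv_l*sqrt(2*lam)``.  ``partition_kick`` adds a zero-mean Gaussian
    kick of relative standard deviation ``partition_kick`` to the lipid
    concentration at division (binomial partitioning of a concentration-level
    variable).
    """

    cv_l: float = 0.0
    partition_kick: float = 0.0
    dnaa_noise_mode: str = "off"  # "off" | "poisson_birth"

    def __post_init__(self) -> None:
        if self.cv_l < 0:
            raise ValueError("cv_l must be non-negative")
        if self.partition_kick < 0:
            raise ValueError("partition_kick must be non-negative")
        if self.dnaa_noise_mode not in ("off", "poisson_birth"):
            raise ValueError("dnaa_noise_mode must be 'off' or 'poisson_birth'")
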