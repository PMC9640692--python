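"""Stochastic component fluctuations and perturbation-relaxation analysis.

The lipid concentration follows

    d[l]/dt = alpha - lam*[l] + xi(t),

an Ornstein–Uhlenbeck process: production at constant rate ``alpha``,
dilution at the growth rate, and white noise realized as additive Gaussian
increments whose variance is calibrated to a target stationary coefficient
of variation.  Fluctuations therefore regress to the mean ``<l> =
alpha/lam`` on the doubling-time scale, ``<dl(t)|l_0> = dl_0 * 2^(-t/tau_d)``
— an initial perturbation is halved every cell cycle.  Because the
initiation volume of the switch models maps monotonically onto the lipid
concentration, initiation-volume perturbations inherit the same geometric
relaxation, ``<dv*_n|v*_0> = dv*_0 * 2^(-n)``, which is the origin of the
adder correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .engine import run_simulation
from .params import EngineParams, NoiseParams, SwitchParams
from .models.switch import SwitchModel


def lipid_step(
    l: float,
    dt: float,
    params: NoiseParams,
    lam: float,
    mean_l: float,
    rng: np.random.Generator,
) -> float:
    """One Euler–Maruyama update of the lipid concentration.

    ``sigma = mean_l * cv_l * sqrt(2*lam)`` makes the stationary CV equal
    ``cv_l``.  Negative excursions are clipped to zero.
    """
    if l < 0 or dt <= 0:
        raise ValueError("need l >= 0 and dt > 0")
    alpha = lam * mean_l
    out = l + (alpha - lam * l) * dt
    if params.cv_l > 0:
        sigma = mean_l * params.cv_l * math.sqrt(2.0 * lam)
        out += sigma * math.sqrt(dt) * rng.standard_normal()
    return max(out, 0.0)


def partition_lipids(
    l: float, params: NoiseParams, rng: np.random.Generator
) -> float:
    """Division kick: zero-mean Gaussian with SD ``partition_kick * l``.

    Mean-field division leaves concentrations unchanged; the kick models
    binomial partitioning noise at the concentration level.
    """
    if params.partition_kick == 0.0:
        return l
    return max(l + params.partition_kick * l * rng.standard_normal(), 0.0)


@dataclass
class PerturbationEnsemble:
    """Per-generation conditional means of an ensemble started from a
    common lipid offset ``delta_l0``."""

    n_replicates: int
    delta_l0: float
    mean_l: float
    mean_v_star: float
    generations: np.ndarray       # 0, 1, 2, ...
    delta_l: np.ndarray           # <l at initiation n> - <l>
    delta_v_star: np.ndarray      # <v*_n> - <v*>


def relaxation_analysis(
    generations: np.ndarray, deviations: np.ndarray
) -> float:
    """Per-generation decay factor ``r`` of a conditional-mean series.

    Fits ``<delta_n> = delta_0 * r^n`` by log-linear least squares on the
    magnitudes.  A geometric halving gives exactly r = 0.5.
    """
    generations = np.asarray(generations, dtype=float)
    deviations = np.asarray(deviations, dtype=float)
    if generations.size < 3:
        raise ValueError("need at least 3 generations to fit a decay factor")
    mags = np.abs(deviations)
    if np.any(mags <= 0):
        raise ValueError("degenerate (zero) deviations: decay factor undefined")
    fit = sps.linregress(generations, np.log2(mags))
    return float(2.0 ** fit.slope)


def run_perturbation_ensemble(
    engine: EngineParams,
    params: SwitchParams | None = None,
    noise: NoiseParams | None = None,
    n_replicates: int = 100,
    delta_l0_rel: float = 0.3,
    n_track: int = 5,
    model_name: str = "ld",
    seed: int | None = None,
) -> PerturbationEnsemble:
    """Replicate lineages subjected to a common lipid perturbation.

    Each replicate runs unperturbed through the burn-in generations; at the
    burn-in division its lipid concentration is reset to ``<l> + delta_l0``
    with ``delta_l0 = delta_l0_rel * <l>``.  The conditional means of the
    lipid concentration and of v* at the following initiation events are
    reported relative to the stationary means: ``<l>`` analytically, and
    ``<v*>`` pooled from the same replicates several generations after the
    perturbation has relaxed (the pooled estimate is far more precise than
    a single reference lineage, which matters because a baseline error of
    order the late-generation deviations would corrupt the decay fit).
    """
    if params is None:
        params = SwitchParams.ld()
    if noise is None:
        noise = NoiseParams(cv_l=0.05)
    if seed is None:
        seed = engine.seed
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(n_replicates)
    mean_l = params.mean_l
    delta_l0 = delta_l0_rel * mean_l

    burn = engine.burn_in_generations
    n_relaxed = 3            # generations pooled for the v* baseline
    n_gen = burn + n_track + 4 + n_relaxed
    engine_rep = EngineParams(
        growth_rate=engine.growth_rate, t_c=engine.t_c,
        t_d_period=engine.t_d_period, tau_b=engine.tau_b, dt=engine.dt,
        n_generations=n_gen, burn_in_generations=burn,
        seed=seed, v_init=engine.v_init, trace_interval=-1.0,
    )
    l_at_init = np.full((n_replicates, n_track), np.nan)
    v_at_init = np.full((n_replicates, n_track), np.nan)
    baseline: list[float] = []
    for i in range(n_replicates):
        model = SwitchModel(
            params, noise=noise, name=model_name,
            perturb_at_division=burn, perturb_l=mean_l + delta_l0,
        )
        rec = run_simulation(
            model, engine_rep, rng=np.random.default_rng(seeds[i])
        )
        v_all = rec.initiations["v_star"].to_numpy()
        for j, (div_count, l_val) in enumerate(model.initiation_samples):
            n = div_count - burn
            if 0 <= n < n_track:
                l_at_init[i, n] = l_val
                v_at_init[i, n] = v_all[j]
            elif n >= n_track + 4:
                baseline.append(v_all[j])

    mean_v = float(np.mean(baseline))
    gens = np.arange(n_track)
    dl = np.nanmean(l_at_init, axis=0) - mean_l
    dv = np.nanmean(v_at_init, axis=0) - mean_v
    return PerturbationEnsemble(
        n_replicates=n_replicates,
        delta_l0=delta_l0,
        mean_l=mean_l,
        mean_v_star=mean_v,
        generations=gens,
        delta_l=dl,
        delta_v_star=dv,
    )
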