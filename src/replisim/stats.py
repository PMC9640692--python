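"""Lineage statistics: initiation-volume series, adder correlations, and
coefficient-of-variation summaries.

The central observable is the initiation volume per origin
``v*_n = V(t_init,n) / n_ori,before``.  Between consecutive initiation
events the added volume per origin is ``Delta v*_n = 2 v*_{n+1} - v*_n``
(the factor 2 accounts for the doubling of origins at initiation n).  A
perfect adder adds a v*-independent volume (regression slope 0 of Delta v*
on v*, and <Delta v*> = <v*>); a perfect sizer initiates at a fixed volume
(slope exactly -1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import LineageRecord, run_simulation
from .params import EngineParams


def initiation_volume_series(
    record: LineageRecord, burn_in: int | None = None
) -> np.ndarray:
    """Ordered v* series after burn-in."""
    return record.v_star_series(burn_in=burn_in)


def added_volume_series(v_star: np.ndarray) -> np.ndarray:
    """Added initiation volume per origin, ``2 v*_{n+1} - v*_n``."""
    v_star = np.asarray(v_star, dtype=float)
    if v_star.size < 2:
        raise ValueError("need at least 2 initiation events")
    return 2.0 * v_star[1:] - v_star[:-1]


@dataclass
class AdderStats:
    """Scatter, binned means and regression of Delta v* against v*."""

    v_star: np.ndarray
    delta_v: np.ndarray
    slope: float
    intercept: float
    pearson_r: float
    n: int
    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_sems: np.ndarray

    @property
    def adder_ratio(self) -> float:
        """<Delta v*> / <v*>; 1 for an adder."""
        return float(self.delta_v.mean() / self.v_star.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"v_star": self.v_star, "delta_v_star": self.delta_v})


def adder_regression(v_star: np.ndarray, n_bins: int = 10) -> AdderStats:
    """Regression and equal-count binning of (v*_n, Delta v*_n) pairs.

    Pearson R and the least-squares slope are computed on the raw pairs;
    the bins (equal-count, to stabilize the SEM in the tails) carry mean
    and standard error per bin.
    """
    v_star = np.asarray(v_star, dtype=float)
    if v_star.size < 11:
        raise ValueError("need at least 10 (v*, delta v*) pairs")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    dv = added_volume_series(v_star)
    x = v_star[:-1]
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate v* series: all values identical, "
                         "regression slope undefined")
    fit = sps.linregress(x, dv)
    order = np.argsort(x, kind="stable")
    edges = np.array_split(order, n_bins)
    centers = np.array([x[idx].mean() for idx in edges])
    means = np.array([dv[idx].mean() for idx in edges])
    sems = np.array([sps.sem(dv[idx]) if len(idx) > 1 else np.nan for idx in edges])
    return AdderStats(
        v_star=x,
        delta_v=dv,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n=int(dv.size),
        bin_centers=centers,
        bin_means=means,
        bin_sems=sems,
    )


@dataclass
class CVStats:
    """Mean, population SD and coefficient of variation of v*."""

    mean: float
    sd: float
    cv: float
    n_events: int


def cv_of_initiation_volume(
    record_or_series, burn_in: int | None = None
) -> CVStats:
    """CV = sigma/mu of the post-burn-in initiation volume series."""
    if isinstance(record_or_series, LineageRecord):
        v = record_or_series.v_star_series(burn_in=burn_in)
    else:
        v = np.asarray(record_or_series, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 initiation events for a CV")
    mu = float(v.mean())
    sd = float(v.std())  # population SD
    return CVStats(mean=mu, sd=sd, cv=sd / mu, n_events=int(v.size))


def growth_rate_scan(
    model_factory,
    growth_rates_per_h,
    engine_template: EngineParams,
    seeds=None,
) -> pd.DataFrame:
    """One lineage per growth rate (and seed); per-rate v* statistics.

    ``model_factory`` is a zero-state callable ``(growth_rate_per_h) ->
    model`` so each run gets a fresh model.  Returns a long-format table
    with one row per (growth rate, seed).
    """
    growth_rates_per_h = np.asarray(growth_rates_per_h, dtype=float)
    if seeds is None:
        seeds = [engine_template.seed]
    rows = []
    for lam_h in growth_rates_per_h:
        for seed in seeds:
            engine = EngineParams(
                growth_rate=lam_h / 60.0,
                t_c=engine_template.t_c,
                t_d_period=engine_template.t_d_period,
                tau_b=engine_template.tau_b,
                dt=engine_template.dt,
                n_generations=engine_template.n_generations,
                burn_in_generations=engine_template.burn_in_generations,
                seed=seed,
                v_init=engine_template.v_init,
                trace_interval=-1.0,
            )
            try:
                rec = run_simulation(model_factory(lam_h), engine)
                stats = cv_of_initiation_volume(rec)
            except Exception as exc:
                raise RuntimeError(
                    f"growth-rate scan failed at lambda={lam_h} /h: {exc}"
                ) from exc
            rows.append(
                (lam_h, seed, stats.mean, stats.sd, stats.cv, stats.n_events)
            )
    return pd.DataFrame(
        rows,
        columns=["growth_rate_per_h", "seed", "mean_v_star", "sd", "cv", "n_events"],
    )
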