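"""Event-driven fixed-step integrator for a single-cell lineage.

The engine owns everything the model families share: exponential volume
growth, threshold-triggered synchronous initiation at all origins, multifork
replication bookkeeping, the SeqA eclipse, division a fixed cycling time
``tau_cc = T_C + T_D`` after the initiation event that scheduled it, and
random selection of one daughter at division.

Integration is explicit Euler with timestep ``dt``; event times (threshold
crossings, eclipse expiry) are resolved by linear interpolation inside the
step, while state updates are applied at step boundaries.  Simultaneous
events within one step are processed initiation -> replication completion ->
division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .chromosome import ChromosomeConfiguration
from .params import EngineParams


class SimulationDiverged(RuntimeError):
    """A state variable became non-finite during integration."""

    def __init__(self, time: float, variable: str, value: float):
        super().__init__(
            f"non-finite state variable {variable!r}={value!r} at t={time:.4f} min"
        )
        self.time = time
        self.variable = variable


def grow_volume(v_b: float, lam: float, t: float) -> float:
    """Exponential growth: V(t) = V_b * exp(lam * t)."""
    if v_b <= 0:
        raise ValueError("birth volume must be positive")
    if lam <= 0:
        raise ValueError("growth rate must be positive")
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    return v_b * math.exp(lam * t)


def detect_threshold_crossing(
    x_prev: float, x_curr: float, theta: float, t_prev: float, dt: float
) -> float | None:
    """Linearly interpolated time of an upward threshold crossing.

    Returns ``t_prev + dt*(theta-x_prev)/(x_curr-x_prev)`` when the signal
    rose from strictly below ``theta`` to at least ``theta`` during the
    step, otherwise ``None``.  A signal already at the threshold at the
    start of the step is not a crossing.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if x_prev < theta <= x_curr:
        return t_prev + dt * (theta - x_prev) / (x_curr - x_prev)
    return None


@dataclass
class CellState:
    """Instantaneous state of one cell (model-owned numbers live on the
    model object, not here)."""

    t: float
    V: float
    chrom: ChromosomeConfiguration
    pending_divisions: list[float] = field(default_factory=list)
    eclipse_until: float = 0.0


class CellCycleModel(Protocol):
    """Interface the engine expects from a model family."""

    name: str
    trace_columns: tuple[str, ...]

    def reset(self, engine: EngineParams, cell: CellState, rng: np.random.Generator) -> None: ...
    def step(self, cell: CellState, dt: float, rng: np.random.Generator) -> None: ...
    def signal(self, cell: CellState) -> float: ...
    @property
    def threshold(self) -> float: ...
    def on_initiation(self, cell: CellState, t_event: float) -> None: ...
    def on_division(self, cell: CellState, rng: np.random.Generator) -> None: ...
    def trace_values(self, cell: CellState) -> tuple: ...


@dataclass
class LineageRecord:
    """Sampled traces and discrete event tables of one lineage."""

    trace: pd.DataFrame
    initiations: pd.DataFrame
    divisions: pd.DataFrame
    model_name: str
    engine: EngineParams

    def v_star_series(self, burn_in: int | None = None) -> np.ndarray:
        """Initiation volumes per origin after burn-in, in event order."""
        if burn_in is None:
            burn_in = self.engine.burn_in_generations
        ev = self.initiations
        if len(ev) == 0:
            raise ValueError("record contains no initiation events")
        return ev.loc[ev["generation"] >= burn_in, "v_star"].to_numpy()

    def inter_initiation_intervals(self, burn_in: int | None = None) -> np.ndarray:
        if burn_in is None:
            burn_in = self.engine.burn_in_generations
        ev = self.initiations
        t = ev.loc[ev["generation"] >= burn_in, "time_min"].to_numpy()
        return np.diff(t)


def divide(
    cell: CellState,
    model=None,
    rng: np.random.Generator | None = None,
    mode: str = "meanfield",
) -> CellState:
    """Divide a cell in place: halve volume and chromosome content, halve
    molecule counts through the model hook, keep one daughter.

    In mean-field mode halving is exact and concentrations are untouched; in
    stochastic mode the model hook applies binomial partitioning to integer
    counts and variance-matched kicks to concentration-level variables.
    """
    if mode not in ("meanfield", "stochastic"):
        raise ValueError("mode must be 'meanfield' or 'stochastic'")
    if not cell.pending_divisions:
        raise ValueError("no pending division to execute")
    cell.chrom.halve()  # raises if n_ori < 2
    cell.V /= 2.0
    cell.pending_divisions.pop(0)
    if model is not None:
        model.on_division(cell, rng)
    return cell


def run_simulation(
    model: CellCycleModel,
    engine: EngineParams,
    rng: np.random.Generator | None = None,
) -> LineageRecord:
    """Integrate one lineage for ``engine.n_generations`` division events.

    The founder cell starts with one fully replicated chromosome.  Identical
    parameters and seed give a bit-identical record.
    """
    if rng is None:
        rng = np.random.default_rng(engine.seed)
    dt = engine.dt
    lam = engine.growth_rate
    t_c = engine.t_c
    tau_cc = engine.tau_cc
    tau_b = engine.tau_b
    growth = math.exp(lam * dt)

    cell = CellState(
        t=0.0,
        V=engine.v_init,
        chrom=ChromosomeConfiguration(n_ori=1, completed=1.0),
        eclipse_until=-math.inf,
    )
    model.reset(engine, cell, rng)
    theta = model.threshold

    trace_rows: list[tuple] = []
    init_rows: list[tuple] = []
    div_rows: list[tuple] = []
    sample_every = engine.trace_interval
    next_sample = 0.0

    x_prev = model.signal(cell)
    gen = 0
    max_steps = engine.max_steps
    if max_steps is None:
        horizon = (engine.n_generations + 20) * engine.doubling_time
        max_steps = int(3 * horizon / dt) + 10_000

    if sample_every > 0:
        trace_rows.append(
            (cell.t, cell.V, cell.chrom.n_ori) + tuple(model.trace_values(cell))
        )
        next_sample = sample_every

    for _ in range(max_steps):
        t0 = cell.t
        v0 = cell.V
        model.step(cell, dt, rng)          # rates evaluated at start-of-step state
        cell.t = t0 + dt
        cell.V = v0 * growth
        cell.chrom.retire_completed(cell.t, t_c)

        x_curr = model.signal(cell)
        if not math.isfinite(x_curr):
            raise SimulationDiverged(cell.t, model.name + ".signal", x_curr)

        event_applied = False
        # --- initiation: predicate = signal above threshold, outside eclipse.
        # Post-initiation suppression is entirely the eclipse's job: if the
        # signal is still above threshold when the eclipse expires, the
        # origin fires again at exactly the eclipse end (premature
        # reinitiation).
        if (x_curr >= theta) and (cell.t >= cell.eclipse_until):
            if x_prev < theta:
                t_fire = detect_threshold_crossing(x_prev, x_curr, theta, t0, dt)
            else:
                t_fire = t0  # already above threshold when the step began
            if t_fire < cell.eclipse_until:
                t_fire = cell.eclipse_until
            v_at = v0 * math.exp(lam * (t_fire - t0))
            n_before = cell.chrom.n_ori
            init_rows.append((t_fire, v_at, n_before, v_at / n_before, gen))
            cell.chrom.start_round(t_fire)
            cell.pending_divisions.append(t_fire + tau_cc)
            cell.eclipse_until = t_fire + tau_b
            model.on_initiation(cell, t_fire)
            event_applied = True

        # --- divisions due in this step
        while cell.pending_divisions and cell.pending_divisions[0] <= cell.t:
            t_div = cell.pending_divisions.pop(0)
            v_before = cell.V
            cell.chrom.halve()
            cell.V = v_before / 2.0
            model.on_division(cell, rng)
            div_rows.append((t_div, v_before, cell.V, gen))
            gen += 1
            event_applied = True

        if event_applied:
            x_curr = model.signal(cell)
        x_prev = x_curr

        if sample_every > 0 and cell.t >= next_sample - 1e-9:
            trace_rows.append(
                (cell.t, cell.V, cell.chrom.n_ori) + tuple(model.trace_values(cell))
            )
            next_sample += sample_every

        if gen >= engine.n_generations:
            break
    else:
        raise RuntimeError(
            f"simulation exceeded {max_steps} steps before reaching "
            f"{engine.n_generations} divisions (last t={cell.t:.1f} min)"
        )

    trace = pd.DataFrame(
        trace_rows,
        columns=["time_min", "volume_um3", "n_ori", *model.trace_columns],
    )
    initiations = pd.DataFrame(
        init_rows,
        columns=["time_min", "volume_um3", "n_ori_before", "v_star", "generation"],
    )
    divisions = pd.DataFrame(
        div_rows,
        columns=["time_min", "volume_before", "volume_after", "generation"],
    )
    return LineageRecord(
        trace=trace,
        initiations=initiations,
        divisions=divisions,
        model_name=model.name,
        engine=engine,
    )
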