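"""Multifork replication bookkeeping.

The chromosome is represented by the number of origins ``n_ori``, the number
of fully replicated genome equivalents ``completed``, and a list of active
replication rounds.  A round started at time ``t_i`` when the cell had ``k``
origins represents ``k`` fork pairs, each duplicating one chromosome copy at
the constant rate ``1/T_C``.  While the round is active it contributes
``k * age / T_C`` genome equivalents on top of the template copies already
counted in ``completed``; when its age reaches ``T_C`` the ``k`` nascent
copies are complete and ``completed`` increases by ``k``.

No per-fork positions are stored: locus copy numbers (titration sites, datA,
DARS1/2) are all derived from round ages or from origin-count history.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ReplicationRound:
    """One synchronous round of replication.

    ``n_origins_at_start`` may become fractional after divisions: halving a
    cell splits the forks of an ongoing round evenly between the daughters
    (mean-field bookkeeping).
    """

    start_time: float
    n_origins_at_start: float

    def age(self, t: float) -> float:
        return t - self.start_time


@dataclass
class ChromosomeConfiguration:
    """Replication state of a single cell."""

    n_ori: int = 1
    completed: float = 1.0
    active_rounds: list[ReplicationRound] = field(default_factory=list)

    def genome_equivalents(self, t: float, t_c: float) -> float:
        """Genome equivalents: completed copies plus nascent DNA.

        For a single round started from one chromosome this is
        ``1 + (t - t_i)/T_C``, i.e. the linear ramp of the titration-site
        count between initiation and termination.
        """
        g = self.completed
        for r in self.active_rounds:
            frac = (t - r.start_time) / t_c
            if frac > 1.0:
                frac = 1.0
            elif frac < 0.0:
                frac = 0.0
            g += r.n_origins_at_start * frac
        return g

    def replicating(self) -> bool:
        return bool(self.active_rounds)

    def start_round(self, t: float) -> None:
        """Fire all origins synchronously; ``n_ori`` doubles."""
        self.active_rounds.append(ReplicationRound(t, self.n_ori))
        self.n_ori *= 2

    def retire_completed(self, t: float, t_c: float) -> None:
        """Convert rounds with age >= T_C into completed genome copies."""
        if not self.active_rounds:
            return
        keep = []
        for r in self.active_rounds:
            if t - r.start_time >= t_c:
                self.completed += r.n_origins_at_start
            else:
                keep.append(r)
        self.active_rounds = keep

    def halve(self) -> None:
        """Division: split chromosome content between two daughters."""
        if self.n_ori < 2:
            raise ValueError(
                f"cannot divide a cell with n_ori={self.n_ori}: a single "
                "origin cannot be halved"
            )
        self.n_ori //= 2
        self.completed /= 2.0
        for r in self.active_rounds:
            r.n_origins_at_start /= 2.0

    def copy(self) -> "ChromosomeConfiguration":
        return ChromosomeConfiguration(
            n_ori=self.n_ori,
            completed=self.completed,
            active_rounds=[
                ReplicationRound(r.start_time, r.n_origins_at_start)
                for r in self.active_rounds
            ],
        )


def advance_replication(
    chrom: ChromosomeConfiguration, dt: float, t_now: float, t_c: float
) -> ChromosomeConfiguration:
    """Advance fork bookkeeping by one timestep (functional form).

    Rounds age implicitly through the absolute clock; this retires every
    round whose age reached ``T_C`` at ``t_now + dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = chrom.copy()
    out.retire_completed(t_now + dt, t_c)
    return out
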