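"""Replica-exchange Monte Carlo over peptide sequence space.

The kernel iterates mutate → score → Metropolis-accept per replica, then
attempts one replica swap per step between two randomly chosen ladder
temperatures.  Scores play the role of energies: the Metropolis rule

    P_accept = min[1, exp(−(S_new − S_old) / kBT)]

always accepts score decreases (the protocol minimizes docking scores), and
the swap between replicas *a* and *b* is accepted with the standard
parallel-tempering probability

    P_swap = min[1, exp((1/kBT_a − 1/kBT_b) (S_a − S_b))]

which preserves the product Boltzmann measure and always moves a better
(lower) score to the colder temperature.

Reproducibility contract — the draw order is part of the API:

* the campaign seed spawns one child stream per run (``numpy`` SeedSequence);
* a run seed spawns one stream per replica plus one swap stream;
* step 0 scores the start once per replica (one noise draw, replica stream);
* each subsequent step, per replica in ladder order: mutation position,
  mutation residue, score noise, one acceptance uniform — all from that
  replica's stream;
* then the swap stream draws the pair index (uniform over unordered
  distinct-temperature pairs) and one acceptance uniform.

A replica's current score is *not* re-evaluated between steps; only proposals
trigger scoring (the usual convention for Metropolis on noisy objectives —
re-scoring the incumbent would make the chain ill-defined).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .backends import BackendFailure, DockingConfig, ScoringBackend
from .sequence import Peptide, mutate

logger = logging.getLogger(__name__)

MOVE_INIT = "init"
MOVE_MUTATION = "mutation"
MOVE_SWAP = "swap"

#: Trajectory TSV column order.
TRAJECTORY_COLUMNS = (
    "run",
    "step",
    "replica",
    "kBT",
    "move",
    "sequence",
    "score",
    "accepted",
)


@dataclass
class ReplicaState:
    """One replica: its peptide, last accepted score, and ladder temperature."""

    peptide: Peptide
    score: float
    kBT: float
    replica_index: int

    def __post_init__(self):
        if self.kBT <= 0:
            raise ValueError(f"kBT must be > 0, got {self.kBT}")


@dataclass
class Trajectory:
    """Per-step record of one REMC run.

    ``records`` rows follow :data:`TRAJECTORY_COLUMNS`; mutation rows hold the
    post-decision replica state, swap rows the post-decision state of the
    colder slot of the attempted pair.  ``swap_attempts`` keeps the attempted
    pair indices for diagnostics.
    """

    run_index: int
    ladder: tuple[float, ...]
    n_steps: int
    seed_entropy: tuple[int, ...]
    alphabet: str = ""
    records: list[tuple] = field(default_factory=list)
    swap_attempts: list[tuple[int, int, int, bool]] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records, columns=TRAJECTORY_COLUMNS)

    def final_states(self) -> list[ReplicaState]:
        """Post-final-step state of each replica, in ladder order."""
        states: dict[int, tuple] = {}
        for row in self.records:
            if row[4] in (MOVE_INIT, MOVE_MUTATION, MOVE_SWAP):
                states[row[2]] = row
        out = []
        for idx in sorted(states):
            row = states[idx]
            peptide = (
                Peptide(row[5], self.alphabet) if self.alphabet else Peptide(row[5])
            )
            out.append(
                ReplicaState(
                    peptide=peptide, score=row[6], kBT=row[3], replica_index=idx
                )
            )
        return out

    @property
    def mutation_acceptance_rate(self) -> float:
        rows = [r for r in self.records if r[4] == MOVE_MUTATION]
        return sum(r[7] for r in rows) / len(rows) if rows else float("nan")

    @property
    def swap_acceptance_rate(self) -> float:
        if not self.swap_attempts:
            return float("nan")
        return sum(a for *_, a in self.swap_attempts) / len(self.swap_attempts)


def metropolis_accept(
    s_old: float, s_new: float, kBT: float, rng: np.random.Generator
) -> bool:
    """Metropolis decision for a score-lowering chain.

    Accepts with probability ``min[1, exp(−(s_new − s_old)/kBT)]``; score
    decreases are always accepted.  Exactly one uniform is consumed per call
    regardless of the outcome, so draw order is decision-independent.
    """
    if kBT <= 0:
        raise ValueError(f"kBT must be > 0, got {kBT}")
    if not (math.isfinite(s_old) and math.isfinite(s_new)):
        raise ValueError(f"scores must be finite, got {s_old}, {s_new}")
    u = float(rng.random())
    return u < math.exp(min(0.0, -(s_new - s_old) / kBT))


def attempt_swap(a: ReplicaState, b: ReplicaState, rng: np.random.Generator) -> bool:
    """Parallel-tempering swap attempt between two temperatures.

    Accepted with probability ``min[1, exp((1/kBT_a − 1/kBT_b)(S_a − S_b))]``
    (detailed balance on the product measure).  On acceptance the replicas
    exchange (peptide, score) while keeping their kBT slots.  One uniform is
    consumed per call.
    """
    if a.kBT == b.kBT:
        raise ValueError("swap requires two distinct ladder temperatures")
    exponent = (1.0 / a.kBT - 1.0 / b.kBT) * (a.score - b.score)
    u = float(rng.random())
    accepted = u < math.exp(min(0.0, exponent))
    if accepted:
        a.peptide, b.peptide = b.peptide, a.peptide
        a.score, b.score = b.score, a.score
    return accepted


def _unordered_pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def run_remc(
    start: Peptide,
    ladder: Sequence[float],
    n_steps: int,
    backend: ScoringBackend,
    config: DockingConfig,
    seed: int | np.random.SeedSequence = 0,
    run_index: int = 0,
) -> Trajectory:
    """One REMC run: every replica starts from ``start``, scored once at step 0.

    ``ladder`` lists the replica temperatures (distinct, > 0); ``n_steps``
    mutation sweeps are performed, each followed by one swap attempt (when the
    ladder has ≥ 2 rungs).  Bitwise reproducible given ``seed``.  A
    :class:`~pepmc.backends.BackendFailure` during a proposal is logged and
    treated as a rejection; a failure while scoring the start is fatal.
    """
    ladder = [float(t) for t in ladder]
    if not ladder:
        raise ValueError("ladder must be non-empty")
    if any(t <= 0 for t in ladder):
        raise ValueError("all ladder temperatures must be > 0")
    if len(set(ladder)) != len(ladder):
        raise ValueError("ladder temperatures must be distinct")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if n_steps == 0:
        logger.warning("run %d: n_steps=0, returning the scored start state", run_index)

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    *replica_ss, swap_ss = ss.spawn(len(ladder) + 1)
    replica_rngs = [np.random.default_rng(s) for s in replica_ss]
    swap_rng = np.random.default_rng(swap_ss)

    traj = Trajectory(
        run_index=run_index,
        ladder=tuple(ladder),
        n_steps=n_steps,
        seed_entropy=tuple(ss.entropy if isinstance(ss.entropy, (list, tuple)) else [ss.entropy]),
        alphabet=start.alphabet,
    )

    replicas = []
    for idx, kBT in enumerate(ladder):
        sample = backend.score(
            start, config, replica_rngs[idx], step_index=0, run_index=run_index
        )
        state = ReplicaState(
            peptide=start.with_pose(sample.pose_id),
            score=sample.value,
            kBT=kBT,
            replica_index=idx,
        )
        replicas.append(state)
        traj.records.append(
            (run_index, 0, idx, kBT, MOVE_INIT, start.sequence, sample.value, True)
        )

    pairs = _unordered_pairs(len(ladder))
    for step in range(1, n_steps + 1):
        for idx, state in enumerate(replicas):
            rng = replica_rngs[idx]
            proposal = mutate(state.peptide, rng)
            try:
                sample = backend.score(
                    proposal, config, rng, step_index=step, run_index=run_index
                )
            except BackendFailure as exc:
                logger.warning(
                    "run %d step %d replica %d: backend failure (%s); "
                    "proposal rejected",
                    run_index,
                    step,
                    idx,
                    exc,
                )
                rng.random()  # keep the acceptance draw slot
                accepted = False
            else:
                accepted = metropolis_accept(state.score, sample.value, state.kBT, rng)
                if accepted:
                    state.peptide = proposal.with_pose(sample.pose_id)
                    state.score = sample.value
            traj.records.append(
                (
                    run_index,
                    step,
                    idx,
                    state.kBT,
                    MOVE_MUTATION,
                    state.peptide.sequence,
                    state.score,
                    accepted,
                )
            )
        if len(ladder) >= 2:
            i, j = pairs[int(swap_rng.integers(len(pairs)))]
            accepted = attempt_swap(replicas[i], replicas[j], swap_rng)
            cold = i if ladder[i] < ladder[j] else j
            traj.swap_attempts.append((step, i, j, accepted))
            traj.records.append(
                (
                    run_index,
                    step,
                    cold,
                    ladder[cold],
                    MOVE_SWAP,
                    replicas[cold].peptide.sequence,
                    replicas[cold].score,
                    accepted,
                )
            )
    logger.info(
        "run %d: %d steps, mutation acceptance %.3f, swap acceptance %.3f, "
        "best final score %.3f",
        run_index,
        n_steps,
        traj.mutation_acceptance_rate,
        traj.swap_acceptance_rate,
        min(s.score for s in replicas),
    )
    return traj


@dataclass(frozen=True)
class SelectedPeptide:
    """The lowest-scoring end-of-run peptide of one campaign run."""

    run_index: int
    peptide: Peptide
    score: float
    kBT: float


@dataclass
class CampaignResult:
    trajectories: list[Trajectory]
    selected: list[SelectedPeptide]

    @property
    def best(self) -> SelectedPeptide:
        return min(
            self.selected, key=lambda s: (s.score, s.kBT, s.peptide.sequence)
        )


def select_best_final(traj: Trajectory) -> SelectedPeptide:
    """Lowest-scoring final-step replica; ties → lower kBT, then sequence."""
    states = traj.final_states()
    best = min(states, key=lambda s: (s.score, s.kBT, s.peptide.sequence))
    return SelectedPeptide(
        run_index=traj.run_index,
        peptide=best.peptide,
        score=best.score,
        kBT=best.kBT,
    )


def run_campaign(
    n_runs: int,
    start: Peptide,
    ladder: Sequence[float],
    n_steps: int,
    backend: ScoringBackend,
    config: DockingConfig,
    seed: int = 0,
) -> CampaignResult:
    """Repeat :func:`run_remc` ``n_runs`` times with derived per-run seeds,
    selecting each run's lowest-scoring end-simulation peptide."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    root = np.random.SeedSequence(seed)
    run_seeds = root.spawn(n_runs)
    trajectories = []
    selected = []
    for run_index, run_ss in enumerate(run_seeds):
        traj = run_remc(
            start, ladder, n_steps, backend, config, seed=run_ss, run_index=run_index
        )
        trajectories.append(traj)
        selected.append(select_best_final(traj))
    return CampaignResult(trajectories=trajectories, selected=selected)
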