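"""Mutation-off MC rescoring and the negative-control-corrected binding energy.

To characterize a fixed candidate sequence, the optimization loop is run with
the mutation step switched off: each step draws a fresh docking score for the
*same* sequence and applies the Metropolis rule to it, so the chain drifts
toward the low tail of the score distribution (the same selection pressure the
optimizer exerts).  The ensemble average is taken over the chain state at each
of the last ``retain_last`` steps of ``n_runs`` independent runs.

The corrected binding energy is

    BE = <E_binding site> − <E_no binding site>

the mean rescored energy at the designated binding site minus the mean at an
experimentally validated non-binding (negative control) site.  Docking scores
carry sequence-dependent offsets that have nothing to do with site-specific
binding; because the MC selection bias is the same at both sites, it cancels
in the difference, which is what makes BE a usable ranking statistic.

Error bars: each run is an independent chain, so the SEM of a site mean is
taken over the per-run means (``sd(run means)/sqrt(n_runs)``); the BE error
bar is the *sum* of the two sites' SEMs (the convention used for the original
analysis — quadrature is available but is not the default).  The reported
``sd`` is the dispersion over all retained samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backends import BackendFailure, DockingConfig, ScoringBackend
from .engine import metropolis_accept
from .sequence import Peptide


@dataclass(frozen=True)
class RescoreResult:
    """Retained-ensemble score statistics for one peptide at one site."""

    peptide: Peptide
    site_label: str
    samples: tuple[float, ...]
    run_means: tuple[float, ...]
    mean: float
    sd: float
    sem: float
    n_runs: int
    n_steps: int
    retain_last: int
    kBT: float


@dataclass(frozen=True)
class BEResult:
    """Negative-control-corrected binding energy with propagated error."""

    peptide: Peptide
    be: float
    mean_binding: float
    mean_control: float
    err: float
    sem_binding: float
    sem_control: float
    name: str = ""


def _sem(samples: np.ndarray, run_means: np.ndarray, method: str) -> float:
    if method == "per_run":
        if len(run_means) < 2:
            return 0.0
        return float(run_means.std(ddof=1) / np.sqrt(len(run_means)))
    if method == "pooled":
        if len(samples) < 2:
            return 0.0
        return float(samples.std(ddof=1) / np.sqrt(len(samples)))
    raise ValueError(f"unknown sem_method {method!r}")


def rescore(
    p: Peptide,
    backend: ScoringBackend,
    config: DockingConfig,
    kBT: float = 0.6,
    n_runs: int = 10,
    n_steps: int = 100,
    retain_last: int = 10,
    seed: int | np.random.SeedSequence = 0,
    sem_method: str = "per_run",
) -> RescoreResult:
    """Fixed-sequence MC rescoring of ``p`` at one site.

    Runs ``n_runs`` independent chains of ``n_steps`` steps at temperature
    ``kBT``.  Step 0 scores the sequence once to initialize the chain; each
    step then draws a fresh score sample and Metropolis-accepts it against the
    current state.  The chain state at each of the last ``retain_last`` steps
    is retained (rejections duplicate the incumbent — the ensemble average is
    over chain states, not distinct poses).  Backend failures reject the step.

    The single-shot no-MC convention (one plain docking call per run) is the
    special case ``n_steps=1, retain_last=1``.

    ``sem_method="per_run"`` (default) takes the SEM over per-run means;
    ``"pooled"`` uses all retained samples as if independent (biased low for
    autocorrelated chains; provided for comparison with pooled-sample
    conventions).
    """
    if retain_last < 1 or retain_last > n_steps:
        raise ValueError("retain_last must be in [1, n_steps]")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    retained: list[float] = []
    run_means: list[float] = []
    for run_index, run_ss in enumerate(ss.spawn(n_runs)):
        rng = np.random.default_rng(run_ss)
        state = backend.score(p, config, rng, step_index=0, run_index=run_index).value
        kept: list[float] = []
        for step in range(1, n_steps + 1):
            try:
                sample = backend.score(
                    p, config, rng, step_index=step, run_index=run_index
                )
            except BackendFailure:
                rng.random()  # keep the acceptance draw slot
            else:
                if metropolis_accept(state, sample.value, kBT, rng):
                    state = sample.value
            if step > n_steps - retain_last:
                kept.append(state)
        retained.extend(kept)
        run_means.append(float(np.mean(kept)))
    samples = np.asarray(retained)
    means = np.asarray(run_means)
    return RescoreResult(
        peptide=p,
        site_label=config.site_label,
        samples=tuple(samples),
        run_means=tuple(means),
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)) if len(samples) > 1 else 0.0,
        sem=_sem(samples, means, sem_method),
        n_runs=n_runs,
        n_steps=n_steps,
        retain_last=retain_last,
        kBT=kBT,
    )


def compute_be(
    binding: RescoreResult,
    control: RescoreResult,
    name: str = "",
    error_method: str = "sum",
) -> BEResult:
    """BE = mean(binding) − mean(control), error = SEM sum (or quadrature).

    Both results must describe the same peptide sequence.  ``error_method``
    ``"sum"`` adds the two SEMs (the convention this statistic was introduced
    with); ``"quadrature"`` combines them as sqrt(sem_b² + sem_c²).
    """
    if binding.peptide.sequence != control.peptide.sequence:
        raise ValueError(
            f"peptide mismatch: {binding.peptide.sequence} vs "
            f"{control.peptide.sequence}"
        )
    if error_method == "sum":
        err = binding.sem + control.sem
    elif error_method == "quadrature":
        err = float(np.hypot(binding.sem, control.sem))
    else:
        raise ValueError(f"unknown error_method {error_method!r}")
    return BEResult(
        peptide=binding.peptide,
        be=binding.mean - control.mean,
        mean_binding=binding.mean,
        mean_control=control.mean,
        err=err,
        sem_binding=binding.sem,
        sem_control=control.sem,
        name=name,
    )


def rank_candidates(results: list[BEResult]) -> list[tuple[BEResult, bool]]:
    """Order candidates by BE (most negative first) and flag unresolved ties.

    Ties in BE break by peptide name.  An entry is flagged when its
    ``[be − err, be + err]`` interval overlaps the best entry's interval —
    i.e. the ranking between it and the leader is not statistically resolved.
    The leader itself is flagged only if some other entry overlaps it.
    """
    if not results:
        raise ValueError("rank_candidates requires a non-empty result list")
    ordered = sorted(results, key=lambda r: (r.be, r.name or r.peptide.sequence))
    best = ordered[0]
    flagged = []
    overlaps_any = False
    for r in ordered[1:]:
        overlap = (r.be - r.err) <= (best.be + best.err) and (
            best.be - best.err
        ) <= (r.be + r.err)
        flagged.append((r, overlap))
        overlaps_any = overlaps_any or overlap
    return [(best, overlaps_any and len(ordered) > 1)] + flagged
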