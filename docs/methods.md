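# Methods

## Model and sampling kernel

The optimizer is Metropolis Monte Carlo over fixed-length peptide sequence
space, with the docking score playing the role of an energy.  The proposal is
a single-point substitution: position uniform over the chain, replacement
uniform over the alphabet excluding the incumbent residue.  This kernel is
symmetric (`P(p→q) = P(q→p)` for every Hamming-1 pair) and ergodic (any
sequence reachable in ≤ length moves), so the Metropolis rule

    P_accept = min[1, exp(−(S_new − S_old)/kBT)]

targets the Boltzmann measure π(s) ∝ exp(−S(s)/kBT) whenever scores are
deterministic.  Proposals are never the identity: re-proposing the incumbent
would only rescale the chain's time unit.

Three replicas run at kBT = 0.2, 0.4, 0.6 kcal/mol (kBT is expressed on the
score scale).  Once per step, after all replicas have moved, one swap is
attempted between a uniformly chosen unordered pair of distinct temperatures,
accepted with the parallel-tempering probability

    P_swap = min[1, exp((1/kBT_a − 1/kBT_b)(S_a − S_b))] ,

which preserves the product measure (detailed balance) and always accepts
when the swap moves the better score to the colder rung.  On acceptance the
replicas exchange (sequence, score) and keep their temperature slots.

With a stochastic backend the recorded score of a replica is the last
*accepted* sample; the incumbent is never re-scored between steps.  This is
the standard noisy-Metropolis convention — re-drawing the incumbent's score
would make the invariant measure undefined.  The consequence is a selection
bias: chains drift toward the low tail of the per-sequence score
distribution.  The rescoring protocol (below) exploits exactly this bias and
cancels it in the BE difference.

## Protocol parameters

| parameter | default | meaning |
|---|---|---|
| length | 8 | peptide chain length |
| start | AAAAAAAA | poly-alanine start of every run |
| ladder | 0.2/0.4/0.6 kcal/mol | replica temperatures |
| n_steps | 100 | mutation sweeps per run (one swap attempt each) |
| n_runs | 9 | independent runs; lowest end-simulation peptide kept per run |
| rescore kBT | 0.6 | temperature of the mutation-off chain |
| rescore runs × steps | 10 × 100 | independent fixed-sequence chains |
| retain_last | 10 | chain states averaged per run |
| RT | 0.593 kcal/mol | K_D → ΔG conversion at room temperature |

Campaign selection takes each run's final-step state with minimum score
across replicas; ties break toward the colder rung, then lexicographically.

## Rescoring and the corrected binding energy

`rescore` runs `n_runs` independent chains on a frozen sequence; each step
draws a fresh score sample and Metropolis-accepts it against the current
state.  The ensemble average is over the chain state at each of the last
`retain_last` steps (rejections duplicate the incumbent — an MC average is
over chain states, not distinct poses).  The single-shot convention (one
plain docking per run) is the special case `n_steps=1, retain_last=1`.

For a Gaussian score distribution N(μ, σ²) the stationary law of this chain
is the exponentially tilted Gaussian N(μ − σ²/kBT, σ²): the retained mean
sits below μ by σ²/kBT and the retained spread still equals σ.  Both are
verified empirically in the tests for σ ≤ 1 at kBT = 0.6.  For σ well above
the kBT scale the acceptance rate collapses (the tilt shift σ²/kBT grows
quadratically) and a 100-step chain no longer equilibrates; the retained
spread then under-represents σ.  This regime is intrinsic to the protocol,
not an implementation artifact, and is why the spread-vs-noise linearity is
only asserted for σ ≤ kBT-scale noise.

`BE = mean_binding − mean_control` subtracts the mean at a validated
non-binding site from the mean at the binding site.  The MC selection bias
(−σ²/kBT) is identical at both sites when their dispersions match, so it
cancels in the difference — a property the tests assert directly.

Error convention: each rescoring run is an independent chain, so the SEM of
a site mean is computed over the per-run means, `sd(run means)/√n_runs`.
Within-run states are strongly autocorrelated; the pooled convention
`sd(all samples)/√(n_runs·retain_last)` under-states the spread by roughly
the integrated autocorrelation factor (~2.6× at the defaults) and is provided
only as `sem_method="pooled"` for comparison.  The BE error bar is the *sum*
of the two SEMs, the convention this statistic was introduced with; quadrature
(`error_method="quadrature"`) is offered but is not the default.  The
dispersion column (`sd`) is always over all retained samples.

## The synthetic landscape generator

The generator stands in for a docking engine.  Mean score of a sequence is a
sum of per-(position, residue) terms (optional pairwise epistasis terms exist
for constructing rugged test landscapes); each call adds Gaussian noise and
returns a fresh pose handle.  The control site is the binding mean plus a
constant offset, or an independent table.

Default term distribution: with probability 0.4 a draw from a tight
"favored-class" mode N(−2.4, 0.05) kcal/mol, otherwise from a broad
background N(−1.1, 0.25).  The two-mode structure models the empirical
shape of peptide docking surfaces, where a class of residues (typically
aromatic/hydrophobic at a pocket lined with Tyr/Phe/Trp) scores similarly
well and clearly better than the rest.  The defaults place random sequences
near −13 kcal/mol and per-position optima near −20 kcal/mol, matching the
score window MC-refined octapeptide docking produces (−12 to −20 kcal/mol),
and they make a 100-step campaign a meaningful benchmark: on a purely
continuous i.i.d. term distribution the coldest chain's equilibrium
Boltzmann excess alone is ~8 % of |optimum|, so no campaign of this length
could sit within 5 % of the optimum — the near-degenerate favored class is
what real surfaces provide and what makes the short protocol effective.
Per-call noise defaults to 1.0 kcal/mol (5–7 % of a typical score, the low
end of observed docking-replica dispersion); the control offset defaults to
+4 kcal/mol.

What the generator does *not* emulate: conformational pose memory (each call
is i.i.d. given the sequence, real redocking is not), backend-version drift,
sequence-dependent noise levels, and any structural realism.  Passing tests
therefore validate the sampler, the selection logic and the statistics — not
docking accuracy.

## Conversions

`ΔG = RT ln K_D` with K_D in molar; RT defaults to 0.593 kcal/mol (R·298 K).
The rounded RT = 0.6 reproduces some published 2-decimal figures (−3.28 /
−5.11 for 4200 μM / 200 μM) and is accepted wherever `rt` is a parameter;
with RT = 0.593 the same K_D values give −3.25 / −5.05.  The uncertainty is
propagated as σ_ΔG = 0.434·(σ_KD/K_D), applied verbatim as the source
analysis defines it.  Note 0.434 = log10(e): the formula is the error of
log10(K_D), and a natural-log propagation in kcal/mol would carry an extra
2.303·RT ≈ 1.366 factor.  The constant is deliberately not "corrected";
the error bars are small either way and the convention matches the published
figures.

## Numerical and reproducibility choices

* RNG: numpy SeedSequence spawning — campaign seed → per-run seeds → one
  stream per replica plus one swap stream.  Each Metropolis decision consumes
  exactly one uniform regardless of outcome, so the draw order (and hence the
  whole trajectory) is bit-reproducible and auditable at DEBUG log level.
* Backend failures (an external engine returning no pose) are mapped to
  proposal rejections with a logged warning; the loop has no failure branch.
  A failure while scoring the start state is fatal.
* Output files carry tool version, config hash and seed in comment headers;
  floats are written with repr round-trip precision, so identical seeds give
  byte-identical TSV/FASTA outputs.
* Degenerate inputs: a 0-step run returns the scored start (with a warning);
  one-rung ladders skip swaps; `retain_last` must not exceed the chain
  length; enumeration is capped (default 10⁶ states) to keep oracle use
  deliberate.
* Problem sizes in the validation suite: stationarity is checked on the
  64-state length-3/4-letter space against the exactly enumerated Boltzmann
  distribution with 2×10⁵-step chains (TV ≈ 0.007–0.010 observed, bound
  0.02/0.03); optimizer recovery uses 10 landscapes × 9 runs of the standard
  campaign; BE calibration uses 500 repetitions of the 10×100 rescoring
  protocol at known site means.  These sizes give 3–4σ headroom on every
  bound while keeping the whole suite around a minute.

## Known limitations

* The swap-pair choice is uniform over unordered pairs, one attempt per step;
  adjacent-pair or multiple-attempt schedules are not implemented.
* No insertions/deletions, cyclic peptides or non-natural residues; the move
  set is single-point substitution only.
* The external-adapter path ships as contract + configuration metadata (box
  geometry, exhaustiveness, energy range, receptor paths, passed through
  verbatim); no docking engine is executed by this package.
* Scores are treated as exchangeable i.i.d. samples per sequence; if a real
  backend's noise is heavy-tailed or autocorrelated across calls, the tilted-
  Gaussian calibration of the rescoring statistics no longer applies
  quantitatively.
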