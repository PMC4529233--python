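# pepmc

Replica-exchange Monte Carlo (REMC) evolution of short peptide binders on
docking-score landscapes, with mutation-off rescoring, negative-control-corrected
binding energies, and K_D ↔ ΔG conversion utilities.

## The problem

Docking-based peptide design evolves a fixed-length sequence toward tighter
predicted binding: mutate one residue, re-dock, and accept or reject the mutant
by the Metropolis rule on the docking score `S` (kcal/mol, lower = better),

    P_accept = min[1, exp(−(S_new − S_old) / k_B T)] .

Three replicas run in parallel at k_B T = 0.2, 0.4, 0.6 and at every step a
replica-exchange swap is attempted between two randomly chosen temperatures
with the standard parallel-tempering probability
`min[1, exp((1/kBT_a − 1/kBT_b)(S_a − S_b))]`, so hot replicas escape local
minima and feed improved sequences to the cold one.  A campaign repeats the
100-step run 9 times from poly-alanine and keeps each run's lowest-scoring
end-simulation peptide.

Raw docking scores carry large sequence-dependent offsets, so candidates are
re-scored with the mutation step switched off (a fixed-sequence MC chain over
repeated dockings at k_B T = 0.6, averaging the chain state over the last 10
configurations of 10 runs) at two sites, and ranked by the corrected binding
energy

    BE = ⟨E_binding site⟩ − ⟨E_no binding site⟩ ,

the mean at the designated binding site minus the mean at an experimentally
validated non-binding (negative control) site; the error bar is the sum of the
two standard errors of the mean (taken over the 10 per-run means).  Measured
dissociation constants are compared on the same scale through
`ΔG = RT ln K_D` (RT = 0.593 kcal/mol) with `σ_ΔG = 0.434·σ_KD/K_D`.

Because a docking engine is an external, non-portable dependency, the package
ships a synthetic scoring backend: an additive per-(position, residue) score
table with optional epistasis, Gaussian per-call noise (5–15 % relative, as
docking replicas show), and a control site modelled as an offset or an
independent table.  The backend contract (`score(sequence) → sample, pose`)
is the same one an external docking adapter implements, so the engine is
indifferent to which is plugged in.  On additive landscapes the exact optimum
and the exact Boltzmann distribution are enumerable, which is what makes the
sampler property-testable.

It is aimed at structural-bioinformatics practitioners who want a tested,
reproducible REMC sequence-evolution kernel and score post-processing, with
the docking engine abstracted behind an adapter.

## Worked example

```yaml
# demo.yaml
length: 8
start_sequence: AAAAAAAA
ladder: [0.2, 0.4, 0.6]
n_steps: 100
n_runs: 9
seed: 7
rescore: {kBT: 0.6, n_runs: 10, n_steps: 100, retain_last: 10}
```

```
$ pepmc evolve --config demo.yaml --out-dir demo_out
9 runs x 100 steps done; best end-simulation peptide HPAIAGGM (score -22.19
kcal/mol at kBT 0.4); outputs in demo_out/
```

With no `backend:` block the campaign draws a synthetic landscape from the
campaign seed; each of the 9 runs starts from octa-alanine (scoring ≈ −13
kcal/mol here) and descends to its lowest end-simulation sequence, written to
`demo_out/selected.fasta` with per-run scores, alongside the full per-step
`trajectory.tsv` (run, step, replica, kBT, move, sequence, score, accepted).
The best score (−22.19) beats the landscape's noise-free optimum because each
recorded score retains its stochastic docking noise, exactly as real docking
scores would.

Converting the packaged reference affinity table (SPR K_D values for the MBP
candidates):

```
$ pepmc convert src/pepmc/data/mbp_affinities.tsv --out affinities.tsv
converted 5 affinities (6 non-quantifiable rows excluded) -> affinities.tsv
```

The output lists, e.g., the best binder (K_D = 72 ± 3 μM) at
ΔG = −5.66 ± 0.02 kcal/mol, and the weakest quantified binder
(4200 ± 1400 μM) at −3.25 kcal/mol; rows marked "CBE" or "No binding" are
excluded and reported in the header.  `pepmc be` re-scores a candidate FASTA
at both sites and writes the ranked BE table; `pepmc simulate-landscape`
serializes a reproducible synthetic landscape.

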