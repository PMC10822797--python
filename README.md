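# larvadisp

Simulation and optimal-control toolkit for coastal invertebrate larval
dispersal. A larva drifts in a two-layer cross-shore current system (an
offshore-moving surface layer over a slower onshore-moving bottom layer),
regulates its depth by discrete vertical swimming, feeds at the surface,
and is scored on how well its trajectory balances predator avoidance,
starvation avoidance, nearshore settlement, and energy reserves for
metamorphosis. A backward-induction dynamic-programming solver constructs
closed-loop swimming policies that maximize the expected trajectory score,
for comparison against classic behavioral archetypes (passive drift,
ontogenetic migration, diel vertical migration, and a hybrid).

## Layout

- `larvadisp.dynamics` — model parameters, state/trajectory types, the
  exact discrete-time position and energy updates, and the Monte-Carlo
  simulator (vectorized over replicates, fully seeded).
- `larvadisp.behaviors` — open-loop schedules built from inclusive surface
  windows, the three named archetypes, and the passive two-state Markov
  vertical process.
- `larvadisp.scoring` — the four subscores (predation, starvation,
  settling, metamorphosis), either predation scheme (nearshore strip or
  diurnal surface), and the weighted composite score.
- `larvadisp.dp` — grid construction, Bellman backups with Gauss-Hermite
  quadrature and bilinear interpolation, the backward solver, and the
  closed-loop policy adapter for simulation.
- `larvadisp.experiments` — behavior summaries, U/F parameter sweeps with
  common random numbers, closed-form feeding thresholds, and the
  behavior-by-scheme comparison table.
- `larvadisp.cli` — the `larvadisp` command.

## CLI

All subcommands accept `--config PATH` (JSON or YAML with blocks
`params`, `weights`, `solver`, `simulation`), `--scheme`, `--seed`,
`--n-reps`, and `--out DIR`; the resolved configuration is echoed into the
output directory. Examples:

```sh
larvadisp simulate --behavior dvm --n-reps 100 --seed 1 --out out/dvm
larvadisp score --behavior hybrid --scheme diurnal --out out/hyb
larvadisp thresholds --behavior ovm
larvadisp optimize --scheme nearshore --out out/policy
larvadisp sweep --param F --values 0.05,0.1,0.15,0.2,0.25 --behaviors dvm,ovm,hybrid --out out/fsweep
larvadisp compare --out out/compare        # solves an optimal policy per scheme
```

Behaviors: `passive`, `ovm`, `dvm`, `hybrid`, `optimal` (solved on the
fly), or `schedule:PATH` pointing at a `t,dZ` CSV.

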