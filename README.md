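# aptevolve

In silico post-SELEX maturation of DNA aptamers.

SELEX-derived aptamers are often thermodynamically marginal: the
selection favours binders, not stable folds, and PCR bias loses good
sequences along the way. `aptevolve` implements the computational
follow-up: starting from one experimentally selected parent aptamer it
runs a genetic-algorithm loop — random point mutagenesis →
deduplication → keep the mutants with the lowest predicted folding
free energy ΔG → re-rank those by a rigid-docking fitness against the
protein target → repeat — and reports the best candidate with its full
mutational lineage. The package is aimed at aptamer/biosensor groups
who want this screening loop, and the downstream assay maths, as
plain, testable Python.

What's inside:

- **`aptevolve.folding`** — a DNA secondary-structure MFE engine
  (Zuker dynamic programming over a SantaLucia-family nearest-neighbor
  model, bundled parameter tables, 37 °C / 1 M Na⁺ defaults), with an
  exhaustive-enumeration oracle for short sequences and batch folding
  ranked by ascending ΔG.
- **`aptevolve.evolve`** — the maturation loop (defaults: 6 rounds,
  ~1000 mutants/round, 2 substitutions per mutant, top 10 by ΔG, top 4
  by docking fitness, elitism, fully seeded).
- **`aptevolve.dock3d`** — coarse per-nucleotide 3D embedding of a
  fold, FFT shape-complementarity rigid docking (all translations per
  rotation in one cross-correlation), a geometric hydrogen-bond
  profiler, and an adapter for externally computed docking-score
  tables.
- **`aptevolve.assay`** — 1:1 Langmuir biolayer-interferometry
  simulation and global kinetic fitting (kon, koff, Kd = koff/kon),
  molecular-beacon design, fluorescence reduction rate
  y = (F0−F)/F0 × 100 %, linear calibration and the 3σ limit of
  detection, and selectivity summaries.
- **`aptevolve.fixtures`** — deterministic synthetic generators
  (random/designed sequences, a block-with-notch docking fixture with
  a known optimum, sensorgram and calibration tables) so everything is
  testable offline.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

The parent anti-interferon-γ aptamer B1-4 ships with the package.
Fold it, then run a reduced-scale maturation (100 mutants per parent)
with −ΔG as the selection fitness:

```python
from aptevolve import B1_4, fold_mfe
from aptevolve.energetics import build_energy_model
from aptevolve.evolve import EvolutionConfig, run_evolution

model = build_energy_model()
res = fold_mfe(B1_4, model=model)
print(f"{res.sequence.id}: dG = {res.delta_g:.2f} kcal/mol")
print(res.dot_bracket)

cfg = EvolutionConfig(n_rounds=6, mutants_per_parent=100,
                      round1_mutants=100, rng_seed=1)
report = run_evolution(B1_4, cfg,
                       fitness_fn=lambda s: -fold_mfe(s, model=model).delta_g,
                       model=model)
for rr in report.rounds:
    print(f"round {rr.round_index}: pool {rr.pool_size_after_dedup:4d}  "
          f"best dG {rr.best_delta_g:7.2f}  best fitness {rr.best_fitness:6.2f}")
gb = report.global_best
print(f"winner: {gb.sequence.id} (generation {gb.generation}), "
      f"dG {gb.delta_g:.2f} kcal/mol")
```

Output:

```
B1-4: dG = -1.50 kcal/mol
.......................(((...((....))...)))................
round 1: pool  100  best dG   -4.10  best fitness   4.10
round 2: pool  398  best dG   -8.10  best fitness   8.10
round 3: pool  397  best dG   -9.70  best fitness   9.70
round 4: pool  399  best dG  -12.80  best fitness  12.80
round 5: pool  400  best dG  -17.50  best fitness  17.50
round 6: pool  400  best dG  -18.80  best fitness  18.80
winner: B1-4.m20.m53.m69.m12.m8.m60 (generation 6), dG -18.80 kcal/mol
```

The parent folds weakly (−1.50 kcal/mol, a small two-helix fold);
round by round the selected top-10 window slides to much more stable
folds, and the winner's id spells out its lineage (which position was
mutated is in `report.lineage_table()`). To use real docking scores as
the fitness instead, export them as CSV and pass
`aptevolve.dock3d.import_external_scores("scores.csv")`; to use the
internal shape docking, pass
`aptevolve.dock3d.make_shape_fitness(receptor_structure)`.

The same pipeline is available from the shell:

```bash
aptevolve fold parent.fasta
aptevolve run --parent parent.fasta --config cfg.yaml --energy-fitness --out out/
aptevolve fixtures block_with_notch --out fixtures/
```

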