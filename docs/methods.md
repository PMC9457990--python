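# Methods

`aptevolve` implements an in silico post-SELEX maturation strategy for
DNA aptamers: starting from a single experimentally selected parent
sequence, it iterates rounds of random point mutagenesis, selection on
predicted folding free energy (ΔG), and re-selection on a rigid-body
docking fitness against the protein target, then analyses the outcome
with standard binding-kinetics and aptasensor-calibration mathematics.
This note records the models, the defaults and why, and what the
synthetic tests do and do not establish.

## Secondary-structure model

Folding is a Zuker-style dynamic program over non-pseudoknotted
structures with Watson–Crick pairs only (no wobble — this is DNA), a
minimum hairpin loop of 3 nt, and loop free energies summed from a
nearest-neighbor model:

- **Parameter set.** The bundled `dna1999` profile is the unified
  SantaLucia-family DNA compilation (37 °C, 1 M NaCl reference) as
  distributed for the classic DNA folding servers: Watson–Crick stack
  ΔG37/ΔH, hairpin/bulge/internal initiation tables to length 30 with
  Jacobson–Stockmayer `lxc·ln(n/30)` extrapolation, terminal-mismatch
  tables for hairpin and internal loops, multibranch linear
  coefficients (closing 12.80, per branch −0.60, per unpaired base 0.00
  kcal/mol), a 0.20 kcal/mol terminal A·T penalty, and the
  tri-/tetraloop exception list. Tables live in a commented TSV
  (`src/aptevolve/data/dna_nn_1999.tsv`); missing entries are a load
  error, never a silent zero.
- **Small internal loops.** The special 1×1/2×1/2×2 lookup tables of
  fuller implementations are deliberately omitted: internal loops score
  initiation (floored at the size-4 value for sizes below 4) plus a
  Ninio asymmetry term (0.60/|n1−n2| unit, capped at 3.00), with
  terminal mismatches applied only when both sides have ≥2 unpaired
  bases and the larger has ≥3. This penalises small loops at least as
  strongly as the special tables would, so it cannot invent spurious
  stable folds; it can miss marginal stabilisation from unusual small
  loops. Bulges of size 1 retain the flanking stack.
- **Dangles.** A both-sides ("d2"-like) terminal-stacking scheme is the
  default for exterior and multibranch helix ends; `dangles="none"`
  drops those terms. Which treatment the original server applied to
  the parent aptamer is not knowable from the outside; the ±0.5
  kcal/mol acceptance band on the printed anchors absorbs this.
- **Conditions.** Default 37 °C and 1 M Na⁺ (the tables' reference
  state). Temperature rescales every term through
  ΔG(T) = ΔH − (ΔH − ΔG37)·T/310.15 K; monovalent salt applies the
  standard entropic per-stack correction −T·0.000368·ln[Na⁺]eff with
  [Na⁺]eff = [Na⁺] + 3.3·√[Mg²⁺].
- **Positive-ΔG reporting.** When the unconstrained optimum is the open
  chain, the best *folded* state is still reported with its positive
  free energy (the convention that produced the printed +0.04 kcal/mol
  control); the open chain appears only when no legal pair exists.
  `report_positive=False` gives the unconstrained MFE, which is what
  the brute-force oracle checks.
- **Determinism.** Traceback prefers hairpin over interior over
  multibranch closures and the smallest (i, j) candidate within each,
  so co-optimal structures resolve identically on every run.

Correctness is pinned by two independent paths: an exhaustive
enumerator of all legal structures (≤14 nt guard) scored by a
standalone loop-decomposition evaluator must agree with the DP to
1e-6 kcal/mol, and every traceback structure must re-score to its
reported ΔG with that same evaluator.

## Maturation loop

Defaults mirror the published protocol: 6 rounds; ~1000 mutants in
round one from the single parent, then 250 per surviving parent
(4×250); exactly 2 substitutions per mutant (small steps match the
observed gradual ΔG descent; configurable); duplicates removed within
the round and against all previously evaluated sequences; top 10 by
ascending ΔG; top 4 of those by descending docking fitness. Indels are
never generated — all candidates stay the parent's length. Elitism
(default on) lets current parents re-enter energy selection so the
best-so-far cannot be lost; the reported winner is the
highest-fitness candidate across *all* rounds, since docking fitness
can degrade in late rounds even as ΔG keeps falling. One seeded
generator drives every stochastic stage; the seed is echoed in the
report, and identical seeds give bit-identical reports.

At test scale (100 mutants/parent) the loop reproduces the qualitative
published behaviour — the round-wise top-10 ΔG window marches
downward from a −1-ish parent to the −15…−19 kcal/mol range by round
six — which is a statement about the selection dynamics, not about any
particular winning sequence.

## Docking fitness

The internal docking stage is a shape-complementarity surrogate whose
contract is *ranking* candidates; it is not a reimplementation of any
published docking server, and external score tables can be dropped in
via `import_external_scores` when real docking output is available.

- **Embedding.** One pseudo-atom per nucleotide: maximal stems are laid
  out as ideal B-form helices (rise 3.4 Å, twist 36°, radius 10 Å,
  paired partners 180° across the axis, hence at the ~20 Å diameter),
  unpaired stretches as a 6.5 Å-step extended chain. This is a coarse
  deterministic shape proxy, not tertiary-structure prediction.
- **Scoring.** Structures are voxelised at 2.0 Å with a 2.0 Å atom
  radius (grid anchored on the structure minimum, so joint rigid
  translations of both partners leave scores unchanged). The receptor
  contributes +1 on its empty contact layer (unoccupied voxels
  6-adjacent to the body) and −9 on the body itself; the ligand
  contributes 1 per occupied voxel. All translations of a rotation are
  scored at once by FFT cross-correlation, verified exactly against
  direct summation; rotations come as prefixes of one fixed
  quaternion pool (identity first), so enlarging the set can only
  improve the best score. A candidate's fitness is its best pose score.
- **Hydrogen bonds.** The profiler is geometric: N/O donors with an
  explicit hydrogen within 1.3 Å, N/O acceptors on the other chain,
  donor–acceptor ≤ 3.5 Å and D–H···A ≥ 120° (common textbook values;
  dedicated profilers differ slightly — both cutoffs are parameters).

## Assay analytics

- **Kinetics.** Strict 1:1 Langmuir binding (the standard instrument
  model): association R(t) = Req(1 − e^−(kon·C+koff)t) with
  Req = Rmax·C/(C + Kd), exponential dissociation, Kd = koff/kon by
  construction. Fitting is global nonlinear least squares in
  log-parameter space over all concentrations jointly, from a 3×3
  multi-start grid (kon 1e4–1e6 M⁻¹s⁻¹ × koff 1e-3–1e-1 s⁻¹) to dodge
  local minima; mass transport is excluded. The simulator's default
  titration (125–2000 nM, Kd 105.6 nM, Rmax 1.2 nm) represents a
  typical BLI experiment on a ~100 nM-affinity aptamer. The real
  instrument protocol has five dips; only association and dissociation
  carry kinetics, so the simulated schedule is baseline/association/
  dissociation at 120 s each.
- **Beacons.** A beacon is stem + loop + stem with the loop the
  reverse complement of a terminal aptamer region (default the 3'
  terminus, keeping clear of 5'-proximal binding-implicated bases;
  configurable) and a 5-bp GC stem chosen deterministically so it
  cannot form ≥(stem−1) pairs with the loop; FAM/BHQ1 labels are
  annotated metadata. Published beacon sequences for such assays are
  supplementary-only, so these designs are constructive defaults, not
  asserted reproductions.
- **Calibration.** Reduction rate y = (F0 − F)/F0 × 100 %; ordinary
  least squares of y against concentration (nM); LOD = 3·SD(blank
  rates)/slope, which requires blank replicates — the synthetic
  calibration fixture's defaults (slope 0.106 %/nM, intercept 5.758 %,
  1–250 nM range, percent-scale blank scatter) describe a typical
  linear aptasensor response.

## What the synthetic data does not show

The generators produce exact model realisations (plus Gaussian noise
where asked): passing tests demonstrate algorithmic correctness —
energy minimisation, selection logic, estimator consistency — not that
the energy model matches real folding, that shape complementarity
predicts real affinity gains, or that a real sensorgram is 1:1
Langmuir. External docking scores and real assay tables can be
substituted at the documented interfaces to test those claims.

## Problem sizes used in the shipped checks

Folding oracle: 200 random 8–14-mers (exhaustive enumeration is
exponential; 14 nt keeps it exact and honest). Maturation properties:
6 rounds at 100 mutants/parent over 3 seeds. FFT/direct equivalence:
grids to 16³. Kinetics: 5-concentration titrations, 20 noisy
replicates. These sizes were chosen so the whole suite runs on a
laptop-class single core in well under an hour while still exercising
every code path at the published round/selection counts.
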