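"""Genetic-algorithm post-SELEX maturation loop.

Each round: mutate the surviving parents into a pool of point mutants,
remove duplicates (within the round and against everything evaluated
before), fold the pool and keep the ``k_energy`` mutants with the
lowest free energy, then re-rank those by docking fitness and keep the
``k_fitness`` best as parents for the next round. The reported winner
is the highest-fitness candidate seen in *any* round, not the last one
— late rounds can lose docking fitness even as free energy keeps
falling.

Defaults mirror the published screening protocol: a single parent
mutated to ~1000 sequences in round one, four survivors at 250 mutants
each thereafter, top 10 by energy, top 4 by docking, six rounds, two
substitutions per mutant.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .energetics import EnergyModel, build_energy_model
from .folding import FoldResult, fold_batch
from .sequences import NucleotideSequence, hamming

logger = logging.getLogger(__name__)

FitnessFn = Callable[[NucleotideSequence], float]

_OTHER_BASES = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


@dataclass(frozen=True)
class Candidate:
    """A lineage-tracked aptamer mutant.

    ``provenance`` records the substitutions relative to the immediate
    parent as (1-based position, new base); replaying them onto the
    parent's bases reproduces this candidate exactly.
    """

    sequence: NucleotideSequence
    generation: int
    parent_id: str
    delta_g: Optional[float] = None
    fitness: Optional[float] = None
    provenance: Tuple[Tuple[int, str], ...] = ()

    @property
    def bases(self) -> str:
        return self.sequence.bases

    def replay_onto(self, parent_bases: str) -> str:
        out = list(parent_bases)
        for pos, base in self.provenance:
            out[pos - 1] = base
        return "".join(out)


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of the maturation loop (defaults = published protocol)."""

    n_rounds: int = 6
    mutants_per_parent: int = 250
    round1_mutants: int = 1000
    subs_per_mutant: int = 2
    k_energy: int = 10
    k_fitness: int = 4
    rng_seed: int = 0
    elitism: bool = True
    dedup_across_rounds: bool = True

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.subs_per_mutant < 1:
            raise ValueError("subs_per_mutant must be >= 1")
        if not (self.k_fitness <= self.k_energy):
            raise ValueError("k_fitness must not exceed k_energy")


@dataclass
class RoundReport:
    round_index: int
    pool_size_before_dedup: int
    pool_size_after_dedup: int
    energy_selected: List[Candidate]
    fitness_selected: List[Candidate]
    best_delta_g: float
    best_fitness: float


@dataclass
class EvolutionReport:
    config: EvolutionConfig
    rounds: List[RoundReport]
    global_best: Candidate
    n_folded: int
    n_fitness_evaluations: int

    def lineage_table(self) -> List[Dict]:
        rows = []
        for rr in self.rounds:
            for c in rr.energy_selected:
                rows.append(
                    {
                        "round": rr.round_index,
                        "id": c.sequence.id,
                        "parent_id": c.parent_id,
                        "bases": c.bases,
                        "delta_g": c.delta_g,
                        "fitness": c.fitness,
                        "mutations": [
                            f"{pos}{base}" for pos, base in c.provenance
                        ],
                        "fitness_selected": c.sequence.id
                        in {x.sequence.id for x in rr.fitness_selected},
                    }
                )
        return rows

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "n_folded": self.n_folded,
            "n_fitness_evaluations": self.n_fitness_evaluations,
            "global_best": {
                "id": self.global_best.sequence.id,
                "bases": self.global_best.bases,
                "generation": self.global_best.generation,
                "delta_g": self.global_best.delta_g,
                "fitness": self.global_best.fitness,
            },
            "rounds": [
                {
                    "round": rr.round_index,
                    "pool_size_before_dedup": rr.pool_size_before_dedup,
                    "pool_size_after_dedup": rr.pool_size_after_dedup,
                    "best_delta_g": rr.best_delta_g,
                    "best_fitness": rr.best_fitness,
                }
                for rr in self.rounds
            ],
            "lineage": self.lineage_table(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def mutate_population(
    parents: Sequence[Candidate],
    n_per_parent: int,
    subs_per_mutant: int,
    rng: np.random.Generator,
) -> List[Candidate]:
    """Draw ``n_per_parent`` random mutants of each parent.

    Each mutant substitutes exactly ``subs_per_mutant`` distinct,
    uniformly chosen positions with a uniformly chosen *different*
    base, so every mutant sits at that exact Hamming distance from its
    parent.
    """
    if not parents:
        raise ValueError("parent list is empty")
    out: List[Candidate] = []
    for parent in parents:
        bases = parent.bases
        L = len(bases)
        if subs_per_mutant > L:
            raise ValueError("subs_per_mutant exceeds sequence length")
        for k in range(n_per_parent):
            positions = sorted(rng.choice(L, size=subs_per_mutant, replace=False))
            mutated = list(bases)
            prov = []
            for pos in positions:
                choices = _OTHER_BASES[bases[pos]]
                mutated[pos] = choices[rng.integers(len(choices))]
                prov.append((int(pos) + 1, mutated[pos]))
            out.append(
                Candidate(
                    sequence=NucleotideSequence(
                        f"{parent.sequence.id}.m{k + 1}", "".join(mutated)
                    ),
                    generation=parent.generation + 1,
                    parent_id=parent.sequence.id,
                    provenance=tuple(prov),
                )
            )
    return out


def deduplicate(
    pool: Sequence[Candidate], history: Set[str] | None = None
) -> List[Candidate]:
    """Keep the first occurrence of each base string; drop history hits."""
    history = history or set()
    seen: Set[str] = set()
    out = []
    for c in pool:
        if c.bases in history or c.bases in seen:
            continue
        seen.add(c.bases)
        out.append(c)
    return out


def select_by_energy(
    pool: Sequence[Candidate],
    k_energy: int,
    model: EnergyModel | None = None,
) -> List[Candidate]:
    """Fold everyone, keep the ``k_energy`` lowest-energy candidates.

    Candidates already annotated with a free energy are not re-folded.
    Ties break lexicographically on bases. A pool smaller than
    ``k_energy`` is returned whole (with a logged warning).
    """
    m = model if model is not None else build_energy_model()
    to_fold = [c for c in pool if c.delta_g is None]
    results = fold_batch([c.sequence for c in to_fold], model=m)
    by_id = {r.sequence.id: r for r in results}
    annotated = [
        c if c.delta_g is not None else replace(c, delta_g=by_id[c.sequence.id].delta_g)
        for c in pool
    ]
    annotated.sort(key=lambda c: (c.delta_g, c.bases))
    if len(annotated) < k_energy:
        logger.warning(
            "pool size %d smaller than k_energy=%d; returning whole pool",
            len(annotated),
            k_energy,
        )
        return annotated
    return annotated[:k_energy]


def select_by_fitness(
    cands: Sequence[Candidate],
    k_fitness: int,
    fitness_fn: FitnessFn,
) -> List[Candidate]:
    """Keep the ``k_fitness`` highest-fitness candidates, descending.

    A fitness evaluation that raises drops that candidate with a logged
    error rather than aborting the round. Ties break lexicographically.
    """
    annotated = []
    for c in cands:
        if c.fitness is not None:
            annotated.append(c)
            continue
        try:
            annotated.append(replace(c, fitness=float(fitness_fn(c.sequence))))
        except Exception:
            logger.exception("fitness evaluation failed for %s; dropped", c.sequence.id)
    annotated.sort(key=lambda c: (-c.fitness, c.bases))
    return annotated[:k_fitness]


def run_evolution(
    parent: NucleotideSequence,
    config: EvolutionConfig,
    fitness_fn: FitnessFn,
    model: EnergyModel | None = None,
) -> EvolutionReport:
    """Run the full maturation loop from a single parent aptamer."""
    m = model if model is not None else build_energy_model()
    rng = np.random.default_rng(config.rng_seed)

    parent_seq = NucleotideSequence(parent.id, parent.bases)
    root = Candidate(sequence=parent_seq, generation=0, parent_id="")
    root_folded = select_by_energy([root], 1, model=m)[0]
    root = replace(root_folded, fitness=float(fitness_fn(root_folded.sequence)))

    history: Set[str] = {root.bases}
    parents: List[Candidate] = [root]
    rounds: List[RoundReport] = []
    global_best = root
    n_folded = 1
    n_fitness = 1
    fitness_seen: Set[str] = {root.bases}

    for rnd in range(1, config.n_rounds + 1):
        n_per_parent = config.round1_mutants if rnd == 1 else config.mutants_per_parent
        n_per_parent = max(1, n_per_parent // max(1, len(parents))) if rnd == 1 else n_per_parent
        pool = mutate_population(parents, n_per_parent, config.subs_per_mutant, rng)
        size_before = len(pool)
        pool = deduplicate(pool, history if config.dedup_across_rounds else {p.bases for p in parents})
        size_after = len(pool)
        history.update(c.bases for c in pool)
        n_folded += len(pool)

        selection_pool = list(pool)
        if config.elitism:
            selection_pool.extend(parents)  # already annotated, not re-folded
        energy_selected = select_by_energy(selection_pool, config.k_energy, model=m)

        new_fitness = [c for c in energy_selected if c.fitness is None and c.bases not in fitness_seen]
        n_fitness += len(new_fitness)
        fitness_seen.update(c.bases for c in new_fitness)
        fitness_selected = select_by_fitness(energy_selected, config.k_fitness, fitness_fn)

        # propagate fitness annotations back into the energy selection
        fit_by_id = {c.sequence.id: c for c in fitness_selected}
        energy_selected = [fit_by_id.get(c.sequence.id, c) for c in energy_selected]

        best_by_fit = max(
            (c for c in fitness_selected if c.fitness is not None),
            key=lambda c: c.fitness,
            default=None,
        )
        if best_by_fit is not None and (
            global_best.fitness is None or best_by_fit.fitness > global_best.fitness
        ):
            global_best = best_by_fit

        rounds.append(
            RoundReport(
                round_index=rnd,
                pool_size_before_dedup=size_before,
                pool_size_after_dedup=size_after,
                energy_selected=energy_selected,
                fitness_selected=fitness_selected,
                best_delta_g=min(c.delta_g for c in energy_selected),
                best_fitness=max(c.fitness for c in fitness_selected),
            )
        )
        parents = fitness_selected

    return EvolutionReport(
        config=config,
        rounds=rounds,
        global_best=global_best,
        n_folded=n_folded,
        n_fitness_evaluations=n_fitness,
    )
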