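import json

import numpy as np
import pytest

from aptevolve.evolve import (
    Candidate,
    EvolutionConfig,
    deduplicate,
    mutate_population,
    run_evolution,
    select_by_energy,
    select_by_fitness,
)
from aptevolve.folding import fold_mfe
from aptevolve.sequences import B1_4, NucleotideSequence, hamming


def _cand(bases, ident="c", **kw):
    defaults = dict(generation=1, parent_id="p")
    defaults.update(kw)
    return Candidate(sequence=NucleotideSequence(ident, bases), **defaults)


def _root(seq=B1_4):
    return Candidate(sequence=seq, generation=0, parent_id="")


class TestMutation:
    def test_every_mutant_sits_at_exact_hamming_distance(self):
        rng = np.random.default_rng(0)
        pool = mutate_population([_root()], 200, 2, rng)
        assert len(pool) == 200
        for c in pool:
            assert hamming(c.bases, B1_4.bases) == 2
            assert len(c.provenance) == 2

    def test_four_parents_at_250_give_a_pool_of_1000(self):
        rng = np.random.default_rng(1)
        parents = [_cand(B1_4.bases[:-1] + b, f"p{b}") for b in "ACGT"]
        assert len(mutate_population(parents, 250, 2, rng)) == 1000

    def test_substituted_base_differs_from_original(self):
        rng = np.random.default_rng(2)
        for c in mutate_population([_root()], 300, 1, rng):
            (pos, new) = c.provenance[0]
            assert new != B1_4.bases[pos - 1]
            assert c.replay_onto(B1_4.bases) == c.bases

    def test_reproducible_from_seed_and_guards(self):
        a = mutate_population([_root()], 50, 2, np.random.default_rng(7))
        b = mutate_population([_root()], 50, 2, np.random.default_rng(7))
        assert [c.bases for c in a] == [c.bases for c in b]
        with pytest.raises(ValueError):
            mutate_population([], 10, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            mutate_population([_cand("ACGT")], 1, 9, np.random.default_rng(0))


class TestDeduplication:
    def test_duplicates_history_and_parent_removed(self):
        a, b = _cand("ACGTACGT", "a"), _cand("ACGTACGT", "b")
        c = _cand("TTTTAAAA", "c")
        assert [x.sequence.id for x in deduplicate([a, b, c])] == ["a", "c"]
        assert deduplicate([a, c], history={"ACGTACGT"}) == [c]
        assert deduplicate([a, c], history=set()) == [a, c]


class TestSelection:
    def test_energy_selection_keeps_lowest(self):
        pool = [
            _cand("AAAATTTT", "x", delta_g=-5.0),
            _cand("CCCCGGGG", "y", delta_g=-1.0),
            _cand("GGGGCCCC", "z", delta_g=2.0),
        ]
        chosen = select_by_energy(pool, 2)
        assert [c.sequence.id for c in chosen] == ["x", "y"]

    def test_energy_selection_equals_sort_oracle(self, energy_model):
        from aptevolve.fixtures import make_random_sequences

        pool = [_root(s) for s in make_random_sequences(25, 30, rng=4)]
        chosen = select_by_energy(pool, 10, model=energy_model)
        oracle = sorted(
            ((fold_mfe(c.sequence, model=energy_model).delta_g, c.bases) for c in pool)
        )[:10]
        assert [(c.delta_g, c.bases) for c in chosen] == oracle

    def test_small_pool_returned_whole_with_warning(self, caplog):
        pool = [_cand("AAAATTTT", "x", delta_g=-5.0)]
        with caplog.at_level("WARNING"):
            assert select_by_energy(pool, 10) == pool
        assert "smaller than k_energy" in caplog.text

    def test_fitness_selection_descending_and_tie_rule(self):
        pool = [
            _cand("AAAA", "a", fitness=10.0),
            _cand("CCCC", "b", fitness=30.0),
            _cand("GGGG", "c", fitness=20.0),
            _cand("TTTT", "d", fitness=5.0),
        ]
        assert [c.fitness for c in select_by_fitness(pool, 2, None)] == [30.0, 20.0]
        fresh = [_cand(b * 4, b) for b in "TGCA"]
        flat = select_by_fitness(fresh, 2, lambda s: 1.0)
        # constant fitness: ties resolve lexicographically on bases
        assert [c.bases for c in flat] == ["AAAA", "CCCC"]

    def test_failing_fitness_drops_candidate_loudly(self, caplog):
        def flaky(seq):
            if seq.bases.startswith("A"):
                raise RuntimeError("no score")
            return 1.0

        pool = [_cand("AAAA", "a"), _cand("CCCC", "b")]
        with caplog.at_level("ERROR"):
            kept = select_by_fitness(pool, 2, flaky)
        assert [c.sequence.id for c in kept] == ["b"]
        assert "fitness evaluation failed" in caplog.text


class TestEvolutionLoop:
    CFG = dict(n_rounds=3, mutants_per_parent=30, round1_mutants=60, rng_seed=5)

    def _energy_fitness(self, model):
        return lambda s: -fold_mfe(s, model=model).delta_g

    def test_report_shape_and_counts(self, energy_model):
        cfg = EvolutionConfig(**self.CFG)
        rep = run_evolution(B1_4, cfg, self._energy_fitness(energy_model), model=energy_model)
        assert len(rep.rounds) == 3
        assert rep.rounds[0].pool_size_before_dedup == 60
        assert rep.rounds[1].pool_size_before_dedup == 4 * 30
        for rr in rep.rounds:
            assert len(rr.energy_selected) == 10
            assert len(rr.fitness_selected) == 4
            dgs = [c.delta_g for c in rr.energy_selected]
            assert dgs == sorted(dgs)
            fits = [c.fitness for c in rr.fitness_selected]
            assert fits == sorted(fits, reverse=True)
            chosen = {c.bases for c in rr.fitness_selected}
            assert chosen <= {c.bases for c in rr.energy_selected}

    def test_elitism_monotonicity(self, energy_model):
        cfg = EvolutionConfig(**self.CFG)
        rep = run_evolution(B1_4, cfg, self._energy_fitness(energy_model), model=energy_model)
        best_dg = [rr.best_delta_g for rr in rep.rounds]
        best_fit = [rr.best_fitness for rr in rep.rounds]
        assert all(a >= b for a, b in zip(best_dg, best_dg[1:]))
        assert all(a <= b for a, b in zip(best_fit, best_fit[1:]))
        assert rep.global_best.fitness == max(best_fit)

    def test_same_seed_reproduces_report_bit_identically(self, energy_model):
        cfg = EvolutionConfig(**self.CFG)
        fit = self._energy_fitness(energy_model)
        a = run_evolution(B1_4, cfg, fit, model=energy_model)
        b = run_evolution(B1_4, cfg, fit, model=energy_model)
        assert a.to_json() == b.to_json()

    def test_provenance_replays_and_no_double_fitness_evaluation(self, energy_model):
        calls = []

        def counting_fitness(seq):
            calls.append(seq.bases)
            return -fold_mfe(seq, model=energy_model).delta_g

        cfg = EvolutionConfig(**self.CFG)
        rep = run_evolution(B1_4, cfg, counting_fitness, model=energy_model)
        assert len(calls) == len(set(calls))  # evaluation-counter audit
        by_id = {B1_4.id: B1_4.bases}
        for rr in rep.rounds:
            for c in rr.energy_selected:
                by_id.setdefault(c.sequence.id, c.bases)
        for rr in rep.rounds:
            for c in rr.energy_selected:
                if c.generation == 0:
                    continue
                parent_bases = by_id.get(c.parent_id)
                if parent_bases is not None:
                    assert c.replay_onto(parent_bases) == c.bases

    def test_full_pipeline_with_internal_docking_fitness(self, energy_model):
        """fold -> embed -> FFT dock as the live fitness, tiny scale."""
        from aptevolve.dock3d import make_shape_fitness
        from aptevolve.fixtures import make_block_with_notch

        receptor, _, _ = make_block_with_notch(8, 3)
        fitness = make_shape_fitness(receptor, model=energy_model, n_rotations=4)
        cfg = EvolutionConfig(n_rounds=2, mutants_per_parent=8, round1_mutants=16, rng_seed=2)
        rep = run_evolution(B1_4, cfg, fitness, model=energy_model)
        assert len(rep.rounds) == 2
        assert rep.global_best.fitness is not None
        assert rep.global_best.fitness >= rep.rounds[0].best_fitness

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EvolutionConfig(k_energy=4, k_fitness=10)
        with pytest.raises(ValueError):
            EvolutionConfig(n_rounds=0)
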