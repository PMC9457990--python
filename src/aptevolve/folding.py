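"""Minimum-free-energy folding of DNA sequences (Zuker dynamic program).

``fold_mfe`` predicts the MFE non-pseudoknotted secondary structure of
a single-stranded DNA oligonucleotide under the nearest-neighbor model
in :mod:`aptevolve.energetics`; ``fold_batch`` folds a pool and ranks
it by ascending free energy, which is the energy-selection step of the
maturation loop.

Free energies are in kcal/mol. By default, when a sequence has no
stabilising structure (best folded state above zero), the best folded
state is still reported with its positive free energy — matching how
the classic DNA folding servers report weak folds — and the open chain
(0.0) appears only when no legal pair exists at all.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np

from . import scoring
from ._zuker import fill_matrices
from .energetics import (
    INF,
    MAXLOOP,
    PAIR_TABLE,
    EnergyModel,
    EnergyParameterSet,
    FoldParameters,
    build_energy_model,
)
from .scoring import enumerate_structures  # re-exported oracle
from .sequences import BASE_INDEX, NucleotideSequence
from .structure import (
    MIN_HAIRPIN,
    SecondaryStructure,
    open_chain,
    parse_dot_bracket,
    to_dot_bracket,
)

__all__ = [
    "FoldResult",
    "fold_mfe",
    "fold_batch",
    "write_fold_report",
    "enumerate_structures",
    "parse_dot_bracket",
    "to_dot_bracket",
]

MAX_FOLD_LENGTH = 512
_EPS = 1e-5


@dataclass(frozen=True)
class FoldResult:
    """A folded sequence: MFE structure plus its free energy (kcal/mol)."""

    sequence: NucleotideSequence
    structure: SecondaryStructure
    delta_g: float

    @property
    def dot_bracket(self) -> str:
        return self.structure.dot_bracket


def _encode_specials(model: EnergyModel, length: int):
    seqs = [k for k in sorted(model.special_hairpins) if len(k) == length]
    if not seqs:
        return np.zeros((0, length), dtype=np.int8), np.zeros(0)
    arr = np.array([[BASE_INDEX[c] for c in k] for k in seqs], dtype=np.int8)
    e = np.array([model.special_hairpins[k] for k in seqs])
    return arr, e


def _run_kernel(s: np.ndarray, m: EnergyModel):
    tri_s, tri_e = _encode_specials(m, 5)
    tet_s, tet_e = _encode_specials(m, 6)
    return fill_matrices(
        s, PAIR_TABLE, m.stack, m.tstackh, m.tstacki, m.mm_multi, m.mm_ext,
        m.hairpin, m.bulge, m.internal,
        m.ninio_per_asym, m.ninio_max, m.ml_unpaired, m.ml_closing,
        m.ml_branch, m.terminal_at, m.lxc,
        m.use_dangles, tri_s, tri_e, tet_s, tet_e,
    )


def _ext_term(s: np.ndarray, i: int, j: int, m: EnergyModel) -> float:
    return scoring.exterior_branch_term(s, i, j, m)


def _trace_v(s, bases, i, j, m, V, M1, WM, pairs):
    pairs.append((i + 1, j + 1))
    target = V[i, j]
    e = scoring.hairpin_energy(s, bases, i, j, m)
    if e <= target + _EPS:
        return
    kmax = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 1)
    for k in range(i + 1, kmax + 1):
        n1 = k - i - 1
        lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - n1))
        for l in range(lmin, j):
            if not np.isfinite(V[k, l]):
                continue
            e = scoring.internal_energy(s, i, j, k, l, m) + V[k, l]
            if e <= target + _EPS:
                _trace_v(s, bases, k, l, m, V, M1, WM, pairs)
                return
    pt = scoring.pair_type(s, i, j)
    close = m.ml_closing + m.ml_branch + m.at_penalty(pt)
    if m.use_dangles:
        ptr = scoring.pair_type(s, j, i)
        close += float(m.mm_multi[ptr, s[j - 1] + 1, s[i + 1] + 1])
    for k in range(i + 2, j - MIN_HAIRPIN - 1):
        if np.isfinite(WM[i + 1, k - 1]) and np.isfinite(M1[k, j - 1]):
            e = WM[i + 1, k - 1] + M1[k, j - 1] + close
            if e <= target + _EPS:
                _trace_wm(s, bases, i + 1, k - 1, m, V, M1, WM, pairs)
                _trace_m1(s, bases, k, j - 1, m, V, M1, WM, pairs)
                return
    raise AssertionError(f"traceback failed at V[{i},{j}]")


def _branch_term(s, i, j, m, V):
    e = V[i, j] + m.ml_branch + m.at_penalty(scoring.pair_type(s, i, j))
    if m.use_dangles:
        e += float(m.mm_multi[scoring.pair_type(s, i, j), s[i - 1] + 1, s[j + 1] + 1])
    return e


def _trace_m1(s, bases, i, j, m, V, M1, WM, pairs):
    target = M1[i, j]
    if np.isfinite(V[i, j]) and _branch_term(s, i, j, m, V) <= target + _EPS:
        _trace_v(s, bases, i, j, m, V, M1, WM, pairs)
        return
    if j - 1 >= i and np.isfinite(M1[i, j - 1]):
        if M1[i, j - 1] + m.ml_unpaired <= target + _EPS:
            _trace_m1(s, bases, i, j - 1, m, V, M1, WM, pairs)
            return
    raise AssertionError(f"traceback failed at M1[{i},{j}]")


def _trace_wm(s, bases, i, j, m, V, M1, WM, pairs):
    target = WM[i, j]
    if np.isfinite(M1[i, j]) and M1[i, j] <= target + _EPS:
        _trace_m1(s, bases, i, j, m, V, M1, WM, pairs)
        return
    for k in range(i + 1, j):
        if np.isfinite(WM[i, k - 1]) and np.isfinite(M1[k, j]):
            if WM[i, k - 1] + M1[k, j] <= target + _EPS:
                _trace_wm(s, bases, i, k - 1, m, V, M1, WM, pairs)
                _trace_m1(s, bases, k, j, m, V, M1, WM, pairs)
                return
    if np.isfinite(WM[i + 1, j]) and WM[i + 1, j] + m.ml_unpaired <= target + _EPS:
        _trace_wm(s, bases, i + 1, j, m, V, M1, WM, pairs)
        return
    raise AssertionError(f"traceback failed at WM[{i},{j}]")


def fold_mfe(
    seq: NucleotideSequence,
    params: FoldParameters | None = None,
    energies: EnergyParameterSet | None = None,
    *,
    model: EnergyModel | None = None,
    report_positive: bool = True,
    max_length: int = MAX_FOLD_LENGTH,
) -> FoldResult:
    """Fold one sequence to its minimum-free-energy structure.

    With ``report_positive`` (the default) a sequence whose best folded
    state is destabilising still gets that state reported, with its
    positive free energy; with ``report_positive=False`` the result is
    the unconstrained optimum, i.e. the open chain at 0.0 in that case.
    """
    n = len(seq)
    if n > max_length:
        raise ValueError(f"{seq.id!r}: length {n} exceeds maximum {max_length}")
    m = model if model is not None else build_energy_model(params, energies)
    if n < MIN_HAIRPIN + 2:
        return FoldResult(seq, open_chain(n), 0.0)
    s = seq.encode()
    bases = seq.bases
    V, M1, WM, W = _run_kernel(s, m)

    pairs: List[tuple] = []
    mfe = float(W[0])
    if mfe < -_EPS or not report_positive:
        if mfe < -_EPS:
            i = 0
            while i < n:
                done = False
                for j in range(i + MIN_HAIRPIN + 1, n):
                    if not np.isfinite(V[i, j]):
                        continue
                    e = V[i, j] + _ext_term(s, i, j, m) + W[j + 1]
                    if e <= W[i] + _EPS:
                        _trace_v(s, bases, i, j, m, V, M1, WM, pairs)
                        i = j + 1
                        done = True
                        break
                if not done:
                    i += 1
        delta_g = mfe if mfe < -_EPS else 0.0
        return FoldResult(seq, SecondaryStructure(n, frozenset(pairs)), delta_g)

    # open chain is optimal; report the best single folded component if any
    best = INF
    best_ij = None
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            if not np.isfinite(V[i, j]):
                continue
            e = V[i, j] + _ext_term(s, i, j, m)
            if e < best - _EPS:
                best = e
                best_ij = (i, j)
    if best_ij is None:
        return FoldResult(seq, open_chain(n), 0.0)
    _trace_v(s, bases, best_ij[0], best_ij[1], m, V, M1, WM, pairs)
    return FoldResult(seq, SecondaryStructure(n, frozenset(pairs)), float(best))


def fold_batch(
    seqs: Sequence[NucleotideSequence],
    params: FoldParameters | None = None,
    energies: EnergyParameterSet | None = None,
    *,
    model: EnergyModel | None = None,
    report_positive: bool = True,
) -> List[FoldResult]:
    """Fold a pool and return results sorted by ascending free energy.

    Ties are broken lexicographically by sequence bases so rankings are
    reproducible. Errors carry the offending sequence id.
    """
    m = model if model is not None else build_energy_model(params, energies)
    results = []
    for seq in seqs:
        try:
            results.append(fold_mfe(seq, model=m, report_positive=report_positive))
        except Exception as exc:  # re-raise with context
            raise type(exc)(f"while folding {seq.id!r}: {exc}") from exc
    results.sort(key=lambda r: (r.delta_g, r.sequence.bases))
    return results


def write_fold_report(results: Iterable[FoldResult], path: str | Path) -> None:
    """Tabular fold report: id, sequence, dot-bracket, delta-G (kcal/mol)."""
    with open(path, "w") as fh:
        fh.write("id\tsequence\tdot_bracket\tdelta_g_kcal_mol\n")
        for r in results:
            fh.write(
                f"{r.sequence.id}\t{r.sequence.bases}\t{r.dot_bracket}\t{r.delta_g:.2f}\n"
            )
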