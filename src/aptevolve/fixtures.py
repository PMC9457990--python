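"""Deterministic synthetic-data generators.

Everything the pipeline consumes can be generated here with no
external downloads: random and designed DNA sequences, geometric
docking fixtures with a known optimum, ideal sensorgrams and
calibration tables. Every generator is a pure function of its
parameters and seed — same spec, same bytes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .assay import PhaseSchedule, Sensorgram, simulate_sensorgram
from .dock3d import Structure3D
from .sequences import NucleotideSequence, reverse_complement
from .structure import SecondaryStructure, parse_dot_bracket


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def make_random_sequences(
    n: int,
    length: int,
    gc_fraction: float = 0.5,
    rng: np.random.Generator | int | None = 0,
    prefix: str = "rnd",
) -> List[NucleotideSequence]:
    """Random DNA with the requested expected GC content."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    g = _rng(rng)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    out = []
    for k in range(n):
        draws = g.choice(4, size=length, p=p)
        out.append(
            NucleotideSequence(f"{prefix}{k}", "".join("ACGT"[d] for d in draws))
        )
    return out


def make_hairpin(
    stem_len: int,
    loop_len: int,
    rng: np.random.Generator | int | None = 0,
) -> NucleotideSequence:
    """A sequence designed to close a perfect GC-rich hairpin.

    The designed dot-bracket ``( * stem_len + . * loop_len + ) *
    stem_len`` is a legal structure of the returned sequence, giving a
    known upper bound on its MFE.
    """
    if stem_len < 1:
        raise ValueError("stem_len must be >= 1")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    g = _rng(rng)
    stem = "".join(g.choice(list("GC"), size=stem_len))
    loop = "".join(g.choice(list("AT"), size=loop_len))
    bases = stem + loop + reverse_complement(stem)
    return NucleotideSequence(f"hp{stem_len}x{loop_len}", bases)


def designed_hairpin_structure(stem_len: int, loop_len: int) -> SecondaryStructure:
    return parse_dot_bracket("(" * stem_len + "." * loop_len + ")" * stem_len)


def make_block_with_notch(
    size: int = 12,
    notch_size: int = 4,
    spacing: float = 2.0,
    displacement: Sequence[float] = (25.0, 0.0, 0.0),
) -> Tuple[Structure3D, Structure3D, np.ndarray]:
    """A cubic receptor with a notch, and a ligand that exactly fills it.

    One pseudo-atom per lattice cell (``spacing`` apart). The notch is
    carved into the centre of the top face; the ligand is the removed
    block, shifted away by ``displacement``, so the known optimal rigid
    shift is ``-displacement`` (returned as ``expected_offset``).
    """
    if notch_size < 1:
        raise ValueError("notch_size must be >= 1")
    if notch_size >= size:
        raise ValueError("notch must be smaller than the block")
    lo = (size - notch_size) // 2
    notch_xy = range(lo, lo + notch_size)
    notch_z = range(size - notch_size, size)

    rec_pts, lig_pts = [], []
    for x in range(size):
        for y in range(size):
            for z in range(size):
                in_notch = x in notch_xy and y in notch_xy and z in notch_z
                (lig_pts if in_notch else rec_pts).append((x, y, z))
    rec = np.array(rec_pts, dtype=float) * spacing
    lig = np.array(lig_pts, dtype=float) * spacing + np.asarray(displacement, dtype=float)

    def as_structure(coords: np.ndarray, chain: str) -> Structure3D:
        n = coords.shape[0]
        return Structure3D(
            atom_names=["C"] * n,
            residue_names=["BLK"] * n,
            chain_ids=[chain] * n,
            residue_indices=np.arange(1, n + 1),
            coords=coords,
            source="synthetic",
        )

    expected_offset = -np.asarray(displacement, dtype=float)
    return as_structure(rec, "R"), as_structure(lig, "L"), expected_offset


def make_sensorgram_set(
    kon: float = 1e5,
    koff: float = 1.056e-2,
    rmax: float = 1.2,
    concentrations: Sequence[float] = (125.0, 250.0, 500.0, 1000.0, 2000.0),
    schedule: PhaseSchedule = PhaseSchedule(),
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = 0,
) -> List[Sensorgram]:
    """Sensorgrams over an analyte titration (defaults: Kd = 105.6 nM)."""
    g = _rng(rng)
    return [
        simulate_sensorgram(kon, koff, rmax, c, schedule, noise_sd, g)
        for c in concentrations
    ]


def make_calibration_set(
    slope: float = 0.106,
    intercept: float = 5.758,
    concentrations: Sequence[float] = (1.0, 5.0, 10.0, 50.0, 100.0, 150.0, 200.0, 250.0),
    noise_sd: float = 0.0,
    blank_sd: float = 0.112,
    n_blanks: int = 11,
    rng: np.random.Generator | int | None = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(concentrations, reduction rates, blank replicate rates).

    Defaults follow a linear aptasensor response over a 1-250 nM
    working range with a percent-scale blank scatter.
    """
    g = _rng(rng)
    x = np.asarray(concentrations, dtype=float)
    y = slope * x + intercept
    if noise_sd > 0:
        y = y + g.normal(0.0, noise_sd, size=y.shape)
    blanks = g.normal(0.0, blank_sd, size=n_blanks)
    return x, y, blanks


@dataclass(frozen=True)
class FixtureSpec:
    """Registry key: a fixture kind plus its parameters and seed."""

    kind: str
    parameters: Tuple[Tuple[str, object], ...] = ()
    rng_seed: int = 0

    def build(self):
        params = dict(self.parameters)
        maker = _REGISTRY.get(self.kind)
        if maker is None:
            raise KeyError(f"unknown fixture kind {self.kind!r}")
        return maker(rng=self.rng_seed, **params) if self.kind in _SEEDED else maker(**params)


_SEEDED = {"random_seq", "hairpin_seq", "sensorgram_set", "calibration_set"}
_REGISTRY = {
    "random_seq": make_random_sequences,
    "hairpin_seq": make_hairpin,
    "block_with_notch": make_block_with_notch,
    "sensorgram_set": make_sensorgram_set,
    "calibration_set": make_calibration_set,
}
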