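"""Nearest-neighbor thermodynamic parameters for DNA secondary structure.

The bundled ``dna1999`` profile is the unified SantaLucia-family DNA
parameter compilation (37 degC, 1 M NaCl reference) that the classic
DNA folding servers used. Free energies are in kcal/mol throughout.

Two layers are exposed:

``EnergyParameterSet``
    the raw dG37/dH tables as read from disk (value-comparable,
    re-loadable, serialisable);
``EnergyModel``
    dense numpy arrays rescaled to the requested temperature and ionic
    strength, in the integer encodings the folding kernels consume.

Temperature rescaling assumes temperature-independent enthalpy,
``dG(T) = dH - (dH - dG37) * T / 310.15``; loop entropies extrapolate
beyond tabulated lengths with the Jacobson-Stockmayer ``lxc * ln(n/30)``
term. Monovalent-salt correction follows the standard per-stack
entropic form, with divalent magnesium folded into an effective sodium
concentration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Tuple

import numpy as np

INF = float("inf")
T37 = 310.15  # K

PAIR_NAMES = ("CG", "GC", "AT", "TA")
PAIR_INDEX = {p: k for k, p in enumerate(PAIR_NAMES)}
# (base_i, base_j) -> pair type; A=0 C=1 G=2 T=3
PAIR_TABLE = -np.ones((4, 4), dtype=np.int8)
for _name, _k in PAIR_INDEX.items():
    PAIR_TABLE[("ACGT".index(_name[0]), "ACGT".index(_name[1]))] = _k

BASE_COL = {"N": 0, "A": 1, "C": 2, "G": 3, "T": 4}

BUILTIN_PROFILES = {"dna1999": "dna_nn_1999.tsv", "dna04": "dna_nn_1999.tsv"}

MAXLOOP = 30  # largest bulge/internal loop considered


class ParameterError(ValueError):
    """Raised for unknown profiles or malformed/incomplete tables."""


@dataclass(frozen=True)
class FoldParameters:
    """Folding conditions.

    temperature : degC, table validity 0-100
    sodium : mol/L monovalent cation (tables referenced to 1.0)
    magnesium : mol/L divalent cation, folded into an effective [Na+]
    dangles : 'd2' applies terminal-stacking (mismatch) terms on both
        sides of every helix end in exterior and multibranch loops;
        'none' drops those terms
    """

    temperature: float = 37.0
    sodium: float = 1.0
    magnesium: float = 0.0
    dangles: str = "d2"

    def __post_init__(self) -> None:
        if not (0.0 <= self.temperature <= 100.0):
            raise ParameterError("temperature outside table validity (0-100 degC)")
        if self.sodium < 0 or self.magnesium < 0:
            raise ParameterError("salt concentrations must be non-negative")
        if self.sodium == 0 and self.magnesium == 0:
            raise ParameterError("at least one cation concentration must be positive")
        if self.dangles not in ("d2", "none"):
            raise ParameterError(f"unknown dangle scheme {self.dangles!r}")

    @property
    def kelvin(self) -> float:
        return self.temperature + 273.15

    def effective_sodium(self) -> float:
        # standard divalent-to-monovalent folding heuristic
        return self.sodium + 3.3 * math.sqrt(self.magnesium)


@dataclass(frozen=True)
class EnergyParameterSet:
    """Raw dG37/dH tables keyed exactly as in the bundled TSV dialect."""

    source: str
    stack: Dict[Tuple[str, str], Tuple[float, float]]
    mismatch: Dict[str, Dict[Tuple[str, str, str], Tuple[float, float]]]
    dangle: Dict[str, Dict[Tuple[str, str], Tuple[float, float]]]
    loops: Dict[str, Tuple[Tuple[float, ...], Tuple[float, ...]]]
    ninio: Tuple[float, float]  # (per-asymmetry, cap), dG37
    multiloop: Dict[str, Tuple[float, float]]  # unpaired/closing/branch
    misc: Dict[str, Tuple[float, float]]
    special_hairpins: Dict[str, Tuple[float, float]]

    def __eq__(self, other: object) -> bool:  # value equality for determinism checks
        if not isinstance(other, EnergyParameterSet):
            return NotImplemented
        return (
            self.stack == other.stack
            and self.mismatch == other.mismatch
            and self.dangle == other.dangle
            and self.loops == other.loops
            and self.ninio == other.ninio
            and self.multiloop == other.multiloop
            and self.misc == other.misc
            and self.special_hairpins == other.special_hairpins
        )


def _parse_value(tok: str) -> float:
    return INF if tok == "INF" else float(tok)


def load_energy_parameters(profile_or_path: str | Path = "dna1999") -> EnergyParameterSet:
    """Load a bundled profile name or a parameter file in the TSV dialect.

    Every Watson-Crick stack, all four mismatch tables, both dangle
    tables and the three loop-initiation tables must be complete;
    anything missing is an error, never a silent zero.
    """
    name = str(profile_or_path)
    if name in BUILTIN_PROFILES:
        path = resources.files("aptevolve.data") / BUILTIN_PROFILES[name]
        text = path.read_text()
        source = name
    else:
        p = Path(profile_or_path)
        if not p.exists():
            raise ParameterError(f"unknown profile or missing file: {profile_or_path!r}")
        text = p.read_text()
        source = str(p)

    stack: Dict[Tuple[str, str], Tuple[float, float]] = {}
    mismatch: Dict[str, Dict] = {k: {} for k in ("tstackh", "tstacki", "mm_multi", "mm_ext")}
    dangle: Dict[str, Dict] = {"dangle5": {}, "dangle3": {}}
    loops: Dict[str, list] = {"hairpin": [INF] * 31, "bulge": [INF] * 31, "internal": [INF] * 31}
    loops_h: Dict[str, list] = {k: [0.0] * 31 for k in loops}
    ninio = {}
    multiloop: Dict[str, Tuple[float, float]] = {}
    misc: Dict[str, Tuple[float, float]] = {}
    special: Dict[str, Tuple[float, float]] = {}

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        term, keys, dg, dh = parts[0], parts[1:-2], _parse_value(parts[-2]), _parse_value(parts[-1])
        if term == "stack":
            stack[(keys[0], keys[1])] = (dg, dh)
        elif term in mismatch:
            mismatch[term][(keys[0], keys[1], keys[2])] = (dg, dh)
        elif term in dangle:
            dangle[term][(keys[0], keys[1])] = (dg, dh)
        elif term in loops:
            loops[term][int(keys[0])] = dg
            loops_h[term][int(keys[0])] = dh
        elif term == "ninio":
            ninio[keys[0]] = dg
        elif term == "multiloop":
            multiloop[keys[0]] = (dg, dh)
        elif term == "misc":
            misc[keys[0]] = (dg, dh)
        elif term in ("triloop", "tetraloop"):
            special[keys[0]] = (dg, dh)
        else:
            raise ParameterError(f"unknown term {term!r} in {source}")

    # completeness checks
    missing = [(a, b) for a in PAIR_NAMES for b in PAIR_NAMES if (a, b) not in stack]
    if missing:
        raise ParameterError(f"incomplete parameter set: missing stacks {missing}")
    for tname, table in mismatch.items():
        if len(table) < len(PAIR_NAMES) * 25:
            raise ParameterError(f"incomplete parameter set: table {tname}")
    for tname, table in dangle.items():
        if len(table) < len(PAIR_NAMES) * 5:
            raise ParameterError(f"incomplete parameter set: table {tname}")
    for tname in loops:
        if all(v == INF for v in loops[tname][3:]):
            raise ParameterError(f"incomplete parameter set: {tname} loop table")
    for key in ("per_asym", "max"):
        if key not in ninio:
            raise ParameterError("incomplete parameter set: ninio terms")
    for key in ("unpaired", "closing", "branch"):
        if key not in multiloop:
            raise ParameterError("incomplete parameter set: multiloop terms")
    for key in ("terminal_at", "lxc"):
        if key not in misc:
            raise ParameterError(f"incomplete parameter set: misc {key}")

    return EnergyParameterSet(
        source=source,
        stack=stack,
        mismatch={k: dict(v) for k, v in mismatch.items()},
        dangle={k: dict(v) for k, v in dangle.items()},
        loops={k: (tuple(loops[k]), tuple(loops_h[k])) for k in loops},
        ninio=(ninio["per_asym"], ninio["max"]),
        multiloop=dict(multiloop),
        misc=dict(misc),
        special_hairpins=dict(special),
    )


def _rescale(dg37: float, dh: float, t_kelvin: float) -> float:
    if dg37 == INF:
        return INF
    return dh - (dh - dg37) * t_kelvin / T37


@dataclass
class EnergyModel:
    """Dense, temperature/salt-adjusted tables for the folding kernels.

    Mismatch tables are indexed ``[pair_type, x, y]`` with x/y the
    neighbouring base + 1 (0 encodes an absent neighbour at a sequence
    terminus).
    """

    stack: np.ndarray          # (4,4)
    tstackh: np.ndarray        # (4,5,5)
    tstacki: np.ndarray
    mm_multi: np.ndarray
    mm_ext: np.ndarray
    dangle5: np.ndarray        # (4,5)
    dangle3: np.ndarray
    hairpin: np.ndarray        # (31,)
    bulge: np.ndarray
    internal: np.ndarray
    ninio_per_asym: float
    ninio_max: float
    ml_unpaired: float
    ml_closing: float
    ml_branch: float
    terminal_at: float
    lxc: float
    special_hairpins: Dict[str, float]
    use_dangles: bool

    @property
    def pair_table(self) -> np.ndarray:
        return PAIR_TABLE

    def at_penalty(self, pair_type: int) -> float:
        return self.terminal_at if pair_type >= 2 else 0.0


def build_energy_model(
    params: FoldParameters | None = None,
    energies: EnergyParameterSet | None = None,
) -> EnergyModel:
    """Rescale a parameter set to concrete folding conditions."""
    params = params or FoldParameters()
    energies = energies or load_energy_parameters()
    tk = params.kelvin

    def arr_mm(table: Dict[Tuple[str, str, str], Tuple[float, float]]) -> np.ndarray:
        out = np.full((4, 5, 5), INF)
        for (p, x, y), (dg, dh) in table.items():
            out[PAIR_INDEX[p], BASE_COL[x], BASE_COL[y]] = _rescale(dg, dh, tk)
        return out

    stack = np.full((4, 4), INF)
    for (p1, p2), (dg, dh) in energies.stack.items():
        stack[PAIR_INDEX[p1], PAIR_INDEX[p2]] = _rescale(dg, dh, tk)

    # per-stack monovalent-salt correction (entropic, zero at 1 M)
    na_eff = params.effective_sodium()
    if na_eff != 1.0:
        stack = stack - tk * 0.000368 * math.log(na_eff)

    d5 = np.full((4, 5), INF)
    d3 = np.full((4, 5), INF)
    for (p, x), (dg, dh) in energies.dangle["dangle5"].items():
        d5[PAIR_INDEX[p], BASE_COL[x]] = _rescale(dg, dh, tk)
    for (p, x), (dg, dh) in energies.dangle["dangle3"].items():
        d3[PAIR_INDEX[p], BASE_COL[x]] = _rescale(dg, dh, tk)

    def arr_loop(name: str) -> np.ndarray:
        dgs, dhs = energies.loops[name]
        return np.array([_rescale(g, h, tk) for g, h in zip(dgs, dhs)])

    special = {
        seq: _rescale(dg, dh, tk) for seq, (dg, dh) in energies.special_hairpins.items()
    }

    return EnergyModel(
        stack=stack,
        tstackh=arr_mm(energies.mismatch["tstackh"]),
        tstacki=arr_mm(energies.mismatch["tstacki"]),
        mm_multi=arr_mm(energies.mismatch["mm_multi"]),
        mm_ext=arr_mm(energies.mismatch["mm_ext"]),
        dangle5=d5,
        dangle3=d3,
        hairpin=arr_loop("hairpin"),
        bulge=arr_loop("bulge"),
        internal=arr_loop("internal"),
        ninio_per_asym=energies.ninio[0],
        ninio_max=energies.ninio[1],
        ml_unpaired=_rescale(*energies.multiloop["unpaired"], tk),
        ml_closing=_rescale(*energies.multiloop["closing"], tk),
        ml_branch=_rescale(*energies.multiloop["branch"], tk),
        terminal_at=_rescale(*energies.misc["terminal_at"], tk),
        lxc=energies.misc["lxc"][0] * tk / T37,
        special_hairpins=special,
        use_dangles=params.dangles == "d2",
    )
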